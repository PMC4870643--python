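"""Displacement models: evaluation, concordance, fitting, selection, looping."""
import math

import numpy as np
import pytest

from fledgemove.geo import GeoPoint, NSDSeries
from fledgemove.nsd import (ModelFit, asymptote_variation, classify_movement,
                            classify_scale, concordance, detect_looping,
                            dispersion_distance, eval_model, fit_model,
                            plausibility_check, select_model)
from fledgemove.simulate import SimConfig, simulate_track

ORIGIN = GeoPoint(52.4, -46.2)


def series(t, nsd):
    return NSDSeries(t=np.asarray(t, float), nsd=np.asarray(nsd, float), origin=ORIGIN)


class TestEvalModel:
    def test_half_migration_inflection_is_half_asymptote(self):
        p = {"delta": 1e6, "theta": 20.0, "phi": 4.0}
        assert eval_model("half_migration", p, [20.0])[0] == pytest.approx(5e5)

    def test_half_migration_asymptote(self):
        p = {"delta": 1e6, "theta": 20.0, "phi": 4.0}
        assert eval_model("half_migration", p, [1e6])[0] == pytest.approx(1e6, rel=1e-9)

    def test_migration_returns_to_zero(self):
        p = {"delta": 1e6, "theta": 20.0, "phi": 4.0, "theta2": 200.0, "phi2": 4.0}
        assert eval_model("migration", p, [1000.0])[0] == pytest.approx(0.0, abs=1e-3)

    def test_migration_requires_ordered_inflections(self):
        p = {"delta": 1e6, "theta": 20.0, "phi": 4.0, "theta2": 10.0, "phi2": 4.0}
        with pytest.raises(ValueError):
            eval_model("migration", p, [1.0])

    def test_nomad_linear(self):
        t = np.arange(0, 90.0)
        np.testing.assert_allclose(eval_model("nomad", {"beta": 5e4}, t), 5e4 * t)

    def test_half_migration_monotone_nondecreasing(self):
        t = np.linspace(0, 300, 500)
        v = eval_model("half_migration", {"delta": 2e6, "theta": 40, "phi": 7}, t)
        assert np.all(np.diff(v) >= 0)

    def test_home_range_saturates(self):
        v = eval_model("home_range", {"kappa": 9e4, "tau": 5.0}, [1e4])
        assert v[0] == pytest.approx(9e4, rel=1e-9)


class TestConcordance:
    def test_perfect(self):
        o = np.array([1.0, 2.0, 3.0])
        assert concordance(o, o) == pytest.approx(1.0)

    def test_shifted_by_one(self):
        # population moments: cov=2/3, var=2/3 each, shift 1 -> 4/7
        assert concordance([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_reversed_is_negative(self):
        assert concordance([1, 2, 3], [3, 2, 1]) < 0

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        o, p = rng.normal(size=30), rng.normal(size=30)
        assert concordance(o, p) == pytest.approx(concordance(p, o), rel=1e-12)

    def test_bounded_by_pearson(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            o = rng.normal(size=25)
            p = 2.0 * o + rng.normal(size=25) + rng.uniform(-3, 3)
            r = np.corrcoef(o, p)[0, 1]
            assert abs(concordance(o, p)) <= abs(r) + 1e-12

    def test_constant_conventions(self):
        assert concordance([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert concordance([2.0, 2.0], [3.0, 3.0]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            concordance([1.0], [1.0])
        with pytest.raises(ValueError):
            concordance([1, 2, np.inf], [1, 2, 3])


class TestFitModel:
    def test_noiseless_half_migration_recovery(self):
        t = np.arange(90.0)
        truth = {"delta": 1e6, "theta": 20.0, "phi": 4.0}
        fit = fit_model(series(t, eval_model("half_migration", truth, t)),
                        "half_migration", seed=0)
        for k, v in truth.items():
            assert fit.params[k] == pytest.approx(v, rel=1e-3)
        assert fit.cc > 0.999999
        assert fit.plausible

    def test_noiseless_nomad_recovery(self):
        t = np.arange(90.0)
        fit = fit_model(series(t, 5e4 * t), "nomad", seed=0)
        assert fit.params["beta"] == pytest.approx(5e4, rel=1e-3)

    def test_noiseless_migration_recovery(self):
        t = np.arange(120.0)
        truth = {"delta": 4e6, "theta": 15.0, "phi": 3.0, "theta2": 80.0, "phi2": 5.0}
        fit = fit_model(series(t, eval_model("migration", truth, t)), "migration", seed=0)
        assert fit.params["delta"] == pytest.approx(4e6, rel=1e-2)
        assert fit.params["theta2"] == pytest.approx(80.0, rel=0.05)

    def test_noisy_delta_recovery_median_under_10pct(self):
        # lognormal multiplicative noise on NSD, 100 seeded replicates
        t = np.arange(90.0)
        truth = {"delta": 1e6, "theta": 20.0, "phi": 4.0}
        clean = eval_model("half_migration", truth, t)
        errs = []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            noisy = clean * np.exp(rng.normal(0.0, 0.2, size=len(t)))
            fit = fit_model(series(t, noisy), "half_migration", seed=rep)
            errs.append(abs(fit.params["delta"] - 1e6) / 1e6)
        assert np.median(errs) < 0.10

    def test_too_few_points_raises(self):
        t = np.arange(5.0)
        with pytest.raises(ValueError):
            fit_model(series(t, t * 100), "nomad")

    def test_deterministic_given_seed(self):
        t = np.arange(0, 90, 1.5)
        rng = np.random.default_rng(9)
        nsd = eval_model("half_migration", {"delta": 5e5, "theta": 15, "phi": 3}, t)
        nsd = nsd * np.exp(rng.normal(0, 0.3, len(t)))
        f1 = fit_model(series(t, nsd), "half_migration", seed=4)
        f2 = fit_model(series(t, nsd), "half_migration", seed=4)
        assert f1.params == f2.params


class TestPlausibility:
    def test_inflection_beyond_track_scale_rejected(self):
        t = np.arange(90.0)
        s = series(t, eval_model("half_migration", {"delta": 1e6, "theta": 20, "phi": 4}, t))
        fit = ModelFit("half_migration", {"delta": 1e6, "theta": 400.0, "phi": 4.0},
                       cc=0.9, plausible=True, residual_sd=0.0)
        assert plausibility_check(fit, s) is False

    def test_asymptote_matching_plateau_accepted(self):
        t = np.arange(90.0)
        truth = {"delta": 1e6, "theta": 20.0, "phi": 4.0}
        s = series(t, eval_model("half_migration", truth, t))
        fit = ModelFit("half_migration", truth, cc=1.0, plausible=True, residual_sd=0.0)
        assert plausibility_check(fit, s) is True

    def test_noiseless_well_specified_fits_all_plausible(self):
        t = np.arange(100.0)
        cases = {
            "home_range": {"kappa": 2e5, "tau": 8.0},
            "nomad": {"beta": 5e4},
            "half_migration": {"delta": 1e6, "theta": 20.0, "phi": 4.0},
            "migration": {"delta": 1e6, "theta": 15.0, "phi": 3.0,
                          "theta2": 70.0, "phi2": 4.0},
        }
        for model, truth in cases.items():
            s = series(t, eval_model(model, truth, t))
            fit = fit_model(s, model, seed=0)
            assert fit.plausible, model

    def test_unsettled_growth_rejected_for_settlement_claim(self):
        # ballistic displacement: NSD keeps accelerating; a logistic fit's
        # settlement claim contradicts the data
        t = np.arange(90.0)
        s = series(t, (350.0 * t) ** 2)
        fit = fit_model(s, "half_migration", seed=0)
        assert fit.plausible is False


class TestSelectModel:
    def _fit(self, model, cc, plausible=True):
        return ModelFit(model, {}, cc=cc, plausible=plausible, residual_sd=0.0)

    def test_highest_concordance_wins(self):
        fits = [self._fit("half_migration", 0.99), self._fit("nomad", 0.80),
                self._fit("home_range", 0.40)]
        assert select_model(fits).model == "half_migration"

    def test_only_implausible_fits_flag_propagates(self):
        fits = [self._fit("nomad", 0.7, False), self._fit("migration", 0.9, False)]
        best = select_model(fits)
        assert best.model == "migration" and best.plausible is False

    def test_implausible_excluded_when_plausible_exists(self):
        fits = [self._fit("migration", 0.99, False), self._fit("nomad", 0.5, True)]
        assert select_model(fits).model == "nomad"

    def test_order_invariance(self):
        import itertools
        fits = [self._fit("half_migration", 0.95), self._fit("migration", 0.97),
                self._fit("nomad", 0.6), self._fit("home_range", 0.95)]
        winners = {select_model(list(p)).model for p in itertools.permutations(fits)}
        assert winners == {"migration"}

    def test_tie_goes_to_parsimony(self):
        fits = [self._fit("migration", 0.95), self._fit("half_migration", 0.95 - 1e-9)]
        assert select_model(fits).model == "half_migration"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_model([])


class TestDetectLooping:
    def test_straight_outbound_false(self, straight_track):
        tr = straight_track(bearing_rad=1.2, speed_kmday=250, duration_days=60)
        from fledgemove.nsd import unwrapped_nsd_series
        assert detect_looping(unwrapped_nsd_series(tr), tr) is False

    def test_simulated_loop_true(self):
        from fledgemove.nsd import unwrapped_nsd_series
        tr, _ = simulate_track(SimConfig(mode="looping", seed=3))
        assert detect_looping(unwrapped_nsd_series(tr), tr) is True

    def test_simulated_half_migration_false(self):
        from fledgemove.nsd import unwrapped_nsd_series
        tr, _ = simulate_track(SimConfig(mode="half_migration", seed=3))
        assert detect_looping(unwrapped_nsd_series(tr), tr) is False


class TestClassifyScale:
    @pytest.mark.parametrize("range_km,expected", [
        (1730.0, "small"),   # sooty albatross mean
        (4117.0, "medium"),  # white-chinned petrel mean
        (23859.0, "large"),  # southern giant petrel mean
        (3000.0, "medium"), (6000.0, "medium"), (6000.1, "large"),
    ])
    def test_bounds(self, range_km, expected):
        assert classify_scale(range_km) == expected

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            classify_scale(-1.0)


class TestDispersionDistance:
    def test_sqrt_delta(self):
        fit = ModelFit("half_migration", {"delta": 25e6, "theta": 1, "phi": 1},
                       cc=1, plausible=True, residual_sd=0)
        assert dispersion_distance(fit) == pytest.approx(5000.0)

    def test_zero(self):
        fit = ModelFit("migration", {"delta": 0.0, "theta": 1, "phi": 1,
                                     "theta2": 2, "phi2": 1},
                       cc=1, plausible=True, residual_sd=0)
        assert dispersion_distance(fit) == 0.0

    def test_not_applicable_for_other_models(self):
        fit = ModelFit("nomad", {"beta": 1e4}, cc=1, plausible=True, residual_sd=0)
        assert dispersion_distance(fit) is None

    def test_adult_simulated_migration_recovery(self):
        # GLS-sampled adult migration settling 5000 km out: sqrt(delta)
        # recovers the settlement distance within 10%
        from fledgemove.nsd import unwrapped_nsd_series
        cfg = SimConfig(mode="migration", seed=8, source="gls", age_class="adult",
                        duration_days=150.0, settlement_distance_km=5000.0,
                        transit_days=20.0)
        tr, _ = simulate_track(cfg)
        from fledgemove.tracks import smooth_track
        s = unwrapped_nsd_series(smooth_track(tr, 3.0))
        fit = fit_model(s, "migration", seed=0)
        assert dispersion_distance(fit) == pytest.approx(5000.0, rel=0.10)


class TestAsymptoteVariation:
    def _fit(self, theta2=None):
        p = {"delta": 16e6, "theta": 10.0, "phi": 2.0}
        if theta2 is not None:
            p.update({"theta2": theta2, "phi2": 2.0})
            return ModelFit("migration", p, cc=1, plausible=True, residual_sd=0)
        return ModelFit("half_migration", p, cc=1, plausible=True, residual_sd=0)

    def test_noiseless_plateau_zero(self):
        t = np.arange(90.0)
        fit = self._fit()
        s = series(t, eval_model("half_migration", fit.params, t))
        assert asymptote_variation(fit, s) == pytest.approx(0.0, abs=1e-6)

    def test_radial_noise_recovered(self):
        t = np.arange(90.0)
        fit = self._fit()
        clean_d = np.sqrt(eval_model("half_migration", fit.params, t))
        ests = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            noisy = (clean_d + rng.normal(0, 300.0, len(t))) ** 2
            ests.append(asymptote_variation(fit, series(t, noisy)))
        assert np.median(ests) == pytest.approx(300.0, rel=0.20)

    def test_empty_plateau_window(self):
        t = np.arange(0, 12.0)
        fit = ModelFit("half_migration", {"delta": 1e6, "theta": 30.0, "phi": 5.0},
                       cc=1, plausible=True, residual_sd=0)
        s = series(t, eval_model("half_migration", fit.params, t) + 1.0)
        assert asymptote_variation(fit, s) is None


class TestClassifyMovement:
    @pytest.mark.parametrize("mode,expected,scale", [
        ("nomad", "nomad", "large"),
        ("half_migration", "half_migration", "medium"),
        ("looping", "large_scale_looping", "small"),
    ])
    def test_phenotype_spot_checks(self, mode, expected, scale):
        tr, _ = simulate_track(SimConfig(mode=mode, seed=2))
        c = classify_movement(tr, seed=0)
        assert c.movement_type == expected
        assert c.scale == scale

    def test_short_track_flagged_partial(self):
        tr, _ = simulate_track(SimConfig(mode="half_migration", seed=4,
                                         duration_days=40.0, transit_days=10.0,
                                         settlement_distance_km=2500.0))
        c = classify_movement(tr, seed=0)
        assert c.partial is True
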