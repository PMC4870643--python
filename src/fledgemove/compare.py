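"""Group comparisons: mixed models with Tukey contrasts, and rank-sum tests.

Species (or other group) effects on per-period trajectory metrics are
tested with a linear mixed model — ``response ~ group + period`` with a
per-individual random intercept, absorbing repeated measures — followed by
all pairwise Tukey-adjusted contrasts (studentized-range family
correction).  Juvenile-vs-adult latitude differences use the two-sided
Wilcoxon rank-sum test on per-individual means, exact for small samples.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ContrastResult", "compare_groups", "compare_age_latitude"]


@dataclass
class ContrastResult:
    """One pairwise group contrast with a family-wise adjusted p-value."""

    group_a: str
    group_b: str
    estimate: float  # mean(group_a) - mean(group_b), response units
    se: float
    p_raw: float
    adjusted_p: float
    method: str  # "lmm_tukey" | "means_tukey_hsd"


def _tukey_adjust(t_stat: float, k: int, df: float, p_raw: float) -> float:
    """Family-wise p from the studentized range; never below the raw p."""
    q = abs(t_stat) * np.sqrt(2.0)
    p = float(stats.studentized_range.sf(q, k, max(df, 2.0)))
    return float(np.clip(max(p, p_raw), 0.0, 1.0))


def compare_groups(table: pd.DataFrame, response: str, group: str = "species_code",
                   individual: str = "individual_id", period: str = "period_index",
                   ) -> list[ContrastResult]:
    """All pairwise group contrasts on a per-period metric.

    Fits ``response ~ C(group) + C(period)`` with a random intercept per
    individual (statsmodels MixedLM) and returns every pairwise difference
    of group means with Tukey (studentized-range) adjusted p-values.  When
    the mixed fit is singular or degenerate the comparison falls back to a
    one-way Tukey HSD on per-individual means, flagged in ``method``.

    Raises
    ------
    ValueError
        With fewer than two groups or fewer than two individuals per group.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[response, group, individual, period]].dropna().copy()
    df.columns = ["y", "g", "ind", "per"]
    levels = sorted(df["g"].unique().astype(str))
    if len(levels) < 2:
        raise ValueError("need at least two groups to compare")
    per_group_n = df.groupby("g")["ind"].nunique()
    if (per_group_n < 2).any():
        raise ValueError("need at least two individuals per group")
    k = len(levels)

    def _fallback() -> list[ContrastResult]:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        means = df.groupby(["ind", "g"], observed=True)["y"].mean().reset_index()
        res = pairwise_tukeyhsd(means["y"], means["g"].astype(str))
        out = []
        for row in res.summary().data[1:]:
            # rows are (group1, group2, mean(group2)-mean(group1), p-adj, ...)
            a, b, diff, p_adj = str(row[0]), str(row[1]), float(row[2]), float(row[3])
            out.append(ContrastResult(a, b, -diff, np.nan, p_adj, p_adj,
                                      "means_tukey_hsd"))
        return out

    if df.groupby("ind").size().max() <= 1:
        # one observation per individual: the random intercept is confounded
        # with the residual, so compare individual means directly
        logger.warning("singular design (<=1 obs/individual); using means")
        return _fallback()

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ C(g) + C(per)", df, groups=df["ind"])
            fit = model.fit(reml=True)
        if not np.all(np.isfinite(fit.bse_fe)):
            raise np.linalg.LinAlgError("non-finite standard errors")
    except Exception as exc:
        logger.warning("mixed model failed (%s); falling back to individual means", exc)
        return _fallback()

    # contrast vectors on the fixed-effect coefficients (treatment coding)
    names = list(fit.model.exog_names)
    cov = fit.cov_params().loc[names, names].to_numpy()
    beta = fit.fe_params.to_numpy()

    def group_vec(level: str) -> np.ndarray:
        v = np.zeros(len(names))
        col = f"C(g)[T.{level}]"
        if col in names:
            v[names.index(col)] = 1.0
        return v

    df_resid = max(len(df) - len(names) - 1, 2)
    results = []
    for a, b in itertools.combinations(levels, 2):
        c = group_vec(a) - group_vec(b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        if se == 0 or not np.isfinite(se):
            return _fallback()
        t = est / se
        p_raw = float(2.0 * stats.t.sf(abs(t), df_resid))
        results.append(ContrastResult(a, b, est, se, p_raw,
                                      _tukey_adjust(t, k, df_resid, p_raw), "lmm_tukey"))
    return results


def compare_age_latitude(juvenile_means, adult_means) -> tuple[float, int]:
    """Two-sided Wilcoxon rank-sum test on per-individual mean latitudes.

    Exact null distribution when the combined sample size is at most 20 and
    there are no ties, otherwise the normal approximation with tie and
    continuity correction.  Returns ``(p, direction)`` with direction +1
    when juveniles sit at higher latitude values than adults, -1 when
    lower, 0 when tied.

    Raises
    ------
    ValueError
        With fewer than 3 individuals in either age class.
    """
    juv = np.asarray(juvenile_means, dtype=float)
    adu = np.asarray(adult_means, dtype=float)
    if len(juv) < 3 or len(adu) < 3:
        raise ValueError("need >= 3 individuals per age class")
    if np.all(juv[0] == np.concatenate([juv, adu])):
        return 1.0, 0
    combined = np.concatenate([juv, adu])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(juv, adu, alternative="two-sided", method=method,
                             use_continuity=True)
    direction = int(np.sign(res.statistic - len(juv) * len(adu) / 2.0))
    return float(res.pvalue), direction
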