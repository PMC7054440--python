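"""Learning-effect evaluation on the estimated skill trajectories.

The program's effectiveness is judged on the *non-masters*: persons whose
estimated initial profile lacks at least one of the four skills.  Their
testing-module scores are compared pre/post by a paired t test with effect
size r = sqrt(t^2 / (t^2 + df)); per-skill mastery rates at the first and
last time point are compared by McNemar's paired-proportion chi-square
(continuity corrected) with Cohen's h = |2 asin(sqrt(p2)) - 2 asin(sqrt(p1))|;
and trajectories are summarized by ability quartile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar

from .data_model import K, SKILLS

__all__ = [
    "identify_non_masters",
    "paired_pre_post",
    "effect_size_r",
    "cohens_h",
    "mastery_change_test",
    "rate_change_summary",
    "ability_group_trajectories",
]


def identify_non_masters(map_alpha: np.ndarray, person_ids=None) -> np.ndarray:
    """IDs of persons whose MAP initial profile is not the full master (1,1,1,1)."""
    map_alpha = np.asarray(map_alpha)
    if person_ids is None:
        person_ids = np.arange(1, map_alpha.shape[0] + 1)
    non_master = map_alpha[:, :, 0].sum(axis=1) < map_alpha.shape[1]
    return np.asarray(person_ids)[non_master]


def effect_size_r(t: float, df: int) -> float:
    """Paired-t effect size r = sqrt(t^2 / (t^2 + df))."""
    return float(np.sqrt(t**2 / (t**2 + df)))


def paired_pre_post(scores_pre, scores_post):
    """Paired t test of post vs pre scores with effect size r.

    Returns (t, df, p, r); t > 0 means the post scores are higher.
    """
    pre = np.asarray(scores_pre, dtype=float)
    post = np.asarray(scores_post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("paired score vectors of equal length >= 2 required")
    if np.var(post - pre) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(post, pre)
    df = pre.size - 1
    return float(res.statistic), df, float(res.pvalue), effect_size_r(res.statistic, df)


def cohens_h(rate1: float, rate2: float) -> float:
    """Arcsine effect size for two proportions, reported as a magnitude."""
    return float(abs(2 * np.arcsin(np.sqrt(rate2)) - 2 * np.arcsin(np.sqrt(rate1))))


def rate_change_summary(rate1: float, rate2: float) -> dict:
    """Pure-arithmetic layer of a mastery-rate row: difference and Cohen's h."""
    return {
        "rate_t1": rate1,
        "rate_t4": rate2,
        "difference": rate2 - rate1,
        "cohens_h": cohens_h(rate1, rate2),
    }


def mastery_change_test(alpha_t1: np.ndarray, alpha_t4: np.ndarray) -> pd.DataFrame:
    """Per-skill mastery-rate change between the first and last time point.

    ``alpha_t1``/``alpha_t4`` are (N, K) binary mastery indicators.  The
    paired-proportion test is McNemar's chi-square on the discordant cells
    with continuity correction; no discordant pairs gives p = 1.
    """
    a1 = np.asarray(alpha_t1)
    a4 = np.asarray(alpha_t4)
    if a1.shape != a4.shape:
        raise ValueError("paired mastery arrays must share a shape")
    rows = []
    for k in range(a1.shape[1]):
        r1, r4 = float(a1[:, k].mean()), float(a4[:, k].mean())
        b = int(((a1[:, k] == 1) & (a4[:, k] == 0)).sum())
        c = int(((a1[:, k] == 0) & (a4[:, k] == 1)).sum())
        if b + c == 0:
            warnings.warn(f"skill {k}: no discordant pairs; p set to 1")
            p = 1.0
        else:
            table = [[int(((a1[:, k] == 1) & (a4[:, k] == 1)).sum()), b],
                     [c, int(((a1[:, k] == 0) & (a4[:, k] == 0)).sum())]]
            p = float(mcnemar(table, exact=False, correction=True).pvalue)
        rows.append({
            "skill": SKILLS[k] if k < len(SKILLS) else f"skill_{k}",
            **rate_change_summary(r1, r4),
            "p_value": p,
        })
    return pd.DataFrame(rows)


def ability_group_trajectories(theta, map_alpha, n_groups: int = 4):
    """Mean mastered-skill counts over time by ability quantile group.

    ``theta`` holds posterior-mean abilities for the analyzed subset,
    ``map_alpha`` their (N, K, T) MAP trajectories.  Quantile cutpoints
    use type-7 (linear interpolation) sample quantiles.  Returns
    (group x time mean table, cutpoints).
    """
    theta = np.asarray(theta, dtype=float)
    map_alpha = np.asarray(map_alpha)
    n = theta.size
    if n < n_groups:
        raise ValueError("fewer persons than groups")
    cuts = np.quantile(theta, np.arange(1, n_groups) / n_groups)
    if np.unique(cuts).size < cuts.size or np.all(theta == theta[0]):
        warnings.warn("degenerate ability quantiles; grouping collapses")
    group = np.searchsorted(cuts, theta, side="right")
    counts = map_alpha.sum(axis=1)  # (N, T)
    t_len = counts.shape[1]
    table = pd.DataFrame(
        [
            {
                "group": gi + 1,
                "n": int((group == gi).sum()),
                **{f"t{t + 1}": (float(counts[group == gi, t].mean())
                                 if (group == gi).any() else np.nan)
                   for t in range(t_len)},
            }
            for gi in range(n_groups)
        ]
    )
    return table, cuts
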