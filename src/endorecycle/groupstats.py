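"""Statistical layer for grouped per-cell traces and experiment means.

The central procedure is the time-of-divergence scan: pooled per-cell values
of two conditions are compared with a two-sided Wilcoxon rank-sum test at
every timepoint, and the divergence time is the first timepoint after which
all subsequent p-values stay at or below the significance level. Because the
cell counts in these assays are small (3–7 per group per experiment), the
rank-sum p-value is computed by exact permutation enumeration for combined
n <= 16 and by the tie- and continuity-corrected normal approximation above
that.

Also here: the ANCOVA-style slope comparison (group x time interaction), the
one-sample t-test against a normalised mean of 100 %, the unpaired two-sample
t-test of experiment means, and the two-sided variance F-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .core import IntensityTrace

__all__ = [
    "DivergenceResult",
    "rank_sum_test",
    "time_of_divergence",
    "compare_slopes",
    "one_sample_t_norm100",
    "two_sample_t",
    "variance_f_test",
]

EXACT_MAX_N = 16  # combined sample size up to which the rank-sum test is exact


@dataclass
class DivergenceResult:
    times_s: np.ndarray
    p_values: np.ndarray
    alpha: float
    divergence_time_s: float | None  # None = "no divergence"
    test: str = "wilcoxon-rank-sum"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        if self.divergence_time_s is not None and self.divergence_time_s not in self.times_s:
            raise ValueError("divergence time must be one of the tested timepoints")


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation enumeration of the rank-sum statistic (midranks, so
    ties are handled) when len(a) + len(b) <= EXACT_MAX_N, otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    w_obs = ranks[:n1].sum()

    if n1 + n2 <= EXACT_MAX_N:
        n = n1 + n2
        sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), n1)])
        total = comb(n, n1)
        # two-sided: double the smaller tail (tail probabilities include w_obs)
        eps = 1e-9
        p_lo = float((sums <= w_obs + eps).sum()) / total
        p_hi = float((sums >= w_obs - eps).sum()) / total
        return min(2.0 * min(p_lo, p_hi), 1.0)

    mu = n1 * (n1 + n2 + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return float(2.0 * sps.norm.sf(z))


def _pooled_by_timepoint(traces: list[IntensityTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Stack traces sharing a common time grid into (times, values[cell, t])."""
    times = traces[0].times_s
    for tr in traces[1:]:
        if len(tr.times_s) != len(times) or not np.allclose(tr.times_s, times):
            raise ValueError("traces must share a common time grid")
    return times, np.vstack([tr.values for tr in traces])


def time_of_divergence(
    group_a: list[IntensityTrace],
    group_b: list[IntensityTrace],
    alpha: float = 0.05,
) -> DivergenceResult:
    """Per-timepoint rank-sum comparison of two groups of traces.

    The divergence time is the earliest timepoint T with p(t) <= alpha for
    every t >= T (including the final timepoint); ``divergence_time_s`` is
    None when no such T exists.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 traces per group")
    times, va = _pooled_by_timepoint(group_a)
    times_b, vb = _pooled_by_timepoint(group_b)
    if len(times) != len(times_b) or not np.allclose(times, times_b):
        raise ValueError("groups must share a common time grid")

    p = np.ones(len(times))
    for i in range(len(times)):
        ai = va[:, i][np.isfinite(va[:, i])]
        bi = vb[:, i][np.isfinite(vb[:, i])]
        if len(ai) < 2 or len(bi) < 2:
            p[i] = 1.0
            continue
        p[i] = rank_sum_test(ai, bi)

    sig = p <= alpha
    div_time: float | None = None
    # suffix scan: earliest T with all subsequent p significant
    ok = True
    for i in range(len(times) - 1, -1, -1):
        ok = ok and sig[i]
        if ok:
            div_time = float(times[i])
        else:
            break
    return DivergenceResult(times_s=times, p_values=p, alpha=alpha, divergence_time_s=div_time)


def compare_slopes(
    points_a: tuple[np.ndarray, np.ndarray], points_b: tuple[np.ndarray, np.ndarray]
) -> float:
    """Two-sided p-value for a slope difference between two (t, y) point sets.

    Pooled OLS with group indicator, time, and group x time interaction; the
    returned p is that of the interaction coefficient (the classic
    equal-slopes ANCOVA test). Identical groups give p = 1.
    """
    ta, ya = (np.asarray(v, dtype=float) for v in points_a)
    tb, yb = (np.asarray(v, dtype=float) for v in points_b)
    if len(ta) < 3 or len(tb) < 3:
        raise ValueError("need >= 3 points per group")
    t = np.concatenate([ta, tb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    X = np.column_stack([np.ones_like(t), t, g, g * t])
    n, k = X.shape
    if n <= k:
        raise ValueError("too few points for the interaction model")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("degenerate design (collinear time values)")
    resid = y - X @ beta
    df = n - k
    s2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[3, 3])
    if se < 1e-14:
        scale = max(1.0, abs(beta[1]))
        return 1.0 if abs(beta[3]) < 1e-10 * scale else 0.0
    tstat = beta[3] / se
    return float(2.0 * sps.t.sf(abs(tstat), df))


def one_sample_t_norm100(values: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample t-test of percent values against 100 %.

    Zero variance at exactly 100 gives (0, 1); zero variance elsewhere gives
    (inf-signed t, p=0), flagged degenerate by the infinite statistic.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need n >= 2")
    sd = values.std(ddof=1)
    mean = values.mean()
    if sd == 0:
        if mean == 100.0:
            return 0.0, 1.0
        return float(np.sign(mean - 100.0) * np.inf), 0.0
    t = (mean - 100.0) / (sd / np.sqrt(len(values)))
    p = float(2.0 * sps.t.sf(abs(t), len(values) - 1))
    return float(t), p


def two_sample_t(
    means_a: np.ndarray, means_b: np.ndarray, *, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided unpaired t-test of per-experiment means (Student's form by
    default, Welch with ``equal_var=False``)."""
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):  # both groups constant and equal
        return 0.0, 1.0
    return float(t), float(p)


def variance_f_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test comparing variances: F = larger s² / smaller s²,
    p = 2 · P(F_df ≥ F) capped at 1. Symmetric in group order."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    if np.isinf(f):
        return float("inf"), 0.0
    p = min(2.0 * float(sps.f.sf(f, dfn, dfd)), 1.0)
    return float(f), p
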