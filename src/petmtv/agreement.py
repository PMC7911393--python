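"""Inter-observer agreement statistics and between-method comparison.

Implements the two-reader agreement machinery: consistency ICC from the
two-way ANOVA decomposition, Kendall's tau-b, BCa bootstrap confidence
intervals with patient-level resampling, a joint bootstrap comparison of
agreement coefficients across methods with Hochberg-corrected p-values, and
Bland-Altman bias / limits-of-agreement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AgreementResult",
    "PairwiseComparison",
    "BlandAltmanResult",
    "icc_consistency",
    "kendall_tau_b",
    "bca_ci",
    "compare_agreement",
    "hochberg_adjust",
    "bland_altman",
    "evaluator_mean_difference",
    "relative_difference_percent",
]


def _as_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"paired series must have shape (n, 2), got {arr.shape}")
    if arr.shape[0] < 3:
        raise ValueError(f"need n >= 3 pairs, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("paired series contains non-finite values")
    return arr


def _icc_consistency_nd(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """ICC(3,1) along the last axis; broadcasts over leading axes."""
    n = x1.shape[-1]
    row_mean = 0.5 * (x1 + x2)
    grand = row_mean.mean(axis=-1, keepdims=True)
    ss_rows = 2.0 * ((row_mean - grand) ** 2).sum(axis=-1)
    ss_cols = n * ((x1.mean(axis=-1, keepdims=True) - grand) ** 2
                   + (x2.mean(axis=-1, keepdims=True) - grand) ** 2).sum(axis=-1)
    ss_tot = ((x1 - grand) ** 2 + (x2 - grand) ** 2).sum(axis=-1)
    ss_err = np.clip(ss_tot - ss_rows - ss_cols, 0.0, None)
    msr = ss_rows / (n - 1)
    mse = ss_err / (n - 1)  # (n-1)(k-1) with k = 2 raters
    denom = msr + mse
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (msr - mse) / denom, np.nan)


def icc_consistency(pairs) -> float:
    """Two-way mixed, single-rater, consistency ICC — ICC(3,1).

    Computed from the two-way ANOVA mean squares: ``(MSR - MSE) /
    (MSR + (k-1) MSE)`` with k = 2 raters.  Invariant to adding a constant
    to either observer's series.
    """
    arr = _as_pairs(pairs)
    row_mean = arr.mean(axis=1)
    if np.ptp(row_mean) < 1e-12 * max(1.0, float(np.abs(row_mean).max())):
        raise ValueError("degenerate series: no between-patient variance")
    return float(_icc_consistency_nd(arr[:, 0], arr[:, 1]))


def kendall_tau_b(pairs) -> float:
    """Kendall's tau-b rank correlation with tie correction."""
    arr = _as_pairs(pairs)
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("degenerate series: all values tied in one observer")
    return float(stats.kendalltau(arr[:, 0], arr[:, 1], variant="b").statistic)


@dataclass
class AgreementResult:
    coefficient: str  # "icc" | "tau"
    estimate: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95
    n_boot: int = 10000
    flags: dict = field(default_factory=dict)


def bca_ci(statistic: Callable[[np.ndarray], float], data,
           n_boot: int = 10000, level: float = 0.95, seed: int = 0,
           max_undefined_frac: float = 0.01) -> tuple[float, float, dict]:
    """Bias-corrected and accelerated bootstrap CI with row resampling.

    ``data`` is an (n, ...) array whose rows (patients) are resampled with
    replacement.  The bias correction z0 comes from the proportion of
    bootstrap replicates below the point estimate; the acceleration from the
    jackknife.  A degenerate bootstrap distribution collapses the CI to the
    point estimate with a flag.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need n >= 3 for bootstrap resampling")
    theta = float(statistic(data))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps[b] = statistic(data[idx])
        except (ValueError, ZeroDivisionError):
            reps[b] = np.nan
    bad = int(np.isnan(reps).sum())
    if bad > max_undefined_frac * n_boot:
        raise ValueError(f"statistic undefined on {bad}/{n_boot} bootstrap replicates")
    reps = reps[~np.isnan(reps)]
    flags: dict = {"n_undefined": bad}
    if np.ptp(reps) < 1e-12:
        flags["degenerate"] = True
        return theta, theta, flags

    alpha = 1.0 - level
    prop = np.mean(reps < theta) + 0.5 * np.mean(reps == theta)
    prop = min(max(prop, 1.0 / (len(reps) + 1)), len(reps) / (len(reps) + 1.0))
    z0 = stats.norm.ppf(prop)
    jack = np.empty(n)
    for i in range(n):
        jack[i] = statistic(np.delete(data, i, axis=0))
    jmean = jack.mean()
    num = ((jmean - jack) ** 3).sum()
    den = 6.0 * (((jmean - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0

    def adj(q):
        z = stats.norm.ppf(q)
        return stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))

    lo = float(np.quantile(reps, adj(alpha / 2.0)))
    hi = float(np.quantile(reps, adj(1.0 - alpha / 2.0)))
    return lo, hi, flags


def agreement_with_ci(pairs, coefficient: str = "icc", n_boot: int = 10000,
                      level: float = 0.95, seed: int = 0) -> AgreementResult:
    """Point estimate plus BCa CI for one method's paired series."""
    stat = icc_consistency if coefficient == "icc" else kendall_tau_b
    arr = _as_pairs(pairs)
    lo, hi, flags = bca_ci(stat, arr, n_boot=n_boot, level=level, seed=seed)
    return AgreementResult(coefficient=coefficient, estimate=float(stat(arr)),
                           ci_lower=lo, ci_upper=hi, level=level, n_boot=n_boot,
                           flags=flags)


@dataclass
class PairwiseComparison:
    method_a: str
    method_b: str
    delta: float
    ci_lower: float
    ci_upper: float
    p_raw: float
    p_hochberg: float = float("nan")


def hochberg_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-up Hochberg adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return []
    return list(multipletests(p, method="simes-hochberg")[1])


def compare_agreement(pairs_by_method: dict[str, np.ndarray],
                      coefficient: str = "icc", n_boot: int = 10000,
                      level: float = 0.95, seed: int = 0) -> list[PairwiseComparison]:
    """Joint patient-level bootstrap comparison of agreement coefficients.

    One patient resample per replicate drives every method, preserving the
    cross-method correlation of the paired series.  For each method pair the
    difference of coefficients is summarised by a percentile CI and a
    two-sided bootstrap p-value ``2 * min(P(d* <= 0), P(d* >= 0))`` with a
    +1 continuity correction; Hochberg correction is applied across all
    pairs of the family.
    """
    names = list(pairs_by_method)
    arrays = {m: _as_pairs(v) for m, v in pairs_by_method.items()}
    n_set = {a.shape[0] for a in arrays.values()}
    if len(n_set) != 1:
        raise ValueError("unaligned series: all methods must cover the same patients")
    n = n_set.pop()
    stat = icc_consistency if coefficient == "icc" else kendall_tau_b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    coefs = np.empty((n_boot, len(names)))
    if coefficient == "icc":
        for j, m in enumerate(names):
            x1 = arrays[m][:, 0][idx]
            x2 = arrays[m][:, 1][idx]
            coefs[:, j] = _icc_consistency_nd(x1, x2)
    else:
        for j, m in enumerate(names):
            arr = arrays[m]
            for b in range(n_boot):
                sub = arr[idx[b]]
                coefs[b, j] = stats.kendalltau(sub[:, 0], sub[:, 1], variant="b").statistic
    point = {m: float(stat(arrays[m])) for m in names}

    alpha = 1.0 - level
    comparisons: list[PairwiseComparison] = []
    for i, ma in enumerate(names):
        for j, mb in enumerate(names):
            if j <= i:
                continue
            d = coefs[:, i] - coefs[:, j]
            d = d[np.isfinite(d)]
            b_eff = len(d)
            p = 2.0 * min((1 + np.sum(d <= 0)) / (b_eff + 1),
                          (1 + np.sum(d >= 0)) / (b_eff + 1))
            comparisons.append(PairwiseComparison(
                method_a=ma, method_b=mb, delta=point[ma] - point[mb],
                ci_lower=float(np.quantile(d, alpha / 2)),
                ci_upper=float(np.quantile(d, 1 - alpha / 2)),
                p_raw=float(min(p, 1.0))))
    adjusted = hochberg_adjust([c.p_raw for c in comparisons])
    for comp, padj in zip(comparisons, adjusted):
        comp.p_hochberg = float(padj)
    return comparisons


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    points: np.ndarray            # (n, 2): per-patient (mean, difference)
    outside_limits: list[int]
    flags: dict = field(default_factory=dict)


def bland_altman(pairs) -> BlandAltmanResult:
    """Bias and 95% limits of agreement between the two observers.

    Differences are observer 1 minus observer 2; limits are bias +/- 1.96 SD
    with normal-theory CIs (SE(bias) = SD/sqrt(n), SE(limit) =
    SD*sqrt(3/n)).
    """
    arr = _as_pairs(pairs)
    d = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    n = len(d)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = bias - 1.96 * sd
    hi = bias + 1.96 * sd
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    outside = [i for i in range(n) if d[i] < lo or d[i] > hi]
    flags = {}
    if sd == 0:
        flags["degenerate"] = True
    return BlandAltmanResult(
        bias=bias, sd=sd, loa_lower=lo, loa_upper=hi,
        bias_ci=(bias - 1.96 * se_bias, bias + 1.96 * se_bias),
        loa_lower_ci=(lo - 1.96 * se_loa, lo + 1.96 * se_loa),
        loa_upper_ci=(hi - 1.96 * se_loa, hi + 1.96 * se_loa),
        points=np.column_stack([means, d]), outside_limits=outside, flags=flags)


def evaluator_mean_difference(means_by_method: dict[str, tuple[float, float]]
                              ) -> dict[str, float]:
    """Absolute difference of the two observers' mean MTVs per method,
    reported to one decimal (cm^3)."""
    return {m: round(abs(m1 - m2), 1) for m, (m1, m2) in means_by_method.items()}


def relative_difference_percent(v1: float, v2: float) -> int:
    """Relative difference of two volumes, rounded to the nearest percent."""
    if v1 == 0:
        raise ValueError("reference volume must be non-zero")
    return int(round(100.0 * (v1 - v2) / v1))
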