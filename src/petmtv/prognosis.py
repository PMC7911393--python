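"""Cut-off determination, survival estimation and classification accounting.

Five-year administrative censoring, empirical ROC with a Youden-index
optimal MTV cut-off, Kaplan-Meier curves with Greenwood variance, the
log-rank test, multivariate Cox proportional-hazards fits (Efron ties, with
a Breslow option), reverse-KM median follow-up, and the bookkeeping of how
observer-specific cut-offs reclassify patients between the low- and
high-MTV groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score

__all__ = [
    "ROCResult",
    "CoxFit",
    "CoxRow",
    "KMResult",
    "censor_at",
    "pfs_event_at_horizon",
    "roc_optimal_cutoff",
    "km_curve",
    "log_rank",
    "cox_fit",
    "reverse_km_median_followup",
    "cutoff_disagreement",
    "classification_disagreement",
]


def censor_at(times, events, horizon: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring: times beyond the horizon become
    (horizon, censored)."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    times = np.asarray(times, dtype=float).copy()
    events = np.asarray(events, dtype=int).copy()
    late = times > horizon
    times[late] = horizon
    events[late] = 0
    return times, events


def pfs_event_at_horizon(times, events, horizon: float = 5.0
                         ) -> tuple[np.ndarray, np.ndarray, int]:
    """Binary outcome "event by the horizon" for ROC construction.

    Patients censored event-free before the horizon carry no 5-year label
    and are excluded; the exclusion count is returned for logging.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    had_event = (events == 1) & (times <= horizon)
    event_free = times >= horizon
    evaluable = had_event | event_free
    outcome = had_event.astype(int)
    return outcome[evaluable], evaluable, int((~evaluable).sum())


@dataclass
class ROCResult:
    auc: float
    cutoff_cm3: float
    sensitivity_pct: float
    specificity_pct: float
    source: str = "mean-of-observers"
    n_excluded: int = 0


def roc_optimal_cutoff(mtv, outcome, source: str = "mean-of-observers",
                       n_excluded: int = 0) -> ROCResult:
    """Empirical ROC of the rule "MTV >= cut-off predicts the event".

    The optimal cut-off maximises Youden's J = Se + Sp - 1 over all observed
    MTV values, ties broken toward the larger cut-off; AUC by the
    trapezoidal rule (rank-equivalent).
    """
    mtv = np.asarray(mtv, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if mtv.shape != outcome.shape:
        raise ValueError("MTV and outcome must be aligned")
    pos = outcome == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present for ROC analysis")
    auc = float(roc_auc_score(outcome, mtv))
    best = (-np.inf, -np.inf, 0.0, 0.0)  # (J, cutoff, Se, Sp)
    for c in np.unique(mtv):
        se = float(np.mean(mtv[pos] >= c))
        sp = float(np.mean(mtv[~pos] < c))
        j = se + sp - 1.0
        if j > best[0] or (j == best[0] and c > best[1]):
            best = (j, float(c), se, sp)
    return ROCResult(auc=auc, cutoff_cm3=best[1], sensitivity_pct=100.0 * best[2],
                     specificity_pct=100.0 * best[3], source=source,
                     n_excluded=n_excluded)


@dataclass
class KMResult:
    """Product-limit curve evaluated at the event times, with Greenwood
    variance, plus the fitted lifelines estimator for plotting."""

    event_times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    fitter: KaplanMeierFitter = field(repr=False)

    def survival_at(self, t: float) -> float:
        return float(self.fitter.predict(t))

    def survival_pct_at(self, t: float) -> float:
        return 100.0 * self.survival_at(t)

    @property
    def median(self) -> float:
        return float(self.fitter.median_survival_time_)


def km_curve(times, events) -> KMResult:
    """Kaplan-Meier estimator with Greenwood variance at the event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    observed = table["observed"].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    t_all = table.index.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > observed,
                         observed / (at_risk * (at_risk - observed)), np.inf)
    s_all = kmf.survival_function_["KM_estimate"].to_numpy()
    greenwood = s_all**2 * np.cumsum(np.where(np.isfinite(terms), terms, 0.0))
    keep = observed > 0
    return KMResult(event_times=t_all[keep], survival=s_all[keep],
                    variance=greenwood[keep], fitter=kmf)


def log_rank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxRow:
    covariate: str
    coefficient: float
    se: float
    hr: float
    ci_lower: float
    ci_upper: float
    p: float


@dataclass
class CoxFit:
    rows: list[CoxRow]

    def __getitem__(self, covariate: str) -> CoxRow:
        for row in self.rows:
            if row.covariate == covariate:
                return row
        raise KeyError(covariate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows]).set_index("covariate")


def cox_fit(sample: pd.DataFrame, covariates: list[str],
            duration_col: str = "time_years", event_col: str = "event",
            ties: str = "efron") -> CoxFit:
    """Multivariate Cox proportional-hazards fit.

    Efron tie handling by default (ties are common in discretised synthetic
    times); ``ties="breslow"`` is available behind the flag.  Raises on no
    events, constant covariates, or non-convergence (e.g. monotone
    likelihood under complete separation).
    """
    if sample[event_col].sum() < 1:
        raise ValueError("no events: Cox model is not estimable")
    for cov in covariates:
        if sample[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant across patients")
    df = sample[[duration_col, event_col, *covariates]]
    if ties == "efron":
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except Exception as exc:
            raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
        summary = cph.summary
        rows = [CoxRow(covariate=cov,
                       coefficient=float(summary.loc[cov, "coef"]),
                       se=float(summary.loc[cov, "se(coef)"]),
                       hr=float(summary.loc[cov, "exp(coef)"]),
                       ci_lower=float(np.exp(summary.loc[cov, "coef"]
                                             - 1.96 * summary.loc[cov, "se(coef)"])),
                       ci_upper=float(np.exp(summary.loc[cov, "coef"]
                                             + 1.96 * summary.loc[cov, "se(coef)"])),
                       p=float(summary.loc[cov, "p"]))
                for cov in covariates]
        return CoxFit(rows=rows)
    if ties == "breslow":
        import statsmodels.duration.hazard_regression as hz

        model = hz.PHReg(df[duration_col], df[covariates],
                         status=df[event_col], ties="breslow")
        try:
            res = model.fit()
        except Exception as exc:
            raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
        rows = []
        for k, cov in enumerate(covariates):
            coef, se = float(res.params[k]), float(res.bse[k])
            rows.append(CoxRow(covariate=cov, coefficient=coef, se=se,
                               hr=float(np.exp(coef)),
                               ci_lower=float(np.exp(coef - 1.96 * se)),
                               ci_upper=float(np.exp(coef + 1.96 * se)),
                               p=float(res.pvalues[k])))
        return CoxFit(rows=rows)
    raise ValueError(f"unknown tie handling {ties!r}")


def reverse_km_median_followup(times, events) -> tuple[float, bool]:
    """Median follow-up by reverse Kaplan-Meier (censoring as the event).

    Returns ``(median_years, reached)``; when the median is not reached the
    longest observed time is returned as an upper bound with
    ``reached=False``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, 1 - events)
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        return float(times.max()), False
    return median, True


def cutoff_disagreement(cutoff_1: float, cutoff_2: float) -> float:
    """Absolute difference of the two evaluator-specific cut-offs, cm^3."""
    if cutoff_1 <= 0 or cutoff_2 <= 0:
        raise ValueError("cut-offs must be > 0")
    return abs(cutoff_1 - cutoff_2)


def classification_disagreement(mtv_obs1, mtv_obs2,
                                cutoff_1: float, cutoff_2: float) -> int:
    """Absolute difference in the number of patients classified low-MTV by
    each evaluator (each under that evaluator's own cut-off)."""
    a = np.asarray(mtv_obs1, dtype=float)
    b = np.asarray(mtv_obs2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unaligned patient lists")
    return int(abs(int((a < cutoff_1).sum()) - int((b < cutoff_2).sum())))
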