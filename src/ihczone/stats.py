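"""Cohort-level statistics: rank tests, Q3 dichotomization, survival analysis.

Continuous morphometric biomarkers are related to binary prognostic factors
with rank tests, split at their third quartile (high = value >= Q3) for
Kaplan-Meier / log-rank analysis, and entered into a Cox proportional-hazards
model pruned by backward Wald elimination. The rank statistics are computed
from the rank formulas directly; the product-limit estimator, the log-rank
test and the Cox partial likelihood are delegated to lifelines (Efron tie
handling), with the elimination loop and reporting implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "DichotomyResult",
    "MannWhitneyResult",
    "KaplanMeierResult",
    "SurvivalFit",
    "CoxResult",
    "CoxBackwardModel",
    "q3_dichotomize",
    "mann_whitney",
    "kruskal_wallis",
    "km_estimate",
    "logrank",
    "km_logrank",
    "cox_backward",
]

ALPHA_SIGNIFICANT = 0.05
Z_95 = 1.96  # normal quantile used for the reported hazard-ratio CIs


@dataclass
class DichotomyResult:
    """Q3 split of a biomarker: threshold and per-case high/low labels."""

    threshold: float
    high: np.ndarray  # bool per case
    degenerate: bool = False


def q3_dichotomize(values) -> DichotomyResult:
    """Split at the third quartile (linear-interpolation quantile, type 7).

    Ties at the threshold go to the high group (value >= Q3). All-equal input
    produces a degenerate all-high split and a warning.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values to dichotomize at Q3")
    q3 = float(np.quantile(values[finite], 0.75))
    high = values >= q3
    degenerate = bool(high.all() or (~high[finite]).all())
    if degenerate:
        warnings.warn("degenerate Q3 split: one group is empty", stacklevel=2)
    return DichotomyResult(q3, high, degenerate)


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    z: float


def _tie_term(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def mann_whitney(values, groups) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with midrank ties and the tie-corrected
    normal approximation (no continuity correction).

    ``groups`` is boolean/binary; U is reported for the True/1 group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(bool)
    n1, n2 = int(groups.sum()), int((~groups).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(values)
    r1 = float(ranks[groups].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie = _tie_term(values)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var_u <= 0:
        return MannWhitneyResult(u, 1.0, 0.0)
    z = (u - mean_u) / np.sqrt(var_u)
    p = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(float(u), float(min(p, 1.0)), float(z))


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([(groups == g).sum() for g in labels])
    if np.any(sizes == 0):
        raise ValueError("every group must be non-empty")
    n = len(values)
    ranks = sps.rankdata(values)
    h = 12.0 / (n * (n + 1)) * sum(
        float(ranks[groups == g].sum()) ** 2 / sz
        for g, sz in zip(labels, sizes)
    ) - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(values) / (n**3 - n)
    if correction <= 0:  # all values identical
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, df=len(labels) - 1))
    return float(h), p


@dataclass
class KaplanMeierResult:
    """Product-limit survival curve as a right-continuous step function."""

    times: np.ndarray  # event times where the curve steps
    survival: np.ndarray  # S(t) just after each step time
    five_year_rate: float

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, horizon_years: float = 5.0) -> KaplanMeierResult:
    """Kaplan-Meier estimate with S(horizon) reported (5-year rate by default).

    At tied times events are processed before censorings (standard risk-set
    convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    step_times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    result = KaplanMeierResult(step_times, surv, 0.0)
    result.five_year_rate = result.survival_at(horizon_years)
    return result


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (df=1) and p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups).astype(bool)
    if groups.all() or (~groups).all():
        raise ValueError("both groups must contain at least one subject")
    if not events.any():
        raise ValueError("no events: log-rank test undefined")
    res = multivariate_logrank_test(times, groups.astype(int), events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalFit:
    """KM curves for a dichotomized biomarker plus the log-rank comparison."""

    km_high: KaplanMeierResult
    km_low: KaplanMeierResult
    logrank_stat: float
    p_value: float

    @property
    def five_year_rates(self) -> tuple[float, float]:
        return self.km_high.five_year_rate, self.km_low.five_year_rate


def km_logrank(times, events, high) -> SurvivalFit:
    """Fit per-group KM curves and the log-rank test for a binary split."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    high = np.asarray(high).astype(bool)
    stat, p = logrank(times, events, high)
    return SurvivalFit(
        km_high=km_estimate(times[high], events[high]),
        km_low=km_estimate(times[~high], events[~high]),
        logrank_stat=stat,
        p_value=p,
    )


@dataclass
class CoxResult:
    """Backward-Wald Cox model: retained covariates and elimination trace.

    ``table`` has one row per retained covariate with columns B, SE, Wald,
    ExpB, ci_lower, ci_upper, p; ``trace`` records (step, dropped covariate,
    its Wald p) in elimination order.
    """

    table: pd.DataFrame
    trace: list[tuple[int, str, float]]
    endpoint: str
    alpha_stay: float
    n: int
    n_events: int

    def summary(self) -> str:
        lines = [
            f"Cox PH regression ({self.endpoint}), backward Wald elimination",
            f"n = {self.n}, events = {self.n_events}, "
            f"stay threshold p <= {self.alpha_stay}",
            "",
            self.table.round(4).to_string(),
        ]
        if self.trace:
            lines += ["", "eliminated: " + ", ".join(
                f"{name} (p={p:.3f})" for _, name, p in self.trace)]
        else:
            lines += ["", "eliminated: none"]
        return "\n".join(lines)


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed."""


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
             covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[[duration_col, event_col] + covariates],
                    duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError/ValueError
        raise ConvergenceError(
            f"Cox fit failed for covariates {covariates}: {exc}"
        ) from exc
    return cph


class CoxBackwardModel:
    """Cox proportional-hazards model with backward Wald elimination.

    Build from a case-level DataFrame, then :meth:`fit` iteratively removes
    the covariate with the largest Wald p-value above ``alpha_stay`` and
    refits until every retained covariate satisfies p <= alpha_stay.
    """

    def __init__(self, data: pd.DataFrame, duration_col: str, event_col: str,
                 covariates: list[str]):
        if len(covariates) < 1:
            raise ValueError("at least one covariate is required")
        missing = [c for c in [duration_col, event_col, *covariates]
                   if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if not data[event_col].astype(bool).any():
            raise ValueError("no events in the data: Cox model undefined")
        self.data = data
        self.duration_col = duration_col
        self.event_col = event_col
        self.covariates = list(covariates)

    @classmethod
    def from_records(cls, records, endpoint: str, covariates: list[str]):
        """Build from CaseRecord objects; endpoint is 'efs' or 'os'."""
        from .morphometry import CaseRecord  # noqa: F401  (type of records)

        df = pd.DataFrame([r.as_row() for r in records])
        return cls(df, f"{endpoint}_time", f"{endpoint}_event", covariates)

    def fit(self, alpha_stay: float = 0.1) -> CoxResult:
        remaining = list(self.covariates)
        trace: list[tuple[int, str, float]] = []
        step = 0
        cph = _fit_cox(self.data, self.duration_col, self.event_col, remaining)
        while len(remaining) > 1:
            wald_p = _wald_pvalues(cph)
            worst = wald_p.idxmax()
            if wald_p[worst] <= alpha_stay:
                break
            step += 1
            trace.append((step, worst, float(wald_p[worst])))
            remaining.remove(worst)
            cph = _fit_cox(self.data, self.duration_col, self.event_col,
                           remaining)
        # a single remaining covariate may still fail the stay criterion
        if len(remaining) == 1:
            wald_p = _wald_pvalues(cph)
            worst = wald_p.idxmax()
            if wald_p[worst] > alpha_stay:
                step += 1
                trace.append((step, worst, float(wald_p[worst])))
                remaining = []

        if remaining:
            table = _cox_table(cph)
        else:
            table = pd.DataFrame(
                columns=["B", "SE", "Wald", "ExpB", "ci_lower", "ci_upper", "p"])
        return CoxResult(
            table=table,
            trace=trace,
            endpoint=self.duration_col.removesuffix("_time"),
            alpha_stay=alpha_stay,
            n=len(self.data),
            n_events=int(self.data[self.event_col].astype(bool).sum()),
        )


def _wald_pvalues(cph: CoxPHFitter) -> pd.Series:
    z = cph.params_ / cph.standard_errors_
    return pd.Series(sps.chi2.sf(z**2, df=1), index=cph.params_.index)


def _cox_table(cph: CoxPHFitter) -> pd.DataFrame:
    b = cph.params_
    se = cph.standard_errors_
    wald = (b / se) ** 2
    return pd.DataFrame({
        "B": b,
        "SE": se,
        "Wald": wald,
        "ExpB": np.exp(b),
        "ci_lower": np.exp(b - Z_95 * se),
        "ci_upper": np.exp(b + Z_95 * se),
        "p": sps.chi2.sf(wald, df=1),
    })


def cox_backward(data: pd.DataFrame, duration_col: str, event_col: str,
                 covariates: list[str], alpha_stay: float = 0.1) -> CoxResult:
    """Functional wrapper over :class:`CoxBackwardModel`."""
    return CoxBackwardModel(data, duration_col, event_col, covariates).fit(
        alpha_stay=alpha_stay)
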