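"""Survival comparisons between true-recurrence and new-primary groups.

Metastasis-free survival is estimated per group with the Kaplan-Meier
product-limit estimator and compared with the two-group log-rank test;
hazard ratios (crude and adjusted for age, grade and estrogen-receptor
status) come from a Cox proportional-hazards partial-likelihood fit.
Time-to-recurrence distributions between the TR and NP groups of each
classification method are compared with the unpaired two-sided rank-sum
test.  Estimation is delegated to lifelines behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .dmp import unpaired_wilcoxon
from .io import PairRecord

__all__ = [
    "SurvivalRecord",
    "KmEstimate",
    "km_estimate",
    "logrank_test",
    "cox_hazard_ratio",
    "CoxResult",
    "time_to_recurrence_comparison",
]


@dataclass
class SurvivalRecord:
    """One subject: follow-up time in years, event indicator, group, covariates."""

    pair_id: str
    time: float
    event: int
    group: str  # "TR" or "NP"
    age: float | None = None
    grade: int | None = None
    er_status: str | None = None

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class KmEstimate:
    """Right-continuous product-limit step function."""

    times: np.ndarray  # distinct event/censoring times, ascending
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) read off the step function by right-continuity."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["time_years"].to_numpy(float), records["event"].to_numpy(int)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_estimate(records) -> KmEstimate:
    """Kaplan-Meier estimate from SurvivalRecords or a time/event DataFrame."""
    times, events = _to_arrays(records)
    if times.size == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].reindex(grid).to_numpy(float)
    # drop the synthetic t=0 row unless an observation sits at 0
    keep = grid > 0 if (times > 0).all() else np.ones_like(grid, bool)
    return KmEstimate(times=grid[keep], survival=surv[keep], at_risk=at_risk[keep])


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with 95% confidence intervals."""

    table: pd.DataFrame  # index covariate; columns coef, hr, hr_lower, hr_upper, p
    converged: bool

    def hazard_ratio(self, covariate: str = "group_TR") -> float:
        return float(self.table.loc[covariate, "hr"])


def cox_hazard_ratio(
    records: pd.DataFrame, adjusted: list[str] | None = None
) -> CoxResult:
    """Cox model of the TR-vs-NP group effect, optionally covariate-adjusted.

    ``records`` needs columns time_years, event, group plus any adjustment
    covariates.  The group enters as an indicator ``group_TR`` so the
    reported hazard ratio is TR relative to NP.  A constant group column
    is inestimable and raises; non-convergence or separation is flagged on
    the result instead of silently returned.
    """
    df = records.copy()
    if df["group"].nunique() < 2:
        raise ValueError("group indicator is constant; hazard ratio inestimable")
    df["group_TR"] = (df["group"] == "TR").astype(float)
    covs = ["group_TR"] + list(adjusted or [])
    model = df[["time_years", "event"] + covs].dropna()
    cph = CoxPHFitter()
    try:
        cph.fit(model, duration_col="time_years", event_col="event")
        converged = True
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    summary = cph.summary
    table = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "hr_lower": summary["exp(coef) lower 95%"],
            "hr_upper": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    return CoxResult(table=table, converged=converged)


def time_to_recurrence_comparison(
    pairs: list[PairRecord], methods: tuple[str, ...] = ("ms", "pis", "clinical")
) -> pd.DataFrame:
    """Rank-sum comparison of recurrence times between TR and NP per method.

    A method whose grouping leaves fewer than two pairs on either side is
    flagged (p is NaN) rather than tested.
    """
    rows = []
    for method in methods:
        labels = [getattr(p, f"label_{method}") for p in pairs]
        times = np.array(
            [p.time_to_recurrence_years for p in pairs], dtype=float
        )
        tr = times[[l == "TR" for l in labels]]
        np_ = times[[l == "NP" for l in labels]]
        if tr.size < 2 or np_.size < 2:
            rows.append((method, tr.size, np_.size, np.nan, True))
        else:
            rows.append(
                (method, tr.size, np_.size, unpaired_wilcoxon(tr, np_), False)
            )
    return pd.DataFrame(
        rows, columns=["method", "n_tr", "n_np", "p_value", "degenerate"]
    )
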