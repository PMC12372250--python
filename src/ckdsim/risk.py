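"""Translate classifier scores into time-to-event risk of MAKE.

MAKE (major adverse kidney event) is the composite of a >= 40% eGFR decline
or kidney failure. Two linked quantities are handled here:

* **T50**, the expected time (days) until 50% of patients with a given
  classifier score experience MAKE. Empirically, T50 at a target score is
  estimated from the 100 patients with the nearest scores (50 above, 50 at
  or below): total person-time over events gives the average time to MAKE,
  and halving it gives the time to 50% cumulative risk under linear risk
  accrual.
* The **log-linear risk model** ``log10(T50) = a + b * score`` fitted to
  (score, T50) pairs. The published coefficients a = 4.1446, b = -0.9498
  are available as :data:`PUBLISHED_INTERCEPT` / :data:`PUBLISHED_SLOPE`.

Under linear accrual, 50 events per 100 patients occur over T50, so the
incidence rate per 100 person-years is ``50 / T50_years``. Both transforms
are monotone in the score (strictly decreasing T50 for b < 0), so cohort
medians of rates coincide with rates at median scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PUBLISHED_INTERCEPT",
    "PUBLISHED_SLOPE",
    "DAYS_PER_YEAR",
    "CohortOutcome",
    "RiskModel",
    "RiskEstimate",
    "CohortSizeError",
    "ZeroEventsError",
    "outcomes_to_frame",
    "time_to_half_risk_empirical",
    "fit_risk_regression",
    "fit_risk_model_empirical",
    "days_to_half_risk",
    "incidence_rate",
    "relative_risk_reduction",
    "risk_estimates",
]

PUBLISHED_INTERCEPT = 4.1446
PUBLISHED_SLOPE = -0.9498
DAYS_PER_YEAR = 365.25

#: Size of the nearest-neighbour window of the empirical T50 estimator.
NEIGHBORHOOD = 100
HALF_NEIGHBORHOOD = NEIGHBORHOOD // 2


class CohortSizeError(ValueError):
    """Cohort too small for the 100-neighbour estimator."""


class ZeroEventsError(ValueError):
    """No events in the selected score window; T50 is undefined there."""


@dataclass(frozen=True)
class CohortOutcome:
    """Follow-up duration and MAKE event indicator for one patient."""

    patient_id: str
    followup_days: float
    event: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.followup_days) or self.followup_days < 0:
            raise ValueError(
                f"followup_days must be finite and >= 0 "
                f"(patient {self.patient_id!r})"
            )


@dataclass(frozen=True)
class RiskModel:
    """log10(days to 50% MAKE risk) = intercept + slope * score."""

    intercept: float
    slope: float
    days_per_year: float = DAYS_PER_YEAR

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("risk model coefficients must be finite")
        if self.days_per_year <= 0:
            raise ValueError("days_per_year must be positive")

    @classmethod
    def published(cls, days_per_year: float = DAYS_PER_YEAR) -> "RiskModel":
        """The published coefficient pair (4.1446, -0.9498)."""
        return cls(PUBLISHED_INTERCEPT, PUBLISHED_SLOPE, days_per_year)


@dataclass(frozen=True)
class RiskEstimate:
    patient_id: str
    score: float
    t50_days: float
    incidence_rate_per_100py: float


def outcomes_to_frame(outcomes: Iterable[CohortOutcome]) -> pd.DataFrame:
    """Tabulate outcomes as a patient-indexed frame (followup_days, event)."""
    rows = list(outcomes)
    return pd.DataFrame(
        {
            "followup_days": [o.followup_days for o in rows],
            "event": [bool(o.event) for o in rows],
        },
        index=pd.Index([o.patient_id for o in rows], name="patient_id"),
    )


def _outcome_frame(outcomes) -> pd.DataFrame:
    if isinstance(outcomes, pd.DataFrame):
        return outcomes
    return outcomes_to_frame(outcomes)


def time_to_half_risk_empirical(
    target_score: float,
    scores: pd.Series,
    outcomes,
) -> float:
    """Nearest-neighbour person-time estimate of T50 at a target score.

    Selects the 50 nearest scores strictly above the target and the 50
    nearest at or below it (falling back to the 100 nearest overall near the
    distribution's extremes), then returns

        (sum of follow-up days over the 100) / (events among the 100) / 2.

    Score-distance ties are broken by patient id for reproducibility.
    """
    out = _outcome_frame(outcomes)
    scores = pd.Series(scores, dtype=float)
    if len(scores) < NEIGHBORHOOD:
        raise CohortSizeError(
            f"need at least {NEIGHBORHOOD} patients, got {len(scores)}"
        )
    dist = (
        (scores - target_score)
        .abs()
        .rename("dist")
        .reset_index()
        .set_axis(["patient_id", "dist"], axis=1)
    )
    dist["above"] = scores.to_numpy() > target_score
    dist = dist.sort_values(["dist", "patient_id"], kind="stable")
    above = dist[dist["above"]]
    below = dist[~dist["above"]]
    if len(above) >= HALF_NEIGHBORHOOD and len(below) >= HALF_NEIGHBORHOOD:
        chosen = pd.concat(
            [above.head(HALF_NEIGHBORHOOD), below.head(HALF_NEIGHBORHOOD)]
        )
    else:  # boundary window: one side exhausted
        chosen = dist.head(NEIGHBORHOOD)
    window = out.loc[chosen["patient_id"]]
    n_events = int(window["event"].sum())
    if n_events == 0:
        raise ZeroEventsError(
            f"no MAKE events among the {NEIGHBORHOOD} neighbours of score "
            f"{target_score:.4g}; T50 undefined there"
        )
    return float(window["followup_days"].sum()) / n_events / 2.0


def fit_risk_regression(
    scores: Sequence[float],
    t50_days: Sequence[float],
    days_per_year: float = DAYS_PER_YEAR,
) -> RiskModel:
    """OLS fit of log10(T50 days) on score."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(t50_days, dtype=float)
    if s.size != t.size:
        raise ValueError("scores and t50_days must have equal length")
    if s.size < 2 or np.unique(s).size < 2:
        raise ValueError("need at least two distinct scores to fit the line")
    if (t <= 0).any():
        raise ValueError("t50_days must be strictly positive")
    fit = stats.linregress(s, np.log10(t))
    return RiskModel(float(fit.intercept), float(fit.slope), days_per_year)


def fit_risk_model_empirical(
    scores: pd.Series,
    outcomes,
    targets: Sequence[float] | None = None,
    days_per_year: float = DAYS_PER_YEAR,
) -> RiskModel:
    """Fit the log-linear risk model from follow-up data.

    Runs the 100-neighbour T50 estimator over a grid of target scores
    (default: 25 points between the 5th and 95th percentile of the observed
    scores) and regresses log10(T50) on score. Targets whose window contains
    no events are dropped.
    """
    scores = pd.Series(scores, dtype=float)
    if targets is None:
        lo, hi = scores.quantile([0.05, 0.95])
        targets = np.linspace(lo, hi, 25)
    out = _outcome_frame(outcomes)
    pts_s, pts_t = [], []
    for target in targets:
        try:
            t50 = time_to_half_risk_empirical(float(target), scores, out)
        except ZeroEventsError:
            continue
        pts_s.append(float(target))
        pts_t.append(t50)
    return fit_risk_regression(pts_s, pts_t, days_per_year)


def days_to_half_risk(score, model: RiskModel):
    """T50 in days: ``10^(a + b*score)``; vectorised over scores."""
    return np.power(10.0, model.intercept + model.slope * np.asarray(score, float))


def incidence_rate(score, model: RiskModel):
    """MAKE incidence per 100 person-years: ``50 / T50_years``.

    50 of 100 patients experience the event over T50 under linear accrual.
    """
    t50_years = days_to_half_risk(score, model) / model.days_per_year
    return 50.0 / t50_years


def relative_risk_reduction(score_before, score_after, model: RiskModel):
    """Percent reduction in incidence rate from a score change.

    rate_after / rate_before = 10^(b * (score_before - score_after)), so the
    reduction is ``100 * (1 - 10^(b * delta))`` with delta the score drop.
    Zero when the scores are equal; positive for a score reduction when
    b < 0.
    """
    delta = np.asarray(score_before, float) - np.asarray(score_after, float)
    return 100.0 * (1.0 - np.power(10.0, model.slope * delta))


def risk_estimates(scores: pd.Series, model: RiskModel) -> pd.DataFrame:
    """Per-patient T50 and incidence rate for a Series of scores."""
    scores = pd.Series(scores, dtype=float)
    t50 = days_to_half_risk(scores.to_numpy(), model)
    return pd.DataFrame(
        {
            "score": scores.to_numpy(),
            "t50_days": t50,
            "incidence_rate_per_100py": 50.0 / (t50 / model.days_per_year),
        },
        index=scores.index,
    )
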