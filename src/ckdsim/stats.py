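"""Cohort-level statistics: tertile risk stratification with a Cox hazard
ratio, paired before/after score comparison, and baseline-benefit
association.

The hazard ratio compares the highest versus lowest score tertile with a
single-covariate Cox proportional-hazards model. The partial likelihood
(Breslow handling of tied event times) is maximised by safeguarded Newton
iteration — with one binary covariate this is a one-dimensional, concave
problem with closed-form derivatives, so no general optimiser is needed.

The Wilcoxon signed-rank and Spearman computations delegate to scipy.stats
behind this module's interface (exact signed-rank distribution for n <= 25
paired differences, normal approximation with continuity correction
otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TertileStrata",
    "SurvivalComparison",
    "WilcoxonResult",
    "SpearmanResult",
    "tertile_stratify",
    "hazard_ratio_high_vs_low",
    "paired_wilcoxon",
    "spearman_association",
]

STRATA = ("low", "intermediate", "high")

#: |beta| bound for the Cox Newton iteration; reached only under complete
#: separation (all events in one group), where the MLE is infinite.
_BETA_BOUND = 15.0


@dataclass(frozen=True)
class TertileStrata:
    """Tertile assignment of patients by score, with the two cut points."""

    assignments: pd.Series  # patient_id -> "low" | "intermediate" | "high"
    cut_points: tuple[float, float]

    def ids(self, stratum: str) -> pd.Index:
        return self.assignments.index[self.assignments == stratum]


@dataclass(frozen=True)
class SurvivalComparison:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValueError("confidence interval must bracket the hazard ratio")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_nonzero: int
    degenerate: bool = False


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def tertile_stratify(scores: pd.Series) -> TertileStrata:
    """Split a cohort into low/intermediate/high score tertiles.

    Cut points are the empirical 1/3 and 2/3 quantiles; scores tied with a
    cut point go to the lower stratum (so an all-equal cohort is entirely
    "low" — a documented degenerate case).
    """
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 3:
        raise ValueError(f"need at least 3 patients to form tertiles, got {len(scores)}")
    q1, q2 = np.quantile(scores.to_numpy(), [1 / 3, 2 / 3])
    labels = np.where(
        scores.to_numpy() <= q1,
        "low",
        np.where(scores.to_numpy() <= q2, "intermediate", "high"),
    )
    return TertileStrata(
        assignments=pd.Series(labels, index=scores.index, name="stratum"),
        cut_points=(float(q1), float(q2)),
    )


def _breslow_newton(time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Maximise the single-binary-covariate Breslow partial likelihood.

    Returns (beta_hat, standard_error). At each distinct event time t with
    d_t events (m1_t of them in the x=1 group) and a risk set holding n0_t
    controls and n1_t exposed, the log partial likelihood is

        l(beta) = beta * sum_t m1_t - sum_t d_t * log(n0_t + n1_t e^beta).
    """
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    event_times = np.unique(time[event])
    d = np.empty(event_times.size)
    m1 = np.empty(event_times.size)
    n0 = np.empty(event_times.size)
    n1 = np.empty(event_times.size)
    for i, t in enumerate(event_times):
        at = event & (time == t)
        risk = time >= t
        d[i] = at.sum()
        m1[i] = (at & (x == 1)).sum()
        n0[i] = (risk & (x == 0)).sum()
        n1[i] = (risk & (x == 1)).sum()

    def loglik(beta):
        return beta * m1.sum() - (d * np.log(n0 + n1 * np.exp(beta))).sum()

    beta = 0.0
    for _ in range(100):
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        score = m1.sum() - (d * n1 * eb / denom).sum()
        info = (d * n0 * n1 * eb / denom**2).sum()
        if info <= 0:  # no information (e.g. a group empty at all event times)
            break
        step = score / info
        # step-halving safeguard keeps the ascent monotone
        ll0 = loglik(beta)
        new = np.clip(beta + step, -_BETA_BOUND, _BETA_BOUND)
        for _ in range(30):
            if loglik(new) >= ll0 - 1e-12:
                break
            new = beta + (new - beta) / 2.0
        if abs(new - beta) < 1e-12:
            beta = new
            break
        beta = new
    eb = np.exp(beta)
    info = (d * n0 * n1 * eb / (n0 + n1 * eb) ** 2).sum()
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return float(beta), float(se)


def hazard_ratio_high_vs_low(strata: TertileStrata, outcomes) -> SurvivalComparison:
    """Cox hazard ratio of the high versus low score tertile.

    The intermediate tertile is excluded; the model has a single binary
    covariate (1 = high tertile) with a Wald 95% confidence interval and
    two-sided p-value.
    """
    from .risk import outcomes_to_frame  # local import avoids cycle at import time

    out = outcomes if isinstance(outcomes, pd.DataFrame) else outcomes_to_frame(outcomes)
    frames = {}
    for stratum in ("low", "high"):
        ids = strata.ids(stratum)
        sub = out.loc[ids]
        if int(sub["event"].sum()) == 0:
            raise ValueError(
                f"no events in the {stratum!r} tertile; the hazard ratio is "
                "not estimable"
            )
        frames[stratum] = sub
    both = pd.concat([frames["low"], frames["high"]])
    xvec = np.concatenate(
        [np.zeros(len(frames["low"])), np.ones(len(frames["high"]))]
    )
    beta, se = _breslow_newton(
        both["followup_days"].to_numpy(float),
        both["event"].to_numpy(bool),
        xvec,
    )
    z = beta / se if se > 0 else np.inf
    p = float(2 * sps.norm.sf(abs(z)))
    return SurvivalComparison(
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=p,
    )


def paired_wilcoxon(
    before_scores,
    after_scores,
    alternative: str = "two-sided",
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired before/after scores.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 nonzero pairs and the normal approximation with continuity
    correction beyond that. All-zero differences yield a degenerate result
    (flagged) rather than an exception.
    """
    before = np.asarray(before_scores, dtype=float)
    after = np.asarray(after_scores, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before and after scores must be paired (equal length)")
    diffs = after - before
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return WilcoxonResult(np.nan, np.nan, 0, degenerate=True)
    method = "exact" if diffs.size <= 25 else "approx"
    with warnings.catch_warnings():
        # ties in |d| force scipy off the exact path; accept its fallback
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(
            diffs, correction=True, alternative=alternative, method=method
        )
    return WilcoxonResult(float(res.statistic), float(res.pvalue), int(diffs.size))


def spearman_association(baseline_scores, deltas) -> SpearmanResult:
    """Spearman rank correlation between baseline score and score change.

    ``deltas`` follow the signed convention after - before, so a negative
    rho means larger score reductions at higher baselines. Ties receive
    average ranks.
    """
    x = np.asarray(baseline_scores, dtype=float)
    y = np.asarray(deltas, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation is undefined for a constant input")
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), int(x.size))
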