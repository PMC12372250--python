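"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a urinary-peptidomics CKD cohort: log-normal peptide
intensities with below-detection-limit missingness, a signed linear
classifier over a peptide panel, baseline scores distributed around a
target median (0.565 by default, the published cohort's median), survival
outcomes driven by the log-linear score/T50 relationship, and per-
intervention fold-change tables biased toward reversing each marker's
weight (so treatment tends to lower the score, as in the efficacious
source trials).

Event times are exponential with mean 2 * T50(score): under linear risk
accrual T50 is the half-life of the cohort-mean time to event, and the
exponential is the simplest law whose person-time/events estimator is
consistent with that generative mean — which makes parameter recovery a
well-posed test. Follow-up (administrative censoring) is log-normal with a
1.5-year median truncated at ``followup_max_years``; an infinite
``followup_max_years`` disables censoring entirely.

All randomness derives from ``CohortSpec.seed`` through per-operation
substreams, so identical (spec, seed) reproduce every array bit-
identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import ClassifierModel, PeptideProfile
from .interventions import FoldChangeTable
from .risk import CohortOutcome

__all__ = [
    "DEFAULT_INTERVENTIONS",
    "CohortSpec",
    "SyntheticCohort",
    "generate_classifier",
    "generate_profiles",
    "generate_outcomes",
    "generate_fold_change_tables",
    "generate_cohort",
]

#: The six intervention classes simulated by default: four drug classes,
#: one dietary and one lifestyle intervention.
DEFAULT_INTERVENTIONS = ("ARB", "Exercise", "GLP1RA", "MRA", "OliveOil", "SGLT2i")

# fixed substream tags so each operation has an independent, reproducible
# random stream derived from the one root seed
_TAG_CLASSIFIER, _TAG_PROFILES, _TAG_OUTCOMES, _TAG_TABLES = 1, 2, 3, 4

_FOLLOWUP_LOG_SIGMA = 0.8  # log-scale sd of follow-up; ~95% range 0.3-7x median


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the published study cohort: 935 patients, a 273-peptide
    classifier panel, median baseline score 0.565, log-linear risk
    coefficients (4.1446, -0.9498), follow-up with median 1.5 years
    truncated at 5 years.
    """

    n_patients: int = 935
    n_peptides: int = 1500
    n_classifier_peptides: int = 273
    missing_rate: float = 0.25
    score_location: float = 0.565
    score_scale: float = 0.30
    followup_max_years: float = 5.0
    followup_median_years: float = 1.5
    risk_intercept: float = 4.1446
    risk_slope: float = -0.9498
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_peptides < 1:
            raise ValueError("n_patients and n_peptides must be positive")
        if not 1 <= self.n_classifier_peptides <= self.n_peptides:
            raise ValueError(
                "n_classifier_peptides must be in [1, n_peptides] "
                f"(got {self.n_classifier_peptides} of {self.n_peptides})"
            )
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.score_scale <= 0:
            raise ValueError("score_scale must be positive")
        if self.followup_max_years <= 0 or self.followup_median_years <= 0:
            raise ValueError("follow-up parameters must be positive")
        if not (np.isfinite(self.risk_intercept) and np.isfinite(self.risk_slope)):
            raise ValueError("risk coefficients must be finite")


@dataclass(frozen=True)
class SyntheticCohort:
    profiles: list[PeptideProfile]
    classifier: ClassifierModel
    outcomes: list[CohortOutcome]
    true_scores: pd.Series

    def __post_init__(self) -> None:
        if not (len(self.profiles) == len(self.outcomes) == len(self.true_scores)):
            raise ValueError("one outcome and one true score per profile")


def _rng(spec: CohortSpec, tag: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(tag,))
    )


def _peptide_ids(n: int) -> pd.Index:
    return pd.Index([f"pep{i:06d}" for i in range(n)], name="peptide_id")


def _patient_ids(n: int) -> pd.Index:
    return pd.Index([f"pt{i:05d}" for i in range(n)], name="patient_id")


def generate_classifier(spec: CohortSpec) -> ClassifierModel:
    """Random signed linear panel over ``n_classifier_peptides`` peptides.

    Weights are drawn N(0, 1/sqrt(m)); for panels of two or more peptides
    both up- and down-regulated markers are guaranteed to be present.
    """
    rng = _rng(spec, _TAG_CLASSIFIER)
    universe = _peptide_ids(spec.n_peptides)
    m = spec.n_classifier_peptides
    chosen = np.sort(rng.choice(spec.n_peptides, size=m, replace=False))
    weights = rng.normal(0.0, 1.0 / math.sqrt(m), size=m)
    weights[weights == 0] = 1.0 / math.sqrt(m)
    if m >= 2 and (np.sign(weights) == np.sign(weights[0])).all():
        weights[rng.integers(m)] *= -1.0  # force both marker directions
    return ClassifierModel(
        weights=pd.Series(weights, index=universe[chosen]),
        bias=0.0,
        transform="log1p",
        name=f"synthetic-{m}",
    )


def _calibrate_to_targets(
    xc: np.ndarray, w: np.ndarray, bias: float, targets: np.ndarray
) -> np.ndarray:
    """Per-patient scale factor exponents making scores hit their targets.

    ``xc`` is the imputed (zeros for missing) classifier-marker intensity
    matrix. Positive-weight markers are scaled by e^u and negative-weight
    markers by e^-u, making the induced score strictly increasing in u;
    u is found by vectorised bisection. Patients with no present marker of
    one sign get the nearest achievable score (clamped u).
    """
    pos, neg = w > 0, w < 0

    def f(u: np.ndarray) -> np.ndarray:
        eu = np.exp(u)[:, None]
        return (
            bias
            + np.log1p(xc[:, pos] * eu) @ w[pos]
            + np.log1p(xc[:, neg] / eu) @ w[neg]
        )

    lo = np.full(len(xc), -30.0)
    hi = np.full(len(xc), 30.0)
    for _ in range(50):
        mid = (lo + hi) / 2.0
        too_low = f(mid) < targets
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return (lo + hi) / 2.0


def generate_profiles(
    spec: CohortSpec, classifier: ClassifierModel
) -> tuple[list[PeptideProfile], pd.Series]:
    """Log-normal intensity profiles with the target score distribution.

    Intensities are log-normal with per-peptide location; each cell is
    independently missing with probability ``missing_rate``. Classifier-
    marker intensities are then shifted (up-regulated markers scaled one
    way, down-regulated the other) so each patient's induced score matches
    a draw from N(score_location, score_scale); the returned true scores
    are the exact classifier scores of the generated (imputed) profiles.
    """
    if not classifier.weights.index.isin(_peptide_ids(spec.n_peptides)).all():
        raise ValueError("classifier peptides must lie in the peptide universe")
    rng = _rng(spec, _TAG_PROFILES)
    n, p = spec.n_patients, spec.n_peptides
    peptides = _peptide_ids(p)
    patients = _patient_ids(n)

    mu = rng.normal(math.log(100.0), 1.0, size=p)
    x = np.exp(mu[None, :] + rng.normal(0.0, 1.0, size=(n, p)))
    missing = rng.random(size=(n, p)) < spec.missing_rate
    targets = rng.normal(spec.score_location, spec.score_scale, size=n)

    cols = peptides.get_indexer(classifier.weights.index)
    w = classifier.weights.to_numpy()
    xc = np.where(missing[:, cols], 0.0, x[:, cols])
    u = _calibrate_to_targets(xc, w, classifier.bias, targets)
    scale = np.ones((n, len(cols)))
    scale[:, w > 0] = np.exp(u)[:, None]
    scale[:, w < 0] = np.exp(-u)[:, None]
    x[:, cols] *= scale
    xc *= scale

    true_scores = pd.Series(
        classifier.bias + np.log1p(xc) @ w, index=patients, name="score"
    )
    matrix = pd.DataFrame(np.where(missing, np.nan, x), index=patients, columns=peptides)
    profiles = [
        PeptideProfile(str(pid), matrix.loc[pid]) for pid in patients
    ]
    return profiles, true_scores


def generate_outcomes(
    true_scores: pd.Series, spec: CohortSpec
) -> list[CohortOutcome]:
    """Survival outcomes consistent with the log-linear risk model.

    Event times are exponential with mean 2 * 10^(a + b*score) days (twice
    the time to 50% risk); follow-up is log-normal with median
    ``followup_median_years`` truncated at ``followup_max_years``. The
    recorded follow-up is the earlier of event and censoring; the event
    indicator marks whether the event came first. ``followup_max_years =
    inf`` disables censoring (every event is observed).
    """
    rng = _rng(spec, _TAG_OUTCOMES)
    scores = pd.Series(true_scores, dtype=float)
    n = len(scores)
    t50 = np.power(10.0, spec.risk_intercept + spec.risk_slope * scores.to_numpy())
    event_days = rng.exponential(2.0 * t50)
    if math.isfinite(spec.followup_max_years):
        censor_days = np.minimum(
            np.exp(
                math.log(spec.followup_median_years * 365.25)
                + _FOLLOWUP_LOG_SIGMA * rng.standard_normal(n)
            ),
            spec.followup_max_years * 365.25,
        )
    else:
        censor_days = np.full(n, np.inf)
    event = event_days <= censor_days
    followup = np.minimum(event_days, censor_days)
    return [
        CohortOutcome(str(pid), float(fu), bool(ev))
        for pid, fu, ev in zip(scores.index, followup, event)
    ]


def generate_fold_change_tables(
    classifier: ClassifierModel,
    k_interventions: int,
    spec: CohortSpec,
    names: Sequence[str] | None = None,
    beneficial_bias: float = 0.05,
    coverage: float = 0.35,
    n_offtarget: int = 50,
    log_fc_sigma: float = 0.5,
) -> list[FoldChangeTable]:
    """Per-intervention fold-change tables over random peptide subsets.

    Each table covers a random ~``coverage`` fraction of the classifier
    panel plus ``n_offtarget`` non-classifier peptides. Log fold changes
    are normal with sd ``log_fc_sigma`` around ``-sign(weight) *
    beneficial_bias`` for panel peptides (treatment tends to reverse each
    marker, lowering the score) and around 0 off-panel; peptides absent
    from a table have implicit fold change 1. ``beneficial_bias = 0``
    removes the benefit (median log fold change ~ 0).
    """
    if k_interventions < 1:
        raise ValueError("k_interventions must be >= 1")
    if names is None:
        if k_interventions <= len(DEFAULT_INTERVENTIONS):
            names = DEFAULT_INTERVENTIONS[:k_interventions]
        else:
            names = tuple(f"intervention{i:02d}" for i in range(k_interventions))
    names = tuple(names)
    if len(names) != k_interventions or len(set(names)) != k_interventions:
        raise ValueError("need k distinct intervention names")
    rng = _rng(spec, _TAG_TABLES)
    universe = _peptide_ids(spec.n_peptides)
    panel = classifier.weights.index
    off_panel = universe.difference(panel)
    w = classifier.weights.to_numpy()
    tables = []
    for name in names:
        covered = rng.random(len(panel)) < coverage
        if not covered.any():
            covered[rng.integers(len(panel))] = True
        log_fc_on = -np.sign(w[covered]) * beneficial_bias + rng.normal(
            0.0, log_fc_sigma, size=int(covered.sum())
        )
        n_off = min(n_offtarget, len(off_panel))
        off_ids = rng.choice(len(off_panel), size=n_off, replace=False)
        log_fc_off = rng.normal(0.0, log_fc_sigma, size=n_off)
        fc = pd.Series(
            np.exp(np.concatenate([log_fc_on, log_fc_off])),
            index=panel[covered].append(off_panel[np.sort(off_ids)]),
        )
        tables.append(FoldChangeTable(intervention_name=name, fold_changes=fc))
    return tables


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Convenience wrapper: classifier, profiles, scores and outcomes."""
    classifier = generate_classifier(spec)
    profiles, true_scores = generate_profiles(spec, classifier)
    outcomes = generate_outcomes(true_scores, spec)
    return SyntheticCohort(profiles, classifier, outcomes, true_scores)
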