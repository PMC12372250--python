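"""In silico intervention engine.

A treatment's effect on the urinary peptidome is summarised by per-peptide
fold changes (mean abundance after treatment / mean abundance before, from
interventional studies). Applying an intervention in silico multiplies each
peptide intensity by its fold change; peptides not covered by the table are
unaffected (implicit fold change 1). Combination regimens multiply the fold
changes of their member interventions, treating effects as independent.

For a patient, every non-empty subset of the k available interventions
(2^k - 1 regimens; 63 for k = 6) is simulated and the regimen attaining the
lowest classifier score is selected as the optimal intervention. Score ties
are broken in favour of fewer interventions, then lexicographic name order,
so the parsimonious regimen wins when additional drugs add nothing.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    TRANSFORMS,
    ClassifierModel,
    MissingIntensityError,
    PeptideProfile,
    score_matrix,
    score_profile,
)

__all__ = [
    "FoldChangeTable",
    "Regimen",
    "OptimizationResult",
    "apply_fold_changes",
    "combine_interventions",
    "enumerate_regimens",
    "select_optimal",
    "optimize_cohort",
    "tabulate_optimal_regimens",
]


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-intervention multiplicative effects on peptide abundances.

    ``fold_changes`` maps peptide id -> positive fold change; peptides absent
    from the map have implicit fold change 1. ``calibrated`` records whether
    the table has been rescaled against a trial-observed effect.
    """

    intervention_name: str
    fold_changes: pd.Series
    calibrated: bool = False

    def __post_init__(self) -> None:
        fc = pd.Series(self.fold_changes, dtype=float)
        if not fc.index.is_unique:
            raise ValueError(
                f"duplicate peptide ids in fold-change table "
                f"{self.intervention_name!r}"
            )
        vals = fc.to_numpy()
        if len(vals) and (not np.isfinite(vals).all() or (vals <= 0).any()):
            raise ValueError(
                f"fold changes for {self.intervention_name!r} must be "
                "positive and finite"
            )
        object.__setattr__(self, "fold_changes", fc)


@dataclass(frozen=True, order=True)
class Regimen:
    """A non-empty set of interventions applied jointly.

    Stored as a sorted tuple of names; ordering (by size, then
    lexicographic) gives the canonical enumeration order and the tie-break
    order for optimal-regimen selection.
    """

    sort_index: tuple = field(init=False, repr=False)
    interventions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = tuple(sorted(self.interventions))
        if not names:
            raise ValueError("a regimen needs at least one intervention")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate interventions in regimen: {names}")
        object.__setattr__(self, "interventions", names)
        object.__setattr__(self, "sort_index", (len(names), names))

    @property
    def label(self) -> str:
        return "+".join(self.interventions)

    def __len__(self) -> int:
        return len(self.interventions)


@dataclass(frozen=True)
class OptimizationResult:
    patient_id: str
    baseline_score: float
    best_regimen: Regimen
    best_score: float
    all_scores: Mapping[Regimen, float]

    def __post_init__(self) -> None:
        if self.all_scores and self.best_score != min(self.all_scores.values()):
            raise ValueError("best_score must be the minimum over all_scores")


def apply_fold_changes(
    profile: PeptideProfile, table: FoldChangeTable
) -> PeptideProfile:
    """Multiply each peptide intensity by its fold change (1 if uncovered).

    Requires an imputed profile; intensities imputed to zero stay zero
    (a peptide below detection limit remains below detection limit).
    """
    if profile.has_missing:
        raise MissingIntensityError(
            f"profile {profile.patient_id!r} has missing intensities; "
            "impute before applying interventions"
        )
    fc = table.fold_changes.reindex(profile.intensities.index, fill_value=1.0)
    return PeptideProfile(profile.patient_id, profile.intensities * fc)


def combine_interventions(
    tables: Sequence[FoldChangeTable],
) -> FoldChangeTable:
    """Combine interventions by multiplying their fold changes per peptide.

    Effects are treated as independent; peptides absent from a member table
    contribute a factor of 1. The combined name is the '+'-joined sorted
    member names. Commutative and associative by construction.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("cannot combine an empty collection of interventions")
    names = [t.intervention_name for t in tables]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate intervention names: {sorted(names)}")
    union = pd.Index([])
    for t in tables:
        union = union.union(t.fold_changes.index)
    combined = pd.Series(1.0, index=union)
    for t in tables:
        combined = combined * t.fold_changes.reindex(union, fill_value=1.0)
    return FoldChangeTable(
        intervention_name="+".join(sorted(names)),
        fold_changes=combined,
        calibrated=all(t.calibrated for t in tables),
    )


def enumerate_regimens(intervention_names: Iterable[str]) -> list[Regimen]:
    """All non-empty subsets of the interventions, in canonical order.

    Canonical order is by regimen size, then lexicographic, so output is
    byte-stable across runs. k interventions yield 2^k - 1 regimens.
    """
    names = sorted(intervention_names)
    if not names:
        raise ValueError("need at least one intervention to enumerate regimens")
    if len(set(names)) != len(names):
        raise ValueError(f"intervention names must be distinct: {names}")
    return [
        Regimen(interventions=combo)
        for size in range(1, len(names) + 1)
        for combo in itertools.combinations(names, size)
    ]


def _combined_tables(
    tables: Sequence[FoldChangeTable], regimens: Sequence[Regimen]
) -> dict[Regimen, FoldChangeTable]:
    by_name = {t.intervention_name: t for t in tables}
    return {
        r: combine_interventions([by_name[n] for n in r.interventions])
        for r in regimens
    }


def _regimen_scores(
    matrix: pd.DataFrame,
    combined: Mapping[Regimen, FoldChangeTable],
    model: ClassifierModel,
) -> pd.DataFrame:
    """Scores of every patient (rows) under every regimen (columns).

    Only the classifier's peptide panel can move the score, so work is
    restricted to those columns.
    """
    support = model.weights.index
    x = matrix.reindex(columns=support, fill_value=0.0).to_numpy(float)
    w = model.weights.to_numpy()
    f = TRANSFORMS[model.transform]
    cols = {}
    for regimen, table in combined.items():
        fc = table.fold_changes.reindex(support, fill_value=1.0).to_numpy()
        cols[regimen] = model.bias + f(x * fc) @ w
    return pd.DataFrame(cols, index=matrix.index)


def select_optimal(
    profile: PeptideProfile,
    tables: Sequence[FoldChangeTable],
    model: ClassifierModel,
) -> OptimizationResult:
    """Score every regimen for one patient and pick the score-minimising one.

    Ties are broken by fewer interventions, then lexicographic order (the
    canonical enumeration order, so the first regimen attaining the minimum
    wins).
    """
    if not tables:
        raise ValueError("need at least one fold-change table")
    baseline = score_profile(profile, model).score
    regimens = enumerate_regimens(t.intervention_name for t in tables)
    combined = _combined_tables(tables, regimens)
    all_scores = {}
    best_regimen, best_score = None, np.inf
    for regimen in regimens:
        treated = apply_fold_changes(profile, combined[regimen])
        s = score_profile(treated, model).score
        all_scores[regimen] = s
        if s < best_score:
            best_regimen, best_score = regimen, s
    return OptimizationResult(
        patient_id=profile.patient_id,
        baseline_score=baseline,
        best_regimen=best_regimen,
        best_score=best_score,
        all_scores=all_scores,
    )


def optimize_cohort(
    matrix: pd.DataFrame,
    tables: Sequence[FoldChangeTable],
    model: ClassifierModel,
) -> list[OptimizationResult]:
    """Vectorised per-patient optimal-regimen selection over a cohort.

    ``matrix`` is an imputed patients x peptides intensity matrix. Equivalent
    to :func:`select_optimal` row by row, sharing the 2^k - 1 combined
    fold-change tables across patients.
    """
    if not tables:
        raise ValueError("need at least one fold-change table")
    baseline = score_matrix(matrix, model)
    regimens = enumerate_regimens(t.intervention_name for t in tables)
    combined = _combined_tables(tables, regimens)
    scores = _regimen_scores(matrix, combined, model)
    # np.argmin takes the first minimum, i.e. the canonical-order tie-break
    best_idx = np.argmin(scores.to_numpy(), axis=1)
    results = []
    for i, pid in enumerate(matrix.index):
        row = scores.iloc[i]
        best = regimens[best_idx[i]]
        results.append(
            OptimizationResult(
                patient_id=str(pid),
                baseline_score=float(baseline.iloc[i]),
                best_regimen=best,
                best_score=float(row.iloc[best_idx[i]]),
                all_scores=dict(row.items()),
            )
        )
    return results


def tabulate_optimal_regimens(
    results: Iterable[OptimizationResult],
) -> pd.Series:
    """Frequency table of optimal regimens, sorted by descending count.

    Counts sum to the number of patients; count ties are ordered by the
    canonical regimen order so output is deterministic.
    """
    counts = Counter(r.best_regimen for r in results)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series(
        [c for _, c in ordered],
        index=pd.Index([r.label for r, _ in ordered], name="regimen"),
        name="n_patients",
        dtype=int,
    )
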