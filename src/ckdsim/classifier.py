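"""Linear peptide-panel scoring of urinary peptide profiles.

A peptide profile maps peptide identifiers to non-negative intensities,
with missing entries representing signals below the detection limit of the
CE-MS platform. A classifier is a linear model over a fixed peptide panel:

    score = bias + sum_i  w_i * f(x_i)

where ``f`` is an elementwise transform (identity or log1p) and peptides in
the panel but absent from a profile contribute ``f(0)``. This mirrors
urinary-peptidomics risk classifiers such as CKD273, which combine a few
hundred peptide biomarkers into a single real-valued risk score (higher
score = higher risk of progression). The production classifier is a
proprietary SVM; the procedures in this package only require a
deterministic profile -> score map, so the classifier is a replaceable
component behind this contract.

Missing intensities must be imputed (to zero, the below-detection-limit
convention) before scoring; :func:`score_profile` refuses profiles with
missing values so the imputation step is always explicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRANSFORMS",
    "PeptideProfile",
    "ClassifierModel",
    "ScoredProfile",
    "MissingIntensityError",
    "impute_missing_as_zero",
    "score_profile",
    "score_cohort",
    "score_matrix",
    "profiles_to_matrix",
]

#: Supported elementwise transforms applied to intensities before weighting.
#: log1p is the default in practice because zero (the imputation value for
#: below-detection-limit signals) is in its domain.
TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: np.asarray(x, dtype=float),
    "log1p": np.log1p,
}


class MissingIntensityError(ValueError):
    """Raised when an operation requires an imputed (complete) profile."""


def _as_series(values, name: str) -> pd.Series:
    s = pd.Series(values, dtype=float)
    if not s.index.is_unique:
        dupes = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate peptide ids in {name}: {dupes[:5]}")
    return s


@dataclass(frozen=True)
class PeptideProfile:
    """One patient's peptide intensity vector.

    ``intensities`` is a float Series indexed by peptide id; NaN marks a
    missing (below detection limit) measurement. Present values must be
    non-negative.
    """

    patient_id: str
    intensities: pd.Series

    def __post_init__(self) -> None:
        s = _as_series(self.intensities, f"profile {self.patient_id!r}")
        present = s.dropna()
        if (present < 0).any():
            bad = present[present < 0].index.tolist()
            raise ValueError(
                f"negative intensities in profile {self.patient_id!r}: {bad[:5]}"
            )
        object.__setattr__(self, "intensities", s)

    @property
    def has_missing(self) -> bool:
        return bool(self.intensities.isna().any())

    @property
    def peptide_ids(self) -> pd.Index:
        return self.intensities.index


@dataclass(frozen=True)
class ClassifierModel:
    """Linear peptide classifier: ``bias + sum w_i * transform(x_i)``."""

    weights: pd.Series
    bias: float = 0.0
    transform: str = "log1p"
    name: str = "classifier"

    def __post_init__(self) -> None:
        w = _as_series(self.weights, f"classifier {self.name!r}")
        if len(w) == 0 or not (w != 0).any():
            raise ValueError("classifier needs at least one nonzero weight")
        if not np.isfinite(w.to_numpy()).all() or not np.isfinite(self.bias):
            raise ValueError("classifier weights and bias must be finite")
        if self.transform not in TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r}; "
                f"choose from {sorted(TRANSFORMS)}"
            )
        object.__setattr__(self, "weights", w)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "transform": self.transform,
            "bias": float(self.bias),
            "weights": {str(k): float(v) for k, v in self.weights.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            weights=pd.Series(d["weights"], dtype=float),
            bias=float(d["bias"]),
            transform=d.get("transform", "log1p"),
            name=d.get("name", "classifier"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ScoredProfile:
    patient_id: str
    score: float
    model_name: str = field(default="classifier")

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score for patient {self.patient_id!r}")


def impute_missing_as_zero(profile: PeptideProfile) -> PeptideProfile:
    """Replace missing intensities by zero (below-detection-limit reading).

    Present entries are unchanged; a complete profile is returned as-is.
    """
    if not profile.has_missing:
        return profile
    return PeptideProfile(profile.patient_id, profile.intensities.fillna(0.0))


def score_profile(profile: PeptideProfile, model: ClassifierModel) -> ScoredProfile:
    """Score one imputed profile with a linear classifier.

    Panel peptides absent from the profile contribute ``transform(0)``.
    Raises :class:`MissingIntensityError` on profiles with missing values so
    imputation is always an explicit, auditable step.
    """
    if profile.has_missing:
        raise MissingIntensityError(
            f"profile {profile.patient_id!r} has missing intensities; "
            "apply impute_missing_as_zero first"
        )
    x = profile.intensities.reindex(model.weights.index, fill_value=0.0)
    fx = TRANSFORMS[model.transform](x.to_numpy())
    score = float(model.bias + model.weights.to_numpy() @ fx)
    return ScoredProfile(profile.patient_id, score, model.name)


def score_cohort(
    profiles: Iterable[PeptideProfile], model: ClassifierModel
) -> list[ScoredProfile]:
    """Score profiles elementwise, preserving order; patient ids must be unique."""
    profiles = list(profiles)
    ids = [p.patient_id for p in profiles]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for pid in ids:
            if pid in seen:
                dupes.append(pid)
            seen.add(pid)
        raise ValueError(f"duplicate patient ids: {sorted(set(dupes))[:5]}")
    return [score_profile(p, model) for p in profiles]


def score_matrix(matrix: pd.DataFrame, model: ClassifierModel) -> pd.Series:
    """Vectorised scoring of an imputed intensity matrix (patients x peptides).

    Equivalent to mapping :func:`score_profile` over the rows; used by the
    pipeline for cohort-scale work.
    """
    if matrix.isna().to_numpy().any():
        raise MissingIntensityError(
            "intensity matrix has missing values; impute (fillna(0)) first"
        )
    x = matrix.reindex(columns=model.weights.index, fill_value=0.0).to_numpy(float)
    fx = TRANSFORMS[model.transform](x)
    return pd.Series(
        model.bias + fx @ model.weights.to_numpy(), index=matrix.index, name="score"
    )


def profiles_to_matrix(profiles: Sequence[PeptideProfile]) -> pd.DataFrame:
    """Stack profiles into a patients x peptides matrix (NaN = missing)."""
    return pd.DataFrame(
        [p.intensities.rename(p.patient_id) for p in profiles]
    )
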