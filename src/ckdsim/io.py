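"""Stable on-disk formats for pipeline inputs and outputs.

* peptide matrix TSV — rows are patients, columns peptide ids, empty cell
  = missing intensity;
* fold-change TSV — columns ``peptide_id``, ``fold_change`` (one file per
  intervention, named after it) or a long format with an extra
  ``intervention`` column; calibrated tables carry a ``calibrated`` column;
* classifier JSON — ``name``, ``transform``, ``bias``, ``weights``;
* outcomes CSV — ``patient_id``, ``followup_days``, ``event`` (0/1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .classifier import PeptideProfile
from .interventions import FoldChangeTable
from .risk import CohortOutcome, outcomes_to_frame

__all__ = [
    "read_peptide_matrix",
    "write_peptide_matrix",
    "read_fold_change_table",
    "write_fold_change_table",
    "read_fold_change_tables",
    "read_outcomes",
    "write_outcomes",
    "matrix_to_profiles",
]

FLOAT_FORMAT = "%.10g"  # byte-stable float rendering in all outputs


def write_peptide_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("patient_id").to_csv(
        path, sep="\t", na_rep="", float_format=FLOAT_FORMAT
    )


def read_peptide_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    return matrix.astype(float)


def matrix_to_profiles(matrix: pd.DataFrame) -> list[PeptideProfile]:
    return [PeptideProfile(str(pid), row) for pid, row in matrix.iterrows()]


def write_fold_change_table(table: FoldChangeTable, path) -> None:
    frame = table.fold_changes.rename("fold_change").rename_axis("peptide_id")
    frame = frame.reset_index()
    if table.calibrated:
        frame["calibrated"] = 1
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_fold_change_table(path, intervention_name: str | None = None) -> FoldChangeTable:
    frame = pd.read_csv(path, sep="\t")
    if intervention_name is None:
        intervention_name = Path(path).stem
    return FoldChangeTable(
        intervention_name=intervention_name,
        fold_changes=pd.Series(
            frame["fold_change"].to_numpy(float),
            index=frame["peptide_id"].astype(str),
        ),
        calibrated="calibrated" in frame.columns,
    )


def read_fold_change_tables(path) -> list[FoldChangeTable]:
    """Load intervention tables from a directory of per-intervention TSV
    files or from one long-format TSV with an ``intervention`` column."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tsv"))
        if not files:
            raise FileNotFoundError(f"no fold-change TSV files in {path}")
        return [read_fold_change_table(f) for f in files]
    frame = pd.read_csv(path, sep="\t")
    if "intervention" not in frame.columns:
        return [read_fold_change_table(path)]
    tables = []
    for name, sub in frame.groupby("intervention", sort=True):
        tables.append(
            FoldChangeTable(
                intervention_name=str(name),
                fold_changes=pd.Series(
                    sub["fold_change"].to_numpy(float),
                    index=sub["peptide_id"].astype(str),
                ),
                calibrated="calibrated" in frame.columns,
            )
        )
    return tables


def write_outcomes(outcomes: Iterable[CohortOutcome], path) -> None:
    frame = outcomes_to_frame(outcomes)
    frame["event"] = frame["event"].astype(int)
    frame.to_csv(path, float_format=FLOAT_FORMAT)


def read_outcomes(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="patient_id")
    frame.index = frame.index.astype(str)
    frame["event"] = frame["event"].astype(bool)
    frame["followup_days"] = frame["followup_days"].astype(float)
    return frame
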