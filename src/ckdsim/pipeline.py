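"""End-to-end orchestration: simulate/load -> impute -> score -> calibrate
-> optimize -> risk transform -> cohort statistics -> report files.

A run is described by a :class:`RunConfig` (constructible from a YAML
document) naming either input files or a synthetic cohort specification,
the trial-observed effects used for calibration, the calibration mode, and
the risk-model source. All randomness flows from the one seed in the
config; outputs are byte-stable given identical config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ckdio
from .classifier import ClassifierModel, score_matrix
from .interventions import (
    FoldChangeTable,
    OptimizationResult,
    optimize_cohort,
    tabulate_optimal_regimens,
)
from .recalibration import RecalibrationRecord, TrialEffect, calibrate_intervention
from .risk import (
    RiskModel,
    days_to_half_risk,
    fit_risk_model_empirical,
    relative_risk_reduction,
)
from .stats import (
    SpearmanResult,
    SurvivalComparison,
    WilcoxonResult,
    hazard_ratio_high_vs_low,
    paired_wilcoxon,
    spearman_association,
    tertile_stratify,
)
from .synthetic import (
    CohortSpec,
    generate_classifier,
    generate_fold_change_tables,
    generate_outcomes,
    generate_profiles,
)

__all__ = [
    "DEFAULT_TRIAL_EFFECTS",
    "InputPaths",
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger(__name__)

CALIBRATION_MODES = ("single_pass", "iterative")
RISK_SOURCES = ("published_constants", "refit")

#: Illustrative trial-observed percentage improvements in time to MAKE for
#: the six default interventions, roughly graded by the strength of kidney-
#: outcome evidence for each class (users supply their own values for real
#: analyses).
DEFAULT_TRIAL_EFFECTS: dict[str, float] = {
    "ARB": 20.0,
    "Exercise": 15.0,
    "GLP1RA": 25.0,
    "MRA": 25.0,
    "OliveOil": 10.0,
    "SGLT2i": 35.0,
}


@dataclass(frozen=True)
class InputPaths:
    """Locations of user-supplied input files."""

    profiles: str
    classifier: str
    fold_changes: str
    outcomes: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one pipeline run.

    Exactly one of ``inputs`` (file paths) or ``synthetic`` (a cohort
    specification) must be given. ``trial_effects`` maps intervention name
    to the trial-observed percentage change in time to MAKE; interventions
    without an entry are applied uncalibrated. With ``risk_source =
    'published_constants'`` the published coefficients (4.1446, -0.9498)
    drive the risk outputs; ``'refit'`` re-estimates them from the cohort's
    own outcomes via the 100-neighbour estimator.
    """

    seed: int = 0
    inputs: InputPaths | None = None
    synthetic: CohortSpec | None = None
    k_interventions: int = 6
    trial_effects: dict[str, float] | None = None
    calibration_mode: str = "single_pass"
    calibration_tolerance: float = 0.5
    calibration_max_iter: int = 25
    risk_source: str = "published_constants"
    days_per_year: float = 365.25
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'inputs' and 'synthetic' must be configured"
            )
        if self.calibration_mode not in CALIBRATION_MODES:
            raise ValueError(f"calibration_mode must be one of {CALIBRATION_MODES}")
        if self.risk_source not in RISK_SOURCES:
            raise ValueError(f"risk_source must be one of {RISK_SOURCES}")
        if self.calibration_tolerance <= 0 or self.calibration_max_iter < 1:
            raise ValueError("invalid calibration tolerance / max_iter")

    @property
    def max_iter(self) -> int:
        return 1 if self.calibration_mode == "single_pass" else self.calibration_max_iter

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if kwargs.get("inputs") is not None:
            kwargs["inputs"] = InputPaths(**kwargs["inputs"])
        if kwargs.get("synthetic") is not None:
            syn = dict(kwargs["synthetic"])
            syn.setdefault("seed", kwargs.get("seed", 0))
            kwargs["synthetic"] = CohortSpec(**syn)
        return cls(**kwargs)


@dataclass
class RunReport:
    """In-memory result of a full pipeline run."""

    config: RunConfig
    classifier: ClassifierModel
    risk_model: RiskModel
    tables: list[FoldChangeTable]
    calibration_records: list[RecalibrationRecord]
    results: list[OptimizationResult]
    per_patient: pd.DataFrame
    regimen_counts: pd.Series
    summary: pd.Series
    wilcoxon: WilcoxonResult
    spearman: SpearmanResult
    hazard: SurvivalComparison | None

    @property
    def n_regimens(self) -> int:
        return len(self.results[0].all_scores) if self.results else 0


def _load_or_generate(config: RunConfig):
    if config.synthetic is not None:
        spec = config.synthetic
        logger.info(
            "generating synthetic cohort: n=%d, peptides=%d, panel=%d, seed=%d",
            spec.n_patients, spec.n_peptides, spec.n_classifier_peptides, spec.seed,
        )
        classifier = generate_classifier(spec)
        profiles, true_scores = generate_profiles(spec, classifier)
        outcomes = ckdio.outcomes_to_frame(generate_outcomes(true_scores, spec))
        matrix = pd.DataFrame(
            [p.intensities.rename(p.patient_id) for p in profiles]
        )
        tables = generate_fold_change_tables(classifier, config.k_interventions, spec)
        return matrix, classifier, tables, outcomes
    paths = config.inputs
    logger.info("loading inputs: %s", paths)
    matrix = ckdio.read_peptide_matrix(paths.profiles)
    classifier = ClassifierModel.from_json(paths.classifier)
    tables = ckdio.read_fold_change_tables(paths.fold_changes)
    outcomes = ckdio.read_outcomes(paths.outcomes) if paths.outcomes else None
    return matrix, classifier, tables, outcomes


def _risk_model(config: RunConfig, scores: pd.Series, outcomes) -> RiskModel:
    if config.risk_source == "published_constants":
        return RiskModel.published(config.days_per_year)
    if outcomes is None:
        raise ValueError("risk_source='refit' requires an outcomes table")
    model = fit_risk_model_empirical(
        scores, outcomes, days_per_year=config.days_per_year
    )
    logger.info(
        "refit risk model: intercept=%.4f slope=%.4f", model.intercept, model.slope
    )
    return model


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order and (optionally) write report files."""
    matrix, classifier, tables, outcomes = _load_or_generate(config)
    logger.info(
        "cohort: %d patients x %d peptides; %d interventions",
        *matrix.shape, len(tables),
    )

    imputed = matrix.fillna(0.0)
    baseline = score_matrix(imputed, classifier)
    logger.info("baseline scores: median %.4f", baseline.median())

    risk_model = _risk_model(config, baseline, outcomes)

    records: list[RecalibrationRecord] = []
    if config.trial_effects:
        calibrated = []
        for table in tables:
            observed = config.trial_effects.get(table.intervention_name)
            if observed is None:
                logger.info(
                    "no trial effect for %s; using raw fold changes",
                    table.intervention_name,
                )
                calibrated.append(table)
                continue
            table, record = calibrate_intervention(
                imputed,
                table,
                classifier,
                risk_model,
                TrialEffect(table.intervention_name, float(observed)),
                tolerance=config.calibration_tolerance,
                max_iter=config.max_iter,
            )
            calibrated.append(table)
            records.append(record)
        tables = calibrated

    results = optimize_cohort(imputed, tables, classifier)
    regimen_counts = tabulate_optimal_regimens(results)
    best_scores = pd.Series(
        [r.best_score for r in results], index=baseline.index, name="best_score"
    )
    best_regimens = [r.best_regimen.label for r in results]
    logger.info(
        "optimized %d patients over %d regimens; median score %.4f -> %.4f",
        len(results), len(results[0].all_scores),
        baseline.median(), best_scores.median(),
    )

    t50_before = days_to_half_risk(baseline.to_numpy(), risk_model)
    t50_after = days_to_half_risk(best_scores.to_numpy(), risk_model)
    rate_before = 50.0 / (t50_before / risk_model.days_per_year)
    rate_after = 50.0 / (t50_after / risk_model.days_per_year)
    rrr = relative_risk_reduction(baseline.to_numpy(), best_scores.to_numpy(), risk_model)

    per_patient = pd.DataFrame(
        {
            "baseline_score": baseline,
            "best_regimen": best_regimens,
            "best_score": best_scores,
            "t50_days_before": t50_before,
            "t50_days_after": t50_after,
            "incidence_rate_before_per_100py": rate_before,
            "incidence_rate_after_per_100py": rate_after,
            "relative_risk_reduction_pct": rrr,
        },
        index=baseline.index,
    )

    wilcoxon = paired_wilcoxon(baseline.to_numpy(), best_scores.to_numpy())
    try:
        spearman = spearman_association(
            baseline.to_numpy(), best_scores.to_numpy() - baseline.to_numpy()
        )
    except ValueError as err:  # constant deltas (e.g. identity interventions)
        logger.warning("baseline/benefit association not estimable: %s", err)
        spearman = SpearmanResult(np.nan, np.nan, len(baseline))
    hazard = None
    if outcomes is not None:
        strata = tertile_stratify(baseline)
        try:
            hazard = hazard_ratio_high_vs_low(strata, outcomes)
        except ValueError as err:  # e.g. an eventless tertile in a small cohort
            logger.warning("tertile hazard ratio not estimable: %s", err)
        else:
            logger.info(
                "high vs low tertile hazard ratio %.2f (95%% CI %.2f-%.2f, p=%.2g)",
                hazard.hazard_ratio, hazard.ci_low, hazard.ci_high, hazard.p_value,
            )

    summary = pd.Series(
        {
            "n_patients": float(len(per_patient)),
            "n_interventions": float(len(tables)),
            "n_regimens": float(len(results[0].all_scores)),
            "median_score_before": float(baseline.median()),
            "median_score_after": float(best_scores.median()),
            "mean_score_delta": float((baseline - best_scores).mean()),
            "median_rate_before_per_100py": float(np.median(rate_before)),
            "median_rate_after_per_100py": float(np.median(rate_after)),
            "median_relative_risk_reduction_pct": float(np.median(rrr)),
            "wilcoxon_p": wilcoxon.p_value,
            "spearman_rho": spearman.rho,
            "spearman_p": spearman.p_value,
            "hazard_ratio_high_vs_low": hazard.hazard_ratio if hazard else np.nan,
            "hazard_ratio_ci_low": hazard.ci_low if hazard else np.nan,
            "hazard_ratio_ci_high": hazard.ci_high if hazard else np.nan,
            "hazard_ratio_p": hazard.p_value if hazard else np.nan,
            "risk_intercept": risk_model.intercept,
            "risk_slope": risk_model.slope,
            "seed": float(config.seed),
        },
        name="value",
    )

    report = RunReport(
        config=config,
        classifier=classifier,
        risk_model=risk_model,
        tables=tables,
        calibration_records=records,
        results=results,
        per_patient=per_patient,
        regimen_counts=regimen_counts,
        summary=summary,
        wilcoxon=wilcoxon,
        spearman=spearman,
        hazard=hazard,
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def write_report(report: RunReport, output_dir) -> list[Path]:
    """Write per-patient, regimen-frequency, summary and calibration CSVs."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = ckdio.FLOAT_FORMAT
    written = []

    path = outdir / "per_patient.csv"
    report.per_patient.rename_axis("patient_id").to_csv(path, float_format=fmt)
    written.append(path)

    path = outdir / "regimen_frequencies.csv"
    report.regimen_counts.to_csv(path)
    written.append(path)

    path = outdir / "summary.csv"
    report.summary.rename_axis("metric").to_csv(path, float_format=fmt)
    written.append(path)

    if report.calibration_records:
        path = outdir / "calibration.csv"
        pd.DataFrame(
            [dataclasses.asdict(r) for r in report.calibration_records]
        ).to_csv(path, index=False, float_format=fmt)
        written.append(path)

    for path in written:
        logger.info("wrote %s", path)
    return written
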