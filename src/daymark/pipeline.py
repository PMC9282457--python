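"""End-to-end orchestration: tables -> biomarkers -> events -> forecaster.

The stages are importable individually; this module wires them together the
way a monitoring study would run them, keeping per-stage record counts so
cohort-level numbers (complete days, samples per partition, test-set size)
are inspectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarker import BiomarkerSeries, SmoothingParams, build_biomarker
from .coding import MOTSC_QUESTIONS, WEBE_QUESTIONS
from .data import DailyPanel, build_day_grid, patient_ids
from .events import (
    detect_exacerbation_events,
    eligibility_mask,
    make_labels,
    sobriety_index,
)
from .factors import (
    BiomarkerDefinition,
    assign_questions,
    principal_components,
    select_complete_days,
    varimax_rotate,
)
from .forecasting import (
    FEATURE_SETS,
    ForecastSample,
    build_feature_rows,
    make_samples,
    predict,
    split_patients,
    train_forecaster,
)
from .metrics import MetricsReport, best_mcc_threshold
from .nn import LSTMClassifier, LSTMConfig

logger = logging.getLogger("daymark")

__all__ = [
    "DEFAULT_DEFINITIONS",
    "PatientData",
    "StudyResult",
    "discover_definitions",
    "prepare_patient",
    "run_forecast_study",
]

DEFAULT_DEFINITIONS = (
    BiomarkerDefinition("WeBe-i", tuple(WEBE_QUESTIONS)),
    BiomarkerDefinition("MotSC-i", tuple(MOTSC_QUESTIONS)),
)


def discover_definitions(q_table: pd.DataFrame) -> list[BiomarkerDefinition]:
    """Re-derive the biomarker item subsets from the data's factor structure.

    Components are retained by the eigenvalue > 1 criterion, but never fewer
    than two: a varimax rotation and a multi-biomarker split both need at
    least two factors to be defined.
    """
    complete = select_complete_days(q_table)
    loadings = principal_components(complete)
    if loadings.k < 2:
        loadings = principal_components(complete, k=2)
    rotated = varimax_rotate(loadings)
    defs = assign_questions(rotated)
    logger.info(
        "factor discovery: %d complete days, %d components retained",
        len(complete),
        loadings.k,
    )
    return defs


def panel_status(panel: DailyPanel) -> list[str]:
    """Gapless daily status; days with no sobriety record count as all tests
    omitted (inside the treatment span an absent record means nothing was
    performed)."""
    return [s if s is not None else "all_omitted" for s in panel.status]


@dataclass
class PatientData:
    """Everything derived for one patient prior to sampling."""

    panel: DailyPanel
    biomarkers: dict[str, BiomarkerSeries]
    ami: np.ndarray
    ami_source: str  # "input" or "approximation"
    in_ee: np.ndarray
    samples: list[ForecastSample]


def prepare_patient(
    pid: str,
    q_table: pd.DataFrame,
    s_table: pd.DataFrame,
    definitions=DEFAULT_DEFINITIONS,
    params: SmoothingParams = SmoothingParams(),
    look_ahead: tuple[int, int] = (1, 3),
    feature_set: str = "biomarker2",
) -> PatientData | None:
    """Build panel, biomarkers, events, labels and samples for one patient.

    Returns None when the patient cannot support the requested feature set
    (e.g. no answers at all to a biomarker's item subset).
    """
    panel = build_day_grid(q_table, s_table, pid)
    try:
        biomarkers = {
            d.name: build_biomarker(panel, d.questions, params, name=d.name)
            for d in definitions
        }
    except ValueError:
        return None

    status = panel_status(panel)
    calendar = detect_exacerbation_events(status, patient_id=pid)
    if panel.ami.notna().all():
        ami, ami_source = panel.ami.to_numpy(dtype=float), "input"
    else:
        ami, ami_source = sobriety_index(status, params), "approximation"
    labels = make_labels(calendar, look_ahead)
    eligible = eligibility_mask(calendar, ami)
    features = build_feature_rows(panel, biomarkers, FEATURE_SETS[feature_set])
    samples = make_samples(features, labels, eligible, patient_id=pid)
    return PatientData(
        panel=panel,
        biomarkers=biomarkers,
        ami=ami,
        ami_source=ami_source,
        in_ee=calendar.in_ee,
        samples=samples,
    )


@dataclass
class StudyResult:
    """Outcome of one forecasting study run."""

    feature_set: str
    look_ahead: tuple[int, int]
    partition: dict[str, str]
    metrics: MetricsReport
    n_test_patients: int
    n_test_days: int
    predictions: pd.DataFrame
    model: LSTMClassifier
    counts: dict[str, int] = field(default_factory=dict)

    def report_row(self) -> dict:
        """Flat metric panel in standard reporting order."""
        row = {
            "features": self.feature_set,
            "look_ahead": f"{self.look_ahead[0]}-{self.look_ahead[1]}",
            "n_patients_test": self.n_test_patients,
            "n_days_test": self.n_test_days,
        }
        row.update(self.metrics.to_dict())
        return row


def run_forecast_study(
    q_table: pd.DataFrame,
    s_table: pd.DataFrame,
    feature_set: str = "biomarker2",
    look_ahead: tuple[int, int] = (1, 3),
    params: SmoothingParams = SmoothingParams(),
    definitions=DEFAULT_DEFINITIONS,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    counts: tuple[int, int, int] | None = None,
    seed: int = 0,
    model_config: dict | None = None,
) -> StudyResult:
    """Run the full forecasting study on prepared tables.

    One global seed governs the patient split, weight initialization and
    minibatch shuffling. ``model_config`` overrides LSTM hyperparameters
    (the same configuration is used whatever the feature set).
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    pids = patient_ids(q_table, s_table)
    partition = split_patients(pids, fractions=fractions, seed=seed, counts=counts)

    by_part: dict[str, list[ForecastSample]] = {
        "train": [], "validation": [], "test": []
    }
    q_groups = dict(tuple(q_table.groupby("patient_id", sort=False)))
    s_groups = dict(tuple(s_table.groupby("patient_id", sort=False)))
    empty_q = q_table.iloc[0:0]
    empty_s = s_table.iloc[0:0]
    n_prepared = 0
    for pid in pids:
        pdata = prepare_patient(
            pid,
            q_groups.get(pid, empty_q),
            s_groups.get(pid, empty_s),
            definitions,
            params,
            look_ahead,
            feature_set,
        )
        if pdata is None:
            logger.warning("patient %s skipped: no usable answers", pid)
            continue
        n_prepared += 1
        by_part[partition[pid]].extend(pdata.samples)
    for part, samples in by_part.items():
        logger.info("%s: %d samples", part, len(samples))

    cfg = LSTMConfig(
        n_features=FEATURE_SETS[feature_set].n_features,
        seed=seed,
        **(model_config or {}),
    )
    model = train_forecaster(by_part["train"], by_part["validation"], cfg)
    test = by_part["test"]
    probs = predict(model, test)
    y = np.array([s.label for s in test])
    metrics = best_mcc_threshold(probs, y)

    predictions = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in test],
            "day": [s.t for s in test],
            "probability": probs,
            "label": y,
        }
    )
    test_patients = {s.patient_id for s in test}
    return StudyResult(
        feature_set=feature_set,
        look_ahead=look_ahead,
        partition=partition,
        metrics=metrics,
        n_test_patients=len(test_patients),
        n_test_days=len(test),
        predictions=predictions,
        model=model,
        counts={
            "patients": len(pids),
            "patients_prepared": n_prepared,
            "train_samples": len(by_part["train"]),
            "validation_samples": len(by_part["validation"]),
            "test_samples": len(test),
        },
    )
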