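"""Feature construction, windowing, patient-level splitting and the
LSTM-based exacerbation-event forecaster.

Three per-day feature layouts are supported, all scaled to [0, 1]:

``raw22``
    The 11 coded answers divided by 100 (missing filled with 0) followed by
    11 answered indicators — the indicator disambiguates a true 0 answer
    from a missing one.
``avg4``
    Mean of the motivation/self-confidence answers (/100, 0 when none), an
    any-answered indicator for that subset, then the same pair for the
    wellbeing subset.
``biomarker2``
    The two smoothed digital biomarkers (motivation/self-confidence index,
    wellbeing index) divided by 100.

Each forecast sample is the feature window ending at an anchor day
(minimum 7, maximum 93 days of history) with a binary label marking an EE
start inside the look-ahead range. Splits are by patient, never by day, so
no patient contributes to more than one partition.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .biomarker import BiomarkerSeries
from .coding import MOTSC_QUESTIONS, QUESTIONS, WEBE_QUESTIONS
from .data import DailyPanel
from .events import LabelSet
from .nn import LSTMClassifier, LSTMConfig

__all__ = [
    "FeatureSetSpec",
    "FEATURE_SETS",
    "ForecastSample",
    "build_feature_rows",
    "make_samples",
    "split_patients",
    "pad_windows",
    "train_forecaster",
    "predict",
]

MIN_HISTORY = 7
MAX_HISTORY = 93


@dataclass(frozen=True)
class FeatureSetSpec:
    """Named per-day feature layout with its fixed width."""

    name: str
    n_features: int


FEATURE_SETS: dict[str, FeatureSetSpec] = {
    "raw22": FeatureSetSpec("raw22", 22),
    "avg4": FeatureSetSpec("avg4", 4),
    "biomarker2": FeatureSetSpec("biomarker2", 2),
}


@dataclass
class ForecastSample:
    """One (history window, label) pair anchored at day ``t``."""

    patient_id: str
    t: int
    window: np.ndarray  # (length, n_features), length in [MIN_HISTORY, MAX_HISTORY]
    label: int


def build_feature_rows(
    panel: DailyPanel,
    biomarkers: dict[str, BiomarkerSeries] | None,
    spec: FeatureSetSpec | str,
) -> np.ndarray:
    """Per-day feature matrix (n_days x n_features) for one patient.

    ``biomarkers`` maps {"MotSC-i": ..., "WeBe-i": ...} and is required for
    the ``biomarker2`` layout (lead days with no biomarker value yet are
    fed as 0).
    """
    if isinstance(spec, str):
        spec = FEATURE_SETS[spec]
    n = panel.n_days
    vals = panel.values[list(QUESTIONS)].to_numpy(dtype=float)

    if spec.name == "raw22":
        answered = (~np.isnan(vals)).astype(float)
        filled = np.nan_to_num(vals, nan=0.0) / 100.0
        return np.concatenate([filled, answered], axis=1)

    if spec.name == "avg4":
        out = np.zeros((n, 4))
        for j, subset in enumerate((MOTSC_QUESTIONS, WEBE_QUESTIONS)):
            cols = [QUESTIONS.index(q) for q in subset]
            sub = vals[:, cols]
            any_ans = ~np.isnan(sub).all(axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means = np.nanmean(sub, axis=1)
            out[:, 2 * j] = np.where(any_ans, np.nan_to_num(means, nan=0.0) / 100.0, 0.0)
            out[:, 2 * j + 1] = any_ans.astype(float)
        return out

    if spec.name == "biomarker2":
        if not biomarkers or "MotSC-i" not in biomarkers or "WeBe-i" not in biomarkers:
            raise ValueError("biomarker2 features require MotSC-i and WeBe-i series")
        out = np.zeros((n, 2))
        out[:, 0] = np.nan_to_num(biomarkers["MotSC-i"].values, nan=0.0) / 100.0
        out[:, 1] = np.nan_to_num(biomarkers["WeBe-i"].values, nan=0.0) / 100.0
        return out

    raise ValueError(f"unknown feature set {spec.name!r}")


def make_samples(
    features: np.ndarray,
    labels: LabelSet,
    eligible: np.ndarray,
    patient_id: str = "",
    min_hist: int = MIN_HISTORY,
    max_hist: int = MAX_HISTORY,
) -> list[ForecastSample]:
    """One sample per eligible, label-defined day with enough history.

    The window covers days ``t - L + 1 .. t`` inclusive with
    ``L = min(t + 1, max_hist)``; days with ``L < min_hist`` yield no
    sample. No feature in the window is dated after the anchor day.
    """
    n = len(features)
    samples = []
    for t in range(n):
        if not (eligible[t] and labels.defined[t]):
            continue
        length = min(t + 1, max_hist)
        if length < min_hist:
            continue
        samples.append(
            ForecastSample(
                patient_id=patient_id,
                t=t,
                window=features[t - length + 1 : t + 1],
                label=int(labels.labels[t]),
            )
        )
    return samples


def split_patients(
    patient_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    counts: tuple[int, int, int] | None = None,
) -> dict[str, str]:
    """Random patient-level partition into train/validation/test.

    Deterministic for a given seed. ``counts`` overrides ``fractions`` with
    exact partition sizes; otherwise validation and test sizes are rounded
    from the fractions and training takes the remainder.
    """
    ids = sorted(set(patient_ids))
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 patients to split")
    if counts is not None:
        n_train, n_val, n_test = counts
        if n_train + n_val + n_test != n:
            raise ValueError(f"counts {counts} do not sum to {n} patients")
    else:
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions {fractions} must sum to 1")
        n_val = int(round(n * fractions[1]))
        n_test = int(round(n * fractions[2]))
        n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("every partition must receive at least one patient")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out: dict[str, str] = {}
    for rank, idx in enumerate(perm):
        if rank < n_train:
            part = "train"
        elif rank < n_train + n_val:
            part = "validation"
        else:
            part = "test"
        out[ids[idx]] = part
    return out


def pad_windows(
    samples: Sequence[ForecastSample], max_hist: int = MAX_HISTORY
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left-pad windows to a dense (N, max_hist, F) batch with a mask.

    Padding sits at the old end; ``mask[i, j] = 1`` on real days. Returns
    ``(X, mask, y)``.
    """
    n = len(samples)
    if n == 0:
        return np.zeros((0, max_hist, 1)), np.zeros((0, max_hist)), np.zeros(0)
    f = samples[0].window.shape[1]
    X = np.zeros((n, max_hist, f))
    mask = np.zeros((n, max_hist))
    y = np.zeros(n)
    for i, s in enumerate(samples):
        L = len(s.window)
        X[i, max_hist - L :] = s.window
        mask[i, max_hist - L :] = 1.0
        y[i] = s.label
    return X, mask, y


def train_forecaster(
    train_samples: Sequence[ForecastSample],
    val_samples: Sequence[ForecastSample],
    config: LSTMConfig,
    max_hist: int = MAX_HISTORY,
) -> LSTMClassifier:
    """Fit the LSTM on training samples with validation-based early stopping."""
    if not len(train_samples) or not len(val_samples):
        raise ValueError("training and validation samples must be non-empty")
    X, m, y = pad_windows(train_samples, max_hist)
    Xv, mv, yv = pad_windows(val_samples, max_hist)
    if X.shape[2] != config.n_features:
        raise ValueError(
            f"config expects {config.n_features} features, windows have {X.shape[2]}"
        )
    model = LSTMClassifier(config)
    model.fit(X, m, y, Xv, mv, yv)
    return model


def predict(
    model: LSTMClassifier,
    samples: Sequence[ForecastSample],
    max_hist: int = MAX_HISTORY,
) -> np.ndarray:
    """Per-sample EE-onset probabilities in [0, 1], order-stable."""
    if not len(samples):
        return np.zeros(0)
    X, m, _ = pad_windows(samples, max_hist)
    return model.predict_proba(X, m)
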