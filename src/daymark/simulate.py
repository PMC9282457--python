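"""Synthetic addiction-monitoring cohorts with MNAR missingness.

Each simulated patient follows a daily three-state latent chain — stable,
deteriorating, in-exacerbation — that drives everything the monitoring
system would record:

* whether the patient answers the questionnaire at all that day (the
  answer probability drops sharply when deteriorating, so missingness is
  missing-not-at-random by construction: silence precedes relapse);
* the ordinal answer values (state-shifted means on the 0-100 scale with
  Gaussian dispersion, snapped to each question's coded grid; the
  motivation/self-confidence items are shifted hardest in deterioration);
* the daily breathalyzer status (alcohol detected or all tests omitted
  while in exacerbation, occasional innocent omissions otherwise).

Stable-state answer means default to the per-question means reported for a
real monitored cohort, so marginal answer distributions are plausible. The
generator emits the exact CSV-shaped tables the readers accept, plus the
ground-truth latent states and exacerbation starts for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import DEFAULT_CODING, MOTSC_QUESTIONS, QUESTIONS
from .events import EventCalendar, LabelSet, make_labels

__all__ = ["SynthConfig", "SynthCohort", "simulate_cohort", "ground_truth_labels"]

STABLE, DETERIORATING, IN_EE = 0, 1, 2

#: Stable-state mean answer value per question (0-100 scale), patterned on
#: a real cohort's marginal answer means.
_BASE_MEANS: dict[str, float] = {
    "HowWas": 73.0,
    "Sleep": 69.0,
    "Eat": 71.0,
    "WorkSchool": 74.0,
    "Routine": 79.0,
    "Exercise": 54.0,
    "Socialized": 76.0,
    "Angry": 91.0,
    "Stress": 77.0,
    "Motivation": 89.0,
    "SelfConf": 91.0,
}


@dataclass
class SynthConfig:
    """Cohort-generator settings; defaults define the standard conditions.

    Probabilities are per day. ``answer_prob_mult`` and ``mean_shift`` are
    indexed (stable, deteriorating, in-EE); ``motsc_extra_shift`` is added
    on top of ``mean_shift`` for the Motivation/SelfConf items outside the
    stable state, making loss of motivation the leading indicator.
    """

    n_patients: int = 300
    days_per_patient: int = 120
    answer_prob: float = 0.9
    question_prob: float = 0.75  # per-question answer prob given an answering day
    answer_prob_mult: tuple[float, float, float] = (1.0, 0.33, 0.22)
    mean_shift: tuple[float, float, float] = (0.0, -30.0, -45.0)
    motsc_extra_shift: float = -10.0
    noise_sd: float = 18.0
    p_stable_to_det: float = 0.03
    p_det_to_ee: float = 0.25
    p_det_to_stable: float = 0.15
    p_ee_to_stable: float = 0.35
    ee_min_days: int = 2
    p_detect_in_ee: float = 0.6  # else all tests omitted while in EE
    p_omit_good: float = 0.05  # innocent omissions outside EEs
    start_date: str = "2020-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.answer_prob,
            self.question_prob,
            self.p_stable_to_det,
            self.p_det_to_ee,
            self.p_det_to_stable,
            self.p_ee_to_stable,
            self.p_detect_in_ee,
            self.p_omit_good,
            *self.answer_prob_mult,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.p_det_to_ee + self.p_det_to_stable > 1.0:
            raise ValueError("deteriorating-state exit probabilities exceed 1")
        if self.days_per_patient < 15:
            raise ValueError("need >= 15 days (start-up period plus minimum history)")

    def zero_signal(self) -> "SynthConfig":
        """Copy with all questionnaire state effects removed (null model)."""
        return SynthConfig(
            **{
                **self.__dict__,
                "answer_prob_mult": (1.0, 1.0, 1.0),
                "mean_shift": (0.0, 0.0, 0.0),
                "motsc_extra_shift": 0.0,
            }
        )


@dataclass
class SynthCohort:
    """Generated tables plus the ground truth that produced them."""

    q_table: pd.DataFrame
    s_table: pd.DataFrame
    states: dict[str, np.ndarray]  # patient -> per-day latent state
    ee_starts: dict[str, np.ndarray]  # patient -> true EE start day indices
    config: SynthConfig

    @property
    def patient_list(self) -> list[str]:
        return sorted(self.states)


def _snap_to_grid(value: float, grid: np.ndarray) -> int:
    return int(grid[np.argmin(np.abs(grid - value))])


def _simulate_states(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.days_per_patient
    states = np.empty(n, dtype=int)
    states[0] = STABLE
    dwell = 0
    for d in range(1, n):
        prev = states[d - 1]
        if prev == STABLE:
            states[d] = DETERIORATING if rng.random() < cfg.p_stable_to_det else STABLE
        elif prev == DETERIORATING:
            u = rng.random()
            if u < cfg.p_det_to_ee:
                states[d] = IN_EE
            elif u < cfg.p_det_to_ee + cfg.p_det_to_stable:
                states[d] = STABLE
            else:
                states[d] = DETERIORATING
        else:  # IN_EE; enforce the minimum event duration
            if dwell < cfg.ee_min_days or rng.random() >= cfg.p_ee_to_stable:
                states[d] = IN_EE
            else:
                states[d] = STABLE
        dwell = dwell + 1 if states[d] == IN_EE and prev == IN_EE else (
            1 if states[d] == IN_EE else 0
        )
    return states


def _true_ee_runs(states: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal in-EE runs of length >= min_len as (start, end) inclusive.

    A run truncated by the end of the observation span to fewer than
    ``min_len`` days is not a ground-truth event."""
    in_ee = states == IN_EE
    runs = []
    t, n = 0, len(states)
    while t < n:
        if in_ee[t]:
            s0 = t
            while t < n and in_ee[t]:
                t += 1
            if t - s0 >= min_len:
                runs.append((s0, t - 1))
        else:
            t += 1
    return runs


def simulate_cohort(config: SynthConfig = SynthConfig()) -> SynthCohort:
    """Generate a cohort; identical config and seed give identical output."""
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start_date, periods=config.days_per_patient, freq="D")
    grids = {
        q: np.array(sorted(DEFAULT_CODING.valid_values(q)), dtype=float)
        for q in QUESTIONS
    }

    q_rows: list[tuple] = []
    s_rows: list[tuple] = []
    states: dict[str, np.ndarray] = {}
    starts: dict[str, np.ndarray] = {}
    width = len(str(max(config.n_patients - 1, 1)))
    for p in range(config.n_patients):
        pid = f"P{p:0{width}d}"
        st = _simulate_states(config, rng)
        states[pid] = st
        starts[pid] = np.array(
            [s for s, _ in _true_ee_runs(st, config.ee_min_days)], dtype=int
        )
        for d in range(config.days_per_patient):
            s = st[d]
            # sobriety record: one collapsed status per treatment day
            if s == IN_EE:
                status = (
                    "alcohol_detected"
                    if rng.random() < config.p_detect_in_ee
                    else "all_omitted"
                )
            else:
                status = (
                    "all_omitted" if rng.random() < config.p_omit_good else "no_alcohol"
                )
            s_rows.append((pid, dates[d], status))

            if rng.random() >= config.answer_prob * config.answer_prob_mult[s]:
                continue  # a fully silent questionnaire day
            shift = config.mean_shift[s]
            for q in QUESTIONS:
                if rng.random() >= config.question_prob:
                    continue
                mu = _BASE_MEANS[q] + shift
                if s != STABLE and q in MOTSC_QUESTIONS:
                    mu += config.motsc_extra_shift
                value = _snap_to_grid(
                    rng.normal(mu, config.noise_sd), grids[q]
                )
                q_rows.append((pid, dates[d], q, value))

    q_table = pd.DataFrame(
        q_rows, columns=["patient_id", "date", "question", "value"]
    )
    s_table = pd.DataFrame(s_rows, columns=["patient_id", "date", "status"])
    s_table["ami"] = np.nan
    return SynthCohort(
        q_table=q_table,
        s_table=s_table,
        states=states,
        ee_starts=starts,
        config=config,
    )


def ground_truth_labels(
    cohort: SynthCohort, look_ahead: tuple[int, int] = (1, 3)
) -> dict[str, LabelSet]:
    """Forecast labels from the true latent EE starts, bypassing detection.

    Used to validate status-based event detection: when the recorded status
    perfectly reflects the latent state, detection-based labels must agree.
    """
    out: dict[str, LabelSet] = {}
    n = cohort.config.days_per_patient
    for pid, st in cohort.states.items():
        intervals = _true_ee_runs(st, cohort.config.ee_min_days)
        in_ee = np.zeros(n, dtype=bool)
        for s0, e in intervals:
            in_ee[s0 : e + 1] = True
        cal = EventCalendar(
            n_days=n, intervals=intervals, in_ee=in_ee, patient_id=pid
        )
        out[pid] = make_labels(cal, look_ahead)
    return out
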