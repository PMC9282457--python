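"""Tabular input handling and per-patient calendar grids.

Two long-format CSV inputs drive everything downstream:

* questionnaire answers, one row per (patient, date, question), with either
  an ``answer`` label column or a pre-coded ``value`` column;
* breathalyzer/sobriety records, one row per (patient, date, test), with a
  ``status`` column in {no_alcohol, alcohol_detected, all_omitted} and an
  optional ``ami`` column carrying an externally computed sobriety index.

Both are validated into tidy :class:`pandas.DataFrame` tables and laid out
per patient on a gapless calendar grid (:class:`DailyPanel`). The grid spans
the first to the last day on which the patient produced any record, so
leading/trailing inactive runs are trimmed while interior gaps — the
missing-data signal the method exploits — are preserved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd

from .coding import DEFAULT_CODING, QUESTIONS, AnswerCoding, CodingError

__all__ = [
    "SOBRIETY_STATUSES",
    "ParseError",
    "DailyPanel",
    "read_questionnaire",
    "read_sobriety",
    "build_day_grid",
    "patient_ids",
]

#: Valid per-day sobriety statuses, in collapse precedence order: a single
#: detected test marks the day even if other tests passed or were omitted.
SOBRIETY_STATUSES = ("alcohol_detected", "no_alcohol", "all_omitted")


class ParseError(ValueError):
    """Malformed input table; message carries the offending row number."""


def _read_csv(path: str | PathLike | io.TextIOBase) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _parse_dates(raw: pd.Series) -> pd.Series:
    dates = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    if dates.isna().any():
        row = int(dates.index[dates.isna()][0]) + 2  # header is line 1
        raise ParseError(f"line {row}: malformed date {raw[dates.isna()].iloc[0]!r}")
    return dates.dt.normalize()


def read_questionnaire(
    path: str | PathLike | io.TextIOBase,
    coding: AnswerCoding = DEFAULT_CODING,
) -> pd.DataFrame:
    """Read and validate a long-format questionnaire CSV.

    Expected columns: ``patient_id, date, question, answer`` (labels) or
    ``patient_id, date, question, value`` (pre-coded numbers); if both are
    present, ``value`` wins where non-empty.

    Returns
    -------
    pandas.DataFrame
        Columns ``patient_id`` (str), ``date`` (day-normalized datetime),
        ``question`` (str), ``value`` (int in the question's coded set);
        at most one row per (patient, date, question).

    Raises
    ------
    ParseError
        Missing columns, malformed dates, unknown questions or labels,
        out-of-set coded values, or duplicate keys — all with line numbers.
    """
    df = _read_csv(path)
    required = {"patient_id", "date", "question"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing required column(s): {sorted(missing)}")
    if "answer" not in df.columns and "value" not in df.columns:
        raise ParseError("need an 'answer' (label) or 'value' (coded) column")

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype(str).str.strip(),
            "date": _parse_dates(df["date"]),
            "question": df["question"].astype(str).str.strip(),
        }
    )

    values = np.full(len(df), np.nan)
    if "value" in df.columns:
        coded = pd.to_numeric(df["value"], errors="coerce")
        values = coded.to_numpy(dtype=float)
    if "answer" in df.columns:
        labels = df["answer"].astype(str).str.strip()
        for i in np.nonzero(np.isnan(values))[0]:
            q = out["question"].iloc[i]
            try:
                values[i] = coding.code(q, labels.iloc[i])
            except CodingError as exc:
                raise ParseError(f"line {i + 2}: {exc}") from exc

    valid = {q: coding.valid_values(q) for q in coding.questions}
    for i, (q, v) in enumerate(zip(out["question"], values)):
        if q not in valid:
            raise ParseError(f"line {i + 2}: unknown question {q!r}")
        if np.isnan(v) or int(v) != v or int(v) not in valid[q]:
            raise ParseError(
                f"line {i + 2}: value {v!r} not in coded set for question {q!r}"
            )
    out["value"] = values.astype(int)

    dup = out.duplicated(subset=["patient_id", "date", "question"])
    if dup.any():
        row = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise ParseError(
            f"line {row}: duplicate (patient, date, question) record"
        )
    return out


def read_sobriety(path: str | PathLike | io.TextIOBase) -> pd.DataFrame:
    """Read a sobriety CSV and collapse multiple tests per day to one status.

    Expected columns: ``patient_id, date, status[, ami]``. Per-day collapse
    precedence is ``alcohol_detected > no_alcohol > all_omitted``; when an
    ``ami`` column is present the day keeps the first non-missing value.

    Returns a frame with one row per (patient, date) and columns
    ``patient_id, date, status, ami`` (``ami`` is NaN where absent).
    """
    df = _read_csv(path)
    required = {"patient_id", "date", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing required column(s): {sorted(missing)}")

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype(str).str.strip(),
            "date": _parse_dates(df["date"]),
            "status": df["status"].astype(str).str.strip(),
        }
    )
    bad = ~out["status"].isin(SOBRIETY_STATUSES)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0]) + 2
        raise ParseError(
            f"line {row}: unknown status {out['status'][bad].iloc[0]!r}"
        )
    if "ami" in df.columns:
        ami = pd.to_numeric(df["ami"], errors="coerce")
        if ((ami < 0) | (ami > 100)).any():
            row = int(np.nonzero(((ami < 0) | (ami > 100)).to_numpy())[0][0]) + 2
            raise ParseError(f"line {row}: ami outside [0, 100]")
        out["ami"] = ami.to_numpy(dtype=float)
    else:
        out["ami"] = np.nan

    precedence = {s: i for i, s in enumerate(SOBRIETY_STATUSES)}
    out["_rank"] = out["status"].map(precedence)
    out = out.sort_values(["patient_id", "date", "_rank"], kind="stable")
    collapsed = out.groupby(["patient_id", "date"], as_index=False).agg(
        status=("status", "first"), ami=("ami", "first")
    )
    return collapsed


@dataclass
class DailyPanel:
    """Gapless per-patient calendar grid of raw daily data.

    Attributes
    ----------
    patient_id : str
    start : pandas.Timestamp
        Calendar date of day index 0.
    values : pandas.DataFrame
        ``n_days x 11`` float frame in canonical question order; NaN marks
        an unanswered question-day.
    status : pandas.Series
        Per-day sobriety status (object dtype; None when the day has no
        sobriety record).
    ami : pandas.Series
        Per-day externally supplied sobriety index, NaN where absent.
    activity : numpy.ndarray
        Boolean per-day flag: any questionnaire answer or sobriety record.
    """

    patient_id: str
    start: pd.Timestamp
    values: pd.DataFrame
    status: pd.Series
    ami: pd.Series
    activity: np.ndarray

    @property
    def n_days(self) -> int:
        return len(self.values)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_days, freq="D")

    def __post_init__(self) -> None:
        n = len(self.values)
        if not (len(self.status) == len(self.ami) == len(self.activity) == n):
            raise ValueError("panel fields must share one day axis")
        if n and not (self.activity[0] and self.activity[-1]):
            raise ValueError("inactive tails must be trimmed")


def patient_ids(q_table: pd.DataFrame, s_table: pd.DataFrame | None = None) -> list[str]:
    """Sorted union of patient ids appearing in the input tables."""
    ids = set(q_table["patient_id"].unique())
    if s_table is not None and len(s_table):
        ids |= set(s_table["patient_id"].unique())
    return sorted(ids)


def build_day_grid(
    q_table: pd.DataFrame,
    s_table: pd.DataFrame | None,
    patient_id: str,
) -> DailyPanel:
    """Lay one patient's records out on a gapless calendar grid.

    The grid spans the first through the last day with any record (answer or
    sobriety test) for the patient, so leading/trailing inactive runs never
    enter the panel; interior all-missing days are kept as such.

    Raises
    ------
    KeyError
        If the patient appears in neither table.
    """
    q = q_table[q_table["patient_id"] == patient_id]
    if s_table is not None and len(s_table):
        s = s_table[s_table["patient_id"] == patient_id]
    else:
        s = pd.DataFrame(columns=["patient_id", "date", "status", "ami"])

    record_dates = pd.concat([q["date"], s["date"]]) if len(s) else q["date"]
    if record_dates.empty:
        raise KeyError(f"patient {patient_id!r} has no records")
    start, stop = record_dates.min(), record_dates.max()
    n = (stop - start).days + 1

    vmat = np.full((n, len(QUESTIONS)), np.nan)
    if len(q):
        t_idx = (q["date"] - start).dt.days.to_numpy()
        q_idx = q["question"].map({qq: j for j, qq in enumerate(QUESTIONS)}).to_numpy()
        vmat[t_idx, q_idx] = q["value"].to_numpy(dtype=float)
    values = pd.DataFrame(vmat, columns=list(QUESTIONS))

    status = pd.Series([None] * n, dtype=object)
    ami = pd.Series(np.full(n, np.nan))
    if len(s):
        t_idx = (s["date"] - start).dt.days.to_numpy()
        status.iloc[t_idx] = s["status"].to_numpy()
        ami.iloc[t_idx] = s["ami"].to_numpy(dtype=float)

    activity = (values.notna().any(axis=1) | status.notna()).to_numpy()
    return DailyPanel(
        patient_id=patient_id,
        start=start,
        values=values,
        status=status,
        ami=ami,
        activity=activity,
    )
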