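"""Ordinal answer coding for the 11-question daily monitoring questionnaire.

Each question offers either five or three answer alternatives. Alternatives
are coded onto a fixed 0-100 grid where a higher value always reflects a more
positive outcome: five-alternative questions use {0, 25, 50, 75, 100} and
three-alternative questions (Exercise, Socialized, Angry) use {0, 50, 100}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "QUESTIONS",
    "WEBE_QUESTIONS",
    "MOTSC_QUESTIONS",
    "AnswerCoding",
    "CodingError",
    "DEFAULT_CODING",
    "code_answer",
    "decode_value",
]

#: Canonical question order; all matrices and panels use this column order.
QUESTIONS: tuple[str, ...] = (
    "HowWas",
    "Sleep",
    "Eat",
    "WorkSchool",
    "Routine",
    "Exercise",
    "Socialized",
    "Angry",
    "Stress",
    "Motivation",
    "SelfConf",
)

#: Default wellbeing item subset (9 questions).
WEBE_QUESTIONS: tuple[str, ...] = (
    "HowWas",
    "Sleep",
    "Eat",
    "WorkSchool",
    "Routine",
    "Exercise",
    "Socialized",
    "Angry",
    "Stress",
)

#: Default motivation / self-confidence item subset (2 questions).
MOTSC_QUESTIONS: tuple[str, ...] = ("Motivation", "SelfConf")

_FIVE = (0, 25, 50, 75, 100)
_THREE = (0, 50, 100)

# label -> coded value, in ascending value order, per question
_LABELS: dict[str, dict[str, int]] = {
    "HowWas": {
        "Very bad": 0,
        "Bad": 25,
        "So-so": 50,
        "Good": 75,
        "Very good": 100,
    },
    "Sleep": {
        "Very badly": 0,
        "Badly": 25,
        "So-so": 50,
        "Well": 75,
        "Very well": 100,
    },
    "Eat": {
        "Very badly": 0,
        "Badly": 25,
        "So-so": 50,
        "Well": 75,
        "Very well": 100,
    },
    "WorkSchool": {
        "Very bad": 0,
        "Bad": 25,
        "So-so": 50,
        "Good": 75,
        "Very good": 100,
    },
    "Routine": {
        "Very badly": 0,
        "Badly": 25,
        "So-so": 50,
        "Well": 75,
        "Very well": 100,
    },
    "Exercise": {
        "No": 0,
        "In my everyday life": 50,
        "Yes": 100,
    },
    "Socialized": {
        "No": 0,
        "Just shortly": 50,
        "Yes": 100,
    },
    "Angry": {
        "Lots of people": 0,
        "A few people": 50,
        "No one": 100,
    },
    "Stress": {
        "Yes, very much so": 0,
        "Yes, quite a bit": 25,
        "Yes, a little": 50,
        "Not so much": 75,
        "Not at all": 100,
    },
    "Motivation": {
        "Not at all": 0,
        "Rather unmotivated": 25,
        "A little motivated": 50,
        "Strongly motivated": 75,
        "Very strongly motivated": 100,
    },
    "SelfConf": {
        "Not at all": 0,
        "Not so much": 25,
        "I think so": 50,
        "Yes, I do": 75,
        "Yes, without any doubt": 100,
    },
}


class CodingError(ValueError):
    """Raised when a question id or answer label is not part of the coding."""


@dataclass(frozen=True)
class AnswerCoding:
    """Mapping from answer labels to coded 0-100 values for every question.

    Attributes
    ----------
    label_maps
        Per-question ordered mapping ``label -> coded value``. Coded values
        are drawn from {0, 25, 50, 75, 100}; three-alternative questions use
        exactly {0, 50, 100}.
    """

    label_maps: dict[str, dict[str, int]] = field(
        default_factory=lambda: {q: dict(m) for q, m in _LABELS.items()}
    )

    def __post_init__(self) -> None:
        for q, m in self.label_maps.items():
            values = tuple(sorted(m.values()))
            if values not in (_FIVE, _THREE):
                raise CodingError(
                    f"question {q!r}: coded values {values} are neither the "
                    f"5-point grid {_FIVE} nor the 3-point grid {_THREE}"
                )

    @property
    def questions(self) -> tuple[str, ...]:
        return tuple(self.label_maps)

    def valid_values(self, question_id: str) -> frozenset[int]:
        """Set of coded values admissible for ``question_id``."""
        try:
            return frozenset(self.label_maps[question_id].values())
        except KeyError:
            raise CodingError(f"unknown question id {question_id!r}") from None

    def code(self, question_id: str, answer_label: str) -> int:
        """Coded 0-100 value for an answer label; see :func:`code_answer`."""
        if question_id not in self.label_maps:
            raise CodingError(f"unknown question id {question_id!r}")
        try:
            return self.label_maps[question_id][answer_label]
        except KeyError:
            raise CodingError(
                f"question {question_id!r} has no answer alternative "
                f"{answer_label!r}"
            ) from None

    def decode(self, question_id: str, value: int) -> str:
        """Answer label whose coded value is ``value`` (inverse of code)."""
        for label, v in self.label_maps.get(question_id, {}).items():
            if v == value:
                return label
        raise CodingError(
            f"question {question_id!r} has no alternative coded as {value!r}"
        )


DEFAULT_CODING = AnswerCoding()


def code_answer(
    question_id: str, answer_label: str, coding: AnswerCoding = DEFAULT_CODING
) -> int:
    """Code an answer label into its 0-100 database value.

    Raises
    ------
    CodingError
        If the question id is unknown or the label is not one of the
        question's listed alternatives.
    """
    return coding.code(question_id, answer_label)


def decode_value(
    question_id: str, value: int, coding: AnswerCoding = DEFAULT_CODING
) -> str:
    """Inverse of :func:`code_answer`."""
    return coding.decode(question_id, value)
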