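"""Schemas for the seven-item dietary BPA exposure risk questionnaire.

The instrument asks how often a participant performs dietary behaviors that
raise bisphenol A (BPA) exposure: eating canned food, microwaving food in
plastic containers, drinking from reusable polycarbonate bottles, drinking
hot beverages from hard plastic cups, microwaving food under plastic stretch
wrap, eating prepared microwaveable meals, and eating packaged food items.

Each question has a small set of ordered answer categories.  A
:class:`QuestionSchema` records, for one question, the category labels in
increasing order of exposure frequency, the integer recode map implied by
that order (1 = lowest frequency), and the three-level bin (low / medium /
high) used as a categorical predictor in the validation regressions, with
the low bin as the reference level.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Code used for a blank (missing) answer in label tables.
MISSING = ""

#: Code used when the participant answered "I don't know".  Converted to
#: :data:`MISSING` before imputation by
#: :func:`bpae.impute.code_dont_know_missing`.
DONT_KNOW = "I don't know"

BIN_LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class QuestionSchema:
    """One question: ordered categories, recode map, and regression bins.

    Parameters
    ----------
    qid:
        Question number, 1-7.
    key:
        Short machine name used as the column name in tables.
    text:
        The question wording shown to participants.
    categories:
        Answer category labels ordered from lowest to highest exposure
        frequency.  The recode map assigns ``1`` to the first label,
        ``2`` to the second, and so on.
    bins:
        Bin level (``"low"``/``"medium"``/``"high"``) for each category,
        parallel to ``categories``.
    reference_bin:
        The bin used as the regression reference level (default ``"low"``).
    """

    qid: int
    key: str
    text: str
    categories: tuple[str, ...]
    bins: tuple[str, ...]
    reference_bin: str = "low"

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.bins):
            raise ValueError(
                f"question {self.qid}: categories and bins differ in length"
            )
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"question {self.qid}: duplicate category labels")
        bad = set(self.bins) - set(BIN_LEVELS)
        if bad:
            raise ValueError(f"question {self.qid}: unknown bin levels {bad}")
        if self.reference_bin not in self.bins:
            raise ValueError(
                f"question {self.qid}: reference bin {self.reference_bin!r} "
                "not among the question's bins"
            )

    @property
    def n_levels(self) -> int:
        return len(self.categories)

    @property
    def recode_map(self) -> dict[str, int]:
        """Category label -> integer code, 1 = lowest exposure frequency."""
        return {c: i + 1 for i, c in enumerate(self.categories)}

    @property
    def code_to_bin(self) -> dict[int, str]:
        return {i + 1: b for i, b in enumerate(self.bins)}

    @property
    def code_to_category(self) -> dict[int, str]:
        return {i + 1: c for i, c in enumerate(self.categories)}


def default_schemas() -> tuple[QuestionSchema, ...]:
    """The seven-question instrument with its published category wording."""
    return (
        QuestionSchema(
            1,
            "canned",
            "In a typical week, how often do you eat canned food?",
            ("None", "1 or 2 /week", "3 or more/week"),
            BIN_LEVELS,
        ),
        QuestionSchema(
            2,
            "micro_plastic",
            "How often do you microwave food stored in plastic containers?",
            ("Never", "Infrequently or Sometimes", "Often or Always"),
            BIN_LEVELS,
        ),
        QuestionSchema(
            3,
            "plastic_bottle",
            "How often do you drink beverages from a re-usable, hard plastic bottle?",
            ("Don't know or Never", "Infrequently or Sometimes", "Often or Always"),
            BIN_LEVELS,
        ),
        QuestionSchema(
            4,
            "hot_cup",
            "Do you drink hot beverages from a hard, clear plastic cup?",
            ("Don't know or Never", "Infrequently or Sometimes", "Often or Always"),
            BIN_LEVELS,
        ),
        QuestionSchema(
            5,
            "stretch_wrap",
            "How often do you microwave your food with plastic stretch wrap on?",
            ("Don't know or Never", "Infrequently or Sometimes", "Often or Always"),
            BIN_LEVELS,
        ),
        QuestionSchema(
            6,
            "micro_meals",
            "In a typical day, how many prepared, microwavable meals do you eat?",
            ("Don't know or None", "1 or 2 items/day", "3 or more items/day"),
            BIN_LEVELS,
        ),
        QuestionSchema(
            7,
            "packaged",
            "In a typical day, how many packaged food items do you eat?",
            ("None or 1 item/day", "2 or 3 items/day", "4 or more items/day"),
            BIN_LEVELS,
        ),
    )


def question_keys(schemas: tuple[QuestionSchema, ...] | None = None) -> list[str]:
    schemas = default_schemas() if schemas is None else schemas
    return [s.key for s in schemas]
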