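"""Keyword classification of recall food items and exposure metrics.

Free-text food descriptions are searched (case-insensitively, substring
match) for the packaging keywords ``canned``, ``packaged``, ``microwave``.
Each item is assigned exactly one category; when several keywords match,
precedence is canned > microwave > packaged, so the highest-weight category
wins.  Two per-participant exposure metrics are computed per recall day and
averaged over observed days:

* weighted servings = sum of servings x weight, with weights 1.0 (canned),
  0.25 (packaged), 0.25 (microwave) reflecting relative BPA contamination
  potential of the packaging;
* total grams = unweighted sum of grams over items in any of the three
  categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KEYWORDS = ("canned", "packaged", "microwave")

#: Relative BPA contamination weight per packaging category.
WEIGHTS = {"canned": 1.0, "packaged": 0.25, "microwave": 0.25, "none": 0.0}

#: Classification precedence when a description matches several keywords.
PRECEDENCE = ("canned", "microwave", "packaged")

#: Column names of the per-participant exposure table.
METRIC_COLUMNS = [
    "weighted_servings",
    "total_grams",
    "servings_canned",
    "servings_packaged",
    "servings_microwave",
    "grams_canned",
    "grams_packaged",
    "grams_microwave",
]


@dataclass
class FoodLists:
    """Keyword-matched food-id sets from a description dictionary.

    Sets may overlap (a description can contain more than one keyword);
    single-category assignment happens at classification time via
    :data:`PRECEDENCE`.
    """

    canned_ids: set
    packaged_ids: set
    microwave_ids: set
    source_description: str = ""

    @property
    def counts(self) -> dict[str, int]:
        return {
            "canned": len(self.canned_ids),
            "packaged": len(self.packaged_ids),
            "microwave": len(self.microwave_ids),
        }


def build_food_lists(
    dictionary: pd.DataFrame,
    case_insensitive: bool = True,
    source_description: str = "keyword search of food-description dictionary",
) -> FoodLists:
    """Search a food dictionary's descriptions for the packaging keywords.

    ``dictionary`` needs columns ``food_id`` and ``food_description``.
    A food id lands in a category's set iff its description contains that
    keyword as a substring.
    """
    if len(dictionary) == 0:
        raise ValueError("empty food dictionary")
    desc = dictionary["food_description"].astype(str)
    if desc.str.len().eq(0).any():
        raise ValueError("food dictionary contains empty descriptions")
    if case_insensitive:
        desc = desc.str.lower()
    sets = {}
    for kw in KEYWORDS:
        mask = desc.str.contains(kw, regex=False)
        sets[kw] = set(dictionary.loc[mask, "food_id"])
    return FoodLists(
        canned_ids=sets["canned"],
        packaged_ids=sets["packaged"],
        microwave_ids=sets["microwave"],
        source_description=source_description,
    )


def classify_item(
    description: str,
    lists: FoodLists | None = None,
    *,
    case_insensitive: bool = True,
    precedence: tuple[str, ...] = PRECEDENCE,
) -> str:
    """Assign one packaging category to a food description.

    Pure function of the description text: returns the first keyword in
    ``precedence`` order that occurs in the description, or ``"none"``.
    ``lists`` is accepted for interface symmetry but classification is
    textual, so dictionary and recall descriptions are treated identically.
    """
    text = str(description)
    if case_insensitive:
        text = text.lower()
    for kw in precedence:
        if kw in text:
            return kw
    return "none"


def classify_items(recall: pd.DataFrame, **kwargs) -> pd.Series:
    """Vectorized :func:`classify_item` over a recall table."""
    return recall["food_description"].map(lambda d: classify_item(d, **kwargs))


def _check_nonnegative(items: pd.DataFrame, column: str) -> None:
    if (items[column].to_numpy(dtype=float) < 0).any():
        raise ValueError(f"negative {column} in recall items")


def weighted_servings(items: pd.DataFrame, lists: FoodLists | None = None) -> float:
    """Weighted servings for one batch of recall items (one participant-day)."""
    if len(items) == 0:
        return 0.0
    _check_nonnegative(items, "servings")
    cats = classify_items(items)
    w = cats.map(WEIGHTS).to_numpy(dtype=float)
    return float(np.dot(items["servings"].to_numpy(dtype=float), w))


def total_grams(items: pd.DataFrame, lists: FoodLists | None = None) -> float:
    """Unweighted grams over classified items; unmatched items excluded."""
    if len(items) == 0:
        return 0.0
    _check_nonnegative(items, "grams")
    cats = classify_items(items)
    keep = cats != "none"
    return float(items.loc[keep.to_numpy(), "grams"].sum())


def exposure_by_day(recall: pd.DataFrame) -> pd.DataFrame:
    """Per participant-day exposure metrics.

    A day counts as observed if it has any recall row at all, even if no
    item matched a keyword (zero exposure is a valid observation).
    """
    _check_nonnegative(recall, "servings")
    _check_nonnegative(recall, "grams")
    df = recall[["participant_id", "day_index", "servings", "grams"]].copy()
    df["category"] = classify_items(recall).to_numpy()
    out = None
    for cat in KEYWORDS:
        sub = (
            df.assign(
                s=np.where(df["category"] == cat, df["servings"], 0.0),
                g=np.where(df["category"] == cat, df["grams"], 0.0),
            )
            .groupby(["participant_id", "day_index"], as_index=False)[["s", "g"]]
            .sum()
            .rename(columns={"s": f"servings_{cat}", "g": f"grams_{cat}"})
        )
        out = sub if out is None else out.merge(
            sub, on=["participant_id", "day_index"]
        )
    out["weighted_servings"] = sum(
        WEIGHTS[cat] * out[f"servings_{cat}"] for cat in KEYWORDS
    )
    out["total_grams"] = sum(out[f"grams_{cat}"] for cat in KEYWORDS)
    return out


def average_over_days(
    by_day: pd.DataFrame, roster: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """Average each exposure metric over a participant's observed days.

    Days without any recall record are missing data, not zero intake, so
    the mean runs over observed days only.  If a ``roster`` of participant
    ids is supplied, participants with zero observed days are logged and
    excluded from the output.
    """
    if len(by_day) == 0:
        raise ValueError("no recall days to average")
    metrics = [c for c in METRIC_COLUMNS if c in by_day.columns]
    grouped = by_day.groupby("participant_id", as_index=False)
    out = grouped[metrics].mean()
    out["n_days_observed"] = grouped.size()["size"].to_numpy()
    if roster is not None:
        roster = pd.Series(roster).unique()
        absent = np.setdiff1d(roster, out["participant_id"].to_numpy())
        if len(absent) > 0:
            logger.warning(
                "%d participant(s) with no recall days excluded from exposure "
                "averages: %s",
                len(absent),
                absent[:10].tolist(),
            )
    return out


def compute_exposure(
    recall: pd.DataFrame, roster: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """Full recall-side pipeline: classify, per-day metrics, day average."""
    return average_over_days(exposure_by_day(recall), roster=roster)
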