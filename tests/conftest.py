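import numpy as np
import pandas as pd
import pytest

from bpae import CohortSpec, default_schemas, generate_cohort


@pytest.fixture(scope="session")
def schemas():
    return default_schemas()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (n=404, three recall days), seed-fixed."""
    spec = CohortSpec(seed=42)
    questionnaire, recall, truth = generate_cohort(spec)
    return spec, questionnaire, recall, truth


@pytest.fixture()
def tiny_dictionary():
    return pd.DataFrame(
        {
            "food_id": [1, 2, 3, 4, 5],
            "food_description": [
                "Tomatoes, canned, diced",
                "Apple, raw",
                "Popcorn, microwave, butter",
                "Snack cake, packaged, chocolate",
                "CANNED soup",
            ],
        }
    )


def make_items(servings_by_category, grams_by_category=None):
    """Build a recall-item frame with one row per (category, servings) pair."""
    desc = {
        "canned": "Soup, chicken noodle, canned",
        "packaged": "Snack cake, packaged, chocolate",
        "microwave": "Popcorn, microwave, butter",
        "none": "Broccoli, raw",
    }
    rows = []
    for cat, servings in servings_by_category:
        rows.append(
            {
                "participant_id": 1,
                "day_index": 1,
                "food_id": 99,
                "food_description": desc[cat],
                "servings": servings,
                "grams": 0.0,
            }
        )
    df = pd.DataFrame(rows)
    if grams_by_category is not None:
        df["grams"] = [g for _, g in grams_by_category]
    return df
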