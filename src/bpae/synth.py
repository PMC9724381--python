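"""Synthetic cohort generator with known ground truth.

Emulates the joint statistical structure the analysis pipeline assumes: a
single log-normal latent exposure factor per participant drives (a) the
seven ordinal questionnaire responses, via Gaussian-noise thresholding onto
each question's marginal category distribution, and (b) the number of
canned / packaged / microwave food items recorded on each 24-hour dietary
recall day, via a Poisson log-link.  Item counts, servings, and grams are
right-skewed by construction.  Missing answers and "I don't know" answers
are injected per question at configurable rates.

Everything is driven by a :class:`CohortSpec` and a seed; identical
(spec, seed) pairs produce bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .questions import DONT_KNOW, MISSING, QuestionSchema, default_schemas

logger = logging.getLogger(__name__)

CATEGORY_KEYS = ("canned", "packaged", "microwave")

# Default per-question marginal category distributions (low -> high
# frequency), normalized to sum to 1.  The raw figures are the observed
# response percentages of the seven-question instrument at baseline.
_RAW_MARGINALS: dict[str, tuple[float, ...]] = {
    "canned": (0.350, 0.541, 0.109),
    "micro_plastic": (0.230, 0.561, 0.209),
    "plastic_bottle": (0.134, 0.420, 0.445),
    "hot_cup": (0.292, 0.537, 0.171),
    "stretch_wrap": (0.577, 0.380, 0.043),
    "micro_meals": (0.142, 0.170, 0.688),
    "packaged": (0.559, 0.374, 0.067),
}

#: Published per-question blank rates (two questions stand out at 26.2%
#: and 19.8%; the microwave-in-plastic question at 6.4%; the rest <1%).
DEFAULT_MISSING_RATES = (0.0025, 0.064, 0.005, 0.262, 0.198, 0.0074, 0.0074)

#: Extra "I don't know" rate per question (a modeling choice, not a
#: published figure): small, on the four questions whose wording offers a
#: don't-know option.
DEFAULT_DONT_KNOW_RATES = (0.0, 0.0, 0.02, 0.02, 0.02, 0.02, 0.0)


def _normalized(p: tuple[float, ...]) -> tuple[float, ...]:
    a = np.asarray(p, dtype=float)
    return tuple(a / a.sum())


def default_marginals() -> dict[str, tuple[float, ...]]:
    return {k: _normalized(v) for k, v in _RAW_MARGINALS.items()}


@dataclass
class CohortSpec:
    """Design constants for one synthetic cohort.

    Defaults reproduce the study conditions: n = 404 participants, three
    recall days, the published marginal response distributions and
    missingness rates, and planted loadings/slopes strong enough that the
    composite-score validation properties hold at n = 404.
    """

    n_participants: int = 404
    n_recall_days: int = 3
    latent_mean: float = 0.0
    latent_sd: float = 1.0
    question_loadings: tuple[float, ...] = (0.8,) * 7
    category_marginals: dict[str, tuple[float, ...]] = field(
        default_factory=default_marginals
    )
    missing_rates: tuple[float, ...] = DEFAULT_MISSING_RATES
    dont_know_rates: tuple[float, ...] = DEFAULT_DONT_KNOW_RATES
    # Poisson log-link: per-day expected item count per packaging category
    # is exp(base + slope * z), z the standardized log-latent factor.
    item_rate_base: dict[str, float] = field(
        default_factory=lambda: {
            "canned": float(np.log(1.2)),
            "packaged": float(np.log(2.0)),
            "microwave": float(np.log(0.25)),
        }
    )
    item_rate_slope: dict[str, float] = field(
        default_factory=lambda: {"canned": 0.8, "packaged": 0.5, "microwave": 0.5}
    )
    distractor_rate: float = 6.0
    grams_per_serving_mean: float = 26.0
    grams_per_serving_sd: float = 0.6
    servings_log_sd: float = 0.5
    # Optional day-level overdispersion: log-normal multiplier on the day
    # rate with this log-scale sd (0 = plain Poisson days).
    day_dispersion_sd: float = 0.0
    effect_null: bool = False
    seed: int = 0

    def validate(self, schemas: tuple[QuestionSchema, ...] | None = None) -> None:
        """Raise ``ValueError`` naming the offending field if invalid."""
        schemas = default_schemas() if schemas is None else schemas
        if self.n_participants < 1:
            raise ValueError("n_participants: must be a positive integer")
        if self.n_recall_days < 1:
            raise ValueError("n_recall_days: must be >= 1")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd: must be positive")
        if len(self.question_loadings) != len(schemas):
            raise ValueError("question_loadings: need one loading per question")
        for lam in self.question_loadings:
            if not 0.0 <= lam <= 1.0:
                raise ValueError("question_loadings: loadings must lie in [0, 1]")
        for s in schemas:
            p = self.category_marginals.get(s.key)
            if p is None:
                raise ValueError(f"category_marginals: missing question {s.key!r}")
            if len(p) != s.n_levels:
                raise ValueError(
                    f"category_marginals: {s.key!r} needs {s.n_levels} probabilities"
                )
            if any(x < 0 for x in p):
                raise ValueError(f"category_marginals: {s.key!r} has negative mass")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(
                    f"category_marginals: {s.key!r} must sum to 1 within 1e-9"
                )
        for name, rates in (
            ("missing_rates", self.missing_rates),
            ("dont_know_rates", self.dont_know_rates),
        ):
            if len(rates) != len(schemas):
                raise ValueError(f"{name}: need one rate per question")
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError(f"{name}: rates must lie in [0, 1]")
        for m, d in zip(self.missing_rates, self.dont_know_rates):
            if m + d > 1.0:
                raise ValueError(
                    "missing_rates/dont_know_rates: per-question sum exceeds 1"
                )
        for cat in CATEGORY_KEYS:
            if cat not in self.item_rate_base:
                raise ValueError(f"item_rate_base: missing category {cat!r}")
            if cat not in self.item_rate_slope:
                raise ValueError(f"item_rate_slope: missing category {cat!r}")
            if self.item_rate_slope[cat] < 0:
                raise ValueError("item_rate_slope: slopes must be nonnegative")
        if self.distractor_rate < 0:
            raise ValueError("distractor_rate: must be nonnegative")
        if self.grams_per_serving_mean <= 0:
            raise ValueError("grams_per_serving_mean: must be positive")
        if self.grams_per_serving_sd <= 0:
            raise ValueError("grams_per_serving_sd: must be positive")
        if self.servings_log_sd < 0:
            raise ValueError("servings_log_sd: must be nonnegative")
        if self.day_dispersion_sd < 0:
            raise ValueError("day_dispersion_sd: must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        spec = cls(**d)
        # YAML round-trips tuples as lists; normalize container types.
        spec.question_loadings = tuple(spec.question_loadings)
        spec.missing_rates = tuple(spec.missing_rates)
        spec.dont_know_rates = tuple(spec.dont_know_rates)
        spec.category_marginals = {
            k: tuple(v) for k, v in spec.category_marginals.items()
        }
        return spec


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    latent_exposure: np.ndarray  # exp of the log-scale latent factor
    expected_category_counts: pd.DataFrame  # per-participant per-day E[count]
    planted_effect_sizes: dict[str, float]  # question key -> loading

    def to_dict(self) -> dict:
        return {
            "latent_exposure": self.latent_exposure.tolist(),
            "expected_category_counts": self.expected_category_counts.to_dict(
                orient="list"
            ),
            "planted_effect_sizes": self.planted_effect_sizes,
        }


# ---------------------------------------------------------------------------
# Synthetic food-description dictionary
# ---------------------------------------------------------------------------

_CANNED_BASES = [
    "Tomatoes", "Corn", "Green beans", "Peaches", "Pears", "Pineapple",
    "Chickpeas", "Black beans", "Kidney beans", "Tuna", "Salmon", "Chicken",
    "Soup, chicken noodle", "Soup, tomato", "Soup, minestrone", "Chili con carne",
    "Beets", "Carrots", "Mushrooms", "Olives", "Pumpkin", "Sardines",
    "Fruit cocktail", "Mandarin oranges", "Refried beans", "Sweet potatoes",
    "Spinach", "Peas", "Clams", "Crab meat",
]
_CANNED_STYLES = ["diced", "whole", "in juice", "in syrup", "low sodium", "in water"]

_PACKAGED_BASES = [
    "Snack cake", "Ice cream bar", "Frozen treat", "Cupcake", "Brownie",
    "Cookie", "Donut", "Toaster pastry", "Pudding cup", "Fruit snack",
    "Candy bar", "Ice cream sandwich", "Sweet roll", "Pie, apple",
    "Pie, cherry", "Gelatin dessert", "Frozen yogurt bar", "Sherbet cup",
    "Cream-filled cake", "Caramel popcorn",
]
_PACKAGED_STYLES = ["chocolate", "vanilla", "strawberry", "single serving"]

_MICROWAVE_ITEMS = [
    "Popcorn, microwave, butter",
    "Popcorn, microwave, light",
    "Popcorn, microwave, kettle corn",
    "Meal, microwave, macaroni and cheese",
    "Meal, microwave, rice and beans",
    "Meal, microwave, pasta with meat sauce",
    "Soup in a cup, microwave, noodle",
    "Soup in a cup, microwave, vegetable",
    "Meal, microwave, burrito bowl",
    "Oatmeal cup, microwave, maple",
    "Meal, microwave, teriyaki chicken",
    "Meal, microwave, lasagna",
]

_DISTRACTOR_ITEMS = [
    "Apple, raw", "Banana, raw", "Orange, raw", "Broccoli, raw",
    "Carrot, raw", "Spinach, fresh", "Chicken breast, grilled",
    "Beef, ground, cooked", "Salmon, baked", "Egg, scrambled",
    "Rice, white, cooked", "Rice, brown, cooked", "Pasta, plain, cooked",
    "Bread, whole wheat", "Bread, white", "Tortilla, flour",
    "Milk, 2% fat", "Yogurt, plain", "Cheese, cheddar", "Butter",
    "Olive oil", "Potato, baked", "Sweet potato, baked", "Lettuce, romaine",
    "Tomato, fresh", "Cucumber, raw", "Avocado, raw", "Almonds, dry roasted",
    "Peanut butter", "Oatmeal, cooked", "Granola bar, oats and honey",
    "Crackers, wheat", "Cereal, corn flakes", "Orange juice, fresh",
    "Coffee, brewed", "Tea, brewed", "Salad, mixed greens",
    "Turkey, roasted", "Pork chop, grilled", "Shrimp, steamed",
    "Quinoa, cooked", "Lentils, boiled", "Hummus", "Strawberries, raw",
    "Blueberries, raw", "Grapes, raw", "Watermelon, raw", "Pear, raw",
    "Zucchini, grilled", "Cauliflower, steamed",
]


def default_food_dictionary() -> pd.DataFrame:
    """A synthetic food-description dictionary (food_id, food_description).

    A stand-in for a proprietary food-coding database: descriptions for
    canned, packaged, and microwave items each contain the corresponding
    keyword; distractor descriptions contain none.  Generated in code, so
    the artifact ships no data files.
    """
    rows: list[tuple[int, str]] = []
    fid = 1000
    for base in _CANNED_BASES:
        for style in _CANNED_STYLES[: 2 if "," in base else 3]:
            rows.append((fid, f"{base}, canned, {style}"))
            fid += 1
    for base in _PACKAGED_BASES:
        for style in _PACKAGED_STYLES[:2]:
            rows.append((fid, f"{base}, packaged, {style}"))
            fid += 1
    for desc in _MICROWAVE_ITEMS:
        rows.append((fid, desc))
        fid += 1
    for desc in _DISTRACTOR_ITEMS:
        rows.append((fid, desc))
        fid += 1
    return pd.DataFrame(rows, columns=["food_id", "food_description"])


def _dictionary_pools(dictionary: pd.DataFrame) -> dict[str, np.ndarray]:
    """Partition dictionary ids by the packaging keyword in the description."""
    from .recall import classify_item  # local import to avoid a cycle at import time

    labels = dictionary["food_description"].map(classify_item)
    pools = {}
    for cat in (*CATEGORY_KEYS, "none"):
        pools[cat] = dictionary.loc[labels == cat, "food_id"].to_numpy()
    return pools


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_responses(
    spec: CohortSpec,
    z: np.ndarray,
    rng: np.random.Generator,
    schemas: tuple[QuestionSchema, ...],
) -> pd.DataFrame:
    """Threshold latent + Gaussian noise onto each question's marginals."""
    n = spec.n_participants
    loadings = np.zeros(len(schemas)) if spec.effect_null else np.asarray(
        spec.question_loadings, dtype=float
    )
    data: dict[str, np.ndarray] = {"participant_id": np.arange(1, n + 1)}
    for s, lam in zip(schemas, loadings):
        noise = rng.standard_normal(n)
        u = lam * z + np.sqrt(1.0 - lam**2) * noise
        p = np.asarray(spec.category_marginals[s.key], dtype=float)
        # interior thresholds on the standard normal scale
        cuts = stats.norm.ppf(np.cumsum(p)[:-1])
        idx = np.searchsorted(cuts, u, side="left")
        data[s.key] = np.asarray(s.categories, dtype=object)[idx]
    return pd.DataFrame(data)


def _draw_recall_items(
    spec: CohortSpec,
    z: np.ndarray,
    rng: np.random.Generator,
    dictionary: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the participant x day x item recall table.

    Returns the recall table and the per-participant expected per-day
    category counts (ground truth).
    """
    n, days = spec.n_participants, spec.n_recall_days
    pools = _dictionary_pools(dictionary)
    ids = np.arange(1, n + 1)
    pid_day = np.repeat(ids, days)
    day_idx = np.tile(np.arange(1, days + 1), n)

    slopes = {
        c: (0.0 if spec.effect_null else spec.item_rate_slope[c])
        for c in CATEGORY_KEYS
    }
    expected = pd.DataFrame(
        {
            "participant_id": ids,
            **{
                c: np.exp(spec.item_rate_base[c] + slopes[c] * z)
                for c in CATEGORY_KEYS
            },
        }
    )

    frames = []
    for cat in (*CATEGORY_KEYS, "none"):
        if cat == "none":
            lam = np.full(n * days, spec.distractor_rate)
        else:
            lam = np.repeat(np.exp(spec.item_rate_base[cat] + slopes[cat] * z), days)
        if spec.day_dispersion_sd > 0:
            mult = np.exp(
                rng.normal(
                    -0.5 * spec.day_dispersion_sd**2,
                    spec.day_dispersion_sd,
                    n * days,
                )
            )
            lam = lam * mult
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        pool = pools[cat]
        if len(pool) == 0:
            raise ValueError(f"food dictionary has no items for category {cat!r}")
        servings = np.exp(rng.normal(0.0, spec.servings_log_sd, total))
        g_per_serving = np.exp(
            rng.normal(
                np.log(spec.grams_per_serving_mean)
                - 0.5 * spec.grams_per_serving_sd**2,
                spec.grams_per_serving_sd,
                total,
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pid_day, counts),
                    "day_index": np.repeat(day_idx, counts),
                    "food_id": rng.choice(pool, size=total),
                    "servings": np.round(servings, 3),
                    "grams": np.round(servings * g_per_serving, 1),
                }
            )
        )
    recall = pd.concat(frames, ignore_index=True)
    recall = recall.sort_values(
        ["participant_id", "day_index", "food_id"], kind="stable"
    ).reset_index(drop=True)
    desc = dictionary.set_index("food_id")["food_description"]
    recall.insert(3, "food_description", recall["food_id"].map(desc).to_numpy())
    return recall, expected


def inject_missingness(
    questionnaire: pd.DataFrame,
    missing_rates,
    dont_know_rates,
    seed: int,
    schemas: tuple[QuestionSchema, ...] | None = None,
) -> pd.DataFrame:
    """Blank out answers and insert "I don't know" codes, per question.

    Each cell of question *i* independently becomes :data:`MISSING` with
    probability ``missing_rates[i]`` and :data:`DONT_KNOW` with probability
    ``dont_know_rates[i]`` (missing-completely-at-random); all other cells
    are left untouched.
    """
    schemas = default_schemas() if schemas is None else schemas
    missing_rates = tuple(missing_rates)
    dont_know_rates = tuple(dont_know_rates)
    for name, rates in (
        ("missing_rates", missing_rates),
        ("dont_know_rates", dont_know_rates),
    ):
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError(f"{name}: rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = questionnaire.copy()
    for s, mr, dk in zip(schemas, missing_rates, dont_know_rates):
        u = rng.random(len(out))
        col = out[s.key].to_numpy(dtype=object, copy=True)
        col[u < mr] = MISSING
        col[(u >= mr) & (u < mr + dk)] = DONT_KNOW
        out[s.key] = col
    return out


def generate_cohort(
    spec: CohortSpec,
    dictionary: pd.DataFrame | None = None,
    schemas: tuple[QuestionSchema, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (questionnaire, recall item table, ground truth).

    The questionnaire table has one row per participant with the seven
    answer columns holding category labels (missingness already injected
    per ``spec``).  The recall table has one row per participant-day-item.
    """
    schemas = default_schemas() if schemas is None else schemas
    spec.validate(schemas)
    dictionary = default_food_dictionary() if dictionary is None else dictionary

    rng = np.random.default_rng(spec.seed)
    ell = rng.normal(spec.latent_mean, spec.latent_sd, spec.n_participants)
    z = (ell - spec.latent_mean) / spec.latent_sd

    questionnaire = _draw_responses(spec, z, rng, schemas)
    recall, expected = _draw_recall_items(spec, z, rng, dictionary)
    miss_seed = int(rng.integers(0, 2**31 - 1))
    questionnaire = inject_missingness(
        questionnaire, spec.missing_rates, spec.dont_know_rates, miss_seed, schemas
    )

    loadings = (0.0,) * len(schemas) if spec.effect_null else spec.question_loadings
    truth = GroundTruth(
        latent_exposure=np.exp(ell),
        expected_category_counts=expected,
        planted_effect_sizes={s.key: float(l) for s, l in zip(schemas, loadings)},
    )
    logger.info(
        "generated cohort: n=%d, %d recall rows", spec.n_participants, len(recall)
    )
    return questionnaire, recall, truth
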