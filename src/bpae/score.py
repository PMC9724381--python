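"""The composite BPA exposure (BPAe) score.

Construction: (i) recode each question's answer so larger integers mean
more frequent exposure behavior; (ii) run PCA on the standardized recoded
responses (correlation matrix) and keep the minimum number of components
whose cumulative explained variance reaches 90%; (iii) form each
participant's sum of retained component scores weighted by the components'
proportions of total variance (not renormalized over the retained set);
(iv) assign the quintile of that weighted sum, 1 = lowest exposure fifth,
5 = highest.

Component signs are ambiguous in any PCA; each loading vector is flipped
so that its coefficient sum is positive (first nonzero coefficient positive
on a tie), which fixes the weighted sum and therefore the quintiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .questions import DONT_KNOW, MISSING, QuestionSchema, default_schemas

logger = logging.getLogger(__name__)


def recode_responses(
    questionnaire: pd.DataFrame,
    schemas: tuple[QuestionSchema, ...] | None = None,
) -> pd.DataFrame:
    """Map category labels to integer codes (1 = lowest frequency).

    Missing cells propagate as NaN.  "I don't know" must have been
    converted to missing upstream; encountering it (or any label outside
    the schema) raises an error naming the row and question.
    """
    schemas = default_schemas() if schemas is None else schemas
    out = pd.DataFrame(index=questionnaire.index)
    if "participant_id" in questionnaire.columns:
        out["participant_id"] = questionnaire["participant_id"]
    for s in schemas:
        rmap = s.recode_map
        codes = np.full(len(questionnaire), np.nan)
        for i, (idx, label) in enumerate(questionnaire[s.key].items()):
            if label is None or (isinstance(label, float) and np.isnan(label)):
                continue
            if label == MISSING:
                continue
            if label == DONT_KNOW:
                raise ValueError(
                    f"row {idx}, question {s.key!r}: {DONT_KNOW!r} found; "
                    "convert don't-know answers to missing first "
                    "(bpae.impute.code_dont_know_missing)"
                )
            try:
                codes[i] = rmap[label]
            except KeyError:
                raise ValueError(
                    f"row {idx}, question {s.key!r}: unknown category {label!r}"
                ) from None
        out[s.key] = codes
    return out


def fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each loading vector (row) so its sum is positive.

    Tie rule: if a row sums to exactly zero, make its first nonzero
    coefficient positive.
    """
    comp = components.copy()
    for j in range(comp.shape[0]):
        s = comp[j].sum()
        if s < 0:
            comp[j] = -comp[j]
        elif s == 0:
            nz = np.nonzero(comp[j])[0]
            if len(nz) and comp[j, nz[0]] < 0:
                comp[j] = -comp[j]
    return comp


@dataclass
class PCAResult:
    """Retained principal components of the standardized responses."""

    k: int
    pc_weights: np.ndarray  # retained components' proportions of total variance
    scores: np.ndarray  # n x k participant scores
    all_weights: np.ndarray  # all components' variance proportions
    loadings: np.ndarray  # k x p sign-fixed loading vectors
    columns: list[str]  # columns that entered the PCA


def select_components(
    matrix: pd.DataFrame | np.ndarray, threshold: float = 0.90
) -> PCAResult:
    """Keep the minimum number of PCs explaining >= ``threshold`` variance.

    PCA runs on the correlation matrix: each column is centered and scaled
    to unit variance, so every question contributes equally regardless of
    its category count.  Variance proportions use all components'
    eigenvalues as the denominator.  Constant columns carry no correlation
    information; they are dropped with a warning.
    """
    if isinstance(matrix, pd.DataFrame):
        cols = [c for c in matrix.columns if c != "participant_id"]
        X = matrix[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        cols = [f"q{j + 1}" for j in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError(
            "matrix has missing cells; restrict to complete cases or impute first"
        )
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError(f"need more than {X.shape[1]} rows for a {X.shape[1]}-column PCA")

    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        dropped = [c for c, f in zip(cols, const) if f]
        warnings.warn(
            f"constant column(s) dropped from PCA: {dropped}", stacklevel=2
        )
        X = X[:, ~const]
        cols = [c for c, f in zip(cols, const) if not f]
        sd = sd[~const]
    if X.shape[1] == 0:
        raise ValueError("all columns constant; PCA undefined")

    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=Z.shape[1], svd_solver="full")
    scores_all = pca.fit_transform(Z)
    weights = pca.explained_variance_ratio_

    signs = np.sign(pca.components_.sum(axis=1))
    for j in np.nonzero(signs == 0)[0]:
        nz = np.nonzero(pca.components_[j])[0]
        signs[j] = np.sign(pca.components_[j, nz[0]]) if len(nz) else 1.0
    components = pca.components_ * signs[:, None]
    scores_all = scores_all * signs[None, :]

    k = int(np.searchsorted(np.cumsum(weights), threshold - 1e-12) + 1)
    k = min(k, len(weights))
    return PCAResult(
        k=k,
        pc_weights=weights[:k].copy(),
        scores=scores_all[:, :k].copy(),
        all_weights=weights.copy(),
        loadings=components[:k].copy(),
        columns=cols,
    )


def composite_sum(pc_scores, pc_weights) -> float | np.ndarray:
    """Variance-weighted sum of component scores.

    For a single participant (1-D scores) returns a float; for an n x k
    score matrix returns the n-vector of weighted sums.  Weights are used
    as given — proportions of *total* variance, not renormalized over the
    retained components.
    """
    s = np.asarray(pc_scores, dtype=float)
    w = np.asarray(pc_weights, dtype=float)
    if w.ndim != 1:
        raise ValueError("pc_weights must be one-dimensional")
    if s.shape[-1] != w.shape[0]:
        raise ValueError(
            f"length mismatch: {s.shape[-1]} scores vs {w.shape[0]} weights"
        )
    out = s @ w
    return float(out) if out.ndim == 0 else out


def assign_quintiles(values) -> np.ndarray:
    """Quintile labels 1-5 from empirical 0.2/0.4/0.6/0.8 quantile breaks.

    Right-closed intervals: a value equal to a break goes to the lower
    quintile.  Degenerate all-identical input gets label 1 everywhere with
    a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty one-dimensional array")
    if np.isnan(v).any():
        raise ValueError("values contain NaN")
    if np.all(v == v[0]):
        warnings.warn(
            "all weighted sums identical; assigning quintile 1 to every row",
            stacklevel=2,
        )
        return np.ones(len(v), dtype=int)
    breaks = np.quantile(v, [0.2, 0.4, 0.6, 0.8])
    return (1 + (v[:, None] > breaks[None, :]).sum(axis=1)).astype(int)


def score_questionnaire(
    questionnaire: pd.DataFrame,
    schemas: tuple[QuestionSchema, ...] | None = None,
    threshold: float = 0.90,
) -> tuple[pd.DataFrame, PCAResult]:
    """Complete-case BPAe scores for a label questionnaire table.

    Returns (scores table, PCA detail).  The table has one row per
    complete-case participant with columns ``participant_id``,
    ``weighted_sum``, ``bpae``.
    """
    schemas = default_schemas() if schemas is None else schemas
    codes = recode_responses(questionnaire, schemas)
    return score_codes(codes, schemas, threshold)


def score_codes(
    codes: pd.DataFrame,
    schemas: tuple[QuestionSchema, ...] | None = None,
    threshold: float = 0.90,
) -> tuple[pd.DataFrame, PCAResult]:
    """BPAe scores from an already-recoded (numeric) response table."""
    schemas = default_schemas() if schemas is None else schemas
    keys = [s.key for s in schemas]
    complete = codes.dropna(subset=keys)
    n_dropped = len(codes) - len(complete)
    if n_dropped:
        logger.info("BPAe: %d incomplete case(s) excluded from PCA", n_dropped)
    if (complete[keys].nunique() <= 1).all():
        # every question constant: no variance to decompose
        warnings.warn(
            "all responses identical; BPAe degenerate (all participants in "
            "quintile 1)",
            stacklevel=2,
        )
        pca = PCAResult(
            k=0,
            pc_weights=np.empty(0),
            scores=np.zeros((len(complete), 0)),
            all_weights=np.empty(0),
            loadings=np.empty((0, len(keys))),
            columns=keys,
        )
        table = pd.DataFrame(
            {
                "participant_id": complete["participant_id"].to_numpy()
                if "participant_id" in complete.columns
                else complete.index.to_numpy(),
                "weighted_sum": 0.0,
                "bpae": 1,
            }
        )
        return table, pca
    pca = select_components(complete[keys], threshold=threshold)
    sums = composite_sum(pca.scores, pca.pc_weights)
    table = pd.DataFrame(
        {
            "participant_id": complete["participant_id"].to_numpy()
            if "participant_id" in complete.columns
            else complete.index.to_numpy(),
            "weighted_sum": sums,
            "bpae": assign_quintiles(sums),
        }
    )
    return table, pca


def validate_monotonicity(
    bpae: pd.Series | np.ndarray,
    recoded: pd.DataFrame,
    schemas: tuple[QuestionSchema, ...] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean recoded response per question by BPAe level, plus monotone flags.

    Returns a (questions x 5) table of means over non-missing responses and
    a per-question boolean flag that is true when the means are
    non-decreasing across levels 1 -> 5 (NaN cells for empty levels are
    skipped in the comparison).
    """
    schemas = default_schemas() if schemas is None else schemas
    keys = [s.key for s in schemas]
    bpae = np.asarray(bpae, dtype=int)
    if len(bpae) != len(recoded):
        raise ValueError("bpae labels and responses must align by participant")
    levels = [1, 2, 3, 4, 5]
    table = pd.DataFrame(index=keys, columns=levels, dtype=float)
    for lev in levels:
        sub = recoded.loc[bpae == lev, keys]
        table[lev] = sub.mean(axis=0, skipna=True) if len(sub) else np.nan
    flags = {}
    for key in keys:
        means = table.loc[key].dropna().to_numpy()
        flags[key] = bool(np.all(np.diff(means) >= 0)) if len(means) > 1 else True
    table.index.name = "question"
    table.columns.name = "bpae_level"
    return table, pd.Series(flags, name="monotone")
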