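"""Multiple imputation of the questionnaire by chained equations.

"I don't know" answers are first converted to missing.  The recoded
(integer) response matrix is then completed m times by chained-equation
predictive mean matching (PMM): in a fixed left-to-right sweep over the
questions, each question's missing entries are imputed by (1) a Bayesian
linear-regression parameter draw on the observed rows given the other six
questions, (2) matching each missing row's predicted value to the k = 5
nearest observed predictions, and (3) copying the observed value of one
randomly chosen donor.  Donor copying guarantees every imputed value is a
legal category code for its question.

All randomness flows from the config seed: one master generator spawns a
seed per imputed dataset, so (input, config) fully determines all m
outputs, and observed cells are never touched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .questions import DONT_KNOW, MISSING

logger = logging.getLogger(__name__)


def code_dont_know_missing(questionnaire: pd.DataFrame) -> pd.DataFrame:
    """Replace every "I don't know" answer with the missing code.

    Operates on a label table.  The number of conversions is logged; a
    column left entirely missing triggers a warning.
    """
    out = questionnaire.copy()
    n_converted = 0
    for col in out.columns:
        if col == "participant_id":
            continue
        mask = out[col] == DONT_KNOW
        n = int(mask.sum())
        if n:
            vals = out[col].to_numpy(dtype=object, copy=True)
            vals[mask.to_numpy()] = MISSING
            out[col] = vals
            n_converted += n
        blank = (out[col] == MISSING) | out[col].isna()
        if blank.all():
            warnings.warn(
                f"question {col!r} is entirely missing after don't-know "
                "conversion",
                stacklevel=2,
            )
    logger.info("converted %d \"I don't know\" answer(s) to missing", n_converted)
    return out


@dataclass
class ImputationConfig:
    m: int = 5
    n_iterations: int = 10
    k_donors: int = 5
    method: str = "pmm"
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("m: need at least 2 imputed datasets")
        if self.n_iterations < 1:
            raise ValueError("n_iterations: must be >= 1")
        if self.k_donors < 1:
            raise ValueError("k_donors: must be >= 1")
        if self.method != "pmm":
            raise ValueError(f"method: unknown imputation method {self.method!r}")


@dataclass
class ImputedSet:
    """m completed response tables plus seed lineage and diagnostics."""

    datasets: list[pd.DataFrame]
    config: ImputationConfig
    seeds: list[int]
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def m(self) -> int:
        return len(self.datasets)


def _pmm_draw(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
    k_donors: int,
) -> np.ndarray:
    """One PMM step: Bayesian beta draw, nearest-prediction donor matching."""
    n_obs, p = X_obs.shape
    XtX = X_obs.T @ X_obs
    XtX_inv = np.linalg.pinv(XtX, hermitian=True)
    beta_hat = XtX_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    nu = max(n_obs - p, 1)
    ss = float(resid @ resid)
    sigma2_star = ss / rng.chisquare(nu) if ss > 0 else 0.0
    # draw beta* ~ N(beta_hat, sigma2* (X'X)^-1) via eigen square root
    # (pinv keeps this well-defined under collinearity mid-chain)
    evals, evecs = np.linalg.eigh(XtX_inv)
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    beta_star = beta_hat + np.sqrt(sigma2_star) * (L @ rng.standard_normal(p))
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_star
    k = min(k_donors, n_obs)
    out = np.empty(len(X_mis))
    for i, yh in enumerate(yhat_mis):
        d = np.abs(yhat_obs - yh)
        donors = np.argpartition(d, k - 1)[:k]
        out[i] = y_obs[donors[rng.integers(k)]]
    return out


def mice_impute(
    codes: pd.DataFrame,
    cfg: ImputationConfig | None = None,
    auxiliaries: pd.DataFrame | None = None,
) -> ImputedSet:
    """Chained-equation multiple imputation of a recoded response table.

    ``codes`` holds one numeric column per question (NaN = missing) and
    optionally a ``participant_id`` column, which is carried through
    untouched.  Returns m completed copies.  A question with no observed
    value at all cannot be modeled and raises an error.

    ``auxiliaries`` optionally adds fully observed numeric columns (row
    aligned with ``codes``) to every conditional model without being
    imputed themselves.  Including the analysis outcome here keeps the
    imputation model congenial with the analysis model — omitting it
    attenuates regression coefficients on imputed predictors.  Off by
    default.
    """
    cfg = ImputationConfig() if cfg is None else cfg
    cfg.validate()
    qcols = [c for c in codes.columns if c != "participant_id"]
    X_full = codes[qcols].to_numpy(dtype=float)
    if auxiliaries is not None:
        aux = auxiliaries.drop(columns="participant_id", errors="ignore")
        if len(aux) != len(codes):
            raise ValueError("auxiliaries: row count differs from codes")
        A = aux.to_numpy(dtype=float)
        if np.isnan(A).any():
            raise ValueError("auxiliaries: must be fully observed")
    else:
        A = np.empty((len(codes), 0))
    mask = np.isnan(X_full)
    for j, col in enumerate(qcols):
        if mask[:, j].all():
            raise ValueError(
                f"question {col!r} is 100% missing; cannot fit its conditional model"
            )

    master = np.random.default_rng(cfg.seed)
    seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=cfg.m)]

    if not mask.any():
        logger.info("no missing cells; returning %d identical copies", cfg.m)
        return ImputedSet(
            datasets=[codes.copy() for _ in range(cfg.m)], config=cfg, seeds=seeds
        )

    n = len(codes)
    ones = np.ones((n, 1))
    missing_cols = [j for j in range(len(qcols)) if mask[:, j].any()]
    datasets: list[pd.DataFrame] = []
    diag_rows: list[tuple] = []
    for d_idx, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        X = X_full.copy()
        # initial fill: random draws from each column's observed values
        for j in missing_cols:
            obs_vals = X_full[~mask[:, j], j]
            X[mask[:, j], j] = rng.choice(obs_vals, size=int(mask[:, j].sum()))
        for sweep in range(cfg.n_iterations):
            for j in missing_cols:  # fixed left-to-right visit order
                others = [c for c in range(len(qcols)) if c != j]
                design = np.hstack([ones, X[:, others], A])
                obs = ~mask[:, j]
                X[mask[:, j], j] = _pmm_draw(
                    X_full[obs, j],
                    design[obs],
                    design[mask[:, j]],
                    rng,
                    cfg.k_donors,
                )
                diag_rows.append(
                    (d_idx, sweep, qcols[j], float(X[mask[:, j], j].mean()))
                )
        completed = codes.copy()
        completed[qcols] = X
        datasets.append(completed)

    diagnostics = pd.DataFrame(
        diag_rows, columns=["dataset", "sweep", "question", "mean_imputed_code"]
    )
    return ImputedSet(datasets=datasets, config=cfg, seeds=seeds, diagnostics=diagnostics)
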