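"""Statistical validation of the questionnaire against recall exposure.

Two routes, mirroring the analysis design:

* Composite route — tie-corrected Kruskal-Wallis rank-sum tests of the
  exposure metrics across the five BPAe groups (the metrics are heavily
  right-skewed, so rank tests rather than ANOVA), with Dunn's tie-corrected
  pairwise z tests and a Bonferroni adjustment over a declared comparison
  family as follow-up.

* Regression route — for each exposure outcome, ordinary least squares on
  the seven questions binned to three levels (low = reference, medium,
  high), fit within each of the m imputed datasets and pooled by Rubin's
  rules with Barnard-Rubin small-sample degrees of freedom.  The pooled
  adjusted R-squared uses a Fisher-z transform of the square root of each
  fit's adjusted R-squared (simple mean available as an option), and the
  overall F statistic is combined across imputations with the D2
  (chi-squared-based) procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .questions import QuestionSchema, default_schemas

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

@dataclass
class KWResult:
    h: float
    df: int
    p: float
    group_sizes: dict

    def __post_init__(self) -> None:
        assert self.h >= 0 and 0 <= self.p <= 1


@dataclass
class DunnResult:
    pair: tuple
    z: float
    p_raw: float
    p_adjusted: float
    adjusted_alpha: float
    family_size: int


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        v = values[groups == g]
        if len(v) == 0:
            warnings.warn(f"empty group {g!r} dropped", stacklevel=3)
            continue
        out[g] = v
    return out


def kruskal_wallis(values, groups) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with a chi-squared reference."""
    by_group = _split_groups(values, groups)
    if len(by_group) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 non-empty groups")
    arrays = list(by_group.values())
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        # scipy raises on all-identical data; H is 0 by definition
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return KWResult(
        h=float(h),
        df=len(by_group) - 1,
        p=float(p),
        group_sizes={g: len(v) for g, v in by_group.items()},
    )


def dunn_pairwise(
    values, groups, family: list[tuple] | None = None, alpha: float = 0.05
) -> list[DunnResult]:
    """Dunn's rank-based pairwise z tests with Bonferroni adjustment.

    ``family`` declares the comparisons tested; the Bonferroni factor is
    the family size (default: all pairs of observed groups).
    """
    by_group = _split_groups(values, groups)
    if family is None:
        family = list(combinations(sorted(by_group), 2))
    for a, b in family:
        if a not in by_group or b not in by_group:
            raise ValueError(f"comparison ({a!r}, {b!r}) references an absent group")
    fam_size = len(family)

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = pd.Series(groups).isin(list(by_group)).to_numpy()
    v, g = values[keep], groups[keep]
    N = len(v)
    ranks = stats.rankdata(v)
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    mean_ranks = {grp: ranks[g == grp].mean() for grp in by_group}
    sizes = {grp: int((g == grp).sum()) for grp in by_group}

    results = []
    for a, b in family:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        results.append(
            DunnResult(
                pair=(a, b),
                z=float(z),
                p_raw=float(p_raw),
                p_adjusted=float(min(1.0, p_raw * fam_size)),
                adjusted_alpha=alpha / fam_size,
                family_size=fam_size,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Binned regression on imputed data
# ---------------------------------------------------------------------------

def bin_responses(
    codes: pd.DataFrame, schemas: tuple[QuestionSchema, ...] | None = None
) -> pd.DataFrame:
    """Map integer response codes to each question's low/medium/high bin.

    Missing codes stay missing.  A code outside the schema raises.
    """
    schemas = default_schemas() if schemas is None else schemas
    out = pd.DataFrame(index=codes.index)
    if "participant_id" in codes.columns:
        out["participant_id"] = codes["participant_id"]
    for s in schemas:
        cmap = s.code_to_bin
        col = codes[s.key]
        bad = col.dropna()[~col.dropna().isin(cmap)]
        if len(bad):
            raise ValueError(
                f"question {s.key!r}: code(s) {sorted(set(bad))} have no bin"
            )
        out[s.key] = col.map(lambda c: cmap.get(int(c)) if pd.notna(c) else np.nan)
    return out


def build_design(
    bins: pd.DataFrame, schemas: tuple[QuestionSchema, ...] | None = None
) -> pd.DataFrame:
    """Reference-cell dummy design: intercept + per-question non-reference bins."""
    schemas = default_schemas() if schemas is None else schemas
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(bins))}
    for s in schemas:
        levels = [b for b in dict.fromkeys(s.bins) if b != s.reference_bin]
        for lev in levels:
            cols[f"{s.key}[{lev}]"] = (bins[s.key] == lev).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=bins.index)


@dataclass
class LinearFit:
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    adj_r2: float
    df_resid: float
    df_model: int
    nobs: int
    wald_chi2: float


def fit_linear(
    outcome,
    bins: pd.DataFrame,
    schemas: tuple[QuestionSchema, ...] | None = None,
) -> LinearFit:
    """OLS of one exposure outcome on the binned questions.

    Requires a full-rank design after dummy coding; rank deficiency raises
    an error naming the offending columns (typically an empty bin level).
    """
    schemas = default_schemas() if schemas is None else schemas
    y = np.asarray(outcome, dtype=float)
    X = build_design(bins, schemas)
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("outcome/design contain missing values; drop them first")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        empty = [c for c in X.columns if X[c].abs().sum() == 0]
        detail = f"empty dummy column(s): {empty}" if empty else "collinear columns"
        raise ValueError(f"design matrix rank {rank} < {X.shape[1]}; {detail}")
    res = sm.OLS(y, X).fit()
    k = X.shape[1] - 1
    # Wald chi-squared for all non-intercept terms (model-vs-null)
    wald_chi2 = float(res.fvalue) * k
    return LinearFit(
        params=res.params,
        bse=res.bse,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        adj_r2=float(res.rsquared_adj),
        df_resid=float(res.df_resid),
        df_model=k,
        nobs=int(res.nobs),
        wald_chi2=wald_chi2,
    )


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledModelFit:
    table: pd.DataFrame  # estimate, se, df, t, p, ci_low, ci_high per coef
    within: pd.Series  # W-bar per coefficient
    between: pd.Series  # B per coefficient
    m: int
    adj_r2: float
    f_stat: float
    f_df1: float
    f_df2: float
    f_p: float


def pool_rubin(fits: list[LinearFit], conf: float = 0.95) -> pd.DataFrame:
    """Rubin's rules for the coefficient table.

    Pooled estimate is the mean across imputations; total variance is
    T = W-bar + (1 + 1/m) B; degrees of freedom follow Barnard-Rubin.
    """
    m = len(fits)
    if m < 2:
        raise ValueError("need at least 2 fits to pool")
    index = fits[0].params.index
    for f in fits[1:]:
        if not f.params.index.equals(index):
            raise ValueError("fits have mismatched coefficient sets")
    est = np.vstack([f.params.to_numpy() for f in fits])
    var = np.vstack([f.bse.to_numpy() ** 2 for f in fits])
    qbar = est.mean(axis=0)
    wbar = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    t_var = wbar + (1.0 + 1.0 / m) * b
    se = np.sqrt(t_var)

    nu_com = fits[0].df_resid
    lam = np.where(t_var > 0, (1.0 + 1.0 / m) * b / t_var, 0.0)
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    with np.errstate(divide="ignore"):
        nu_old = np.where(lam > 0, (m - 1.0) / lam**2, np.inf)
    df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)

    tstat = np.divide(qbar, se, out=np.zeros_like(qbar), where=se > 0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    tcrit = stats.t.ppf(0.5 + conf / 2.0, df)
    table = pd.DataFrame(
        {
            "estimate": qbar,
            "se": se,
            "df": df,
            "t": tstat,
            "p": p,
            "ci_low": qbar - tcrit * se,
            "ci_high": qbar + tcrit * se,
        },
        index=index,
    )
    table.attrs["within"] = pd.Series(wbar, index=index)
    table.attrs["between"] = pd.Series(b, index=index)
    return table


def pool_r2(fits: list[LinearFit], method: str = "fisher_z") -> float:
    """Pool adjusted R-squared across imputations.

    Default: Fisher-z transform of the square root of each adjusted
    R-squared, averaged, back-transformed, squared.  Negative adjusted
    R-squared is truncated at 0 before the transform (flagged).
    ``method="mean"`` gives the simple mean for sensitivity checks.
    """
    r2s = np.array([f.adj_r2 for f in fits], dtype=float)
    if method == "mean":
        return float(r2s.mean())
    if method != "fisher_z":
        raise ValueError(f"unknown pooling method {method!r}")
    if (r2s < 0).any():
        warnings.warn(
            "negative adjusted R-squared truncated at 0 before Fisher-z pooling",
            stacklevel=2,
        )
    r2s = np.clip(r2s, 0.0, 1.0 - 1e-12)
    z = np.arctanh(np.sqrt(r2s))
    return float(np.tanh(z.mean()) ** 2)


def pooled_f(fits: list[LinearFit]) -> tuple[float, float, float, float]:
    """Combine the per-imputation model chi-squared statistics (D2).

    Given Wald chi-squared statistics d_1..d_m on k df, the D2 procedure
    forms F = (d-bar/k - (m+1)/(m-1) r) / (1 + r) with
    r = (1 + 1/m) var(sqrt(d)), referred to F(k, k^(-3/m) (m-1) (1+1/r)^2).
    Returns (F, df1, df2, p).
    """
    m = len(fits)
    if m < 2:
        raise ValueError("need at least 2 fits to pool an F statistic")
    k = fits[0].df_model
    if any(f.df_model != k for f in fits):
        raise ValueError("fits have mismatched model degrees of freedom")
    d = np.array([f.wald_chi2 for f in fits], dtype=float)
    r = (1.0 + 1.0 / m) * np.var(np.sqrt(d), ddof=1)
    dbar = d.mean()
    if r <= 0:
        f_val = dbar / k
        df2 = np.inf
        p = float(stats.chi2.sf(k * f_val, k))
    else:
        f_val = (dbar / k - (m + 1.0) / (m - 1.0) * r) / (1.0 + r)
        f_val = max(f_val, 0.0)
        df2 = k ** (-3.0 / m) * (m - 1.0) * (1.0 + 1.0 / r) ** 2
        p = float(stats.f.sf(f_val, k, df2))
    return float(f_val), float(k), float(df2), p


def pool_fits(
    fits: list[LinearFit], conf: float = 0.95, r2_method: str = "fisher_z"
) -> PooledModelFit:
    """Coefficient table, pooled adjusted R-squared, and D2 overall F."""
    table = pool_rubin(fits, conf=conf)
    f_val, df1, df2, f_p = pooled_f(fits)
    return PooledModelFit(
        table=table,
        within=table.attrs["within"],
        between=table.attrs["between"],
        m=len(fits),
        adj_r2=pool_r2(fits, method=r2_method),
        f_stat=f_val,
        f_df1=df1,
        f_df2=df2,
        f_p=f_p,
    )


def pooled_regression(
    imputed_codes: list[pd.DataFrame],
    outcome: pd.DataFrame,
    outcome_column: str,
    schemas: tuple[QuestionSchema, ...] | None = None,
    conf: float = 0.95,
    r2_method: str = "fisher_z",
) -> PooledModelFit:
    """Fit one outcome on the binned questions in each imputed dataset, pool.

    ``outcome`` is a per-participant table (``participant_id`` +
    ``outcome_column``).  Participants without an outcome value (e.g. no
    recall days) are excluded listwise — only questionnaire predictors were
    imputed.
    """
    schemas = default_schemas() if schemas is None else schemas
    fits = []
    for codes in imputed_codes:
        merged = codes.merge(
            outcome[["participant_id", outcome_column]],
            on="participant_id",
            how="inner",
        )
        merged = merged.dropna(subset=[outcome_column])
        bins = bin_responses(merged, schemas)
        fits.append(fit_linear(merged[outcome_column], bins, schemas))
    if len({f.nobs for f in fits}) > 1:
        raise ValueError("imputed datasets yield different analysis sample sizes")
    return pool_fits(fits, conf=conf, r2_method=r2_method)
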