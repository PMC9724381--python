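"""Rank tests, binned regression, and Rubin/D2 pooling against hand oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bpae import (
    LinearFit,
    bin_responses,
    dunn_pairwise,
    fit_linear,
    kruskal_wallis,
    pool_fits,
    pool_r2,
    pool_rubin,
    pooled_f,
)
from bpae.infer import build_design
from bpae.questions import default_schemas


def kw_h_oracle(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H computed from the rank definition."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(t**3 - t) / (n**3 - n)
    return h / correction


def make_fit(params, bse, df_resid=100.0, adj_r2=0.1, df_model=None, chi2=None):
    idx = [f"b{i}" for i in range(len(params))]
    params = pd.Series(np.asarray(params, dtype=float), index=idx)
    bse = pd.Series(np.asarray(bse, dtype=float), index=idx)
    k = len(params) if df_model is None else df_model
    return LinearFit(
        params=params,
        bse=bse,
        cov=pd.DataFrame(np.diag(bse**2), index=idx, columns=idx),
        adj_r2=adj_r2,
        df_resid=df_resid,
        df_model=k,
        nobs=int(df_resid + len(params)),
        wald_chi2=float(k if chi2 is None else chi2),
    )


class TestKruskalWallis:
    def test_identical_groups_zero(self):
        res = kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.h == 0.0 and res.p == 1.0

    def test_matches_rank_formula_oracle(self):
        a, b = np.array([1.0, 2, 3]), np.array([10.0, 11, 12])
        res = kruskal_wallis(np.concatenate([a, b]), ["a"] * 3 + ["b"] * 3)
        assert res.h == pytest.approx(kw_h_oracle([a, b]), abs=1e-12)
        assert res.df == 1

    def test_separated_groups_are_extreme_assignment(self):
        """Fully separated groups maximize H over all 20 rank assignments."""
        from itertools import combinations

        vals = np.array([1.0, 2, 3, 10, 11, 12])
        h_obs = kw_h_oracle([vals[:3], vals[3:]])
        hs = []
        for idx in combinations(range(6), 3):
            g1 = vals[list(idx)]
            g2 = vals[[i for i in range(6) if i not in idx]]
            hs.append(kw_h_oracle([g1, g2]))
        assert h_obs == pytest.approx(max(hs), abs=1e-12)
        # both extreme splits attain it: exact permutation p = 2/20
        assert sum(h >= h_obs - 1e-12 for h in hs) == 2

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        v = rng.exponential(1.0, 60)
        g = np.repeat(["a", "b", "c"], 20)
        h1 = kruskal_wallis(v, g).h
        h2 = kruskal_wallis(np.log(v + 1.0), g).h
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_tie_correction_applied(self):
        v = np.array([1.0, 1, 2, 2, 3, 3, 4, 4])
        g = ["a"] * 4 + ["b"] * 4
        res = kruskal_wallis(v, g)
        assert res.h == pytest.approx(kw_h_oracle([v[:4], v[4:]]), abs=1e-12)

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 non-empty groups"):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestDunn:
    def test_identical_groups(self):
        res = dunn_pairwise([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res[0].z == pytest.approx(0.0)
        assert res[0].p_adjusted == 1.0

    def test_bonferroni_threshold_for_two_comparisons(self):
        v = np.arange(9.0)
        g = np.repeat(["a", "b", "c"], 3)
        res = dunn_pairwise(v, g, family=[("a", "b"), ("a", "c")], alpha=0.05)
        assert all(r.adjusted_alpha == pytest.approx(0.025) for r in res)
        assert all(r.family_size == 2 for r in res)
        assert all(r.p_adjusted >= r.p_raw for r in res)

    def test_hand_computed_fixture(self):
        """Three untied groups of two: mean ranks 1.5/3.5/5.5, pooled rank
        variance N(N+1)/12 = 3.5."""
        v = [1.0, 2, 3, 4, 5, 6]
        g = ["a", "a", "b", "b", "c", "c"]
        res = dunn_pairwise(v, g)
        se = np.sqrt(3.5 * (0.5 + 0.5))
        expected = {("a", "b"): -2.0 / se, ("a", "c"): -4.0 / se, ("b", "c"): -2.0 / se}
        for r in res:
            assert r.z == pytest.approx(expected[r.pair], abs=1e-12)
            assert r.p_raw == pytest.approx(2 * stats.norm.sf(abs(r.z)), abs=1e-12)

    def test_absent_group_raises(self):
        with pytest.raises(ValueError, match="absent group"):
            dunn_pairwise([1, 2, 3, 4], ["a", "a", "b", "b"], family=[("a", "z")])


class TestBinResponses:
    def test_three_codes_map_to_bins(self, schemas):
        codes = pd.DataFrame(
            {"participant_id": [1, 2, 3], **{s.key: [1.0, 2.0, 3.0] for s in schemas}}
        )
        bins = bin_responses(codes, schemas)
        for s in schemas:
            assert bins[s.key].tolist() == ["low", "medium", "high"]

    def test_missing_stays_missing(self, schemas):
        codes = pd.DataFrame(
            {"participant_id": [1], **{s.key: [np.nan] for s in schemas}}
        )
        bins = bin_responses(codes, schemas)
        assert bins.drop(columns="participant_id").isna().all().all()

    def test_unmapped_code_raises(self, schemas):
        codes = pd.DataFrame(
            {"participant_id": [1], **{s.key: [1.0] for s in schemas}}
        )
        codes.loc[0, "canned"] = 9.0
        with pytest.raises(ValueError, match="canned"):
            bin_responses(codes, schemas)


def _bins_frame(schemas, n, rng):
    return pd.DataFrame(
        {s.key: rng.choice(["low", "medium", "high"], n) for s in schemas}
    )


class TestFitLinear:
    def test_exact_fit_recovers_indicator(self):
        schemas = default_schemas()[:1]
        bins = pd.DataFrame({"canned": ["low", "medium", "high"] * 4})
        y = (bins["canned"] == "medium").astype(float)
        fit = fit_linear(y, bins, schemas)
        assert fit.params["canned[medium]"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["canned[high]"] == pytest.approx(0.0, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_outcome_near_zero(self):
        schemas = default_schemas()
        rng = np.random.default_rng(10)
        bins = _bins_frame(schemas, 4000, rng)
        y = rng.standard_normal(4000)
        fit = fit_linear(y, bins, schemas)
        assert np.abs(fit.params.drop("Intercept")).max() < 0.2
        assert abs(fit.adj_r2) < 0.01

    def test_matches_normal_equations_oracle(self):
        schemas = default_schemas()[:2]
        rng = np.random.default_rng(11)
        bins = pd.DataFrame(
            {
                "canned": ["low", "medium", "high"] * 4,
                "micro_plastic": ["low"] * 4 + ["medium"] * 4 + ["high"] * 4,
            }
        )
        y = rng.standard_normal(12)
        fit = fit_linear(y, bins, schemas)
        # independent design construction and normal-equations solve
        X = np.column_stack(
            [
                np.ones(12),
                (bins["canned"] == "medium").to_numpy(float),
                (bins["canned"] == "high").to_numpy(float),
                (bins["micro_plastic"] == "medium").to_numpy(float),
                (bins["micro_plastic"] == "high").to_numpy(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        schemas = default_schemas()[:1]
        bins = pd.DataFrame({"canned": ["low", "medium"] * 6})  # no "high"
        y = np.arange(12.0)
        with pytest.raises(ValueError, match=r"canned\[high\]"):
            fit_linear(y, bins, schemas)

    def test_design_has_fifteen_columns(self, schemas):
        rng = np.random.default_rng(12)
        X = build_design(_bins_frame(schemas, 30, rng), schemas)
        assert X.shape[1] == 15  # intercept + 7 questions x 2 dummies


class TestRubinPooling:
    def test_identical_fits_degenerate(self):
        fits = [make_fit([1.0, 2.0], [0.5, 0.4]) for _ in range(5)]
        table = pool_rubin(fits)
        np.testing.assert_allclose(table["estimate"], [1.0, 2.0])
        np.testing.assert_allclose(table["se"], [0.5, 0.4])
        np.testing.assert_allclose(table.attrs["between"], 0.0)

    def test_hand_computed_m2_fixture(self):
        """Estimates 1 and 3 with unit within-variance: pooled estimate 2,
        T = 1 + 1.5 * 2 = 4, SE = 2."""
        fits = [make_fit([1.0], [1.0]), make_fit([3.0], [1.0])]
        table = pool_rubin(fits)
        assert table["estimate"].iloc[0] == pytest.approx(2.0)
        assert table["se"].iloc[0] == pytest.approx(2.0)
        assert table.attrs["within"].iloc[0] == pytest.approx(1.0)
        assert table.attrs["between"].iloc[0] == pytest.approx(2.0)

    def test_total_variance_at_least_within(self):
        rng = np.random.default_rng(13)
        fits = [
            make_fit(rng.standard_normal(3), rng.uniform(0.1, 1.0, 3))
            for _ in range(5)
        ]
        table = pool_rubin(fits)
        assert (table["se"] ** 2 >= table.attrs["within"] - 1e-12).all()
        assert (table["ci_low"] <= table["estimate"]).all()
        assert (table["estimate"] <= table["ci_high"]).all()

    def test_mismatched_fits_raise(self):
        a = make_fit([1.0], [1.0])
        b = make_fit([1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="mismatch"):
            pool_rubin([a, b])


class TestPoolR2:
    def test_constant(self):
        fits = [make_fit([1.0], [1.0], adj_r2=0.032) for _ in range(5)]
        assert pool_r2(fits) == pytest.approx(0.032, abs=1e-12)

    def test_zeros(self):
        fits = [make_fit([1.0], [1.0], adj_r2=0.0) for _ in range(2)]
        assert pool_r2(fits) == 0.0

    def test_fisher_z_hand_computation(self):
        fits = [
            make_fit([1.0], [1.0], adj_r2=0.1),
            make_fit([1.0], [1.0], adj_r2=0.3),
        ]
        z = np.mean([np.arctanh(np.sqrt(0.1)), np.arctanh(np.sqrt(0.3))])
        assert pool_r2(fits) == pytest.approx(float(np.tanh(z) ** 2), abs=1e-12)

    def test_negative_truncated_with_flag(self):
        fits = [
            make_fit([1.0], [1.0], adj_r2=-0.05),
            make_fit([1.0], [1.0], adj_r2=0.1),
        ]
        with pytest.warns(UserWarning, match="truncated"):
            out = pool_r2(fits)
        assert 0.0 <= out < 0.1


class TestPooledF:
    def test_degenerate_identical_chi2(self):
        k = 5
        fits = [make_fit([0.0] * k, [1.0] * k, chi2=float(k)) for _ in range(3)]
        f_val, df1, df2, p = pooled_f(fits)
        assert f_val == pytest.approx(1.0)
        assert df1 == k and np.isinf(df2)
        assert p == pytest.approx(stats.chi2.sf(k, k))

    def test_hand_applied_d2_formulas(self):
        k, chis = 5, [10.0, 14.0, 12.0]
        fits = [make_fit([0.0] * k, [1.0] * k, chi2=c) for c in chis]
        m = 3
        r = (1 + 1 / m) * np.var(np.sqrt(chis), ddof=1)
        expected_f = (np.mean(chis) / k - (m + 1) / (m - 1) * r) / (1 + r)
        expected_df2 = k ** (-3 / m) * (m - 1) * (1 + 1 / r) ** 2
        f_val, df1, df2, p = pooled_f(fits)
        assert f_val == pytest.approx(expected_f, abs=1e-12)
        assert df2 == pytest.approx(expected_df2, abs=1e-9)
        assert p == pytest.approx(stats.f.sf(expected_f, k, expected_df2), abs=1e-12)

    def test_single_fit_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            pooled_f([make_fit([0.0], [1.0])])


def test_pool_fits_bundles_everything():
    fits = [make_fit([1.0, 2.0], [0.5, 0.4], adj_r2=0.05, chi2=3.0) for _ in range(5)]
    pooled = pool_fits(fits)
    assert pooled.m == 5
    assert pooled.adj_r2 == pytest.approx(0.05, abs=1e-12)
    assert pooled.f_df1 == 2.0
    assert set(pooled.table.columns) >= {"estimate", "se", "p", "ci_low", "ci_high"}
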