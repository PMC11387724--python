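"""GLS partitions, VIF, PGLS with Pagel's lambda, BH-FDR, Mantel flag."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from plumagediv.phylo import PhyloCovariance, vcv_from_tree
from plumagediv.simulate import brownian_tips, simulate_tree
from plumagediv.stats import (
    PGLS,
    StatsError,
    aggregate_overlap,
    bh_adjust,
    fit_gls,
    fit_pgls,
    mantel_correlation,
    partition_pairs,
    vif,
)


def make_pair_df(rng, n=120, sympatric_frac=0.4):
    sym = rng.random(n) < sympatric_frac
    df = pd.DataFrame(
        {
            "phylo_dist": rng.uniform(1, 20, n),
            "ndvi_overlap": rng.uniform(0, 1, n),
            "sympatric": sym,
            "overlap_frac": np.where(sym, rng.uniform(0.05, 1, n), 0.0),
            "min_distance": np.where(sym, 0.0, rng.uniform(0.1, 50, n)),
        }
    )
    df["geo_predictor"] = df["sympatric"].astype(float)
    return df


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.33])[0] == pytest.approx(0.33)

    def test_matches_reference_implementation_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 40))
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_step_up_definition_oracle(self, rng):
        p = rng.uniform(0, 1, 15)
        m = p.size
        expected = np.empty(m)
        order = np.argsort(p)
        for rank_pos, idx in enumerate(order, start=1):
            candidates = [
                min(1.0, p[order[j]] * m / (j + 1)) for j in range(rank_pos - 1, m)
            ]
            expected[idx] = min(candidates)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, 25)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_fuzzed_bh_properties(self, p):
        q = bh_adjust(p)
        p = np.asarray(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.2])


class TestVIF:
    def test_orthogonal_predictors_give_one(self):
        n = 40
        df = pd.DataFrame(
            {
                "phylo_dist": np.tile([1.0, -1.0], n // 2),
                "geo_predictor": np.tile([1.0, 1.0, -1.0, -1.0], n // 4),
                "ndvi_overlap": np.tile([1.0, -1.0, -1.0, 1.0], n // 4),
            }
        )
        assert all(v == pytest.approx(1.0) for v in vif(df).values())

    def test_duplicated_predictor_is_infinite(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame(
            {"phylo_dist": x, "geo_predictor": 2 * x, "ndvi_overlap": rng.normal(size=50)}
        )
        out = vif(df)
        assert np.isinf(out["phylo_dist"]) and np.isinf(out["geo_predictor"])

    def test_matches_r_squared_oracle(self, rng):
        z = rng.normal(size=(60, 3))
        z[:, 1] += 0.8 * z[:, 0]
        df = pd.DataFrame(z, columns=["phylo_dist", "geo_predictor", "ndvi_overlap"])
        out = vif(df)
        for j, name in enumerate(df.columns):
            others = np.column_stack(
                [np.ones(60)] + [z[:, k] for k in range(3) if k != j]
            )
            beta, *_ = np.linalg.lstsq(others, z[:, j], rcond=None)
            resid = z[:, j] - others @ beta
            r2 = 1 - resid.var() / z[:, j].var()
            assert out[name] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestFitGLS:
    def test_exact_linear_recovery(self, rng):
        df = make_pair_df(rng, 80)
        x = df["phylo_dist"].to_numpy()
        df["jnd_crown"] = 2.0 * (x - x.mean()) / x.std(ddof=1)
        fit = fit_gls(df, "jnd_crown", geo_categorical=True)
        assert fit.loc["phylo_dist", "effect_size"] == pytest.approx(2.0, abs=1e-8)
        assert abs(fit.loc["ndvi_overlap", "effect_size"]) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        df = make_pair_df(rng, 90)
        df["jnd_crown"] = rng.normal(size=90)
        fit = fit_gls(df, "jnd_crown", geo_categorical=False, standardize="none")
        X = np.column_stack(
            [
                np.ones(90),
                df["phylo_dist"],
                df["geo_predictor"],
                df["ndvi_overlap"],
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ df["jnd_crown"].to_numpy())
        np.testing.assert_allclose(fit["effect_size"].to_numpy(), beta[1:], rtol=1e-9)

    def test_constant_predictor_dropped(self, rng):
        df = make_pair_df(rng, 60)
        df["ndvi_overlap"] = 0.5
        df["jnd_crown"] = rng.normal(size=60)
        fit = fit_gls(df, "jnd_crown", geo_categorical=True)
        assert "ndvi_overlap" not in fit.index

    def test_too_few_rows_rejected(self, rng):
        df = make_pair_df(rng, 8)
        df["jnd_crown"] = 1.0
        with pytest.raises(StatsError, match="rows"):
            fit_gls(df, "jnd_crown")


class TestPartition:
    def test_sizes_and_predictor_substitution(self, rng):
        df = make_pair_df(rng, 50, sympatric_frac=0.3)
        parts = partition_pairs(df)
        assert len(parts["all"]) == 50
        assert len(parts["sympatric"]) + len(parts["allopatric"]) == 50
        assert set(parts["all"]["geo_predictor"].unique()) <= {0.0, 1.0}
        assert (parts["sympatric"]["geo_predictor"] == parts["sympatric"]["overlap_frac"]).all()
        assert (parts["allopatric"]["geo_predictor"] == parts["allopatric"]["min_distance"]).all()
        assert (parts["sympatric"]["min_distance"] == 0).all()
        assert (parts["allopatric"]["overlap_frac"] == 0).all()

    def test_all_sympatric_leaves_empty_partition(self, rng):
        df = make_pair_df(rng, 20, sympatric_frac=1.1)
        parts = partition_pairs(df)
        assert parts["allopatric"].empty

    @pytest.mark.parametrize(
        "how, expected", [("mean", 0.45), ("max", 0.6), ("min", 0.3), ("species1", 0.3)]
    )
    def test_overlap_aggregation(self, how, expected):
        assert aggregate_overlap(0.3, 0.6, how) == pytest.approx(expected)


class TestPGLS:
    def test_lambda_zero_equals_ols_on_ultrametric_tree(self, rng):
        tree = simulate_tree(20, seed=3, depth=10.0)
        cov = vcv_from_tree(tree)
        y = rng.normal(size=20)
        x = rng.normal(size=20)
        res = fit_pgls(y, x, cov, lambda_mode="fixed", lam=0.0)
        X = np.column_stack([np.ones(20), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.slope == pytest.approx(beta[1], rel=1e-10)
        resid = y - X @ beta
        sigma2 = resid @ resid / 18
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.std_error == pytest.approx(se, rel=1e-10)

    def test_star_tree_fixed_lambda_equals_ols(self, rng):
        n = 12
        cov = PhyloCovariance([f"s{i}" for i in range(n)], 5.0 * np.eye(n))
        y, x = rng.normal(size=n), rng.normal(size=n)
        res = fit_pgls(y, x, cov, lambda_mode="fixed", lam=1.0)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.slope == pytest.approx(beta[1], rel=1e-10)

    def test_ml_lambda_matches_grid_scan_oracle(self, rng):
        tree = simulate_tree(30, seed=8, depth=10.0)
        cov = vcv_from_tree(tree)
        y = brownian_tips(tree, rate=1.0, rng=rng).to_numpy()
        y = 0.7 * y + 0.3 * rng.normal(size=30) * y.std()
        x = rng.normal(size=30)
        model = PGLS(lambda_mode="ml").fit(y, x, cov)
        from plumagediv.stats import _gls_solve

        X = np.column_stack([np.ones(30), x])
        grid = np.linspace(0, 1, 2001)
        lls = []
        for lam in grid:
            V = cov.C * lam
            np.fill_diagonal(V, np.diag(cov.C))
            lls.append(_gls_solve(y, X, V)[2])
        lam_grid = grid[int(np.argmax(lls))]
        assert model.lam_ == pytest.approx(lam_grid, abs=2e-3)
        assert model.loglik_ >= max(lls) - 1e-6

    def test_ml_likelihood_dominates_boundaries(self, rng):
        tree = simulate_tree(25, seed=4, depth=10.0)
        cov = vcv_from_tree(tree)
        y = rng.normal(size=25)
        x = rng.normal(size=25)
        ml = PGLS(lambda_mode="ml").fit(y, x, cov)
        for lam in (0.0, 1.0):
            fixed = PGLS(lambda_mode="fixed", lam=lam).fit(y, x, cov)
            assert ml.loglik_ >= fixed.loglik_ - 1e-8

    def test_small_sample_rejected(self, rng):
        cov = PhyloCovariance(["a", "b", "c"], np.eye(3))
        with pytest.raises(StatsError):
            fit_pgls(rng.normal(size=3), rng.normal(size=3), cov)

    def test_get_set_params(self):
        m = PGLS(lambda_mode="ml")
        assert m.get_params()["lambda_mode"] == "ml"
        m.set_params(lambda_mode="fixed", lam=0.5)
        assert m.lam == 0.5


class TestMantel:
    def test_identical_matrices_give_r_one(self, rng):
        n = 12
        d = np.abs(rng.normal(size=(n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        r, p = mantel_correlation(d, d, permutations=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_independent_matrices_usually_nonsignificant(self, rng):
        n = 15

        def rand_dist():
            d = np.abs(rng.normal(size=(n, n)))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            return d

        r, p = mantel_correlation(rand_dist(), rand_dist(), permutations=199, seed=2)
        assert abs(r) < 0.5
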