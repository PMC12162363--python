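import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from crabmap import drivers_regression as dr
from conftest import km_template


def make_table(n=400, seed=3, varying=False, noise=0.1):
    """Coarse-cell table with one predictor; β is constant or β(u) = u_x."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 1, size=(n, 2))
    v = rng.standard_normal(n)
    beta = xy[:, 0] if varying else 2.0
    y = 1.0 + beta * v + noise * rng.standard_normal(n)
    return pd.DataFrame({"SR": y, "x": xy[:, 0], "y": xy[:, 1], "v": v})


class TestAggregation:
    def test_uniform_grid_aggregates_to_constant(self):
        t = km_template(16, 16)
        table = dr.aggregate_blocks({"a": t.like(np.full((16, 16), 3.25))}, block=4)
        assert (table["a"] == 3.25).all()
        assert len(table) == 16

    def test_land_fraction_boundary_is_inclusive(self):
        t = km_template(4, 4)
        land = np.zeros((4, 4))
        land[:2, :] = 1  # exactly half of every 4x4 block
        table = dr.aggregate_blocks({"a": t.like(np.ones((4, 4)))}, block=4,
                                    land_mask=t.like(land))
        assert len(table) == 1  # retained at exactly 0.5

    def test_block_means_match_bruteforce(self):
        rng = np.random.default_rng(1)
        t = km_template(24, 24)
        vals = rng.random((24, 24))
        table = dr.aggregate_blocks({"a": t.like(vals)}, block=6)
        for _, row in table.iterrows():
            bi, bj = int(row["row"]), int(row["col"])
            block = vals[bi * 6:(bi + 1) * 6, bj * 6:(bj + 1) * 6]
            assert row["a"] == pytest.approx(block.mean(), abs=1e-12)

    def test_sub_threshold_cells_excluded(self):
        t = km_template(8, 8)
        land = np.zeros((8, 8))
        land[:, :1] = 1  # 25% land in the left block only
        with pytest.raises(ValueError):
            dr.aggregate_blocks({"a": t.like(np.ones((8, 8)))}, block=4,
                                land_mask=t.like(land))


class TestPearsonScreen:
    def test_duplicate_variable_eliminated(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(197)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(197)})
        screen = dr.pearson_matrix(table, ["a", "b", "c"])
        assert len({"a", "b"} & set(screen.retained)) == 1
        assert screen.correlation.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_normals_weakly_correlated(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.standard_normal((197, 4)), columns=list("abcd"))
        screen = dr.pearson_matrix(table, list("abcd"))
        off = screen.correlation.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.2
        assert screen.retained == list("abcd")

    def test_survivors_pass_bruteforce_gates(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((197, 5))
        X[:, 4] = 0.9 * X[:, 0] + 0.4 * X[:, 1]
        table = pd.DataFrame(X, columns=list("abcde"))
        screen = dr.pearson_matrix(table, list("abcde"))
        sub = table[screen.retained].to_numpy()
        r = np.abs(np.corrcoef(sub, rowvar=False))
        np.fill_diagonal(r, 0)
        assert r.max() < 0.75
        from crabmap.sdm import _vif
        assert _vif(sub).max() < 5


class TestStepwiseMLR:
    def test_selects_single_true_predictor_in_low_noise_limit(self):
        rng = np.random.default_rng(5)
        n = 200
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
        X["SR"] = 2.0 * X["a"] + 1e-6 * rng.standard_normal(n)
        rep = dr.stepwise_mlr(X, "SR", list("abcde"))
        # the true predictor is found and carries the whole signal; AIC's
        # scale invariance can admit spurious terms, but only with
        # vanishing coefficients
        assert "a" in rep.selected
        assert rep.coefficients.loc["a", "coefficient"] == pytest.approx(2.0, abs=1e-4)
        extras = [v for v in rep.selected if v != "a"]
        for v in extras:
            assert abs(rep.coefficients.loc[v, "coefficient"]) < 1e-4

    def test_pure_noise_usually_selects_little(self):
        # with AIC's fixed +2 penalty the best of 8 noise predictors slips
        # in with known nonzero probability; the intercept-only model must
        # still be the modal outcome and overfitting must stay mild
        outcomes = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((60, 8)), columns=list("abcdefgh"))
            X["SR"] = rng.standard_normal(60)
            rep = dr.stepwise_mlr(X, "SR", list("abcdefgh"))
            outcomes.append(tuple(sorted(rep.selected)))
        counts = pd.Series(outcomes).value_counts()
        assert counts.index[0] == ()
        assert np.mean([len(o) for o in outcomes]) < 2.5

    def test_selected_aic_beats_full_and_empty(self):
        rng = np.random.default_rng(7)
        n = 150
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
        X["SR"] = X["a"] - 0.5 * X["c"] + 0.3 * rng.standard_normal(n)
        rep = dr.stepwise_mlr(X, "SR", list("abcde"))
        y = X["SR"].to_numpy()
        full, _ = dr._ols_aic(y, X[list("abcde")].to_numpy())
        empty, _ = dr._ols_aic(y, np.empty((n, 0)))
        assert rep.aic <= full + 1e-9
        assert rep.aic <= empty + 1e-9
        assert rep.adj_r2 <= rep.r2

    def test_requires_enough_rows(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((12, 5)),
                         columns=list("abcde"))
        X["SR"] = 1.0
        with pytest.raises(ValueError):
            dr.stepwise_mlr(X, "SR", list("abcde"))


class TestGWR:
    def test_constant_coefficients_match_global_ols(self):
        table = make_table(n=400, varying=False)
        rep = dr.gwr(table, "SR", ["v"])
        ols = sm.OLS(table["SR"], sm.add_constant(table["v"])).fit()
        dev = np.abs(rep.local_coefficients["v"] - ols.params.iloc[1]).max()
        assert dev < 0.05

    def test_recovers_longitude_varying_coefficient(self):
        table = make_table(n=400, varying=True)
        rep = dr.gwr(table, "SR", ["v"])
        corr = np.corrcoef(rep.local_coefficients["v"], table["x"])[0, 1]
        assert corr > 0.9

    def test_large_bandwidth_reduces_to_ols(self):
        table = make_table(n=100, varying=False)
        rep = dr.gwr(table, "SR", ["v"], bandwidth=1e6)
        ols = sm.OLS(table["SR"], sm.add_constant(table["v"])).fit()
        assert rep.rss == pytest.approx(float(ols.ssr), rel=1e-6)

    def test_optimal_bandwidth_is_local_minimum(self):
        table = make_table(n=150, varying=True, seed=9)
        rep = dr.gwr(table, "SR", ["v"])
        y = table["SR"].to_numpy()
        X = table[["v"]].to_numpy()
        coords = table[["x", "y"]].to_numpy()

        def aicc_at(b):
            _, hat, yhat = dr._gwr_fit(y, X, coords, b)
            return dr._gwr_aicc(y, yhat, hat)

        assert rep.aicc <= aicc_at(rep.bandwidth * 2) + 1e-6
        assert rep.aicc <= aicc_at(rep.bandwidth / 2) + 1e-6

    def test_gwr_beats_mlr_on_spatially_varying_data(self):
        table = make_table(n=300, varying=True, noise=0.3, seed=13)
        mlr = dr.stepwise_mlr(table.assign(z=np.random.default_rng(0).standard_normal(300)),
                              "SR", ["v", "z"])
        g = dr.gwr(table, "SR", ["v"])
        assert g.adj_r2 > mlr.adj_r2
        assert g.aicc < mlr.aicc

    def test_ols_two_oracle_agreement(self):
        # QR (lstsq) path vs explicit normal equations
        rng = np.random.default_rng(15)
        X = rng.standard_normal((100, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(100)
        design = np.column_stack([np.ones(100), X])
        beta_qr, *_ = np.linalg.lstsq(design, y, rcond=None)
        beta_ne = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.abs(beta_qr - beta_ne).max() < 1e-8
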