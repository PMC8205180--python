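"""Pixel aggregation, collinearity pruning, standardization, RDA and
forward selection."""

import numpy as np
import pandas as pd
import pytest

from phytoreg import environment as env
from phytoreg.gridding import GridSpec

GRID = GridSpec(origin=(0.0, 0.0), cell_size=1.0)


def pixel_table(rng, n=200, var_names=("v1", "v2")):
    df = pd.DataFrame(
        {
            "lon": rng.uniform(0, 3, n),
            "lat": rng.uniform(0, 3, n),
        }
    )
    for v in var_names:
        df[v] = rng.standard_normal(n)
    return df


class TestAggregate:
    def test_constant_field(self):
        rng = np.random.default_rng(0)
        px = pixel_table(rng)
        px["v1"] = 7.5
        out, _ = env.aggregate_pixels(px[["lon", "lat", "v1"]], GRID)
        assert (out["v1"] == 7.5).all()

    def test_four_pixels_average(self):
        px = pd.DataFrame(
            {"lon": [0.1, 0.2, 0.3, 0.4], "lat": [0.5] * 4, "v": [1.0, 2.0, 3.0, 4.0]}
        )
        out, _ = env.aggregate_pixels(px, GRID)
        assert out.loc["c000_000", "v"] == pytest.approx(2.5)

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(1)
        px = pixel_table(rng, n=500)
        out, _ = env.aggregate_pixels(px, GRID)
        # oracle: per-cell mean by explicit loop
        for cid, row in out.iterrows():
            ix, iy = int(cid[1:4]), int(cid[5:8])
            mask = (
                (px["lon"] >= ix) & (px["lon"] < ix + 1) & (px["lat"] >= iy) & (px["lat"] < iy + 1)
            )
            assert row["v1"] == pytest.approx(px.loc[mask, "v1"].mean())

    def test_uncovered_cells_flagged(self):
        rng = np.random.default_rng(2)
        px = pixel_table(rng, n=50)
        px = px[px["lon"] < 1.0]  # leave columns 1-2 uncovered
        with pytest.warns(UserWarning, match="no pixel coverage"):
            out, missing = env.aggregate_pixels(px, GRID, cell_ids=["c000_000", "c002_002"])
        assert missing == ["c002_002"]
        assert list(out.index) == ["c000_000"]


class TestPrune:
    def test_identical_columns_drop_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)})
        kept, report = env.prune_collinear(df, threshold=0.8)
        assert kept.shape[1] == 2
        assert len(report) == 1 and report["r"].iloc[0] == pytest.approx(1.0)

    def test_identity_when_uncorrelated(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        kept, report = env.prune_collinear(df, threshold=0.8)
        assert list(kept.columns) == list("abcd")
        assert report.empty

    def test_hand_traced_greedy_elimination(self):
        """Five variables with a planted correlation structure; the greedy
        rule (drop the worst pair's member with the larger mean |r|) is
        traced by hand."""
        rng = np.random.default_rng(5)
        n = 2000
        z = rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "a": z + 0.05 * rng.standard_normal(n),
                "b": z + 0.05 * rng.standard_normal(n),
                "c": z + 0.8 * rng.standard_normal(n),
                "d": rng.standard_normal(n),
                "e": rng.standard_normal(n),
            }
        )
        kept, report = env.prune_collinear(df, threshold=0.8)
        # worst pair is (a, b) with r ~ 0.998; both correlate ~0.78 with c,
        # but one of them also correlates slightly more on average -> the
        # survivor set must be {one of a/b, c, d, e}
        assert report["dropped"].iloc[0] in {"a", "b"}
        assert set(kept.columns) >= {"c", "d", "e"}
        assert kept.shape[1] == 4
        # oracle: after dropping one of a/b no remaining pair exceeds 0.8
        corr = kept.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.8

    def test_constant_column_reported(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"a": rng.standard_normal(20), "k": np.ones(20)})
        kept, report = env.prune_collinear(df, threshold=0.8)
        assert "k" not in kept.columns
        assert (report["reason"] == "constant column").any()


class TestStandardize:
    def test_three_point_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z, means, sds = env.standardize(df)
        np.testing.assert_allclose(z["x"], [-1, 0, 1])

    def test_idempotent_to_numerical_precision(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.standard_normal(50)})
        z1, *_ = env.standardize(df)
        z2, *_ = env.standardize(z1)
        np.testing.assert_allclose(z1["x"], z2["x"], atol=1e-10)

    def test_round_trip(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((40, 3)) * 5 + 2, columns=list("abc"))
        z, means, sds = env.standardize(df)
        back = env.destandardize(z, means, sds)
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), atol=1e-10)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="constant"):
            env.standardize(pd.DataFrame({"x": np.ones(5)}))


class TestRda:
    def test_orthogonal_predictors_explain_nothing(self):
        n = 16
        t = np.arange(n)
        Y = pd.DataFrame({"y": np.cos(2 * np.pi * t / n)})
        X = pd.DataFrame({"x": np.sin(2 * np.pi * t / n)})
        res = env.rda(Y, X)
        assert res.proportion_explained == pytest.approx(0.0, abs=1e-10)

    def test_perfect_fit(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        B = rng.standard_normal((3, 5))
        Y = pd.DataFrame(X.to_numpy() @ B)
        res = env.rda(Y, X)
        assert res.proportion_explained == pytest.approx(1.0, abs=1e-10)

    def test_trace_ratio_oracle(self):
        rng = np.random.default_rng(10)
        Y = pd.DataFrame(rng.standard_normal((20, 10)))
        X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        res = env.rda(Y, X)
        # closed-form oracle: hat matrix projection, tr(Yhat'Yhat)/tr(Y'Y)
        Yc = Y - Y.mean()
        Xc = (X - X.mean()).to_numpy()
        H = Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T)
        Yhat = H @ Yc.to_numpy()
        oracle = np.trace(Yhat.T @ Yhat) / np.trace(Yc.to_numpy().T @ Yc.to_numpy())
        assert res.proportion_explained == pytest.approx(oracle, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal(15)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.standard_normal(15)})
        Y = pd.DataFrame({"y": rng.standard_normal(15)})
        with pytest.raises(ValueError, match="rank-deficient"):
            env.rda(Y, X)

    def test_invariant_to_rotation_and_scaling_of_x(self):
        rng = np.random.default_rng(12)
        Y = pd.DataFrame(rng.standard_normal((25, 6)))
        X = rng.standard_normal((25, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        p1 = env.rda(Y, pd.DataFrame(X)).proportion_explained
        p2 = env.rda(Y, pd.DataFrame(X @ Q)).proportion_explained
        p3 = env.rda(Y, pd.DataFrame(X * np.array([2.0, 0.5, 10.0]))).proportion_explained
        assert p1 == pytest.approx(p2, abs=1e-10)
        assert p1 == pytest.approx(p3, abs=1e-10)


class TestForwardSelect:
    def test_perfect_predictor_enters_first_with_minimal_p(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(30)
        X = pd.DataFrame({"signal": x, "junk": rng.standard_normal(30)})
        Y = pd.DataFrame({"y1": 2 * x, "y2": -x})
        res = env.forward_select(Y, X, permutations=199, alpha=0.05, seed=0)
        assert res.selected[0] == "signal"
        assert res.steps["p"].iloc[0] == pytest.approx(1 / 200)

    def test_aic_only_path_is_monotone(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.standard_normal((40, 6)), columns=list("abcdef"))
        Y = pd.DataFrame(
            X.to_numpy() @ rng.standard_normal((6, 4)) + 0.5 * rng.standard_normal((40, 4))
        )
        res = env.forward_select(Y, X, permutations=9, alpha=1.0, seed=1)
        aics = res.steps["aic"].to_numpy()
        assert np.all(np.diff(aics) <= 0)

    def test_no_admission_warns(self):
        rng = np.random.default_rng(15)
        Y = pd.DataFrame(rng.standard_normal((30, 3)))
        X = pd.DataFrame({"noise": rng.standard_normal(30)})
        with pytest.warns(UserWarning, match="no variable"):
            res = env.forward_select(Y, X, permutations=49, alpha=0.0001, seed=2)
        assert res.selected == []
        assert res.proportion_explained == pytest.approx(0.0)

    def test_p_values_on_grid(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(25)
        X = pd.DataFrame({"x": x})
        Y = pd.DataFrame({"y": x + rng.standard_normal(25)})
        res = env.forward_select(Y, X, permutations=99, alpha=1.0, seed=3)
        p = res.steps["p"].iloc[0]
        assert 1 / 100 <= p <= 1
        assert round(p * 100, 6) == int(round(p * 100))
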