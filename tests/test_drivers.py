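"""Scaling, PCA, RDA, dbRDA forward selection and driver attribution."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

import benthos as b
from benthos.datasets import (
    REFERENCE_DISPERSAL_AXES,
    REFERENCE_ENV_VARIABLES,
    REFERENCE_SELECTION_AXES,
    reference_loadings,
)


class TestMinMax:
    def test_known_values(self):
        assert np.allclose(b.minmax_scale([2, 4, 6]), [0, 0.5, 1])

    def test_idempotent_on_unit_range(self):
        x = np.array([0.0, 0.3, 1.0])
        assert np.allclose(b.minmax_scale(x), x)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            b.minmax_scale([3, 3, 3])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=10).filter(
            lambda v: max(v) - min(v) > 1e-6
        ),
        st.floats(0.1, 10),
        st.floats(-50, 50),
    )
    @settings(deadline=None, max_examples=50)
    def test_affine_invariance(self, vec, a, c):
        x = np.asarray(vec)
        assert np.allclose(b.minmax_scale(a * x + c), b.minmax_scale(x), atol=1e-8)

    def test_table_drops_constant_with_warning(self):
        df = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.warns(UserWarning, match="flat"):
            out = b.minmax_scale_table(df)
        assert list(out.columns) == ["ok"]


class TestPca:
    def test_perfectly_correlated_single_axis(self):
        x = np.linspace(0, 1, 10)
        df = pd.DataFrame({"a": x, "b": 2 * x}, index=[f"s{i}" for i in range(10)])
        res = b.pca(df)
        assert res.explained.iloc[0] == pytest.approx(100.0)

    def test_isotropic_cloud_splits_evenly(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(8000, 2)), columns=["a", "b"])
        res = b.pca(df)
        assert res.explained.iloc[0] == pytest.approx(50.0, abs=2.0)

    def test_axis_count_bounded(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(32, 58)))
        df.columns = [f"v{j}" for j in range(58)]
        res = b.pca(df)
        assert len(res.axes) <= min(31, 58)
        assert len(res.axes) >= 30

    def test_reconstruction_with_all_axes(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        res = b.pca(df)
        centered = df.to_numpy() - df.to_numpy().mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, centered, atol=1e-9)

    def test_loadings_orthonormal_and_variance_ordered(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(20, 6)) * [5, 4, 3, 2, 1, 0.5])
        df.columns = [f"v{j}" for j in range(6)]
        res = b.pca(df)
        l = res.loadings.to_numpy()
        assert np.allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-9)
        assert (np.diff(res.explained.to_numpy()) <= 1e-9).all()

    def test_sign_convention_top_loading_positive(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        res = b.pca(df)
        for ax in res.axes:
            col = res.loadings[ax]
            assert col.loc[col.abs().idxmax()] > 0


class TestRdaExplained:
    def test_exact_linear_community_fully_explained(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(12)]
        env = pd.DataFrame(rng.normal(size=(12, 2)), index=idx, columns=["e1", "e2"])
        comm = pd.DataFrame(env.to_numpy() @ rng.normal(size=(2, 5)), index=idx,
                            columns=[f"t{j}" for j in range(5)])
        assert b.rda_explained(comm, env, transform="identity") == pytest.approx(100.0)

    def test_orthogonal_env_explains_nothing(self):
        idx = [f"s{i}" for i in range(8)]
        comm = pd.DataFrame({"t1": [1.0, -1, 1, -1, 1, -1, 1, -1]}, index=idx)
        env = pd.DataFrame({"e": [1.0, 1, -1, -1, 1, 1, -1, -1]}, index=idx)
        assert b.rda_explained(comm, env, transform="identity") == pytest.approx(0.0, abs=1e-9)

    def test_random_community_matches_df_expectation(self):
        # with p orthonormal-ish random constraints, expected explained
        # fraction of pure noise is ~ p / (n - 1)
        rng = np.random.default_rng(5)
        n, p, reps = 32, 6, 40
        vals = []
        for _ in range(reps):
            idx = [f"s{i}" for i in range(n)]
            comm = pd.DataFrame(rng.normal(size=(n, 20)), index=idx,
                                columns=[f"t{j}" for j in range(20)])
            env = pd.DataFrame(rng.normal(size=(n, p)), index=idx,
                               columns=[f"e{j}" for j in range(p)])
            vals.append(b.rda_explained(comm, env, transform="identity"))
        assert np.mean(vals) == pytest.approx(100.0 * p / (n - 1), abs=2.0)

    def test_too_many_constraints_rejected(self):
        idx = [f"s{i}" for i in range(4)]
        rng = np.random.default_rng(0)
        comm = pd.DataFrame(rng.normal(size=(4, 3)), index=idx, columns=list("abc"))
        env = pd.DataFrame(rng.normal(size=(4, 4)), index=idx, columns=list("wxyz"))
        with pytest.raises(ValueError):
            b.rda_explained(comm, env)


class TestRandomSubcommunity:
    def _dataset(self, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(16)]
        counts = pd.DataFrame(rng.integers(1, 50, size=(16, 30)), index=idx,
                              columns=[f"t{j}" for j in range(30)])
        env = b.EnvTable(pd.DataFrame(rng.normal(size=(16, 3)), index=idx,
                                      columns=["e1", "e2", "e3"]))
        return b.OtuTable(counts), env

    def test_random_keystones_not_significant_usually(self):
        table, env = self._dataset()
        rng = np.random.default_rng(1)
        sig = 0
        outer = 20
        for i in range(outer):
            ids = list(rng.choice(table.taxon_ids, size=8, replace=False))
            res = b.random_subcommunity_test(table, env, ids, n_draws=49, seed=i)
            if res["p_two_sided"] < 0.05:
                sig += 1
        assert sig <= 4  # ~5% expected, allow slack at this resolution

    def test_k_too_large_rejected(self):
        table, env = self._dataset()
        with pytest.raises(ValueError):
            b.random_subcommunity_test(table, env, table.taxon_ids, n_draws=9)


def planted_response(scores: pd.DataFrame, axis: str) -> pd.DataFrame:
    d = squareform(pdist(scores[[axis]].to_numpy()))
    return pd.DataFrame(d, index=scores.index, columns=scores.index)


class TestDbrda:
    def _predictors(self, seed=0, n=32, p=6):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n, p)),
                          index=[f"s{i}" for i in range(n)],
                          columns=[f"v{j}" for j in range(p)])
        return b.pca(df)

    def test_planted_axis_recovered_first(self):
        pres = self._predictors()
        resp = planted_response(pres.scores, "PC3")
        sel = b.dbrda_forward_select(resp, pres, permutations=499, seed=1)
        assert sel.retained_axes[:1] == ["PC3"]
        assert sel.retained[0]["adj_r2"] > 0.95
        assert len(sel.retained_axes) == 1

    def test_pure_noise_rarely_retains(self):
        pres = self._predictors(seed=3)
        rng = np.random.default_rng(4)
        empty = 0
        runs = 12
        for i in range(runs):
            noise = squareform(pdist(rng.normal(size=(32, 3))))
            resp = pd.DataFrame(noise, index=pres.scores.index, columns=pres.scores.index)
            sel = b.dbrda_forward_select(resp, pres, permutations=199, seed=i)
            if not sel.retained_axes:
                empty += 1
        assert empty >= runs - 2

    def test_adjusted_r2_monotone_and_bounded(self):
        pres = self._predictors(seed=6)
        rng = np.random.default_rng(7)
        signal = (
            squareform(pdist(pres.scores[["PC1"]]))
            + 0.5 * squareform(pdist(pres.scores[["PC2"]]))
            + 0.1 * squareform(pdist(rng.normal(size=(32, 2))))
        )
        resp = pd.DataFrame(signal, index=pres.scores.index, columns=pres.scores.index)
        sel = b.dbrda_forward_select(resp, pres, permutations=199, seed=8)
        adj = [d["adj_r2"] for d in sel.retained]
        assert all(x < y + 1e-12 for x, y in zip(adj, adj[1:])) or len(adj) <= 1
        assert all(a <= sel.full_adj_r2 + 1e-9 for a in adj)

    def test_euclidean_response_equals_classical_rda(self):
        # on a Euclidean-embeddable response the dbRDA R2 of one predictor
        # equals the RDA R2 on the embedded coordinates
        pres = self._predictors(seed=9, n=6, p=2)
        resp = planted_response(pres.scores, "PC1")
        sel = b.dbrda_forward_select(resp, pres, permutations=99, seed=0)
        assert sel.retained_axes == ["PC1"]
        assert sel.retained[0]["r2"] == pytest.approx(1.0, abs=1e-6)

    def test_asymmetric_response_rejected(self):
        pres = self._predictors()
        resp = planted_response(pres.scores, "PC1")
        resp.iloc[0, 1] += 1
        with pytest.raises(ValueError):
            b.dbrda_forward_select(resp, pres)


class TestAttribution:
    def test_reference_env_loaders(self):
        attr = b.attribute_drivers(
            REFERENCE_SELECTION_AXES,
            REFERENCE_DISPERSAL_AXES,
            reference_loadings(),
            env_variables=REFERENCE_ENV_VARIABLES,
        )
        tl = attr.top_loadings
        pc2 = tl[(tl.axis == "PC2") & (tl.scope == "environmental")].iloc[0]
        assert pc2.variable == "pH"
        assert pc2.loading == pytest.approx(-0.7301)
        pc5 = tl[(tl.axis == "PC5") & (tl.scope == "environmental")].iloc[0]
        assert pc5.variable == "Moisture"
        assert pc5.loading == pytest.approx(-0.7764)
        assert pc5.process == "dispersal"

    def test_axis_retained_by_both_is_selection(self):
        loadings = reference_loadings()
        attr = b.attribute_drivers(["PC2"], ["PC2", "PC5"], loadings,
                                   env_variables=REFERENCE_ENV_VARIABLES)
        assert attr.dispersal_axes == ["PC5"]
        assert "PC2" in attr.selection_related

    def test_sign_flip_invariance(self):
        loadings = reference_loadings()
        flipped = loadings.copy()
        flipped["PC2"] = -flipped["PC2"]
        a1 = b.attribute_drivers(["PC2"], [], loadings)
        a2 = b.attribute_drivers(["PC2"], [], flipped)
        assert a1.selection_related == a2.selection_related

    def test_single_variable_attributed(self):
        loadings = pd.DataFrame({"PC1": [0.9]}, index=["only"])
        attr = b.attribute_drivers(["PC1"], [], loadings)
        assert attr.selection_related == {"PC1": "only"}

    def test_empty_retained_sets_valid(self):
        attr = b.attribute_drivers([], [], reference_loadings())
        assert attr.selection_related == {} and attr.dispersal_related == {}
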