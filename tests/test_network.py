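"""Correlation matrices, clustering order, PCA and threshold networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gggqtl import network


def frame(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"v{i + 1}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols,
                        index=[f"s{i + 1}" for i in range(arr.shape[0])])


def brute_force_spearman(x, y):
    """Spearman via explicit average ranks computed by sorting."""
    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks
    rx, ry = avg_ranks(np.asarray(x)), avg_ranks(np.asarray(y))
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearmanMatrix:
    def test_monotone_pair_is_one(self):
        df = frame(np.column_stack([np.arange(10.0), np.exp(np.arange(10.0))]))
        corr = network.spearman_matrix(df)
        assert corr.rs.loc["v1", "v2"] == pytest.approx(1.0)

    def test_antitone_pair_is_minus_one(self):
        x = np.random.default_rng(0).normal(size=12)
        corr = network.spearman_matrix(frame(np.column_stack([x, -x])))
        assert corr.rs.loc["v1", "v2"] == pytest.approx(-1.0)

    def test_ties_match_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, 30).astype(float)   # heavy ties
        y = rng.integers(0, 3, 30).astype(float)
        corr = network.spearman_matrix(frame(np.column_stack([x, y])))
        assert corr.rs.loc["v1", "v2"] == pytest.approx(
            brute_force_spearman(x, y), abs=1e-12)

    def test_pairwise_complete_with_missing(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = x + 0.1 * rng.normal(size=20)
        y[:3] = np.nan
        corr = network.spearman_matrix(frame(np.column_stack([x, y])))
        expected = brute_force_spearman(x[3:], y[3:])
        assert corr.rs.loc["v1", "v2"] == pytest.approx(expected, abs=1e-12)
        assert corr.n_obs.loc["v1", "v2"] == 17

    def test_pair_below_floor_missing(self):
        x = np.arange(10.0)
        y = np.full(10, np.nan)
        y[:3] = [1.0, 2.0, 3.0]
        corr = network.spearman_matrix(frame(np.column_stack([x, y])))
        assert np.isnan(corr.rs.loc["v1", "v2"])
        assert np.isnan(corr.p_bh.loc["v1", "v2"])

    def test_bh_at_least_raw_and_symmetric(self):
        rng = np.random.default_rng(3)
        corr = network.spearman_matrix(frame(rng.normal(size=(15, 6))))
        p, q = corr.p_raw.to_numpy(), corr.p_bh.to_numpy()
        iu = np.triu_indices(6, k=1)
        assert (q[iu] >= p[iu] - 1e-12).all()
        np.testing.assert_allclose(corr.rs.to_numpy(), corr.rs.to_numpy().T)
        assert np.allclose(np.diag(corr.rs), 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = network.spearman_matrix(frame(np.column_stack([x, y])))
        warped = network.spearman_matrix(
            frame(np.column_stack([np.exp(3 * x), y**3])))
        assert warped.rs.loc["v1", "v2"] == pytest.approx(
            base.rs.loc["v1", "v2"], abs=1e-12)


class TestHierarchicalOrder:
    def test_correlated_blocks_contiguous(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(30, 1)) + 0.05 * rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 1)) + 0.05 * rng.normal(size=(30, 3))
        df = frame(np.column_stack([a, b]),
                   cols=["a1", "a2", "a3", "b1", "b2", "b3"])
        corr = network.spearman_matrix(df)
        order, _ = network.hierarchical_order(corr)
        labels = ["a" if c.startswith("a") else "b" for c in order]
        assert labels in (["a"] * 3 + ["b"] * 3, ["b"] * 3 + ["a"] * 3)

    def test_identical_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        df = frame(np.column_stack([x, x, rng.normal(size=10)]))
        corr = network.spearman_matrix(df)
        _, z = network.hierarchical_order(corr)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_four_variable_average_linkage_heights(self):
        # hand-built correlation matrix; distances d = 1 - rs
        rs = np.array([
            [1.0, 0.9, 0.2, 0.1],
            [0.9, 1.0, 0.3, 0.2],
            [0.2, 0.3, 1.0, 0.8],
            [0.1, 0.2, 0.8, 1.0],
        ])
        idx = ["a", "b", "c", "d"]
        from gggqtl.types import CorrelationMatrix
        corr = CorrelationMatrix(
            rs=pd.DataFrame(rs, index=idx, columns=idx),
            p_raw=pd.DataFrame(0.0, index=idx, columns=idx),
            p_bh=pd.DataFrame(0.0, index=idx, columns=idx))
        _, z = network.hierarchical_order(corr)
        # merges: (a,b) at 0.1, (c,d) at 0.2, then average of the 4 cross
        # distances (0.8, 0.9, 0.7, 0.8) = 0.8
        heights = sorted(z[:, 2])
        assert heights == pytest.approx([0.1, 0.2, 0.8], abs=1e-12)


class TestPca:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        res = network.pca_summary(frame(rng.normal(size=(20, 5))))
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_data_single_component(self):
        u = np.random.default_rng(7).normal(size=10)
        df = frame(np.column_stack([u, 2 * u, -u]))
        res = network.pca_summary(df)
        assert res.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(8)
        res = network.pca_summary(frame(rng.normal(size=(15, 4))))
        gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)

    def test_condition_shift_separates_on_pc1(self):
        rng = np.random.default_rng(9)
        e = np.repeat([0.0, 1.0], 25)
        x = 2.0 * e[:, None] + 0.3 * rng.normal(size=(50, 30))
        res = network.pca_summary(frame(x))
        pc1 = res.scores["PC1"].to_numpy()
        r = np.corrcoef(pc1, e)[0, 1]
        assert abs(r) > 0.9


class TestBuildNetwork:
    def test_threshold_one_noise_empty(self):
        rng = np.random.default_rng(10)
        corr = network.spearman_matrix(frame(rng.normal(size=(20, 6))))
        net = network.build_network(corr, threshold=1.0)
        assert net.n_edges == 0

    def test_threshold_zero_fdr_off_complete(self):
        rng = np.random.default_rng(11)
        corr = network.spearman_matrix(frame(rng.normal(size=(10, 5))))
        net = network.build_network(corr, threshold=0.0, fdr_level=None)
        assert net.n_edges == 5 * 4 // 2

    def test_three_block_components(self):
        rng = np.random.default_rng(12)
        blocks = []
        for _ in range(3):
            latent = rng.normal(size=(60, 1))
            blocks.append(latent + 0.2 * rng.normal(size=(60, 4)))
        corr = network.spearman_matrix(frame(np.column_stack(blocks)))
        net = network.build_network(corr, threshold=0.5)
        import networkx as nx
        comps = [c for c in nx.connected_components(net.graph) if len(c) > 1]
        assert len(comps) == 3
        assert sorted(len(c) for c in comps) == [4, 4, 4]

    def test_edge_sets_nested_across_thresholds(self):
        rng = np.random.default_rng(13)
        corr = network.spearman_matrix(frame(rng.normal(size=(25, 8))))
        edges = {}
        for thr in (0.1, 0.3, 0.5):
            net = network.build_network(corr, threshold=thr, fdr_level=None)
            edges[thr] = set(map(frozenset, net.graph.edges))
        assert edges[0.5] <= edges[0.3] <= edges[0.1]


class TestPropertySweep:
    @staticmethod
    @pytest.fixture(scope="class")
    def sweep_curves():
        rng = np.random.default_rng(14)
        latent = rng.normal(size=(40, 2))
        x = np.column_stack([latent[:, [i // 4]] + 0.4 * rng.normal(size=(40, 1))
                             for i in range(8)])
        curves = network.property_sweep(frame(x),
                                        thresholds=np.arange(0.0, 1.01, 0.05),
                                        n_random=20, seed=15)
        return curves

    def test_density_one_at_zero_threshold(self, sweep_curves):
        obs = sweep_curves[sweep_curves["kind"] == "observed"]
        assert obs[obs["threshold"] == 0.0]["density"].iloc[0] == pytest.approx(1.0)

    def test_edges_monotone_nonincreasing(self, sweep_curves):
        obs = sweep_curves[sweep_curves["kind"] == "observed"].sort_values("threshold")
        assert (np.diff(obs["n_edges"].to_numpy()) <= 0).all()

    def test_randomized_fewer_edges_at_mid_threshold(self, sweep_curves):
        mid = sweep_curves[np.isclose(sweep_curves["threshold"], 0.5)]
        obs = mid[mid["kind"] == "observed"]["n_edges"].iloc[0]
        rnd = mid[mid["kind"] == "random_mean"]["n_edges"].iloc[0]
        assert rnd < obs

    def test_stats_recomputable_from_edge_count(self, sweep_curves):
        obs = sweep_curves[sweep_curves["kind"] == "observed"]
        n = 8
        np.testing.assert_allclose(
            obs["density"], obs["n_edges"] / (n * (n - 1) / 2), atol=1e-12)
        np.testing.assert_allclose(
            obs["average_degree"], 2.0 * obs["n_edges"] / n, atol=1e-12)
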