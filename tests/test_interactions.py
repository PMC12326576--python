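"""SHAP interaction matrices, percentile thresholding and networks."""

import numpy as np
import pandas as pd
import pytest

from crcstrat.interactions import (
    InteractionMatrix,
    ThresholdConfig,
    aggregate_interactions,
    build_network,
    cv_interaction_matrix,
    export_network,
    fold_interaction_matrix,
    interaction_tensor,
    network_metrics,
    select_interaction_features,
    subgroup_interaction_analysis,
)
from crcstrat.modeling import BackendError, CVConfig, make_backend, run_repeated_cv

from conftest import cohort_features, make_spec


def matrix_from(values, names=None) -> InteractionMatrix:
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[0])]
    return InteractionMatrix(values=pd.DataFrame(values, index=names, columns=names))


def brute_force_selection(values, percentile, min_interactions):
    """Independent route: sort upper-triangle values, index the percentile,
    count strict exceedances per row."""
    values = np.asarray(values, dtype=float)
    iu = np.triu_indices(values.shape[0], k=1)
    thr = np.percentile(values[iu], percentile)
    sig = (values > thr) & ~np.eye(values.shape[0], dtype=bool)
    counts = sig.sum(1)
    return [j for j in range(values.shape[0]) if counts[j] >= min_interactions], thr


@pytest.fixture(scope="module")
def fitted_xgb(rng_module=np.random.default_rng(17)):
    X = rng_module.normal(size=(250, 10))
    logits = 1.2 * X[:, 0] - 1.0 * X[:, 1] + 2.0 * X[:, 2] * X[:, 3]
    y = (logits + 0.3 * rng_module.normal(size=250) > 0).astype(int)
    backend = make_backend("xgboost", 0, {"n_estimators": 80, "max_depth": 4})
    backend.fit(X, y)
    return backend, X


class TestInteractionTensor:
    def test_rows_sum_to_phi(self, fitted_xgb):
        backend, X = fitted_xgb
        tensor = interaction_tensor(backend, X[:30])
        phi, _ = backend.shap_values(X[:30])
        assert np.abs(tensor.sum(axis=2) - phi).max() < 1e-5

    def test_tensor_symmetric(self, fitted_xgb):
        backend, X = fitted_xgb
        tensor = interaction_tensor(backend, X[:10])
        assert np.abs(tensor - tensor.transpose(0, 2, 1)).max() < 1e-6

    def test_additive_model_has_no_interactions(self, rng):
        """Depth-1 trees are additive by construction: every off-diagonal
        interaction entry vanishes."""
        X = rng.normal(size=(200, 6))
        y = (X[:, 0] - X[:, 1] > 0).astype(int)
        backend = make_backend("xgboost", 0, {"n_estimators": 60, "max_depth": 1})
        backend.fit(X, y)
        tensor = interaction_tensor(backend, X[:40])
        off = tensor - np.einsum("nij,ij->nij", tensor, np.eye(6))
        assert np.abs(off).max() < 1e-6

    def test_unsupported_backend_names_supported(self, small_features, small_study):
        backend = make_backend("lightgbm", 0, {"n_estimators": 5})
        backend.fit(small_features.values.to_numpy(), small_study.labels.to_numpy())
        with pytest.raises(BackendError, match="xgboost"):
            interaction_tensor(backend, small_features.values.to_numpy()[:5])

    def test_planted_product_term_dominates(self, fitted_xgb):
        backend, X = fitted_xgb
        m = fold_interaction_matrix(backend, X, [f"f{j}" for j in range(10)])
        v = m.values.to_numpy()
        iu = np.triu_indices(10, k=1)
        top = np.argmax(v[iu])
        pair = (iu[0][top], iu[1][top])
        assert pair == (2, 3)


class TestAggregation:
    def test_single_matrix_identity(self):
        m = matrix_from([[0, 1], [1, 0]])
        agg = aggregate_interactions([m])
        assert agg.values.equals(m.values)

    def test_two_matrices_mean(self):
        a = matrix_from([[0, 1], [1, 0]])
        b = matrix_from([[0, 3], [3, 0]])
        agg = aggregate_interactions([a, b])
        assert agg.values.iloc[0, 1] == pytest.approx(2.0)

    def test_feature_mismatch_rejected(self):
        a = matrix_from([[0, 1], [1, 0]], names=["x", "y"])
        b = matrix_from([[0, 1], [1, 0]], names=["x", "z"])
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_interactions([a, b])

    def test_seeded_cv_aggregate_deterministic(self, small_cv, small_features):
        a = cv_interaction_matrix(small_cv, small_features)
        b = cv_interaction_matrix(small_cv, small_features)
        assert a.values.equals(b.values)


class TestSelection:
    def test_matches_brute_force_on_random_matrices(self, rng):
        """Percentile + count selection equals the independent sort-and-count
        route on 100 random symmetric matrices up to 30x30."""
        for _ in range(100):
            n = int(rng.integers(3, 31))
            raw = rng.random((n, n))
            sym = np.triu(raw, 1) + np.triu(raw, 1).T
            pct = float(rng.choice([90.0, 95.0, 99.0]))
            mc = int(rng.integers(1, 5))
            m = matrix_from(sym)
            sel = select_interaction_features(m, ThresholdConfig(pct, mc))
            expect_idx, expect_thr = brute_force_selection(sym, pct, mc)
            assert sel.retained == [f"f{j}" for j in expect_idx]
            assert sel.threshold == pytest.approx(expect_thr)

    def test_impossible_count_empty_retention(self):
        m = matrix_from(np.ones((4, 4)) - np.eye(4))
        sel = select_interaction_features(m, ThresholdConfig(95.0, 4))
        assert sel.retained == []

    def test_retention_monotone_in_percentile(self, rng):
        raw = rng.random((12, 12))
        sym = np.triu(raw, 1) + np.triu(raw, 1).T
        m = matrix_from(sym)
        prev = None
        for pct in (90.0, 95.0, 99.0):
            kept = set(select_interaction_features(m, ThresholdConfig(pct, 2)).retained)
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_grid_reports_all_three_percentiles(self, rng):
        raw = rng.random((8, 8))
        m = matrix_from(np.triu(raw, 1) + np.triu(raw, 1).T)
        sel = select_interaction_features(m, ThresholdConfig(95.0, 1))
        assert list(sel.grid.columns) == [90.0, 95.0, 99.0]
        # retained counts decrease as min_interactions grows
        for p in sel.grid.columns:
            col = sel.grid[p].astype(int)
            assert (col.diff().dropna() <= 0).all()


class TestNetwork:
    def test_single_significant_pair(self):
        v = np.zeros((5, 5))
        v[0, 1] = v[1, 0] = 1.0
        sel = select_interaction_features(matrix_from(v), ThresholdConfig(95.0, 1))
        g = build_network(matrix_from(v), sel)
        assert sorted(g.nodes) == ["f0", "f1"]
        assert g.number_of_edges() == 1
        assert g["f0"]["f1"]["weight"] == pytest.approx(1.0)

    def test_empty_retention_valid_empty_network(self):
        v = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="all-zero"):
            sel = select_interaction_features(matrix_from(v), ThresholdConfig(95.0, 2))
        g = build_network(matrix_from(v), sel)
        assert g.number_of_nodes() == 0

    def test_path_graph_betweenness(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        metrics = network_metrics(g)
        assert metrics.loc["B", "betweenness"] == pytest.approx(1.0)
        assert metrics.loc["A", "betweenness"] == pytest.approx(0.0)
        assert metrics.loc["B", "interaction_count"] == 2

    def test_complete_graph_zero_betweenness(self):
        import networkx as nx

        g = nx.complete_graph(["A", "B", "C", "D"])
        for _u, _v, d in g.edges(data=True):
            d["weight"] = 2.0
        metrics = network_metrics(g)
        assert (metrics["betweenness"] == 0).all()
        assert (metrics["weighted_degree"] == 6.0).all()

    def test_weighted_degree_equals_adjacency_row_sum(self, rng):
        raw = rng.random((6, 6))
        sym = np.triu(raw, 1) + np.triu(raw, 1).T
        m = matrix_from(sym)
        sel = select_interaction_features(m, ThresholdConfig(90.0, 1))
        g = build_network(m, sel)
        metrics = network_metrics(g)
        adj = m.values.loc[sel.retained, sel.retained].to_numpy()
        mask = sel.significant.loc[sel.retained, sel.retained].to_numpy()
        rowsum = (adj * mask).sum(1)
        for i, name in enumerate(sel.retained):
            assert metrics.loc[name, "weighted_degree"] == pytest.approx(rowsum[i])

    def test_export_round_trip(self, tmp_path, rng):
        import networkx as nx

        raw = rng.random((6, 6))
        m = matrix_from(np.triu(raw, 1) + np.triu(raw, 1).T)
        sel = select_interaction_features(m, ThresholdConfig(90.0, 1))
        g = build_network(m, sel)
        for fmt, reader in (("gexf", nx.read_gexf), ("graphml", nx.read_graphml)):
            path = tmp_path / f"net.{fmt}"
            export_network(g, path, fmt=fmt)
            back = reader(path)
            assert set(back.nodes) == set(g.nodes)
            assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
            for u, v in g.edges:
                assert back.edges[u, v]["weight"] == pytest.approx(g.edges[u, v]["weight"])
            for node in g.nodes:
                assert "betweenness" in back.nodes[node]

    def test_empty_network_exports(self, tmp_path):
        import networkx as nx

        export_network(nx.Graph(), tmp_path / "empty.gexf", fmt="gexf")
        assert nx.read_gexf(tmp_path / "empty.gexf").number_of_nodes() == 0


class TestSubgroup:
    def test_all_subjects_equals_global(self, small_cv, small_features):
        global_m = cv_interaction_matrix(small_cv, small_features)
        net, sub_m, _sel = subgroup_interaction_analysis(
            small_cv, small_features, small_features.sample_ids,
            ThresholdConfig(95.0, 2))
        np.testing.assert_allclose(sub_m.values.to_numpy(),
                                   global_m.values.to_numpy(), atol=1e-12)

    def test_disjoint_partition_weighted_mean_identity(self, small_cv, small_features):
        """Per fold, the subject-weighted mean of two partitioning clusters'
        matrices reproduces the global fold matrix."""
        ids = small_features.sample_ids
        half = len(ids) // 2
        a_ids, b_ids = ids[:half], ids[half:]
        X = small_features.values.to_numpy()
        assignments = small_cv.fold_map.iloc[:, 0].to_numpy()
        f = int(assignments[0])
        idx = np.flatnonzero(assignments == f)
        backend = small_cv.registry[(0, f)]
        names = small_features.feature_names
        idx_a = [i for i in idx if ids[i] in set(a_ids)]
        idx_b = [i for i in idx if ids[i] in set(b_ids)]
        m_all = fold_interaction_matrix(backend, X[idx], names).values.to_numpy()
        m_a = fold_interaction_matrix(backend, X[idx_a], names).values.to_numpy()
        m_b = fold_interaction_matrix(backend, X[idx_b], names).values.to_numpy()
        weighted = (len(idx_a) * m_a + len(idx_b) * m_b) / len(idx)
        np.testing.assert_allclose(weighted, m_all, atol=1e-10)

    def test_small_cluster_warns_but_computes(self, small_cv, small_features):
        with pytest.warns(UserWarning, match="noisy"):
            net, m, _ = subgroup_interaction_analysis(
                small_cv, small_features, small_features.sample_ids[:3],
                ThresholdConfig(95.0, 1))
        assert m.values.shape[0] == small_features.n_features

    def test_subgroup_carrier_ranks_interaction_higher(self):
        """When only subgroup G's labels carry the product term, the planted
        pair ranks higher in G's matrix than in the global one."""
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            n, p = 300, 8
            X = r.normal(size=(n, p))
            carrier = np.arange(n) < n // 2
            logits = 0.8 * X[:, 0] + np.where(carrier, 2.5 * X[:, 2] * X[:, 3], 0.0)
            y = (logits + 0.3 * r.normal(size=n) > 0).astype(int)
            backend = make_backend("xgboost", seed, {"n_estimators": 60, "max_depth": 4})
            backend.fit(X, y)
            names = [f"f{j}" for j in range(p)]

            def pair_rank(mat):
                v = mat.values.to_numpy()
                iu = np.triu_indices(p, k=1)
                order = np.argsort(v[iu])[::-1]
                pairs = list(zip(iu[0][order], iu[1][order]))
                return pairs.index((2, 3))

            rank_g = pair_rank(fold_interaction_matrix(backend, X[carrier], names))
            rank_all = pair_rank(fold_interaction_matrix(backend, X, names))
            hits += rank_g <= rank_all
        assert hits >= 4, hits
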