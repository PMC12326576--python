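"""SHAP-embedding clustering, KNN projection and per-cluster summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from crcstrat.containers import FeatureMatrix
from crcstrat.explain import ShapMatrix
from crcstrat.stratify import (
    Embedding2D,
    _box_stats,
    cluster_risk_profiles,
    cluster_taxa_distributions,
    embed_shap,
    project_external,
    select_clustering,
)


def shap_matrix(values, prefix="s"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    frame = pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
                         columns=[f"f{j}" for j in range(values.shape[1])])
    return ShapMatrix(phi=frame, baseline=pd.Series(0.0, index=frame.index),
                      provenance="test")


def embedding_from(coords, prefix="s"):
    coords = np.asarray(coords, dtype=float)
    frame = pd.DataFrame(coords, index=[f"{prefix}{i}" for i in range(coords.shape[0])],
                         columns=["tsne1", "tsne2"])
    return Embedding2D(coords=frame, params={}, source="test")


class TestEmbedding:
    def test_duplicate_phi_rows_land_together(self, rng):
        phi = rng.normal(size=(30, 8))
        phi[7] = phi[3]
        emb = embed_shap(shap_matrix(phi), perplexity=5, seed=0)
        coords = emb.coords.to_numpy()
        diam = np.ptp(coords, axis=0).max()
        gap = np.linalg.norm(coords[7] - coords[3])
        assert gap < 0.01 * diam

    def test_perplexity_bound_reported(self, rng):
        phi = rng.normal(size=(12, 4))
        with pytest.raises(ValueError, match="must be < 4.0"):
            embed_shap(shap_matrix(phi), perplexity=10)

    def test_minimum_subjects(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            embed_shap(shap_matrix(rng.normal(size=(3, 4))))

    def test_seeded_and_reproducible(self, rng):
        phi = rng.normal(size=(25, 6))
        a = embed_shap(shap_matrix(phi), perplexity=5, seed=4)
        b = embed_shap(shap_matrix(phi), perplexity=5, seed=4)
        assert a.coords.equals(b.coords)


def brute_silhouette(coords, labels):
    """Textbook per-point silhouette s = (b - a) / max(a, b), averaged."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    out = []
    for i in range(len(coords)):
        own = labels == labels[i]
        if own.sum() == 1:
            out.append(0.0)        # singleton-cluster convention
            continue
        d = np.linalg.norm(coords - coords[i], axis=1)
        a = d[own & (np.arange(len(coords)) != i)].mean()
        b = min(d[labels == other].mean() for other in set(labels) - {labels[i]})
        out.append((b - a) / max(a, b))
    return float(np.mean(out))


class TestClusteringSelection:
    def test_perfectly_separated_pairs(self):
        emb = embedding_from([[0, 0], [0, 0], [10, 0], [10, 0]])
        result = select_clustering(emb, k_range=range(2, 4))
        assert result.k == 2
        assert result.silhouette == pytest.approx(1.0)

    def test_paired_points_closed_form(self):
        """{0,1,10,11} at k=2: per-point (b-a)/max(a,b) averages to 0.8997
        (outer points 9.5/10.5, inner points 8.5/9.5)."""
        emb = embedding_from([[0, 0], [1, 0], [10, 0], [11, 0]])
        result = select_clustering(emb, k_range=range(2, 4))
        expected = (2 * 9.5 / 10.5 + 2 * 8.5 / 9.5) / 4
        assert result.silhouette == pytest.approx(expected, abs=1e-9)
        assert result.silhouette == pytest.approx(
            brute_silhouette(emb.coords.to_numpy(), result.labels.to_numpy()), abs=1e-9)

    def test_sklearn_silhouette_matches_textbook_formula(self, rng):
        """All 2-cluster assignments of up to 6 integer points agree with the
        hand formula (the library is the pipeline's scorer, the brute force the
        oracle)."""
        pts = rng.integers(0, 8, size=(6, 2)).astype(float)
        pts += rng.normal(scale=1e-6, size=pts.shape)   # break exact ties
        for assignment in itertools.product([0, 1], repeat=6):
            labels = np.array(assignment)
            if len(set(assignment)) < 2:
                continue
            assert silhouette_score(pts, labels) == pytest.approx(
                brute_silhouette(pts, labels), abs=1e-9)

    def test_grid_and_argmax_returned(self, rng):
        centers = np.array([[0, 0], [8, 8], [-8, 8]])
        coords = np.vstack([c + rng.normal(scale=0.4, size=(15, 2)) for c in centers])
        result = select_clustering(embedding_from(coords), k_range=range(2, 6))
        assert result.k == 3
        assert result.grid.shape == (3, 4)
        best = result.grid.max().max()
        assert result.silhouette == pytest.approx(best)
        assert set(result.labels.unique()) == {1, 2, 3}

    def test_planted_subgroup_recovered(self):
        """Well-separated phi blobs (one = the high-risk subgroup): the
        selected clustering matches ground truth with ARI >= 0.7."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            blobs = [r.normal(loc=mu, scale=0.5, size=(40, 6))
                     for mu in ([0] * 6, [4] * 6, [-4, 4, -4, 4, -4, 4])]
            phi = np.vstack(blobs)
            truth = np.repeat([0, 1, 2], 40)
            emb = embed_shap(shap_matrix(phi), perplexity=15, seed=seed)
            result = select_clustering(emb, k_range=range(2, 7), seed=seed)
            ari = adjusted_rand_score(truth, result.labels.to_numpy())
            assert ari >= 0.7, (seed, ari)

    def test_too_few_subjects(self):
        emb = embedding_from(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="at least"):
            select_clustering(emb, k_range=range(2, 11))


class TestProjection:
    def _setup(self, rng):
        phi = rng.normal(size=(20, 5))
        coords = rng.normal(size=(20, 2))
        train = shap_matrix(phi)
        emb = embedding_from(coords)
        clustering = select_clustering(
            embedding_from(np.vstack([np.zeros((10, 2)), 8 + np.zeros((10, 2))])
                           + rng.normal(scale=0.1, size=(20, 2))),
            k_range=range(2, 3))
        return train, emb, clustering, phi

    def test_identical_phi_with_k1_reproduces_coords(self, rng):
        train, emb, clustering, phi = self._setup(rng)
        ext = shap_matrix(phi[4:5], prefix="e")
        proj = project_external(train, emb, ext, clustering, k_neighbors=1)
        np.testing.assert_allclose(proj.coords.to_numpy()[0],
                                   emb.coords.to_numpy()[4], atol=1e-12)

    def test_two_equidistant_neighbors_average(self):
        train = shap_matrix([[0.0], [2.0]])
        emb = embedding_from([[0, 0], [2, 0]])
        clustering = select_clustering(
            embedding_from([[0, 0], [0.1, 0], [5, 5], [5.1, 5]]), k_range=range(2, 3))
        ext = shap_matrix([[1.0]], prefix="e")
        proj = project_external(train, emb, ext, clustering, k_neighbors=2)
        np.testing.assert_allclose(proj.coords.to_numpy()[0], [1.0, 0.0], atol=1e-12)

    def test_tiny_perturbation_keeps_coords(self, rng):
        train, emb, clustering, phi = self._setup(rng)
        ext_a = shap_matrix(phi[4:5], prefix="e")
        ext_b = shap_matrix(phi[4:5] + 1e-10, prefix="e")
        pa = project_external(train, emb, ext_a, clustering, k_neighbors=3)
        pb = project_external(train, emb, ext_b, clustering, k_neighbors=3)
        np.testing.assert_allclose(pa.coords.to_numpy(), pb.coords.to_numpy(), atol=1e-12)

    def test_feature_mismatch_rejected(self, rng):
        train, emb, clustering, phi = self._setup(rng)
        bad = shap_matrix(np.zeros((1, 3)), prefix="e")
        with pytest.raises(ValueError, match="different features"):
            project_external(train, emb, bad, clustering)


class TestRiskProfiles:
    def _clustering(self, labels):
        from crcstrat.stratify import ClusteringResult

        labels = pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])
        return ClusteringResult(method="kmeans", k=labels.nunique(), labels=labels,
                                silhouette=0.5, grid=pd.DataFrame(), seed=0,
                                centroids=pd.DataFrame(np.zeros((labels.nunique(), 2)),
                                                       index=sorted(labels.unique()),
                                                       columns=["tsne1", "tsne2"]))

    def test_equal_probabilities_equal_medians(self):
        clustering = self._clustering([1, 1, 2, 2, 3, 3])
        probs = pd.Series(0.4, index=clustering.labels.index)
        profile = cluster_risk_profiles(clustering, probs)
        assert (profile.table["median"] == 0.4).all()

    def test_sizes_sum_to_subject_count(self):
        clustering = self._clustering([1, 1, 2, 3, 3, 3])
        probs = pd.Series(np.linspace(0.1, 0.9, 6), index=clustering.labels.index)
        profile = cluster_risk_profiles(clustering, probs)
        assert profile.table["n"].sum() == 6

    def test_ordered_by_median_risk(self):
        clustering = self._clustering([1, 1, 2, 2])
        probs = pd.Series([0.2, 0.3, 0.8, 0.9], index=clustering.labels.index)
        profile = cluster_risk_profiles(clustering, probs)
        assert list(profile.table.index) == [2, 1]

    def test_missing_probability_rejected(self):
        clustering = self._clustering([1, 2])
        probs = pd.Series([0.5], index=["s0"])
        with pytest.raises(ValueError, match="without an out-of-fold"):
            cluster_risk_profiles(clustering, probs)

    def test_box_stats_match_order_statistics(self, rng):
        """Median/quartiles/whiskers agree with a direct order-statistics
        computation on 100 random vectors."""
        for _ in range(100):
            v = rng.normal(size=rng.integers(5, 40))
            s = _box_stats(v)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            assert s["median"] == pytest.approx(med)
            assert s["q1"] == pytest.approx(q1)
            assert s["q3"] == pytest.approx(q3)
            iqr = q3 - q1
            inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
            assert s["whisker_low"] == pytest.approx(inside.min())
            assert s["whisker_high"] == pytest.approx(inside.max())
            assert sorted(s["outliers"]) == sorted(v[(v < inside.min()) | (v > inside.max())])

    def test_taxa_distribution_single_cluster_equals_whole_group(self, rng):
        clustering = self._clustering([1, 1, 1, 1])
        vals = pd.DataFrame(rng.normal(size=(4, 2)), columns=["gA", "gB"],
                            index=clustering.labels.index)
        fm = FeatureMatrix(values=vals)
        out = cluster_taxa_distributions(clustering, fm, ["gA"])
        assert out.loc[0, "median"] == pytest.approx(vals["gA"].median())

    def test_unknown_taxon_lists_available(self, rng):
        clustering = self._clustering([1, 1])
        fm = FeatureMatrix(values=pd.DataFrame(np.zeros((2, 2)), columns=["gA", "gB"],
                                               index=clustering.labels.index))
        with pytest.raises(ValueError, match="unknown taxa.*gA"):
            cluster_taxa_distributions(clustering, fm, ["gZ"])
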