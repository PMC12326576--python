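"""SHAP-embedding stratification of adenoma subjects.

The subject x feature Shapley matrix is embedded in 2-D with t-SNE; adenoma
subjects are clustered on the two embedding coordinates with K-means,
agglomerative and BIRCH clustering over a k grid, the winner picked by
silhouette score; external adenoma subjects are projected into the embedding
by k-nearest-neighbour regression in phi-space and assigned to the nearest
cluster centroid; per-cluster CRC-risk and taxon distributions summarise the
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, Birch, KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .containers import FeatureMatrix
from .explain import ShapMatrix

CLUSTER_METHODS = ("kmeans", "agglomerative", "birch")


@dataclass
class Embedding2D:
    coords: pd.DataFrame            # subjects x (tsne1, tsne2)
    params: dict
    source: str = "shap"

    @property
    def subject_ids(self) -> list[str]:
        return list(self.coords.index)


def embed_shap(shap: ShapMatrix, *, perplexity: float = 30.0, max_iter: int = 1000,
               seed: int = 0, source: str = "shap") -> Embedding2D:
    """2-D t-SNE of the phi matrix (all subjects, both classes); seeded."""
    n = shap.phi.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 subjects to embed, got {n}")
    max_perp = n / 3
    if perplexity >= max_perp:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} subjects; must be < {max_perp:.1f}"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, max_iter=max_iter,
                init="pca", random_state=seed, method="exact" if n < 50 else "barnes_hut")
    coords = tsne.fit_transform(shap.phi.to_numpy())
    frame = pd.DataFrame(coords, index=shap.phi.index, columns=["tsne1", "tsne2"])
    return Embedding2D(coords=frame,
                       params={"perplexity": perplexity, "max_iter": max_iter, "seed": seed},
                       source=source)


def embed_features(features: FeatureMatrix, **kwargs) -> Embedding2D:
    """t-SNE of the raw feature matrix (baseline contrast to the phi embedding)."""
    proxy = ShapMatrix(phi=features.values, baseline=pd.Series(0.0, index=features.sample_ids),
                       provenance="features")
    return embed_shap(proxy, source="features", **kwargs)


@dataclass
class ClusteringResult:
    method: str
    k: int
    labels: pd.Series               # adenoma subjects -> 1..k
    silhouette: float
    grid: pd.DataFrame              # method x k silhouette scores (NaN = invalid)
    seed: int
    centroids: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _fit_clusterer(method: str, k: int, coords: np.ndarray, seed: int) -> np.ndarray:
    if method == "kmeans":
        return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(coords)
    if method == "agglomerative":
        return AgglomerativeClustering(n_clusters=k).fit_predict(coords)
    if method == "birch":
        return Birch(n_clusters=k).fit_predict(coords)
    raise ValueError(f"unknown clustering method {method!r}; available: {CLUSTER_METHODS}")


def select_clustering(embedding: Embedding2D, *, methods=CLUSTER_METHODS,
                      k_range=range(2, 11), seed: int = 0) -> ClusteringResult:
    """Evaluate every (method, k) pair on the 2-D coordinates and return the
    silhouette argmax (ties: first method in ``methods``, then smaller k).

    A combination yielding an empty or single cluster is recorded as invalid
    (NaN in the grid) rather than failing the whole selection.
    """
    coords = embedding.coords.to_numpy()
    ks = list(k_range)
    if coords.shape[0] < max(ks) + 1:
        raise ValueError(
            f"need at least {max(ks) + 1} subjects to search k up to {max(ks)}"
        )
    grid = pd.DataFrame(index=list(methods), columns=ks, dtype=float)
    best = None
    for method in methods:
        for k in ks:
            try:
                labels = _fit_clusterer(method, k, coords, seed)
            except Exception:
                continue
            if np.unique(labels).size != k:
                continue  # empty cluster: invalid cell
            score = float(silhouette_score(coords, labels, metric="euclidean"))
            grid.loc[method, k] = score
            if best is None or score > best[0]:
                best = (score, method, k, labels)
    if best is None:
        raise ValueError("no (method, k) combination produced a valid clustering")
    score, method, k, labels = best
    # relabel clusters 1..k in order of first appearance for determinism
    remap = {old: new for new, old in enumerate(pd.unique(labels), start=1)}
    labels = pd.Series([remap[v] for v in labels], index=embedding.subject_ids, name="cluster")
    centroids = embedding.coords.groupby(labels).mean()
    return ClusteringResult(method=method, k=k, labels=labels, silhouette=score,
                            grid=grid, seed=seed, centroids=centroids)


@dataclass
class ExternalProjection:
    coords: pd.DataFrame            # external subjects x (tsne1, tsne2)
    clusters: pd.Series             # external subjects -> assigned cluster
    k_neighbors: int


def project_external(train_shap: ShapMatrix, train_embedding: Embedding2D,
                     ext_shap: ShapMatrix, clustering: ClusteringResult,
                     *, k_neighbors: int = 5) -> ExternalProjection:
    """KNN projection of external subjects into the training embedding.

    Each external subject's coordinates are the unweighted mean of the t-SNE
    coordinates of its ``k_neighbors`` nearest training subjects in phi-space
    (Euclidean); its cluster is the nearest selected-cluster centroid in
    embedding space.
    """
    if train_shap.feature_names != ext_shap.feature_names:
        raise ValueError("training and external SHAP matrices have different features")
    if train_shap.subject_ids != train_embedding.subject_ids:
        raise ValueError("training SHAP matrix and embedding subjects are misaligned")
    if k_neighbors > train_shap.phi.shape[0]:
        raise ValueError("k_neighbors exceeds the number of training subjects")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(train_shap.phi.to_numpy())
    _, idx = nn.kneighbors(ext_shap.phi.to_numpy())
    train_coords = train_embedding.coords.to_numpy()
    coords = train_coords[idx].mean(axis=1)
    cent = clustering.centroids
    d = np.linalg.norm(coords[:, None, :] - cent.to_numpy()[None, :, :], axis=2)
    assigned = cent.index.to_numpy()[d.argmin(axis=1)]
    frame = pd.DataFrame(coords, index=ext_shap.subject_ids, columns=["tsne1", "tsne2"])
    return ExternalProjection(coords=frame,
                              clusters=pd.Series(assigned, index=ext_shap.subject_ids),
                              k_neighbors=k_neighbors)


@dataclass
class ClusterRiskProfile:
    """Per-cluster CRC-probability distribution, ordered by median risk."""

    table: pd.DataFrame             # cluster x {n, median, q1, q3}
    external: pd.DataFrame | None   # external overlay records


def cluster_risk_profiles(clustering: ClusteringResult, oof_probability: pd.Series,
                          external_probability: pd.Series | None = None,
                          external_projection: ExternalProjection | None = None) -> ClusterRiskProfile:
    """Summarise out-of-fold mean CRC probability per cluster.

    Clusters are ordered by descending median probability. External adenoma
    subjects (ensemble probabilities + projected coordinates) are attached as
    overlay records when provided.
    """
    missing = [s for s in clustering.labels.index if s not in oof_probability.index]
    if missing:
        raise ValueError(f"clustered subjects without an out-of-fold probability: {missing}")
    probs = oof_probability.loc[clustering.labels.index]
    rows = []
    for cluster, members in clustering.labels.groupby(clustering.labels):
        p = probs.loc[members.index].to_numpy()
        rows.append({"cluster": cluster, "n": p.size,
                     "median": float(np.median(p)),
                     "q1": float(np.percentile(p, 25)),
                     "q3": float(np.percentile(p, 75))})
    table = pd.DataFrame(rows).set_index("cluster").sort_values("median", ascending=False)
    external = None
    if external_probability is not None:
        external = pd.DataFrame({"probability": external_probability})
        if external_projection is not None:
            external = external.join(external_projection.coords)
            external["cluster"] = external_projection.clusters
    return ClusterRiskProfile(table=table, external=external)


def _box_stats(values: np.ndarray) -> dict:
    """Median, quartiles, Tukey whiskers (1.5 x IQR rule) and outliers."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    in_lo = values[values >= q1 - 1.5 * iqr]
    in_hi = values[values <= q3 + 1.5 * iqr]
    lo = float(in_lo.min()) if in_lo.size else float(q1)
    hi = float(in_hi.max()) if in_hi.size else float(q3)
    outliers = values[(values < lo) | (values > hi)]
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": lo, "whisker_high": hi,
            "outliers": [float(v) for v in outliers]}


def cluster_taxa_distributions(clustering: ClusteringResult, features: FeatureMatrix,
                               taxa: list[str],
                               external_values: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cluster box statistics for selected taxa, with an external overlay.

    ``features`` may be any sample x feature table (CLR values or relative
    abundances); unknown taxa raise an error listing what is available.
    """
    unknown = [t for t in taxa if t not in features.feature_names]
    if unknown:
        available = ", ".join(features.feature_names[:20])
        raise ValueError(f"unknown taxa {unknown}; available features start with: {available}")
    rows = []
    for cluster, members in clustering.labels.groupby(clustering.labels):
        sub = features.values.loc[members.index]
        for taxon in taxa:
            stats = _box_stats(sub[taxon].to_numpy(dtype=float))
            rows.append({"cluster": cluster, "taxon": taxon, "n": len(members), **stats})
    frame = pd.DataFrame(rows)
    if external_values is not None:
        ext_rows = []
        for taxon in taxa:
            if taxon in external_values.columns:
                for sid, val in external_values[taxon].items():
                    ext_rows.append({"cluster": "external", "taxon": taxon, "n": 1,
                                     "median": float(val), "q1": np.nan, "q3": np.nan,
                                     "whisker_low": np.nan, "whisker_high": np.nan,
                                     "outliers": [], "subject": sid})
        frame = pd.concat([frame, pd.DataFrame(ext_rows)], ignore_index=True)
    return frame
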