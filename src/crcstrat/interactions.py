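"""SHAP interaction matrices and thresholded interaction networks.

Per cross-validation fold, the feature x feature SHAP interaction tensor is
computed for the held-out subjects (signed tensors are checked against the
subjects' phi vectors — each row of the tensor sums to the feature's Shapley
value), absolute values are taken per subject, averaged over the fold's
subjects, and symmetrised; fold matrices are averaged into one aggregate
matrix. Features are retained when they carry at least ``min_interactions``
pairwise values strictly above the chosen percentile of the upper-triangle
distribution, and a weighted undirected network is built over the retained
features with degree / weighted-degree / betweenness node metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .modeling import INTERACTION_BACKENDS, BackendError, CVResult


@dataclass
class InteractionMatrix:
    """Symmetric nonnegative matrix of absolute mean SHAP interaction values.

    The diagonal (main effects) is zeroed: the analysis targets pairwise
    interactions and main-effect magnitudes would otherwise dominate every
    percentile threshold.
    """

    values: pd.DataFrame
    n_subjects: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("interaction matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("interaction matrix must be nonnegative")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def upper_triangle(self) -> np.ndarray:
        v = self.values.to_numpy()
        iu = np.triu_indices(v.shape[0], k=1)
        return v[iu]


@dataclass
class ThresholdConfig:
    percentile: float = 95.0
    min_interactions: int = 10

    def validate(self) -> None:
        if not (0.0 < self.percentile < 100.0):
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")
        if self.min_interactions < 1:
            raise ValueError(f"min_interactions must be >= 1, got {self.min_interactions}")


def interaction_tensor(backend, X: np.ndarray, *, consistency_tol: float = 1e-5) -> np.ndarray:
    """Per-subject signed SHAP interaction tensors, consistency-checked.

    Asserts that each subject's tensor rows (diagonal included) sum to the
    subject's phi vector before any absolute value is taken.
    """
    if not getattr(backend, "supports_interactions", False):
        raise BackendError(
            f"backend {backend.name!r} exposes no SHAP interaction tensor; "
            f"supported backends: {INTERACTION_BACKENDS}"
        )
    tensor = backend.shap_interactions(X)
    # the booster's native contribs share the tensor's float32 arithmetic,
    # so they are the right (and fast) reference for the row-sum identity
    phi_fn = getattr(backend, "shap_values_native", backend.shap_values)
    phi, _ = phi_fn(X)
    resid = float(np.abs(tensor.sum(axis=2) - phi).max())
    if resid > consistency_tol:
        raise AssertionError(
            f"interaction tensor rows do not reproduce phi: residual {resid:.3g}"
        )
    return tensor


def fold_interaction_matrix(backend, X_fold: np.ndarray, feature_names: list[str],
                            *, signed_mean: bool = False) -> InteractionMatrix:
    """Fold-level interaction matrix from one model's held-out subjects.

    Default is mean-of-absolute (|Phi_ij| per subject, then averaged), since a
    signed mean lets opposite-sign interactions cancel; ``signed_mean=True``
    takes |mean| instead.
    """
    tensor = interaction_tensor(backend, X_fold)
    if signed_mean:
        mat = np.abs(tensor.mean(axis=0))
    else:
        mat = np.abs(tensor).mean(axis=0)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 0.0)
    return InteractionMatrix(
        values=pd.DataFrame(mat, index=feature_names, columns=feature_names),
        n_subjects=int(tensor.shape[0]),
    )


def aggregate_interactions(fold_matrices: list[InteractionMatrix]) -> InteractionMatrix:
    """Element-wise mean over all fold matrices across all repeats."""
    if not fold_matrices:
        raise ValueError("no fold matrices to aggregate")
    names = fold_matrices[0].feature_names
    for m in fold_matrices[1:]:
        if m.feature_names != names:
            raise ValueError("fold matrices have mismatched feature sets")
    stack = np.stack([m.values.to_numpy() for m in fold_matrices])
    return InteractionMatrix(
        values=pd.DataFrame(stack.mean(axis=0), index=names, columns=names),
        n_subjects=sum(m.n_subjects for m in fold_matrices),
        provenance={"n_folds": len(fold_matrices)},
    )


def cv_interaction_matrix(cv: CVResult, features: FeatureMatrix,
                          *, subjects: list[str] | None = None,
                          signed_mean: bool = False) -> InteractionMatrix:
    """Aggregate interaction matrix over the whole cross-validation.

    ``subjects`` restricts the per-fold averaging to a subject subset (e.g. a
    risk cluster); folds holding out none of the subset are skipped.
    """
    keep = set(features.sample_ids if subjects is None else subjects)
    unknown = keep - set(features.sample_ids)
    if unknown:
        raise ValueError(f"subjects not in the feature matrix: {sorted(unknown)[:10]}")
    X = features.values.to_numpy(dtype=float)
    sample_ids = np.array(features.sample_ids)
    matrices = []
    n_repeats = cv.fold_map.shape[1]
    for r in range(n_repeats):
        assignments = cv.fold_map.iloc[:, r].to_numpy()
        for f in np.unique(assignments):
            idx = np.flatnonzero((assignments == f)
                                 & np.isin(sample_ids, list(keep)))
            if idx.size == 0:
                continue
            matrices.append(fold_interaction_matrix(
                cv.registry[(r, int(f))], X[idx], features.feature_names,
                signed_mean=signed_mean,
            ))
    return aggregate_interactions(matrices)


@dataclass
class FeatureSelection:
    retained: list[str]
    threshold: float
    counts: pd.Series               # significant-interaction count per feature
    significant: pd.DataFrame       # boolean feature x feature mask
    grid: pd.DataFrame              # retained-feature counts over the 90/95/99 grid


def _significant_mask(values: np.ndarray, percentile: float) -> tuple[np.ndarray, float]:
    iu = np.triu_indices(values.shape[0], k=1)
    threshold = float(np.percentile(values[iu], percentile))
    mask = values > threshold
    np.fill_diagonal(mask, False)
    return mask, threshold


def select_interaction_features(matrix: InteractionMatrix, config: ThresholdConfig,
                                *, grid_percentiles=(90.0, 95.0, 99.0),
                                grid_max_count: int | None = None) -> FeatureSelection:
    """Percentile + minimum-count feature retention.

    The threshold is the configured percentile of the upper-triangle
    off-diagonal distribution; an entry is significant when strictly greater.
    A feature is retained when its significant-interaction count reaches
    ``min_interactions``. The retained-count grid over the 90/95/99
    percentiles (as a function of the minimum count) is returned for
    threshold auditing.
    """
    config.validate()
    names = matrix.feature_names
    if len(names) < 2:
        raise ValueError("need at least 2 features to threshold interactions")
    v = matrix.values.to_numpy()
    mask, threshold = _significant_mask(v, config.percentile)
    counts = pd.Series(mask.sum(axis=1), index=names)
    retained = [n for n in names if counts[n] >= config.min_interactions]
    if v.max() == 0:
        import warnings

        warnings.warn("all-zero interaction matrix: nothing retained", stacklevel=2)
    max_count = grid_max_count or max(1, int(counts.max()) + 1)
    grid = pd.DataFrame(index=range(1, max_count + 1), columns=list(grid_percentiles), dtype=int)
    for p in grid_percentiles:
        gmask, _ = _significant_mask(v, p)
        gcounts = gmask.sum(axis=1)
        for mc in grid.index:
            grid.loc[mc, p] = int((gcounts >= mc).sum())
    return FeatureSelection(retained=retained, threshold=threshold, counts=counts,
                            significant=pd.DataFrame(mask, index=names, columns=names),
                            grid=grid)


def build_network(matrix: InteractionMatrix, selection: FeatureSelection) -> nx.Graph:
    """Weighted undirected network over retained features.

    Edges are the significant pairs among retained features; the weight is
    the aggregated interaction value. An empty retention yields a valid empty
    graph.
    """
    unknown = set(selection.retained) - set(matrix.feature_names)
    if unknown:
        raise ValueError(f"retained features not in matrix: {sorted(unknown)}")
    g = nx.Graph()
    g.add_nodes_from(selection.retained)
    for i, a in enumerate(selection.retained):
        for b in selection.retained[i + 1:]:
            if selection.significant.loc[a, b]:
                g.add_edge(a, b, weight=float(matrix.values.loc[a, b]))
    return g


def network_metrics(network: nx.Graph) -> pd.DataFrame:
    """Per-node interaction count, weighted degree and betweenness.

    Betweenness uses edge distance 1/weight (stronger interactions are
    closer) and standard normalisation by (n-1)(n-2)/2.
    """
    for _u, _v, d in network.edges(data=True):
        d["distance"] = 1.0 / d["weight"] if d["weight"] > 0 else float("inf")
    betweenness = nx.betweenness_centrality(network, weight="distance", normalized=True)
    rows = [{
        "feature": node,
        "interaction_count": network.degree(node),
        "weighted_degree": float(network.degree(node, weight="weight")),
        "betweenness": float(betweenness[node]),
    } for node in network.nodes]
    return pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["interaction_count", "weighted_degree", "betweenness"])


def subgroup_interaction_analysis(cv: CVResult, features: FeatureMatrix,
                                  cluster_subjects: list[str], config: ThresholdConfig,
                                  *, signed_mean: bool = False
                                  ) -> tuple[nx.Graph, InteractionMatrix, FeatureSelection]:
    """The full interaction pipeline restricted to one subject subgroup.

    Per-fold averaging uses only the subgroup members present in each held-out
    fold; folds contributing none are skipped. Subgroups under 5 subjects are
    computed anyway, with a warning.
    """
    if len(cluster_subjects) < 5:
        import warnings

        warnings.warn(
            f"subgroup has only {len(cluster_subjects)} subjects; "
            "interaction estimates will be noisy", stacklevel=2,
        )
    matrix = cv_interaction_matrix(cv, features, subjects=cluster_subjects,
                                   signed_mean=signed_mean)
    selection = select_interaction_features(matrix, config)
    return build_network(matrix, selection), matrix, selection


def export_network(network: nx.Graph, path: str | Path, *, fmt: str = "gexf") -> None:
    """Write the network (GEXF for Gephi, or GraphML) with node metrics attached."""
    metrics = network_metrics(network)
    g = network.copy()
    for node in g.nodes:
        g.nodes[node]["interaction_count"] = int(metrics.loc[node, "interaction_count"])
        g.nodes[node]["weighted_degree"] = float(metrics.loc[node, "weighted_degree"])
        g.nodes[node]["betweenness"] = float(metrics.loc[node, "betweenness"])
    for _u, _v, d in g.edges(data=True):
        d.pop("distance", None)
    if fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"format must be 'gexf' or 'graphml', got {fmt!r}")
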