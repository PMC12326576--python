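"""SHAP-embedding stratification of adenoma subjects.

Embeds the subject x feature Shapley matrix with t-SNE, clusters the adenoma
subjects on the two components (K-means / agglomerative / BIRCH over
k = 2..10, silhouette-selected), projects external adenoma subjects into the
embedding with a KNN fitted on training phi vectors, and summarises per-
cluster CRC risk and the distributions of the top discriminative taxa.
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from crcstrat.explain import ShapMatrix, global_importance
from crcstrat.preprocess import read_features, read_metadata
from crcstrat.stratify import (
    Embedding2D,
    cluster_risk_profiles,
    cluster_taxa_distributions,
    embed_shap,
    project_external,
    select_clustering,
)


def read_shap(path: Path) -> ShapMatrix:
    phi = pd.read_csv(path, sep="\t", index_col="subject_id")
    return ShapMatrix(phi=phi, baseline=pd.Series(0.0, index=phi.index),
                      provenance="loaded")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--data", default="results/data")
    parser.add_argument("--prep", default="results/preprocess")
    parser.add_argument("--model", default="results/model")
    parser.add_argument("--explain", default="results/explain")
    parser.add_argument("--out", default="results/stratify")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    shap = read_shap(Path(args.explain) / "shap_train.tsv")
    metadata = read_metadata(Path(args.data) / "train_metadata.tsv")
    embedding = embed_shap(shap, perplexity=30, seed=args.seed)
    embedding.coords.to_csv(out / "tsne_embedding.tsv", sep="\t",
                            index_label="subject_id")

    adenoma = [s for s in shap.subject_ids if metadata.loc[s, "diagnosis"] == "adenoma"]
    clustering = select_clustering(
        Embedding2D(coords=embedding.coords.loc[adenoma], params=embedding.params),
        k_range=range(2, 11), seed=args.seed)
    print(f"best clustering: {clustering.method} with k={clustering.k}, "
          f"silhouette {clustering.silhouette:.3f}")
    print("silhouette grid (method x k):")
    print(clustering.grid.round(3).to_string())
    clustering.labels.to_frame().to_csv(out / "cluster_labels.tsv", sep="\t",
                                        index_label="subject_id")

    oof = pd.read_csv(Path(args.model) / "oof_probabilities.tsv", sep="\t",
                      index_col="sample_id").mean(axis=1)
    ext_shap = read_shap(Path(args.explain) / "shap_external.tsv")
    ext_meta = read_metadata(Path(args.data) / "external_metadata.tsv")
    ext_adenoma = [s for s in ext_shap.subject_ids
                   if ext_meta.loc[s, "diagnosis"] == "adenoma"]
    projection = None
    ext_prob = None
    if ext_adenoma:
        sub = ShapMatrix(phi=ext_shap.phi.loc[ext_adenoma],
                         baseline=ext_shap.baseline.loc[ext_adenoma],
                         provenance=ext_shap.provenance)
        projection = project_external(shap, embedding, sub, clustering, k_neighbors=5)
        ext_pred = pd.read_csv(Path(args.model) / "external_predictions.tsv",
                               sep="\t", index_col="sample_id")
        ext_prob = ext_pred.loc[ext_adenoma, "mean_probability"]

    profile = cluster_risk_profiles(clustering, oof, ext_prob, projection)
    profile.table.to_csv(out / "cluster_risk_profiles.tsv", sep="\t")
    print("\nper-cluster CRC probability (ordered by median risk):")
    print(profile.table.round(3).to_string())
    if projection is not None:
        print("\nexternal adenoma subjects projected into clusters:")
        print(projection.clusters.value_counts().to_string())

    features = read_features(Path(args.prep) / "features.tsv")
    imp = global_importance(shap, top_k=20)
    top_taxa = [f for f in imp.ranking
                if features.feature_kind[f] == "taxon_clr"][:3]
    dist = cluster_taxa_distributions(clustering, features, top_taxa)
    dist["outliers"] = dist["outliers"].map(lambda v: ";".join(f"{x:.5g}" for x in v))
    dist.to_csv(out / "cluster_taxa_distributions.tsv", sep="\t", index=False)
    print(f"\ntop taxa {top_taxa}: per-cluster medians")
    print(dist.pivot_table(index="cluster", columns="taxon", values="median").round(2).to_string())


if __name__ == "__main__":
    main()
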