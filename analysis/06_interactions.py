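"""SHAP interaction networks, globally and per risk cluster.

Aggregates fold-wise absolute mean SHAP interaction matrices over the whole
cross-validation, retains features with >= 10 interactions above the 95th
percentile, builds the weighted interaction network with degree/betweenness
hub metrics, exports GEXF/GraphML for Gephi, and repeats the analysis for
the two highest-risk adenoma clusters.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from crcstrat.interactions import (
    ThresholdConfig,
    build_network,
    cv_interaction_matrix,
    export_network,
    network_metrics,
    select_interaction_features,
    subgroup_interaction_analysis,
)
from crcstrat.preprocess import read_features

from importlib import import_module
import sys

sys.path.insert(0, str(Path(__file__).parent))
load_cv = import_module("04_explain").load_cv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", default="results/data")
    parser.add_argument("--prep", default="results/preprocess")
    parser.add_argument("--model", default="results/model")
    parser.add_argument("--stratify", default="results/stratify")
    parser.add_argument("--out", default="results/interactions")
    parser.add_argument("--percentile", type=float, default=95.0)
    parser.add_argument("--min-count", type=int, default=10)
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    features = read_features(Path(args.prep) / "features.tsv")
    cv = load_cv(Path(args.model) / "registry.pkl")
    config = ThresholdConfig(percentile=args.percentile, min_interactions=args.min_count)

    matrix = cv_interaction_matrix(cv, features)
    matrix.values.to_csv(out / "interaction_matrix.tsv", sep="\t")
    selection = select_interaction_features(matrix, config)
    selection.grid.to_csv(out / "retention_grid.tsv", sep="\t",
                          index_label="min_interactions")
    pd.DataFrame({"interaction_value": matrix.upper_triangle()}).to_csv(
        out / "interaction_values.tsv", sep="\t", index=False)
    network = build_network(matrix, selection)
    metrics = network_metrics(network).sort_values("weighted_degree", ascending=False)
    metrics.to_csv(out / "network_metrics.tsv", sep="\t")
    export_network(network, out / "network_global.gexf", fmt="gexf")
    export_network(network, out / "network_global.graphml", fmt="graphml")
    print(f"global network: {len(selection.retained)} features retained "
          f"({args.percentile:.0f}th percentile, >= {args.min_count} interactions), "
          f"{network.number_of_edges()} edges")
    print("top hubs by weighted degree:")
    print(metrics.head(8).round(4).to_string())

    truth = json.loads((Path(args.data) / "train_truth.json").read_text())
    if truth["interaction_pair"]:
        a, b, coef = truth["interaction_pair"]
        v = matrix.values
        import numpy as np

        iu = np.triu_indices(v.shape[0], k=1)
        vals = v.to_numpy()[iu]
        order = np.argsort(vals)[::-1]
        names = matrix.feature_names
        pairs = [frozenset((names[iu[0][k]], names[iu[1][k]])) for k in order]
        rank = pairs.index(frozenset((a, b))) + 1
        print(f"planted interaction {a} x {b} (coef {coef}) ranks #{rank} by weight")

    labels = pd.read_csv(Path(args.stratify) / "cluster_labels.tsv", sep="\t",
                         index_col="subject_id")["cluster"]
    risk = pd.read_csv(Path(args.stratify) / "cluster_risk_profiles.tsv", sep="\t",
                       index_col="cluster")
    for cluster in risk.index[:2]:
        members = labels.index[labels == cluster].tolist()
        net, _m, sel = subgroup_interaction_analysis(cv, features, members, config)
        export_network(net, out / f"network_cluster{cluster}.gexf", fmt="gexf")
        hubs = network_metrics(net).sort_values("weighted_degree", ascending=False).head(3)
        print(f"\ncluster {cluster} ({len(members)} subjects): "
              f"{len(sel.retained)} features retained, {net.number_of_edges()} edges; "
              f"top hubs: {list(hubs.index)}")


if __name__ == "__main__":
    main()
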