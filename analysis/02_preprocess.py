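"""Filter, normalise and assemble features; compare cohort demographics.

Reads the cohorts written by 01_simulate.py, applies the 10% prevalence
filter and the centered log-ratio transform, appends the four clinical
covariates, and reports the Fisher / Mann-Whitney cohort-comparison table
(the published Table-1-style summary).
"""

import argparse
from pathlib import Path

from crcstrat.cohort_stats import cohort_comparison
from crcstrat.preprocess import (
    assemble_features,
    clr_transform,
    prevalence_filter,
    read_abundance_table,
    read_metadata,
    write_features,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", default="results/data")
    parser.add_argument("--out", default="results/preprocess")
    parser.add_argument("--min-prev", type=float, default=0.10)
    parser.add_argument("--pseudocount", type=float, default=1.0)
    args = parser.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    table = read_abundance_table(data / "train_abundance.tsv")
    metadata = read_metadata(data / "train_metadata.tsv")
    ext_table = read_abundance_table(data / "external_abundance.tsv")
    ext_metadata = read_metadata(data / "external_metadata.tsv")

    filtered = prevalence_filter(table, args.min_prev)
    print(f"prevalence filter ({args.min_prev:.0%}): "
          f"{table.n_taxa} -> {filtered.n_taxa} genera")
    countries = sorted(set(metadata["country"]) | set(ext_metadata["country"]))
    features = assemble_features(clr_transform(filtered, args.pseudocount), metadata,
                                 country_categories=countries)
    ext_counts = ext_table.counts.reindex(columns=filtered.taxon_names, fill_value=0)
    ext_features = assemble_features(
        clr_transform(type(filtered)(ext_counts), args.pseudocount), ext_metadata,
        country_categories=countries)
    write_features(features, out / "features.tsv")
    write_features(ext_features, out / "features_external.tsv")
    print(f"feature matrix: {features.values.shape[0]} x {features.n_features} "
          f"({len(features.taxon_features())} CLR taxa + "
          f"{features.n_features - len(features.taxon_features())} covariates)")

    comparison = cohort_comparison(metadata)
    comparison.to_csv(out / "cohort_comparison.tsv", sep="\t")
    print("\ntraining cohort comparison (CRC vs adenoma):")
    print(comparison.to_string())


if __name__ == "__main__":
    main()
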