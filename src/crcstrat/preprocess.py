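"""Reading abundance/metadata tables, taxon filtering, CLR normalisation,
covariate encoding.

The normalisation follows Aitchison's compositional treatment: counts (plus a
pseudocount) are mapped per sample to centered log-ratios,
``clr_j = ln x_j - mean_k ln x_k``, so each sample row sums to zero and only
relative information is retained. An additive log-ratio (ALR) variant against
a reference taxon is available behind a flag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    METADATA_COLUMNS,
    AbundanceTable,
    FeatureMatrix,
    FormatError,
    validate_metadata,
)


def read_abundance_table(path: str | Path, *, fmt: str | None = None,
                         samples_as_rows: bool = True) -> AbundanceTable:
    """Read a TSV/CSV count table (first column sample id, header taxon names).

    ``fmt`` is inferred from the suffix when omitted. ``samples_as_rows=False``
    transposes a taxon x sample table after reading.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in {"tsv", "csv"}:
        raise FormatError(f"unsupported abundance format {fmt!r}; use tsv or csv")
    sep = "\t" if fmt == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.size == 0:
        raise FormatError(f"{path}: empty abundance table")
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ].tolist()
    if non_numeric:
        raise FormatError(f"{path}: non-numeric cells in columns {non_numeric}")
    if not samples_as_rows:
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return AbundanceTable(frame)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata TSV (columns sample_id + required covariates)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    if "sample_id" not in frame.columns:
        raise FormatError(f"{path}: metadata must contain a sample_id column")
    frame = frame.set_index("sample_id")
    frame.index = frame.index.astype(str)
    return validate_metadata(frame)


def prevalence_filter(table: AbundanceTable, min_prev: float = 0.10) -> AbundanceTable:
    """Keep taxa detected (count > 0) in at least ``min_prev`` of samples.

    The boundary is inclusive; taxon order and the sample set are preserved.
    """
    if not (0.0 < min_prev <= 1.0):
        raise ValueError(f"min_prev must be in (0, 1], got {min_prev}")
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence >= min_prev
    if not keep.any():
        raise ValueError(
            f"prevalence filter at {min_prev:.0%} removed all {table.n_taxa} taxa"
        )
    return AbundanceTable(table.counts.loc[:, keep.to_numpy()])


def clr_transform(table: AbundanceTable, pseudocount: float = 1.0) -> FeatureMatrix:
    """Centered log-ratio transform of ``counts + pseudocount`` per sample.

    ``pseudocount = 0`` is allowed only when every count is positive.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if table.n_samples == 0:
        raise ValueError("cannot CLR-transform a zero-sample table")
    x = table.counts.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError("pseudocount = 0 requires strictly positive counts")
    logs = np.log(x)
    clr = logs - logs.mean(axis=1, keepdims=True)
    values = pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns)
    kind = pd.Series("taxon_clr", index=values.columns)
    return FeatureMatrix(values=values, feature_kind=kind)


def alr_transform(table: AbundanceTable, reference: str, pseudocount: float = 1.0) -> FeatureMatrix:
    """Additive log-ratio against a reference taxon (dropped from the output)."""
    if reference not in table.counts.columns:
        raise ValueError(f"reference taxon {reference!r} not in table")
    x = table.counts.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError("pseudocount = 0 requires strictly positive counts")
    ref = np.log(x[:, table.counts.columns.get_loc(reference)])
    vals = np.log(x) - ref[:, None]
    frame = pd.DataFrame(vals, index=table.counts.index, columns=table.counts.columns)
    frame = frame.drop(columns=[reference])
    return FeatureMatrix(values=frame, feature_kind=pd.Series("taxon_clr", index=frame.columns))


def assemble_features(clr: FeatureMatrix, metadata: pd.DataFrame, *,
                      country_encoding: str = "codes",
                      country_categories: list[str] | None = None) -> FeatureMatrix:
    """Append encoded clinical covariates (age, BMI, gender, country) to the
    CLR taxa. Diagnosis is never a feature.

    Gender is coded F=0 / M=1; country as stable integer codes over the sorted
    category list by default, or one-hot with ``country_encoding="onehot"``.
    ``country_categories`` pins the category universe so an external cohort is
    encoded consistently with training.
    """
    validate_metadata(metadata)
    missing_ids = [s for s in clr.sample_ids if s not in metadata.index]
    if missing_ids:
        raise FormatError(f"samples missing from metadata: {missing_ids}")
    meta = metadata.loc[clr.sample_ids]
    for col in ("age", "bmi", "gender", "country"):
        bad = meta.index[meta[col].isna()].tolist()
        if bad:
            raise FormatError(f"samples missing covariate {col!r}: {bad}")

    gender_map = {"F": 0, "M": 1}
    unknown = set(meta["gender"]) - set(gender_map)
    if unknown:
        raise FormatError(f"unknown gender codes: {sorted(unknown)}")
    cov = pd.DataFrame(index=meta.index)
    cov["age"] = meta["age"].astype(float)
    cov["bmi"] = meta["bmi"].astype(float)
    cov["gender"] = meta["gender"].map(gender_map).astype(float)

    categories = country_categories or sorted(meta["country"].unique())
    unknown = set(meta["country"]) - set(categories)
    if unknown:
        raise FormatError(f"countries outside the declared categories: {sorted(unknown)}")
    encodings = {"gender": gender_map}
    if country_encoding == "codes":
        code_map = {c: i for i, c in enumerate(categories)}
        cov["country"] = meta["country"].map(code_map).astype(float)
        encodings["country"] = code_map
    elif country_encoding == "onehot":
        for c in categories:
            cov[f"country_{c}"] = (meta["country"] == c).astype(float)
        encodings["country"] = {"onehot": categories}
    else:
        raise ValueError(f"country_encoding must be 'codes' or 'onehot', got {country_encoding!r}")

    values = pd.concat([clr.values, cov], axis=1)
    kind = pd.concat([
        clr.feature_kind,
        pd.Series("covariate", index=cov.columns),
    ])
    return FeatureMatrix(values=values, feature_kind=kind, encodings=encodings)


def write_features(features: FeatureMatrix, path: str | Path) -> None:
    features.values.to_csv(path, sep="\t", index_label="sample_id")


def read_features(path: str | Path, *, covariates: tuple = ("age", "bmi", "gender", "country")) -> FeatureMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    kind = pd.Series(
        ["covariate" if c in covariates or c.startswith("country_") else "taxon_clr"
         for c in frame.columns],
        index=frame.columns,
    )
    return FeatureMatrix(values=frame, feature_kind=kind)
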