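"""Core in-memory containers shared across pipeline stages.

Everything is a light wrapper around :class:`pandas.DataFrame` so that the
standard I/O, joining and selection machinery stays available; the wrappers
only add the invariants each stage relies on (unique identifiers, nonnegative
counts, aligned sample order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every cohort must provide
METADATA_COLUMNS = ("age", "bmi", "gender", "country", "diagnosis")

#: diagnosis coding: CRC is the positive class throughout
POSITIVE_LABEL = "CRC"
NEGATIVE_LABEL = "adenoma"


class FormatError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AbundanceTable:
    """Sample x genus count matrix.

    ``counts`` has sample identifiers as the index and taxon (genus) names as
    columns; entries are nonnegative integers (read counts).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon names: {dup}")
        if self.counts.size == 0:
            raise FormatError("empty abundance table")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("abundance table contains non-numeric cells")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"missing value at sample {idx[r]!r}, taxon {cols[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at sample {idx[r]!r}, taxon {cols[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample metadata frame (index = sample id).

    Required columns: age, bmi, gender, country, diagnosis. Diagnosis must be
    binary adenoma/CRC; age and bmi positive where present (missing values are
    caught later, when features are assembled, so the offending samples can be
    named).
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if metadata.index.has_duplicates:
        dup = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dup}")
    bad_dx = set(metadata["diagnosis"].dropna().unique()) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad_dx:
        raise FormatError(
            f"diagnosis must be one of {{{NEGATIVE_LABEL}, {POSITIVE_LABEL}}}; got {sorted(bad_dx)}"
        )
    for col in ("age", "bmi"):
        vals = pd.to_numeric(metadata[col], errors="coerce")
        nonpos = metadata.index[vals.notna() & (vals <= 0)].tolist()
        if nonpos:
            raise FormatError(f"non-positive {col} for samples: {nonpos}")
    return metadata


def diagnosis_labels(metadata: pd.DataFrame) -> pd.Series:
    """0/1 labels with CRC coded 1 (positive class)."""
    return (metadata["diagnosis"] == POSITIVE_LABEL).astype(int)


@dataclass
class FeatureMatrix:
    """Sample x feature real-valued matrix with per-feature provenance.

    ``feature_kind`` maps each feature name to ``"taxon_clr"`` or
    ``"covariate"``; ``encodings`` records how categorical covariates were
    coded so predictions remain interpretable.
    """

    values: pd.DataFrame
    feature_kind: pd.Series = field(default=None)  # type: ignore[assignment]
    encodings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_kind is None:
            self.feature_kind = pd.Series("taxon_clr", index=self.values.columns)
        if list(self.feature_kind.index) != list(self.values.columns):
            raise FormatError("feature_kind index must match feature columns")
        if self.values.isna().to_numpy().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise FormatError(f"missing feature values for samples: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def taxon_features(self) -> list[str]:
        return [f for f in self.feature_names if self.feature_kind[f] == "taxon_clr"]
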