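"""Shared fixtures: small seeded cohorts and a fitted cross-validation run.

Everything is generated programmatically; session-scoped fixtures amortise
model fitting across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crcstrat.modeling import CVConfig, run_repeated_cv
from crcstrat.preprocess import assemble_features, clr_transform, prevalence_filter
from crcstrat.synthetic import CohortSpec, generate_cohort


def make_spec(**overrides) -> CohortSpec:
    """A compact planted-signal cohort spec used across the suite."""
    defaults = dict(
        n_cases=90,
        n_controls=110,
        n_taxa=40,
        effect_taxa=[(5, 2.5), (9, -2.5), (14, 2.5)],
        interaction_pair=None,
        zero_inflation_prob=0.05,
        seed=11,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def cohort_features(spec: CohortSpec, min_prev: float = 0.10):
    """(features, labels, study) for a generated cohort."""
    study = generate_cohort(spec)
    filtered = prevalence_filter(study.abundance, min_prev)
    features = assemble_features(clr_transform(filtered), study.metadata)
    return features, study.labels, study


@pytest.fixture(scope="session")
def small_study():
    return generate_cohort(make_spec())


@pytest.fixture(scope="session")
def small_features(small_study):
    filtered = prevalence_filter(small_study.abundance, 0.10)
    return assemble_features(clr_transform(filtered), small_study.metadata)


@pytest.fixture(scope="session")
def small_cv(small_features, small_study):
    """5-fold x 2-repeat xgboost CV on the planted cohort (10 models)."""
    config = CVConfig(n_folds=5, n_repeats=2, seed=3, backend="xgboost",
                      params={"n_estimators": 60, "max_depth": 4})
    return run_repeated_cv(small_features, small_study.labels, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_metadata():
    """Hand-built metadata frame with two diagnosis groups."""
    n = 40
    r = np.random.default_rng(5)
    return pd.DataFrame({
        "age": r.normal(62, 10, n).clip(30),
        "bmi": r.normal(27, 5, n).clip(15),
        "gender": r.choice(["F", "M"], n),
        "country": r.choice(["CA", "FRA", "USA"], n),
        "diagnosis": ["CRC"] * 18 + ["adenoma"] * 22,
    }, index=[f"S{i:03d}" for i in range(n)])
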