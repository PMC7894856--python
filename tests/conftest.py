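"""Shared fixtures: a small cohort with planted structure and its
engineered feature matrix, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from riskclust import features, synthgen

MISSING_RATES = {
    "labs": 0.15,
    "vitals": 0.08,
    "pharmacy": 0.05,
    "sociodemographic": 0.02,
}


@pytest.fixture(scope="session")
def small_structure():
    return synthgen.demo_structure(n_total=800, n_subgroups=6, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_structure):
    table = synthgen.generate_cohort(small_structure, 800, seed=123)
    return synthgen.inject_missingness(
        table, MISSING_RATES, "MAR_on_utilization", seed=124
    )


@pytest.fixture(scope="session")
def small_inputs(small_cohort):
    measures = synthgen.generate_repeated_measures(small_cohort, seed=125)
    targets = {
        k: g.adherence
        for k, g in enumerate(small_cohort.structure.subgroups)
        if g.adherence is not None
    }
    fills = synthgen.generate_fill_histories(
        small_cohort, adherence_targets=targets or None, seed=126
    )
    return small_cohort, measures, fills


@pytest.fixture(scope="session")
def small_features(small_inputs):
    cohort, measures, fills = small_inputs
    return features.build_features(
        cohort.data, cohort.dictionary, measures, fills, seed=127
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
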