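"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from ppgglu import GlucoseLink, build_feature_table, scenario_preset, simulate_cohort
from ppgglu.pipeline import feature_matrix
from ppgglu.synthetic import ScenarioSpec


@pytest.fixture(scope="session")
def small_cohort():
    """40-record single-subject cohort with the default (moderate) noise."""
    spec = ScenarioSpec("nir_single", 40, (4.4, 6.4))
    return simulate_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def small_xy(small_table):
    X, y, _ = feature_matrix(small_table)
    return X, y


@pytest.fixture(scope="session")
def noiseless_cohort():
    """30-record zero-noise cohort: features are deterministic in glucose."""
    spec = ScenarioSpec("nir_single", 30, (4.4, 6.4))
    return simulate_cohort(spec, link=GlucoseLink.noiseless(), seed=13)


@pytest.fixture(scope="session")
def noiseless_table(noiseless_cohort):
    # without noise there is nothing to condition away, and skipping the
    # band-pass keeps the extracted amplitudes free of filter bias
    return build_feature_table(noiseless_cohort, condition=False)
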