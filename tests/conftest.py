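"""Shared fixtures: the standard synthetic cohort and derived artifacts.

Session-scoped because generation plus passenger annotation plus FDR
calibration is the expensive part of the suite; every test treats these as
read-only.
"""

import pytest

from misl import FixtureSpec, MislConfig, generate_cohorts
from misl.core import calibrate_config, collect_passenger_annotations


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard study conditions: 3 cancers x 200 samples, 500 genes,
    10 HI-LO + 10 HI-HI plants, 50 passengers, effect 1.0, noise 0.4,
    seed 7 (the FixtureSpec defaults)."""
    return generate_cohorts(FixtureSpec())


@pytest.fixture(scope="session")
def standard_cohorts(standard_fixture):
    return standard_fixture[0]


@pytest.fixture(scope="session")
def standard_truth(standard_fixture):
    return standard_fixture[1]


@pytest.fixture(scope="session")
def standard_passengers(standard_cohorts):
    return collect_passenger_annotations(standard_cohorts, MislConfig())


@pytest.fixture(scope="session")
def calibrated_cfg(standard_cohorts):
    cfg, _ = calibrate_config(
        standard_cohorts, MislConfig(seed=11), n_permutations=10
    )
    return cfg


@pytest.fixture(scope="session")
def small_fixture():
    """A light-weight cohort for plumbing tests."""
    spec = FixtureSpec(
        n_cancers=2,
        samples_per_cancer=60,
        n_genes=80,
        n_planted_hi_lo=3,
        n_planted_hi_hi=3,
        n_passengers=6,
        seed=3,
    )
    return generate_cohorts(spec)
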