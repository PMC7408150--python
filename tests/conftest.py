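"""Shared fixtures: cohorts and the (expensive) domain-mapped cohort."""

import numpy as np
import pytest

from gliomap import evaluation as ev
from gliomap import phantom as ph


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small 8-patient cohort for cheap unit tests."""
    cfg = ph.PhantomConfig(
        image_size=32, slices_per_patient=4,
        n_patients={(d, c): 2 for d in ph.DOMAINS for c in (0, 1)}, seed=1)
    return cfg, ph.generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_config():
    """The scaled study conditions used by the stochastic properties."""
    return ev.ExperimentConfig(seed=5)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return ph.generate_cohort(study_config.phantom)


@pytest.fixture(scope="session")
def mapped_cohort(study_config, study_cohort):
    """CycleGAN-mapped combined cohort Ã ∪ B (trains two toy CycleGANs)."""
    return ev.map_cohort(study_config, study_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
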