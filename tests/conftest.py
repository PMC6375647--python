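"""Shared fixtures: synthetic complexes and the (expensive) benchmark study.

The study dataset, its cross-validation reports and the trained study model
are session-scoped so the classifier, CAM and acceptance tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from voxpocket import benchmark, synthetic
from voxpocket.synthetic import SyntheticSpec

STUDY_SEED = 7


@pytest.fixture(scope="session")
def toy_pot():
    return synthetic.toy_potential()


@pytest.fixture(scope="session")
def sample_record():
    return synthetic.make_complex(SyntheticSpec(seed=11), "amide", 0)


@pytest.fixture(scope="session")
def sample_result(sample_record, toy_pot):
    return synthetic.process_complex(sample_record, toy_pot)


@pytest.fixture(scope="session")
def study_data():
    return benchmark.build_study_data(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def energy_cv(study_data):
    return benchmark.run_crossvalidation(study_data, "energy", seed=STUDY_SEED)


@pytest.fixture(scope="session")
def occupancy_cv(study_data):
    return benchmark.run_crossvalidation(study_data, "occupancy", seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_model(study_data):
    return benchmark.train_study_model(study_data, seed=STUDY_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
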