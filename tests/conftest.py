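import numpy as np
import pytest

from dualpet.datatypes import build_features
from dualpet.evaluation import stratified_split
from dualpet.model import ModelConfig, train_model
from dualpet.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_cn=24, n_ad=36, n_abpos_cn=5, n_abneg_ad=6,
        perfusion_effect=0.4, amyloid_effect=0.5, noise_sd=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_splits(small_cohort):
    sp = stratified_split(small_cohort, seed=7)
    by = {
        p: [r for r in small_cohort if sp.assignment[r.subject_id] == p]
        for p in ("train", "validation", "test")
    }
    return tuple(build_features(by[p]) for p in ("train", "validation", "test"))


@pytest.fixture(scope="session")
def quick_config():
    return ModelConfig(seed=7, lr=1e-3, max_epochs=60,
                       early_stop_patience=50, lr_decay_patience=25)


@pytest.fixture(scope="session")
def trained_dual(small_splits, quick_config):
    tr, va, _ = small_splits
    return train_model(tr, va, quick_config, phase="dual")


@pytest.fixture(scope="session")
def trained_early(small_splits, quick_config):
    tr, va, _ = small_splits
    return train_model(tr, va, quick_config, phase="early")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
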