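import numpy as np
import pytest

from specsim import (
    SynthConfig,
    compute_subject_similarity,
    estimate_background,
    generate_subject_tfr,
    log_power,
    remove_background,
)

# small end-to-end scale used by most integration-style tests: the full
# 2x2 design at a coarse time axis and few channels
TINY = dict(
    n_categories=8,
    n_subjects=4,
    n_channels=4,
    time_span=(-0.6, 2.0, 0.2),
    signal_window=(0.2, 1.0),
)


def preprocess(ds, mode="mean_spectrum"):
    ds_log = log_power(ds)
    return remove_background(ds_log, estimate_background(ds_log, mode))


def subject_similarity(cfg, subject_index, level, group_key=0):
    ds, gt = generate_subject_tfr(cfg, subject_index, group_key=group_key)
    return compute_subject_similarity(preprocess(ds), level), gt


@pytest.fixture(scope="session")
def tiny_cfg():
    return SynthConfig.reduced(**TINY, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return generate_subject_tfr(tiny_cfg, 0)


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_dataset):
    ds, gt = tiny_dataset
    return preprocess(ds), gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
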