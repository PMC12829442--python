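import dataclasses

import pytest

from edal.datasets import ShiftConfig
from edal.evidential import desk_scale_model_params


@pytest.fixture(scope="session")
def tiny_shift_cfg():
    """Small dataset bundle for fast structural tests."""
    return ShiftConfig(n_in=240, n_pool=360, n_test=90, d=6, seed=5)


@pytest.fixture(scope="session")
def tiny_model_params():
    """Model parameters sized for smoke tests, not for accuracy."""
    pars = desk_scale_model_params()
    pars.update(hidden_dims=(8, 8), max_epochs=30, patience=10)
    return pars


@pytest.fixture(scope="session")
def default_cfg():
    return ShiftConfig()


def small_cfg(**overrides):
    return dataclasses.replace(ShiftConfig(), **overrides)
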