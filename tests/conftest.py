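import numpy as np
import pytest

from nmrbind.binding import ExchangeParams, TitrationCondition, binding_state


@pytest.fixture
def jdgf_condition():
    """200 uM visible species + ligand at molar ratio 0.1."""
    return TitrationCondition.from_uM(200.0, 20.0)


@pytest.fixture
def jdgf_params():
    """K_d = 380 uM, k_off = 580 s^-1 (the DNAJB6 JD-GF-like optimum)."""
    return ExchangeParams.from_kd(380e-6, 580.0)


@pytest.fixture
def jdgf_state(jdgf_condition, jdgf_params):
    return binding_state(jdgf_condition, jdgf_params)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
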