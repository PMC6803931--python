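import numpy as np
import pytest

from ratekit import RateLaw, RateLawParams
from ratekit.datasets import SynthSpec, synth_rate_series


@pytest.fixture
def am_sub_params():
    """Moderate-tunneling sub-Arrhenius AM parameters (OH + H2 benchmark)."""
    return RateLawParams(RateLaw.AM, A=1.11e-10, eps_dd=9170.0, d=-0.086)


@pytest.fixture
def am_anti_params():
    """Anti-Arrhenius AM parameters (OH + HBr benchmark): negative Ea."""
    return RateLawParams(RateLaw.AM, A=7.43e-14, eps_dd=-324.61, d=1.24)


@pytest.fixture
def arrhenius_series():
    """Noise-free Arrhenius data, A=1, Ea=1000 cal/mol, 20 points 200-400 K."""
    p = RateLawParams(RateLaw.ARRHENIUS, A=1.0, Ea=1000.0)
    return synth_rate_series(SynthSpec(p, 200.0, 400.0, n=20))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
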