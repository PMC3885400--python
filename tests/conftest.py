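import numpy as np
import pytest

from neuroreflect.inversion import HemoglobinInverter
from neuroreflect.synthetic import SdEventProfile, gen_trace_bundle
from neuroreflect.tissue_optics import load_default_chromophores


@pytest.fixture(scope="session")
def table():
    return load_default_chromophores()


@pytest.fixture(scope="session")
def diffusion_inverter():
    """Conversion model built with the fast analytic forward (shared)."""
    return HemoglobinInverter(forward="diffusion").fit()


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic SD episode trace set (normalized optical scale)."""
    return gen_trace_bundle(SdEventProfile(seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
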