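import pytest
from hypothesis import HealthCheck, settings, strategies as st

import pyropig as pp
from pyropig.spectra import StickSpectrum

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library():
    return pp.default_library()


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free, bleed-free, jitter-free simulation settings."""
    return pp.SimConfig(seed=3, noise_sd=0.0, bleed_intensity=0.0,
                        coelution_jitter=0.0)


@pytest.fixture(scope="session")
def reference_runs(library, clean_cfg):
    """Noise-free pure-pigment runs for every library entry."""
    return {pid: pp.simulate_pyrogram(pp.Formulation.equal_parts(pid),
                                      library, clean_cfg)[0]
            for pid in library.pigments}


@pytest.fixture(scope="session")
def ams_library(reference_runs):
    return pp.build_ams_library(reference_runs)


@st.composite
def stick_spectra(draw, max_peaks=12, min_mz=1, max_mz=500):
    n = draw(st.integers(1, max_peaks))
    mzs = draw(st.lists(st.integers(min_mz, max_mz), min_size=n, max_size=n,
                        unique=True))
    intens = draw(st.lists(
        st.floats(0.1, 1e4, allow_nan=False, allow_infinity=False),
        min_size=n, max_size=n))
    return StickSpectrum.from_pairs(zip(mzs, intens))
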