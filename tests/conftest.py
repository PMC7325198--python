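import numpy as np
import pytest

import powderid as pid


@pytest.fixture
def clean_sim():
    """Noise-free, background-free, single-line (no doublet) instrument model."""
    def make(seed=0, **kw):
        kw.setdefault("doublet", False)
        kw.setdefault("bg_coeffs", ())
        kw.setdefault("noise_scale", 0.0)
        return pid.SimConfig(seed=seed, **kw)
    return make


@pytest.fixture
def single_peak_phase():
    def make(position, rel=100.0, wavelength=pid.CU_KALPHA1):
        return pid.Phase("single", np.array([position]), np.array([rel]), wavelength)
    return make


@pytest.fixture
def library6():
    return pid.fixture_library(6, seed=11)


@pytest.fixture
def small_pattern():
    t = 5.0 + 0.019 * np.arange(64)
    rng = np.random.default_rng(5)
    return pid.Pattern(t, rng.uniform(0.0, 1.0, 64), {"label": "small"})
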