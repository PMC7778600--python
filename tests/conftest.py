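import numpy as np
import pytest

from theranost import RamanGenConfig, Spectrum, SpectrumCollection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_axis():
    return np.arange(400.0, 2001.0)


@pytest.fixture
def smooth_spectrum(simple_axis):
    """Spike-free smooth spectrum: two broad bumps on a gentle slope."""
    x = simple_axis
    y = (
        100.0
        + 0.05 * (x - 400.0)
        + 300.0 * np.exp(-0.5 * ((x - 1000.0) / 40.0) ** 2)
        + 200.0 * np.exp(-0.5 * ((x - 1600.0) / 60.0) ** 2)
    )
    return Spectrum(axis=x, intensity=y)


@pytest.fixture
def small_collection(rng):
    """Five replicate spectra on a shared axis with mild noise."""
    x = np.linspace(500.0, 1800.0, 260)
    base = 50.0 + 400.0 * np.exp(-0.5 * ((x - 1200.0) / 80.0) ** 2)
    spectra = [
        Spectrum(axis=x, intensity=base + rng.normal(0, 5.0, x.size),
                 meta={"spectrum_id": f"r{i}"})
        for i in range(5)
    ]
    return SpectrumCollection(spectra, labels=["a", "a", "a", "b", "b"])


@pytest.fixture
def default_gen_config():
    return RamanGenConfig(seed=7)
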