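import numpy as np
import pytest

from nephromet.spectrum import Spectrum
from nephromet.synthetic import GeneratorConfig
from nephromet.templates import load_templates


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture
def clean_config():
    """Noiseless, baseline-free, water-free generator settings."""
    return GeneratorConfig(noise_sd=0.0, baseline_params=(),
                           water_artifact=(0.0, 0.1))


@pytest.fixture
def default_config():
    return GeneratorConfig()


def make_spectrum(y_func, ppm_start=-0.3, ppm_stop=10.0, step=5e-4,
                  sample_id="test"):
    """Build a Spectrum from a callable evaluated on the default grid."""
    n = int(round((ppm_stop - ppm_start) / step)) + 1
    ppm = ppm_start + step * np.arange(n)
    return Spectrum(ppm_start=ppm_start, ppm_step=step,
                    intensities=np.asarray(y_func(ppm), dtype=float),
                    sample_id=sample_id)


@pytest.fixture
def spectrum_factory():
    return make_spectrum
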