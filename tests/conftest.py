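import numpy as np
import pytest

from histokit.synth import default_nuclei_spec, synth_he_image


@pytest.fixture(scope="session")
def nuclei_field():
    """The default 12-nucleus synthetic H&E field with its ground truth."""
    spec = default_nuclei_spec()
    rgb, truth = synth_he_image(spec)
    return rgb, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
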