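import numpy as np
import pytest

from ictal.synthdata import generate_bonn_set, generate_chb_patient


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def bonn_sets():
    """Small synthetic Bonn-like A/D/E sets (12 channels each)."""
    return {
        "A": generate_bonn_set("bonn_normal", 12, seed=101),
        "D": generate_bonn_set("bonn_interictal", 12, seed=101),
        "E": generate_bonn_set("bonn_ictal", 12, seed=101),
    }


@pytest.fixture(scope="session")
def chb_patient():
    """One synthetic CHB-like patient with 5 unmistakable seizures."""
    return generate_chb_patient("p01", n_seizures=5, seed=77)
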