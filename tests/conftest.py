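import numpy as np
import pytest

from heartsound import bundled_reference_model, generate_recording
from heartsound.pipeline import preprocess_trace
from heartsound.simulate import class_presets

#: Sampling rate used by the signal-level tests; the pipeline's window
#: constants scale with fs (50 ms half-width, ~1 s STMHT window), and the
#: spectral-feature bin spacing depends only on segment duration.
FS = 4000.0


@pytest.fixture(scope="session")
def bundled_model():
    return bundled_reference_model()


@pytest.fixture(scope="session")
def nm_recording():
    """A clean 10-cycle normal recording plus ground truth."""
    spec = class_presets(FS)["NM"]
    return generate_recording(spec, 10, seed=1)


@pytest.fixture(scope="session")
def nm_preprocessed(nm_recording):
    trace, truth = nm_recording
    return preprocess_trace(trace), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
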