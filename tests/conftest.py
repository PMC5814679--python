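import numpy as np
import pytest

from avbind import stimuli as st
from avbind.pipeline import build_condition_suite


@pytest.fixture(scope="session")
def short_envelopes():
    """A matched pair of 3-s stream envelopes at 1 kHz."""
    e1 = st.make_am_envelope(3.0, 1000.0, 7.0, seed=11)
    e2 = st.make_am_envelope(3.0, 1000.0, 7.0, seed=22)
    return e1, e2


@pytest.fixture(scope="session")
def condition_suite():
    """Envelope-only stimulus suite for neural simulation (all conditions)."""
    return build_condition_suite(seed=3)


@pytest.fixture(scope="session")
def audio_suite(short_envelopes):
    """Audio-bearing stimulus sets for the main conditions."""
    e1, e2 = short_envelopes
    return {c: st.build_stimulus_set(c, e1, e2) for c in ("A1", "A1V1", "A12V1")}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
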