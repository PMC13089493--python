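import numpy as np
import pytest

from napscape import preprocess, simulate
from napscape.io import seconds_to_samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def prep(nap, stages=("N2",)):
    """Filter + re-reference a simulated nap and build its eligibility mask."""
    reref = preprocess.rereference(preprocess.bandpass(nap.recording))
    sec = nap.hypnogram.eligible_seconds(int(reref.duration_s), stages)
    mask = seconds_to_samples(sec, reref.fs, reref.n_samples)
    return reref, mask


@pytest.fixture(scope="session")
def baseline_nap():
    """One 10-minute baseline nap shared across read-only tests."""
    spec = simulate.NapSpec(
        duration_min=10.0, sol_min=1.0, channels=("Cz", "C4", "TP9", "TP10")
    )
    return simulate.simulate_nap(spec, 2024)


@pytest.fixture(scope="session")
def stimulation_nap():
    """One 12-minute stimulation nap with planted evoked K-complexes."""
    spec = simulate.NapSpec(
        duration_min=12.0,
        sol_min=1.0,
        condition="stimulation",
        channels=("Cz", "TP9", "TP10"),
        p_evoked=0.4,
        stim_start_after_onset_s=10.0,
    )
    return simulate.simulate_nap(spec, 77)
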