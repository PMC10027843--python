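import numpy as np
import pytest

from arrestnirs import pipeline, synth
from arrestnirs.optics import OpticalGeometry


@pytest.fixture(scope="session")
def geometry() -> OpticalGeometry:
    return OpticalGeometry()


@pytest.fixture(scope="session")
def default_config() -> synth.AnimalConfig:
    return synth.AnimalConfig(seed=7)


@pytest.fixture(scope="session")
def default_recording(default_config, geometry) -> synth.AnimalRecording:
    return synth.simulate_animal(default_config, geometry)


@pytest.fixture(scope="session")
def default_session(default_recording, geometry) -> pipeline.ProcessedSession:
    return pipeline.process_recording(default_recording, geometry)


@pytest.fixture(scope="session")
def preset_cohort(geometry):
    """The eight-animal cohort mirroring the published per-animal grid."""
    return synth.simulate_cohort(8, preset="cohort", seed=11, geometry=geometry)


def brute_force_first_crossing(ts, marker, threshold, post_s=300.0):
    """Independent exhaustive scan used as the detection oracle in tests."""
    times = ts.times
    best = None
    for i in range(ts.n):
        if times[i] <= marker or times[i] > marker + post_s:
            continue
        if np.isfinite(ts.data[i]) and ts.data[i] < threshold:
            best = times[i] - marker
            break
    return best
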