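import numpy as np
import pytest
from hypothesis import settings

from fogkit.signal_model import SensorRecording, Site, TrialRecording
from fogkit.synthetic import SimulationConfig, simulate_trial

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

FS = 128.0


def make_trial(duration_s=10.0, fs=FS, fill=None, seed=0):
    """A minimal three-site trial; ``fill(site, channel) -> (3, n) array``."""
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    recs = {}
    for site in Site:
        if fill is None:
            acc = rng.normal(0, 0.1, (3, n))
            gyr = rng.normal(0, 1.0, (3, n))
        else:
            acc = fill(site, "accel")
            gyr = fill(site, "gyro")
        recs[site] = SensorRecording(site=site, accel=acc, gyro=gyr, fs=fs)
    return TrialRecording(recordings=recs, subject_id="T", med_state="OFF", difficulty=1)


@pytest.fixture
def small_trial():
    return make_trial()


@pytest.fixture(scope="session")
def sim_trial():
    """One default-condition simulated trial with freezing episodes."""
    cfg = SimulationConfig(seed=11, episode_rate=4.0, duration_s=60.0)
    return simulate_trial(cfg, seed=11)
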