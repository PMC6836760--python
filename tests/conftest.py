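import numpy as np
import pytest

from quieteye import DetectionParams, build_scene_layout
from quieteye.simulate import SimulationConfig, generate_dataset

PERIOD = 1000.0 / 30.0


@pytest.fixture(scope="session")
def layout():
    return build_scene_layout()


@pytest.fixture()
def params():
    return DetectionParams()


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    """60 zero-noise trials (3 participants x 5 per cell) with ground truth."""
    cfg = SimulationConfig(
        n_participants=3, trials_per_cell=5, noise_sd_deg=0.0, seed=20240701
    )
    return cfg, generate_dataset(cfg)


def make_recording(x, y, valid=None, trial_id="t", rate=30.0, **meta):
    """Build a recording from coordinate lists on the nominal 30 Hz grid."""
    from quieteye import GazeRecording

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if valid is None:
        valid = np.ones(n, dtype=bool)
    meta.setdefault("participant", "P01")
    meta.setdefault("condition", "undefended")
    meta.setdefault("outcome", "hit")
    return GazeRecording(
        trial_id=trial_id,
        sampling_rate_hz=rate,
        t_ms=np.arange(n) * (1000.0 / rate),
        x_deg=x,
        y_deg=y,
        valid=np.asarray(valid, dtype=bool),
        **meta,
    )
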