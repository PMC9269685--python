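import warnings

import numpy as np
import pytest

import transferkin as tk

# the default 15 Hz cutoff sits at Nyquist for 30 Hz data; the clamp
# warning is expected throughout and would otherwise drown the output
warnings.filterwarnings("ignore", message="cutoff .* Nyquist")


@pytest.fixture
def default_profile():
    return tk.TransferProfile()


@pytest.fixture
def noiseless_trial(default_profile):
    return tk.simulate_trial(default_profile, seed=0, sensor="kinect_azure")


def random_sequence(seed: int, sensor="kinect_azure", n: int = 20) -> tk.SkeletonSequence:
    """Small random recording used for round-trip and alignment properties."""
    rng = np.random.default_rng(seed)
    model = tk.get_sensor_model(sensor)
    joints = model.joint_vocabulary[: rng.integers(2, len(model.joint_vocabulary) + 1)]
    timestamps = np.cumsum(rng.uniform(0.02, 0.05, size=n))
    positions, valid = {}, {}
    for j in joints:
        pos = rng.normal(0, 1000, size=(n, 3))
        v = rng.random(n) > 0.1
        pos[~v] = np.nan
        positions[j] = pos
        valid[j] = v
    return tk.SkeletonSequence(
        sensor=model,
        timestamps=timestamps,
        positions=positions,
        valid=valid,
        trial_id=f"t{seed}",
        subject_id="s1",
    )
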