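import numpy as np
import pytest

from dyadsync.pose import PoseSequence
from dyadsync.synthetic import (
    DyadSimConfig,
    ObserverSimConfig,
    generate_follower,
    generate_leader,
    generate_observer_data,
    generate_schedule,
    generate_traits,
)


@pytest.fixture
def leader():
    return generate_leader(DyadSimConfig(n_frames=300, seed=7))


@pytest.fixture
def dyad(leader):
    cfg = DyadSimConfig(n_frames=300, seed=7, lag_frames=3, follower_noise_sd=2.0)
    return leader, generate_follower(leader, cfg)


@pytest.fixture
def simple_pose():
    """Two-frame sequence with easy hand-checkable coordinates."""
    frame0 = np.array(
        [[0.0, 0.0], [3.0, 4.0], [6.0, 8.0], [0.0, 5.0], [5.0, 0.0], [1.0, 1.0], [2.0, 2.0]]
    )
    frame1 = frame0 + np.array([10.0, -2.0])  # pure translation
    return PoseSequence(coords=np.stack([frame0, frame1]), fps=25.0)


@pytest.fixture(scope="session")
def observer_dataset():
    """Small study: 12 participants x 8 videos, default generating values."""
    rng = np.random.default_rng(21)
    schedule = generate_schedule(8, seed=3)
    measured = schedule.video_conditions.assign(synchrony=rng.uniform(0.5, 0.95, 8))
    traits = generate_traits(12, seed=3)
    config = ObserverSimConfig(n_participants=12, seed=3)
    trials, truth = generate_observer_data(measured, traits, config)
    return {"trials": trials, "traits": traits, "truth": truth, "measured": measured}
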