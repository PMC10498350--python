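import numpy as np
import pytest

from placotax import SyntheticSpec, Trajectory, TrialMeta, simulate_trajectory


@pytest.fixture
def warm_up_meta() -> TrialMeta:
    """Gradient trial with the warm side at +y (theta = pi/2)."""
    return TrialMeta(condition="gradient", t1=22.0, t2=18.0, grad=0.1,
                     trial_id="fixture")


@pytest.fixture
def straight_up_trajectory() -> Trajectory:
    """Noise-free constant-velocity path straight up the warm axis:
    0.05 mm per 30 s frame, 211 frames."""
    n = 211
    return Trajectory(frame=np.arange(n), x=np.zeros(n), y=0.05 * np.arange(n))


@pytest.fixture
def diffusive_trajectory() -> Trajectory:
    """Long unbiased isotropic walk (fixed seed)."""
    traj, _ = simulate_trajectory(
        SyntheticSpec(mode="diffusive", n_frames=2000, seed=42,
                      arena_diameter=1e6))
    return traj


def make_walk(mode="diffusive", n_frames=211, seed=0, **kw):
    kw.setdefault("arena_diameter", 1e9)  # effectively unbounded
    traj, meta = simulate_trajectory(
        SyntheticSpec(mode=mode, n_frames=n_frames, seed=seed, **kw))
    return traj, meta
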