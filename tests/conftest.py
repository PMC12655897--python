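import numpy as np
import pytest

from aclird.config import PipelineConfig
from aclird.datamodel_io import ANGLE_CHANNELS, TrialKinematics, TrialMeta
from aclird.synthgen import SynthParams, generate_cut_trial


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def make_trial():
    """Factory for synthetic cut trials."""

    def _make(**kwargs):
        params = SynthParams(**kwargs)
        return generate_cut_trial(params)

    return _make


@pytest.fixture
def default_trial(make_trial):
    return make_trial(seed=1)


def build_manual_trial(
    duration_s=6.0,
    sample_rate=100.0,
    speed_fn=None,
    heading_fn=None,
    vz_fn=None,
    angle_const=None,
):
    """Hand-built trial: constant-speed straight run by default.

    ``speed_fn(t)``/``vz_fn(t)`` override the horizontal speed and vertical
    velocity; ``heading_fn(t)`` returns unit headings (n, 2).
    """
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    speed = speed_fn(t) if speed_fn else np.full(n, 5.0)
    if heading_fn:
        heading = heading_fn(t)
    else:
        heading = np.column_stack([np.ones(n), np.zeros(n)])
    vel_xy = speed[:, None] * heading
    vz = vz_fn(t) if vz_fn else -0.4 * np.cos(2 * np.pi * 3.0 * t)
    from scipy.integrate import cumulative_trapezoid

    pos = np.column_stack([
        cumulative_trapezoid(vel_xy[:, 0], t, initial=0.0),
        cumulative_trapezoid(vel_xy[:, 1], t, initial=0.0),
        1.0 + cumulative_trapezoid(vz, t, initial=0.0),
    ])
    vel = np.column_stack([vel_xy, vz])
    defaults = angle_const or {}
    angles = {c: np.full(n, float(defaults.get(c, 10.0))) for c in ANGLE_CHANNELS}
    return TrialKinematics(sample_rate, t, pos, vel, angles)


@pytest.fixture
def straight_trial():
    return build_manual_trial()


@pytest.fixture
def default_meta():
    return TrialMeta(
        player_id="P01", sex="male", task="AGTT", cut_limb="right",
        injured_limb="none", trial_index=1,
    )
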