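"""Synthetic cut-maneuver trial generator with embedded ground truth.

The generated pelvis trajectory is two constant-heading straight segments
meeting at the cut contact, so the angle between entry and exit directions is
exactly the requested cut angle.  Pelvis vertical velocity is a sinusoid at
step frequency whose local minima fall exactly on the ground-truth foot
contacts (amplitude 0.4 m/s, tapered to zero outside the stepping interval).
The resultant horizontal speed carries a peak shortly before the cut and a dip
at the direction change, which is the signature the eligibility filters of the
cut-angle algorithm key on.

Joint angles are flat baselines with one raised-cosine bump per stance of the
corresponding limb; the baseline equals the value at initial contact and the
bump apex (at mid-stance, which is also where knee flexion peaks) equals the
pKF value, so both frames are independently controllable via
``factor_targets`` and both lie at zero-slope points of the curve (exact to
sub-sample alignment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .datamodel_io import ANGLE_CHANNELS, TrialKinematics, TrialMeta
from .errors import ParameterError

#: vertical-velocity oscillation amplitude, m/s
VERTICAL_VEL_AMPLITUDE = 0.4

#: factor id -> angle channel stem (None: handled specially)
FACTOR_CHANNELS = {
    "HF": "hip_flex",
    "KF": "knee_flex",
    "AF": "ankle_flex",
    "KV": "knee_valgus",
    "HA": "hip_abd",
    "HI": "hip_rot",
    "TIB": "trunk_lat_bend",
    "TCR": "trunk_rot",
}
KNOWN_FACTORS = ("HK",) + tuple(FACTOR_CHANNELS)
FRAMES = ("IC", "pKF")

#: default (IC value, mid-stance value) per factor, degrees
DEFAULT_CURVES = {
    "HF": (35.0, 50.0),
    "KF": (35.0, 70.0),
    "AF": (-5.0, -12.0),
    "KV": (1.0, 1.2),
    "HA": (2.0, 3.0),
    "HI": (5.0, 7.0),
    "TIB": (4.0, 5.0),
    "TCR": (2.0, 3.0),
}


@dataclass
class SynthParams:
    """Parameters of one synthetic cut trial."""

    cut_angle_deg: float = 75.0
    approach_speed: float = 5.0          # m/s
    exit_speed: float = 4.0              # m/s
    step_frequency: float = 3.0          # steps/s
    n_steps_before: int = 8
    n_steps_after: int = 8
    noise_sd: float = 0.0                # deg on angles, m/s on velocities
    seed: int = 0
    factor_targets: Optional[Mapping[str, float]] = None  # "KF@IC" -> value
    sample_rate: float = 100.0
    player_id: str = "SYN01"
    sex: str = "male"
    task: str = "AGTT"
    cut_limb: str = "right"
    injured_limb: str = "none"
    trial_index: int = 1

    def validate(self) -> None:
        if not (10.0 <= self.cut_angle_deg <= 110.0):
            raise ParameterError("cut_angle_deg must lie in [10, 110]")
        if self.approach_speed <= 0 or self.exit_speed <= 0:
            raise ParameterError("speeds must be positive")
        if self.step_frequency <= 0:
            raise ParameterError("step_frequency must be positive")
        if self.n_steps_before < 6 or self.n_steps_after < 6:
            raise ParameterError("at least 6 steps required on each side of the cut")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for key in (self.factor_targets or {}):
            fid, _, frame = key.partition("@")
            if fid not in KNOWN_FACTORS or frame not in FRAMES:
                raise ParameterError(
                    f"unknown factor target {key!r} (expected '<factor>@IC/pKF')"
                )


@dataclass
class SynthTruth:
    """Ground truth embedded in a generated trial."""

    contact_samples: np.ndarray          # all foot-contact sample indices
    cut_contact_index: int               # sample of the final pre-cut contact
    true_cut_angle: float                # degrees
    true_ic: int
    true_pkf: int
    true_factor_values: dict[str, float]  # "KF@IC" -> value
    stance_duration_s: float = 0.0


def _curve_params(params: SynthParams) -> dict[str, tuple[float, float]]:
    """Resolve (IC value, apex value) per factor from defaults + targets."""
    targets = dict(params.factor_targets or {})
    curves = {f: list(v) for f, v in DEFAULT_CURVES.items()}
    for key, value in targets.items():
        fid, _, frame = key.partition("@")
        if fid == "HK":
            continue  # handled below, needs KF already resolved
        curves[fid][0 if frame == "IC" else 1] = float(value)
    # HK ratio target: knee(median)/hip(Q1) over a short window; with smooth
    # curves this is approximately knee/hip at the frame, so set hip there.
    for key, value in targets.items():
        fid, _, frame = key.partition("@")
        if fid != "HK":
            continue
        if not value or abs(value) < 0.05:
            raise ParameterError("HK target too close to zero to synthesize")
        i = 0 if frame == "IC" else 1
        curves["HF"][i] = curves["KF"][i] / float(value)
    return {f: (v[0], v[1]) for f, v in curves.items()}


def generate_cut_trial(
    params: SynthParams,
) -> tuple[TrialKinematics, TrialMeta, SynthTruth]:
    """Generate one cut trial; deterministic for a fixed seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    f = params.step_frequency
    dt = 1.0 / fs

    # contact timeline: n_before steps, the cut contact, n_after steps
    n_contacts = params.n_steps_before + params.n_steps_after + 1
    lead = max(0.5, 2.2 - params.n_steps_before / f)  # 2 s entry window fits
    tail = max(0.5, 2.2 - params.n_steps_after / f)
    contact_times = lead + np.arange(n_contacts) / f
    i_cut = params.n_steps_before
    t_cut = contact_times[i_cut]
    duration = contact_times[-1] + tail
    n = int(round(duration * fs))
    t = np.arange(n) * dt
    contact_samples = np.round(contact_times * fs).astype(int)
    cut_sample = int(contact_samples[i_cut])

    # --- horizontal kinematics ---
    theta = math.radians(params.cut_angle_deg)
    u_in = np.array([1.0, 0.0])
    u_out = np.array([math.cos(theta), math.sin(theta)])

    # smooth approach->exit transition placed after the dip so the resultant
    # speed minimum stays at/after the cut contact
    blend = 0.5 * (1.0 + np.tanh((t - (t_cut + 0.35)) / 0.15))
    base = params.approach_speed + (params.exit_speed - params.approach_speed) * blend
    bump_amp = 0.15 * params.approach_speed + max(
        0.0, params.exit_speed - params.approach_speed) + 0.3
    dip_amp = 0.4 * min(params.approach_speed, params.exit_speed)
    speed = (
        base
        + bump_amp * np.exp(-0.5 * ((t - (t_cut - 0.35)) / 0.12) ** 2)
        - dip_amp * np.exp(-0.5 * ((t - (t_cut + 0.05)) / 0.10) ** 2)
    )
    heading = np.where(t[:, None] < t_cut, u_in[None, :], u_out[None, :])
    vel_xy = speed[:, None] * heading
    pos_xy = np.zeros_like(vel_xy)
    pos_xy[:, 0] = cumulative_trapezoid(vel_xy[:, 0], t, initial=0.0)
    pos_xy[:, 1] = cumulative_trapezoid(vel_xy[:, 1], t, initial=0.0)

    # --- vertical kinematics: minima of vz exactly at the contacts ---
    phase = 2.0 * math.pi * f * (t - contact_times[0])
    envelope = np.ones(n)
    ramp = 0.5 / f
    left = (t >= contact_times[0] - ramp) & (t < contact_times[0])
    right = (t > contact_times[-1]) & (t <= contact_times[-1] + ramp)
    envelope[t < contact_times[0] - ramp] = 0.0
    envelope[t > contact_times[-1] + ramp] = 0.0
    envelope[left] = 0.5 * (1 - np.cos(np.pi * (t[left] - (contact_times[0] - ramp)) / ramp))
    envelope[right] = 0.5 * (1 + np.cos(np.pi * (t[right] - contact_times[-1]) / ramp))
    vz = -VERTICAL_VEL_AMPLITUDE * np.cos(phase) * envelope
    z = 1.0 + cumulative_trapezoid(vz, t, initial=0.0)

    pelvis_pos = np.column_stack([pos_xy, z])
    pelvis_vel = np.column_stack([vel_xy, vz])

    # --- joint angles ---
    stance_dur = 0.7 / f
    curves = _curve_params(params)
    other_limb = "left" if params.cut_limb == "right" else "right"

    def limb_of(contact_idx: int) -> str:
        return params.cut_limb if (contact_idx - i_cut) % 2 == 0 else other_limb

    angles = {}
    for fid, stem in FACTOR_CHANNELS.items():
        ic_val, apex_val = curves[fid]
        if stem in ("trunk_lat_bend", "trunk_rot"):
            series = np.full(n, ic_val)
            for ci in range(n_contacts):
                tau = (t - contact_times[ci]) / stance_dur
                mask = (tau >= 0) & (tau < 1)
                series[mask] = ic_val + (apex_val - ic_val) * np.sin(np.pi * tau[mask]) ** 2
            angles[stem] = series
        else:
            for side in ("left", "right"):
                series = np.full(n, ic_val)
                for ci in range(n_contacts):
                    if limb_of(ci) != side:
                        continue
                    tau = (t - contact_times[ci]) / stance_dur
                    mask = (tau >= 0) & (tau < 1)
                    series[mask] = (
                        ic_val + (apex_val - ic_val) * np.sin(np.pi * tau[mask]) ** 2
                    )
                angles[f"{stem}_{side[0]}"] = series

    # --- ground truth (read back before noise) ---
    true_ic = cut_sample
    true_pkf = int(round((t_cut + stance_dur / 2) * fs))
    stance_end = min(n, int(contact_samples[i_cut + 1]))
    side = params.cut_limb[0]
    truth_values: dict[str, float] = {}
    for frame, sample in (("IC", true_ic), ("pKF", true_pkf)):
        for fid, stem in FACTOR_CHANNELS.items():
            key = stem if stem.startswith("trunk") else f"{stem}_{side}"
            truth_values[f"{fid}@{frame}"] = float(angles[key][sample])
        half = int(round(0.05 * fs))
        a = max(cut_sample, sample - half)
        b = min(stance_end, sample + half + 1)
        knee = angles[f"knee_flex_{side}"][a:b]
        hip = angles[f"hip_flex_{side}"][a:b]
        q1 = float(np.percentile(hip, 25))
        truth_values[f"HK@{frame}"] = float(np.median(knee)) / q1 if q1 else float("nan")

    # --- noise ---
    if params.noise_sd > 0:
        for key in angles:
            angles[key] = angles[key] + rng.normal(0.0, params.noise_sd, n)
        pelvis_vel = pelvis_vel + rng.normal(0.0, params.noise_sd, pelvis_vel.shape)
        pelvis_pos = pelvis_pos + rng.normal(0.0, 0.01 * params.noise_sd,
                                             pelvis_pos.shape)

    trial = TrialKinematics(
        sample_rate=fs, t=t, pelvis_pos=pelvis_pos, pelvis_vel=pelvis_vel,
        angles=angles,
    )
    meta = TrialMeta(
        player_id=params.player_id, sex=params.sex, task=params.task,
        cut_limb=params.cut_limb, injured_limb=params.injured_limb,
        trial_index=params.trial_index,
    )
    truth = SynthTruth(
        contact_samples=contact_samples,
        cut_contact_index=cut_sample,
        true_cut_angle=params.cut_angle_deg,
        true_ic=true_ic,
        true_pkf=true_pkf,
        true_factor_values=truth_values,
        stance_duration_s=stance_dur,
    )
    return trial, meta, truth


def generate_control_cohort(
    n_players: int,
    population: Mapping[str, tuple[float, float]],
    seed: int,
    sex: str = "male",
    task: str = "AGTT",
    base_params: Optional[SynthParams] = None,
    trials_per_player: int = 1,
) -> list[tuple[TrialKinematics, TrialMeta, SynthTruth]]:
    """Generate a healthy-control cohort with per-player factor values drawn
    from the stated normal distributions.

    ``population`` maps ``"<factor>@<frame>"`` to ``(mu, sigma)``.
    """
    if n_players < 2:
        raise ParameterError("n_players must be >= 2")
    for key, (mu, sigma) in population.items():
        fid, _, frame = key.partition("@")
        if fid not in KNOWN_FACTORS or frame not in FRAMES:
            raise ParameterError(f"unknown population metric {key!r}")
        if sigma <= 0:
            raise ParameterError(f"sigma must be positive for {key!r}")
    base = base_params or SynthParams(sex=sex, task=task)
    rng = np.random.default_rng(seed)
    out = []
    for p in range(n_players):
        targets = {k: float(rng.normal(mu, sigma))
                   for k, (mu, sigma) in population.items()}
        for ti in range(trials_per_player):
            params = replace(
                base,
                seed=int(rng.integers(0, 2**31 - 1)),
                factor_targets=targets,
                player_id=f"CTRL{p + 1:03d}",
                sex=sex,
                task=task,
                cut_limb="right" if ti % 2 == 0 else "left",
                injured_limb="none",
                trial_index=ti + 1,
            )
            out.append(generate_cut_trial(params))
    return out
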