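"""Multistep cut-angle identification.

For every step, the angle between the normalized horizontal pelvis
displacements over the k steps before and the k steps after it (k = 5) is a
candidate cut angle.  Candidates then pass three filters:

1. plausibility: angles outside [10, 110] degrees are discarded
   (boundaries inclusive);
2. resultant-velocity interval: only candidates between a local maximum of
   the horizontal pelvis speed and the subsequent local minimum remain;
3. derivative window: only candidates within 500 ms (total width, centered)
   of the first local maximum of the mediolateral-velocity derivative after
   the resultant-speed peak remain.

The final cut angle is the largest surviving candidate (ties broken by
earliest sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks

from ._filters import lowpass
from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel_io import TrialKinematics
from .errors import EligibilityError, InsufficientStepsError, NoCutDetectedError
from .gait_events import FootContactSeries, StepRecord, segment_steps

__all__ = [
    "Candidate", "CutAngleResult",
    "candidate_angles", "plausibility_filter",
    "velocity_interval_filter", "derivative_window_filter",
    "compute_cut_angle",
]


class Candidate(NamedTuple):
    step_index: int
    sample: int
    angle_deg: float


@dataclass
class CutAngleResult:
    candidates: list[Candidate]
    plausible: list[Candidate]
    velocity_eligible: list[Candidate]
    derivative_eligible: list[Candidate]
    final_angle_deg: float
    final_sample: int


def candidate_angles(
    steps: list[StepRecord], trial: TrialKinematics, k: int = 5
) -> list[Candidate]:
    """Per-step candidate angles between the +/- k-step displacement vectors."""
    n = len(steps)
    if n < 2 * k + 1:
        raise InsufficientStepsError(
            f"{n} steps segmented; need at least {2 * k + 1} for k={k}"
        )
    pos = trial.pelvis_pos[:, :2]
    out = []
    for i in range(k, n - k):
        p_prev = pos[steps[i - k].start]
        p_cur = pos[steps[i].start]
        p_next = pos[steps[i + k].start]
        v_in = p_cur - p_prev
        v_out = p_next - p_cur
        ni, no = np.linalg.norm(v_in), np.linalg.norm(v_out)
        if ni == 0.0 or no == 0.0:
            continue  # degenerate (stationary) step; no direction defined
        cosang = float(np.clip(np.dot(v_in / ni, v_out / no), -1.0, 1.0))
        out.append(Candidate(i, steps[i].start, float(np.degrees(np.arccos(cosang)))))
    return out


def plausibility_filter(
    candidates: list[Candidate], config: PipelineConfig = DEFAULT_CONFIG
) -> list[Candidate]:
    """Keep candidates within the plausible cut-angle range (inclusive)."""
    lo, hi = config.plausibility_lo_deg, config.plausibility_hi_deg
    return [c for c in candidates if lo <= c.angle_deg <= hi]


def _speed_extrema(
    trial: TrialKinematics, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    speed = lowpass(trial.horizontal_speed(), trial.sample_rate,
                    config.lowpass_hz, config.lowpass_order)
    maxima, _ = find_peaks(speed, prominence=config.speed_peak_prominence)
    minima, _ = find_peaks(-speed, prominence=config.speed_peak_prominence)
    return speed, maxima, minima


def velocity_interval_filter(
    plausible: list[Candidate],
    trial: TrialKinematics,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[Candidate]:
    """Keep candidates lying between a resultant-speed local maximum and the
    subsequent local minimum."""
    _, maxima, minima = _speed_extrema(trial, config)
    if maxima.size == 0:
        raise EligibilityError("velocity_interval",
                               "no local maximum in resultant pelvis speed")
    intervals = []
    for m in maxima:
        nxt = minima[minima > m]
        if nxt.size:
            intervals.append((int(m), int(nxt[0])))
    if config.velocity_filter_first_pair_only:
        intervals = intervals[:1]
    return [
        c for c in plausible
        if any(a <= c.sample <= b for a, b in intervals)
    ]


def derivative_window_filter(
    velocity_eligible: list[Candidate],
    trial: TrialKinematics,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[Candidate]:
    """Keep candidates within the eligibility window around the first local
    maximum of the mediolateral-velocity derivative after the speed peak."""
    fs = trial.sample_rate
    speed, _, _ = _speed_extrema(trial, config)
    peak = int(np.argmax(speed))
    vy = lowpass(trial.pelvis_vel[:, 1], fs, config.lowpass_hz,
                 config.lowpass_order)
    deriv = lowpass(np.gradient(vy, 1.0 / fs), fs, config.lowpass_hz,
                    config.lowpass_order)
    stop = min(trial.n_samples, peak + int(round(config.derivative_search_s * fs)) + 1)
    seg = deriv[peak:stop]
    # a relative prominence keeps filter ripple from masquerading as the
    # first substantive maximum
    prom = config.derivative_peak_rel_prominence * float(np.ptp(seg)) if seg.size else 0.0
    peaks, _ = find_peaks(seg, prominence=max(prom, 1e-12))
    if peaks.size == 0:
        raise EligibilityError(
            "derivative_window",
            "no local maximum in the mediolateral-velocity derivative",
        )
    m = peak + int(peaks[0])
    half = int(round(0.5 * config.derivative_window_s * fs))
    return [c for c in velocity_eligible if abs(c.sample - m) <= half]


def compute_cut_angle(
    trial: TrialKinematics,
    contacts: FootContactSeries,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CutAngleResult:
    """Chain the candidate operator and the three filters; the final angle is
    the largest eligible candidate."""
    steps = segment_steps(contacts, trial)
    candidates = candidate_angles(steps, trial, k=config.candidate_step_k)
    if not candidates:
        raise NoCutDetectedError("candidates")
    plausible = plausibility_filter(candidates, config)
    if not plausible:
        raise NoCutDetectedError("plausibility")
    vel_ok = velocity_interval_filter(plausible, trial, config)
    if not vel_ok:
        raise NoCutDetectedError("velocity_interval")
    deriv_ok = derivative_window_filter(vel_ok, trial, config)
    if not deriv_ok:
        raise NoCutDetectedError("derivative_window")
    best = min(deriv_ok, key=lambda c: (-c.angle_deg, c.sample))
    return CutAngleResult(
        candidates=candidates,
        plausible=plausible,
        velocity_eligible=vel_ok,
        derivative_eligible=deriv_ok,
        final_angle_deg=best.angle_deg,
        final_sample=best.sample,
    )
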