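"""Foot-contact detection, step segmentation and the final-stance window.

Foot contacts are local minima of the low-pass-filtered pelvis vertical
velocity.  The final stance window before the direction change (the FC
window) opens at the last contact at/before the cut sample and closes at the
next contact, capped so a missed contact cannot inflate it.  Initial contact
(IC) is the window start; peak knee flexion (pKF) is the sample of maximum
stance-limb knee flexion inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ._filters import lowpass
from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel_io import TrialKinematics
from .errors import EventDetectionError

__all__ = [
    "FootContactSeries", "FCWindow", "StepRecord",
    "detect_foot_contacts", "segment_steps", "locate_fc_window",
]


@dataclass
class FootContactSeries:
    contact_samples: np.ndarray  # strictly increasing sample indices
    source_signal: str = "pelvis_vel_z"

    def __len__(self) -> int:
        return int(self.contact_samples.shape[0])


@dataclass
class FCWindow:
    """Stance window of the final foot strike before the direction change."""

    start: int        # foot-strike sample
    end: int          # exclusive
    ic: int           # initial-contact sample (== start)
    pkf: int          # peak-knee-flexion sample
    stance_limb: str  # "left" | "right"
    duration_s: float

    def __post_init__(self) -> None:
        if not (self.start <= self.ic <= self.pkf < self.end):
            raise EventDetectionError(
                f"inconsistent FC window: start={self.start} ic={self.ic} "
                f"pkf={self.pkf} end={self.end}"
            )


@dataclass
class StepRecord:
    index: int
    start: int               # contact sample opening the step
    end: int                 # next contact sample (exclusive)
    displacement: np.ndarray  # horizontal pelvis displacement (2,), meters


def detect_foot_contacts(
    trial: TrialKinematics, config: PipelineConfig = DEFAULT_CONFIG
) -> FootContactSeries:
    """Detect foot contacts as prominent local minima of the filtered pelvis
    vertical velocity."""
    vz = lowpass(trial.pelvis_vel[:, 2], trial.sample_rate,
                 config.lowpass_hz, config.lowpass_order)
    distance = max(1, int(round(config.min_separation_s * trial.sample_rate)))
    idx, _ = find_peaks(-vz, prominence=config.min_prominence, distance=distance)
    if idx.size < 2:
        raise EventDetectionError(
            f"only {idx.size} foot contact(s) detected; need at least 2"
        )
    return FootContactSeries(contact_samples=idx.astype(int))


def segment_steps(
    contacts: FootContactSeries, trial: TrialKinematics
) -> list[StepRecord]:
    """Split the trial into consecutive steps between detected contacts."""
    cs = contacts.contact_samples
    if cs.size < 2:
        raise EventDetectionError("at least 2 contacts required to segment steps")
    steps = []
    for i in range(cs.size - 1):
        a, b = int(cs[i]), int(cs[i + 1])
        disp = trial.pelvis_pos[b, :2] - trial.pelvis_pos[a, :2]
        steps.append(StepRecord(index=i, start=a, end=b, displacement=disp))
    return steps


def locate_fc_window(
    trial: TrialKinematics,
    contacts: FootContactSeries,
    cut_sample: int,
    stance_limb: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> FCWindow:
    """Locate the final pre-cut stance window and its IC/pKF frames."""
    cs = contacts.contact_samples
    if not (0 <= cut_sample < trial.n_samples):
        raise EventDetectionError(f"cut sample {cut_sample} outside trial")
    at_or_before = cs[cs <= cut_sample]
    if at_or_before.size == 0:
        raise EventDetectionError("no foot contact at or before the cut sample")
    start = int(at_or_before[-1])
    after = cs[cs > start]
    cap = start + max(1, int(round(config.max_stance_s * trial.sample_rate)))
    end = int(after[0]) if after.size else cap
    end = min(end, cap, trial.n_samples)
    if end <= start:
        raise EventDetectionError("empty stance window")
    knee = trial.angle("knee_flex", stance_limb)
    pkf = start + int(np.argmax(knee[start:end]))
    return FCWindow(
        start=start, end=end, ic=start, pkf=pkf, stance_limb=stance_limb,
        duration_s=(end - start) / trial.sample_rate,
    )
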