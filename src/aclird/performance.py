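"""Entry/exit velocity-acceleration metrics and z-score speedometer dials.

The center of mass is proxied by the pelvis trajectory.  The entry window
spans the 2 s preceding the stance start; the exit window spans 2 s after the
stance end (clipped to the trial end, with the clip flagged).  Dials
discretize the z-score against healthy-control norms into seven levels:
|z| in [0,1) -> 0 (green), [1,2) -> +/-1 (yellow), [2,3) -> +/-2 (orange),
>= 3 -> +/-3 (red).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel_io import NormativeStats, TrialKinematics
from .errors import ParameterError
from .gait_events import FCWindow

__all__ = [
    "PerformanceMetrics", "METRIC_IDS",
    "extract_performance", "zscore", "dial_index", "attach_norms",
]

METRIC_IDS = ("peak_vel_in", "peak_acc_in", "min_dec_in",
              "peak_vel_out", "peak_acc_out")

DIAL_COLORS = {0: "green", 1: "yellow", 2: "orange", 3: "red"}


@dataclass
class PerformanceMetrics:
    peak_vel_in: float     # m/s
    peak_acc_in: float     # m/s^2, >= 0
    min_dec_in: float      # m/s^2, <= 0
    peak_vel_out: float    # m/s
    peak_acc_out: float    # m/s^2
    exit_clipped: bool = False
    exit_span_s: float = 0.0
    z: dict[str, float] = field(default_factory=dict)
    dial: dict[str, int] = field(default_factory=dict)

    def values(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_IDS}


def extract_performance(
    trial: TrialKinematics,
    window: FCWindow,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> PerformanceMetrics:
    """Extract entry/exit speed and acceleration metrics around the FC window."""
    fs = trial.sample_rate
    n_in = int(round(config.entry_window_s * fs))
    n_out = int(round(config.exit_window_s * fs))
    if window.start - n_in < 0:
        raise ParameterError(
            f"trial too short: entry window needs {config.entry_window_s} s "
            f"before sample {window.start}"
        )
    # raw speed + central differences: a zero-lag low-pass would overshoot
    # at sharp speed corners and bias the deceleration extrema
    speed = trial.horizontal_speed()
    acc = np.gradient(speed, 1.0 / fs)

    entry = slice(window.start - n_in, window.start)
    exit_end = min(trial.n_samples, window.end + n_out)
    out = slice(window.end, exit_end)
    clipped = exit_end < window.end + n_out
    if out.stop - out.start < 2:
        raise ParameterError("exit window contains fewer than 2 samples")

    return PerformanceMetrics(
        peak_vel_in=float(np.max(speed[entry])),
        peak_acc_in=float(max(0.0, np.max(acc[entry]))),
        min_dec_in=float(min(0.0, np.min(acc[entry]))),
        peak_vel_out=float(np.max(speed[out])),
        peak_acc_out=float(max(0.0, np.max(acc[out]))),
        exit_clipped=clipped,
        exit_span_s=(out.stop - out.start) / fs,
    )


def zscore(value: float, norms: NormativeStats) -> float:
    """Standardized deviation of ``value`` from the control mean."""
    if norms.sigma <= 0:
        raise ParameterError("sigma must be positive")
    return (value - norms.mu) / norms.sigma


def dial_index(z: float) -> int:
    """Discretize a z-score to the seven-level speedometer dial in [-3, 3]."""
    if not math.isfinite(z):
        raise ParameterError(f"non-finite z-score: {z!r}")
    return int(math.copysign(min(3, math.floor(abs(z))), z)) if z else 0


def attach_norms(
    metrics: PerformanceMetrics,
    norms: Mapping[str, NormativeStats],
) -> PerformanceMetrics:
    """Fill z-scores and dials for every metric with available norms."""
    for mid, value in metrics.values().items():
        if mid in norms:
            z = zscore(value, norms[mid])
            metrics.z[mid] = z
            metrics.dial[mid] = dial_index(z)
    return metrics
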