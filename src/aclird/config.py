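"""Pipeline configuration.

Every tunable constant of the pipeline lives here so that a single YAML
file controls window lengths, filter bounds and tolerances end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    # --- gait-event detection ---
    lowpass_hz: float = 10.0           # zero-lag low-pass cutoff for pelvis signals
    lowpass_order: int = 4
    min_prominence: float = 0.1        # m/s, vertical-velocity minima
    min_separation_s: float = 0.2      # s, minimum spacing between contacts
    max_stance_s: float = 0.5          # s, cap on the stance window length

    # --- cut-angle algorithm ---
    candidate_step_k: int = 5          # steps before/after the current step
    plausibility_lo_deg: float = 10.0  # candidates outside [lo, hi] are discarded
    plausibility_hi_deg: float = 110.0
    speed_peak_prominence: float = 0.3       # m/s, resultant-speed extrema
    velocity_filter_first_pair_only: bool = False
    derivative_search_s: float = 1.0         # search window after the speed peak
    derivative_window_s: float = 0.5         # total eligibility width around the max
    derivative_peak_rel_prominence: float = 0.25  # of the derivative's range

    # --- performance ---
    entry_window_s: float = 2.0
    exit_window_s: float = 2.0

    # --- risk factors ---
    hk_subwindow_s: float = 0.1        # sub-window for the knee/hip ratio statistic
    threshold_tolerance_pct: float = 5.0
    tolerance_mode: str = "sigma"      # "sigma": thr = mu +/- (1+tol/100)*sigma
    asymmetry_denominator: str = "mean"  # or "max"

    # --- report ---
    stance_resample_points: int = 101

    def __post_init__(self) -> None:
        if self.lowpass_hz <= 0 or self.lowpass_order < 1:
            raise ParameterError("invalid low-pass filter settings")
        if self.plausibility_lo_deg >= self.plausibility_hi_deg:
            raise ParameterError("plausibility bounds must satisfy lo < hi")
        if self.tolerance_mode not in ("sigma", "threshold"):
            raise ParameterError(f"unknown tolerance_mode {self.tolerance_mode!r}")
        if self.asymmetry_denominator not in ("mean", "max"):
            raise ParameterError(
                f"unknown asymmetry_denominator {self.asymmetry_denominator!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = PipelineConfig()
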