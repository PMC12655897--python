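"""Nine-factor risk extraction, classification and aggregation.

Factor values are read for the stance (cutting) limb at one of two frames:
initial contact (IC) or peak knee flexion (pKF).  Eight factors are
instantaneous angles; HK is the ratio of the median knee-flexion angle to
the first quartile of the hip-flexion angle over a 100 ms sub-window
centered on the frame sample (clipped to the stance window).

A trial is at overall risk when at least 4 of the 9 factors are at risk
simultaneously; a category (SKL/KVC/TPI) is at risk when every one of its
factors is.  The deviation from a violated threshold is expressed as a
percentage of the threshold magnitude (100% = double or half the
threshold); for a zero threshold only the absolute deviation is reported
and the >100% "extreme" rule does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel_io import TrialKinematics
from .errors import InsufficientDataError, ParameterError
from .gait_events import FCWindow
from .normative import CATEGORIES, FACTOR_ORDER, ThresholdSet
from .synthgen import FACTOR_CHANNELS

__all__ = [
    "FactorValues", "FactorRiskRecord", "FactorRisk", "TrialRisk",
    "PlayerFactorSummary", "extract_factor_values", "classify_factors",
    "trial_risk", "player_summary", "cohort_summary", "color_bin",
]

COLOR_BINS = ("green", "yellow", "orange", "red")


@dataclass
class FactorValues:
    """The nine factor values for one trial at one frame (stance limb)."""

    frame: str                     # "IC" | "pKF"
    values: dict[str, float]       # factor id -> value
    sex: Optional[str] = None
    task: Optional[str] = None

    def __getitem__(self, factor: str) -> float:
        return self.values[factor]


@dataclass
class FactorRiskRecord:
    factor: str
    value: float
    at_risk: bool
    deviation_pct: Optional[float]  # None when the violated threshold is 0
    deviation_abs: float
    extreme: bool                   # deviation_pct > 100
    threshold_repr: str


@dataclass
class FactorRisk:
    frame: str
    records: dict[str, FactorRiskRecord]

    def __getitem__(self, factor: str) -> FactorRiskRecord:
        return self.records[factor]


@dataclass
class TrialRisk:
    frame: str
    n_factors_at_risk: int
    overall_at_risk: bool
    category_at_risk: dict[str, bool]


@dataclass
class FactorSummaryEntry:
    factor: str
    n_trials: int
    n_at_risk: int
    pct_trials_at_risk: float
    color_bin: str
    majority_flag: bool
    max_deviation_pct: Optional[float]
    max_deviation_trial: Optional[str]


@dataclass
class PlayerFactorSummary:
    frame: str
    n_trials: int
    entries: dict[str, FactorSummaryEntry]

    def __getitem__(self, factor: str) -> FactorSummaryEntry:
        return self.entries[factor]


def extract_factor_values(
    trial: TrialKinematics,
    window: FCWindow,
    frame: str,
    config: PipelineConfig = DEFAULT_CONFIG,
    sex: Optional[str] = None,
    task: Optional[str] = None,
) -> FactorValues:
    """Read the nine factor values at the IC or pKF frame of the stance."""
    if frame not in ("IC", "pKF"):
        raise ParameterError(f"frame must be 'IC' or 'pKF', got {frame!r}")
    sample = window.ic if frame == "IC" else window.pkf
    if not (window.start <= sample < window.end):
        raise ParameterError(
            f"{frame} sample {sample} outside stance window "
            f"[{window.start}, {window.end})"
        )
    side = window.stance_limb
    values: dict[str, float] = {}
    for factor, stem in FACTOR_CHANNELS.items():
        if stem.startswith("trunk"):
            values[factor] = float(trial.angle(stem)[sample])
        else:
            values[factor] = float(trial.angle(stem, side)[sample])

    half = int(round(0.5 * config.hk_subwindow_s * trial.sample_rate))
    a = max(window.start, sample - half)
    b = min(window.end, sample + half + 1)
    knee = trial.angle("knee_flex", side)[a:b]
    hip = trial.angle("hip_flex", side)[a:b]
    hip_q1 = float(np.percentile(hip, 25))
    if hip_q1 == 0.0:
        raise ParameterError("hip-flexion first quartile is zero; HK undefined")
    values["HK"] = float(np.median(knee)) / hip_q1
    return FactorValues(frame=frame, values=values, sex=sex, task=task)


def classify_factors(
    values: FactorValues, thresholds: ThresholdSet
) -> FactorRisk:
    """Classify each factor against its directional threshold."""
    if values.frame != thresholds.frame:
        raise ParameterError(
            f"frame mismatch: values {values.frame}, thresholds {thresholds.frame}"
        )
    if values.sex is not None and values.sex != thresholds.sex:
        raise ParameterError("sex stratum mismatch")
    if values.task is not None and values.task != thresholds.task:
        raise ParameterError("task stratum mismatch")

    records = {}
    for factor in FACTOR_ORDER:
        th = thresholds[factor]
        v = values[factor]
        if th.direction == "above":
            at_risk = v > th.value
            bound = th.value
            repr_ = f">{th.value:g}"
        elif th.direction == "below":
            at_risk = v < th.value
            bound = th.value
            repr_ = f"<{th.value:g}"
        else:  # outside: beyond either HA bound
            repr_ = f"outside[{th.lower:g},{th.upper:g}]"
            if v > th.upper:
                at_risk, bound = True, th.upper
            elif v < th.lower:
                at_risk, bound = True, th.lower
            else:
                at_risk, bound = False, th.upper
        dev_abs = abs(v - bound) if at_risk else 0.0
        if at_risk and bound != 0.0:
            dev_pct: Optional[float] = 100.0 * dev_abs / abs(bound)
        elif at_risk:
            dev_pct = None  # percent of a zero threshold is undefined
        else:
            dev_pct = 0.0
        extreme = dev_pct is not None and dev_pct > 100.0
        records[factor] = FactorRiskRecord(
            factor=factor, value=v, at_risk=at_risk,
            deviation_pct=dev_pct, deviation_abs=dev_abs,
            extreme=extreme, threshold_repr=repr_,
        )
    return FactorRisk(frame=values.frame, records=records)


def trial_risk(factor_risk: FactorRisk) -> TrialRisk:
    """Aggregate one trial's factor flags to overall and category risk."""
    if set(factor_risk.records) != set(FACTOR_ORDER):
        raise ParameterError("factor risk must cover all 9 factors")
    n = sum(1 for r in factor_risk.records.values() if r.at_risk)
    cats = {
        cat: all(factor_risk[f].at_risk for f in members)
        for cat, members in CATEGORIES.items()
    }
    return TrialRisk(
        frame=factor_risk.frame,
        n_factors_at_risk=n,
        overall_at_risk=n >= 4,
        category_at_risk=cats,
    )


def color_bin(pct: float) -> str:
    """Map a percentage of at-risk trials to the summary color bin:
    [0,20) green, [20,50] yellow, (50,70] orange, (70,100] red."""
    if not (0.0 <= pct <= 100.0):
        raise ParameterError(f"percentage out of range: {pct}")
    if pct < 20.0:
        return "green"
    if pct <= 50.0:
        return "yellow"
    if pct <= 70.0:
        return "orange"
    return "red"


def player_summary(
    factor_risks: Sequence[FactorRisk],
    frame: str,
    trial_ids: Optional[Sequence[str]] = None,
) -> PlayerFactorSummary:
    """Per-factor percentage of a player's trials at risk, with color bins,
    the majority flag (>= 50% of trials) and the largest deviation."""
    risks = [fr for fr in factor_risks if fr.frame == frame]
    if not risks:
        raise InsufficientDataError(f"no trials for frame {frame}")
    if trial_ids is None:
        trial_ids = [str(i + 1) for i in range(len(risks))]
    n = len(risks)
    entries = {}
    for factor in FACTOR_ORDER:
        flags = [fr[factor].at_risk for fr in risks]
        k = sum(flags)
        pct = 100.0 * k / n
        max_pct, max_tid = None, None
        for fr, tid in zip(risks, trial_ids):
            dp = fr[factor].deviation_pct
            if dp is not None and (max_pct is None or dp > max_pct):
                max_pct, max_tid = dp, tid
        entries[factor] = FactorSummaryEntry(
            factor=factor, n_trials=n, n_at_risk=k,
            pct_trials_at_risk=pct, color_bin=color_bin(pct),
            majority_flag=pct >= 50.0,
            max_deviation_pct=max_pct, max_deviation_trial=max_tid,
        )
    return PlayerFactorSummary(frame=frame, n_trials=n, entries=entries)


def cohort_summary(
    summaries: Sequence[PlayerFactorSummary],
) -> dict[str, dict[str, int]]:
    """Count players per color bin for every factor (counts partition the
    player set)."""
    if not summaries:
        raise InsufficientDataError("no player summaries")
    counts = {f: {c: 0 for c in COLOR_BINS} for f in FACTOR_ORDER}
    for summ in summaries:
        for factor in FACTOR_ORDER:
            counts[factor][summ[factor].color_bin] += 1
    return counts
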