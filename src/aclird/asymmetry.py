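"""Inter-limb sagittal-plane asymmetry and the 0-3 Asymmetry Score.

The per-joint limb summary is the peak sagittal angle inside the final
stance window, averaged over that limb's trials (sign preserved, so an
all-plantarflexed ankle yields a negative summary).  The asymmetry
percentage is the symmetric mean-normalized percent difference

    pct = 100 * |a_inj - a_non| / mean(|a_inj|, |a_non|)

which is scale-invariant and symmetric under limb exchange.  Score bins:
[0, 20) -> 0, [20, 50) -> 1, [50, 70) -> 2, [70, inf) -> 3.  A z-score of
the percentage above 3 against control asymmetry marks an extreme deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel_io import NormativeStats, TrialKinematics
from .errors import InsufficientDataError, ParameterError, UndefinedAsymmetryError
from .gait_events import FCWindow

__all__ = [
    "AsymmetryResult", "SAGITTAL_CHANNELS",
    "limb_summary", "asymmetry_percent", "asymmetry_score", "extreme_flag",
    "joint_asymmetry",
]

SAGITTAL_CHANNELS = {"hip": "hip_flex", "knee": "knee_flex", "ankle": "ankle_flex"}

SCORE_COLORS = {0: "green", 1: "yellow", 2: "orange", 3: "red"}


@dataclass
class AsymmetryResult:
    joint: str                    # "hip" | "knee" | "ankle"
    pct: float                    # >= 0
    direction: str                # injured_higher | noninjured_higher | equal
    score: int                    # 0..3
    extreme_flag: Optional[bool]  # None when no norms available
    injured_summary: float
    noninjured_summary: float


def limb_summary(
    trials: Sequence[tuple[TrialKinematics, FCWindow]], limb: str
) -> dict[str, float]:
    """Per-joint peak sagittal angle within the stance window, averaged over
    the given limb's trials."""
    if not trials:
        raise InsufficientDataError(f"no trials available for limb {limb!r}")
    out = {}
    for joint, stem in SAGITTAL_CHANNELS.items():
        peaks = [
            float(np.max(trial.angle(stem, limb)[w.start:w.end]))
            for trial, w in trials
        ]
        out[joint] = float(np.mean(peaks))
    return out


def asymmetry_percent(
    a_injured: float,
    a_noninjured: float,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[float, str]:
    """Symmetric percent difference between limb summaries, plus which limb
    shows the higher value."""
    if a_injured == 0.0 and a_noninjured == 0.0:
        raise UndefinedAsymmetryError("both limb summaries are zero")
    if config.asymmetry_denominator == "max":
        denom = max(abs(a_injured), abs(a_noninjured))
    else:
        denom = 0.5 * (abs(a_injured) + abs(a_noninjured))
    pct = 100.0 * abs(a_injured - a_noninjured) / denom
    if a_injured > a_noninjured:
        direction = "injured_higher"
    elif a_injured < a_noninjured:
        direction = "noninjured_higher"
    else:
        direction = "equal"
    return pct, direction


def asymmetry_score(pct: float) -> int:
    """Bin the asymmetry percentage to the 0-3 Asymmetry Score."""
    if pct < 0:
        raise ParameterError(f"asymmetry percentage must be >= 0, got {pct}")
    if pct < 20.0:
        return 0
    if pct < 50.0:
        return 1
    if pct < 70.0:
        return 2
    return 3


def extreme_flag(pct: float, norms: NormativeStats) -> bool:
    """True when the asymmetry percentage deviates more than 3 SD above the
    healthy-control asymmetry."""
    if norms.sigma <= 0:
        raise ParameterError("sigma must be positive")
    return (pct - norms.mu) / norms.sigma > 3.0


def joint_asymmetry(
    injured_trials: Sequence[tuple[TrialKinematics, FCWindow]],
    noninjured_trials: Sequence[tuple[TrialKinematics, FCWindow]],
    injured_limb: str,
    noninjured_limb: str,
    norms: Optional[dict[str, NormativeStats]] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[AsymmetryResult]:
    """Full per-joint asymmetry assessment for one player."""
    inj = limb_summary(injured_trials, injured_limb)
    non = limb_summary(noninjured_trials, noninjured_limb)
    results = []
    for joint in SAGITTAL_CHANNELS:
        pct, direction = asymmetry_percent(inj[joint], non[joint], config)
        flag = None
        if norms and joint in norms:
            flag = extreme_flag(pct, norms[joint])
        results.append(AsymmetryResult(
            joint=joint, pct=pct, direction=direction,
            score=asymmetry_score(pct), extreme_flag=flag,
            injured_summary=inj[joint], noninjured_summary=non[joint],
        ))
    return results
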