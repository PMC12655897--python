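"""Risk-factor threshold construction and the bundled reference table.

Nine factors across three categories:

* SKL (sagittal knee loading): HK (knee/hip flexion ratio), HF, KF, AF
* KVC (knee valgus collapse): KV, HA (two-sided), HI
* TPI (trunk-pelvis imbalance): TIB, TCR

A factor is directional: "above" flags values exceeding the threshold,
"below" flags values under it, and HA is two-sided ("outside" its
abduction/adduction band).  Thresholds are stratified by sex x task x frame
(8 strata).  Cohort-derived thresholds are ``mu +/- (1 + tol/100) * sigma``
of the healthy-control factor values; the conservative tolerance (default
5%) inflates sigma rather than the threshold, which stays well-defined for
near-zero thresholds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel_io import SEXES, TASKS
from .errors import InsufficientDataError, ParameterError

__all__ = [
    "FACTOR_ORDER", "CATEGORIES", "FACTOR_DIRECTIONS", "FACTOR_UNITS",
    "FactorThreshold", "ThresholdSet", "ThresholdLibrary",
    "bundled_thresholds", "derive_thresholds",
    "library_to_csv_text", "load_threshold_table",
]

FRAMES = ("IC", "pKF")

FACTOR_ORDER = ("HK", "HF", "KF", "AF", "KV", "HA", "HI", "TIB", "TCR")

CATEGORIES = {
    "SKL": ("HK", "HF", "KF", "AF"),
    "KVC": ("KV", "HA", "HI"),
    "TPI": ("TIB", "TCR"),
}

FACTOR_DIRECTIONS = {
    "HK": "above", "HF": "above", "KF": "below", "AF": "below",
    "KV": "above", "HA": "outside", "HI": "above",
    "TIB": "above", "TCR": "above",
}

FACTOR_UNITS = {f: ("ratio" if f == "HK" else "degrees") for f in FACTOR_ORDER}


@dataclass(frozen=True)
class FactorThreshold:
    factor: str
    direction: str                 # "above" | "below" | "outside"
    value: Optional[float] = None  # one-sided bound
    lower: Optional[float] = None  # two-sided ("outside") only
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction == "outside":
            if self.lower is None or self.upper is None or self.lower >= self.upper:
                raise ParameterError(
                    f"two-sided factor {self.factor} needs lower < upper bounds"
                )
        elif self.direction in ("above", "below"):
            if self.value is None:
                raise ParameterError(f"factor {self.factor} needs a threshold value")
        else:
            raise ParameterError(f"unknown direction {self.direction!r}")


@dataclass
class ThresholdSet:
    sex: str
    task: str
    frame: str
    thresholds: dict[str, FactorThreshold]

    def __post_init__(self) -> None:
        missing = set(FACTOR_ORDER) - set(self.thresholds)
        if missing:
            raise ParameterError(f"threshold set incomplete, missing {sorted(missing)}")

    def __getitem__(self, factor: str) -> FactorThreshold:
        return self.thresholds[factor]


@dataclass
class ThresholdLibrary:
    sets: dict[tuple[str, str, str], ThresholdSet]
    provenance: str = "cohort_derived"   # or "bundled"

    def get(self, sex: str, task: str, frame: str) -> ThresholdSet:
        key = (sex, task, frame)
        if key not in self.sets:
            raise ParameterError(f"no thresholds for stratum {key}")
        return self.sets[key]

    @property
    def complete(self) -> bool:
        return all((s, t, f) in self.sets
                   for s in SEXES for t in TASKS for f in FRAMES)


# Bundled reference thresholds: one row per factor, columns ordered as
# (male AGTT IC, male AGTT pKF, male FS IC, male FS pKF,
#  female AGTT IC, female AGTT pKF, female FS IC, female FS pKF).
_BUNDLED = {
    "HK":  (0.7, 0.4, 0.0, 0.1, 0.6, 0.4, 0.0, 0.1),
    "HF":  (43.5, 46.0, 41.4, 31.0, 43.9, 44.8, 33.8, 26.6),
    "KF":  (32.2, 65.0, 26.2, 78.8, 31.7, 64.2, 24.8, 77.9),
    "AF":  (-10.7, -16.6, -22.8, -23.8, -10.9, -16.5, -23.1, -21.5),
    "KV":  (2.3, 1.4, 2.2, 2.4, 2.0, 2.1, 2.1, 3.2),
    "HA_upper": (10.3, 10.4, 8.1, 8.0, 9.9, 9.8, 8.0, 7.9),
    "HA_lower": (-7.8, -7.5, -2.9, -6.4, -10.0, -10.9, -7.0, -7.4),
    "HI":  (14.5, 10.4, 10.2, 10.2, 13.8, 10.9, 12.4, 10.5),
    "TIB": (10.3, 8.6, 8.6, 7.1, 8.7, 8.3, 9.7, 8.0),
    "TCR": (7.3, 4.4, 6.5, 5.6, 5.6, 4.9, 7.3, 5.3),
}

_STRATA = tuple(
    (sex, task, frame) for sex in SEXES for task in TASKS for frame in FRAMES
)
# column order of _BUNDLED matches _STRATA because SEXES=(male, female),
# TASKS=(AGTT, FS), FRAMES=(IC, pKF)


def bundled_thresholds() -> ThresholdLibrary:
    """The published reference threshold library (all 8 strata, 9 factors)."""
    sets = {}
    for col, (sex, task, frame) in enumerate(_STRATA):
        thr = {}
        for factor in FACTOR_ORDER:
            if factor == "HA":
                thr[factor] = FactorThreshold(
                    "HA", "outside",
                    lower=_BUNDLED["HA_lower"][col],
                    upper=_BUNDLED["HA_upper"][col],
                )
            else:
                thr[factor] = FactorThreshold(
                    factor, FACTOR_DIRECTIONS[factor], value=_BUNDLED[factor][col]
                )
        sets[(sex, task, frame)] = ThresholdSet(sex, task, frame, thr)
    return ThresholdLibrary(sets=sets, provenance="bundled")


def derive_thresholds(
    control_factor_values: Mapping[tuple[str, str, str], Mapping[str, Sequence[float]]],
    tolerance_pct: float = 5.0,
) -> ThresholdLibrary:
    """Build thresholds from healthy-control factor observations.

    ``control_factor_values`` maps each (sex, task, frame) stratum to a
    mapping factor -> list of control observations.
    """
    k = 1.0 + tolerance_pct / 100.0
    sets = {}
    for stratum, per_factor in control_factor_values.items():
        sex, task, frame = stratum
        thr = {}
        for factor in FACTOR_ORDER:
            values = np.asarray(per_factor.get(factor, ()), dtype=float)
            if values.size < 2:
                raise InsufficientDataError(
                    f"stratum {stratum}, factor {factor}: "
                    f"{values.size} control observation(s), need >= 2"
                )
            mu = float(np.mean(values))
            sd = float(np.std(values, ddof=1))
            if sd <= 0:
                raise InsufficientDataError(
                    f"stratum {stratum}, factor {factor}: zero variance"
                )
            direction = FACTOR_DIRECTIONS[factor]
            if direction == "above":
                thr[factor] = FactorThreshold(factor, "above", value=mu + k * sd)
            elif direction == "below":
                thr[factor] = FactorThreshold(factor, "below", value=mu - k * sd)
            else:
                thr[factor] = FactorThreshold(
                    factor, "outside", lower=mu - k * sd, upper=mu + k * sd
                )
        sets[stratum] = ThresholdSet(sex, task, frame, thr)
    return ThresholdLibrary(sets=sets, provenance="cohort_derived")


def _rows(library: ThresholdLibrary):
    for (sex, task, frame) in sorted(library.sets):
        ts = library.sets[(sex, task, frame)]
        for factor in FACTOR_ORDER:
            th = ts[factor]
            if th.direction == "outside":
                yield (sex, task, frame, factor, "above", th.upper)
                yield (sex, task, frame, factor, "below", th.lower)
            else:
                yield (sex, task, frame, factor, th.direction, th.value)


def library_to_csv_text(library: ThresholdLibrary) -> str:
    """Serialize a library to the flat delimited threshold-table format."""
    buf = io.StringIO()
    buf.write("sex,task,frame,factor,direction,value\n")
    for sex, task, frame, factor, direction, value in _rows(library):
        buf.write(f"{sex},{task},{frame},{factor},{direction},{float(value)!r}\n")
    return buf.getvalue()


def save_threshold_table(library: ThresholdLibrary, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(library_to_csv_text(library))
    return path


def load_threshold_table(path: str | Path) -> ThresholdLibrary:
    """Load a flat threshold table (sex, task, frame, factor, direction, value)."""
    df = pd.read_csv(path)
    sets: dict[tuple[str, str, str], dict[str, FactorThreshold]] = {}
    grouped: dict[tuple, dict[str, dict[str, float]]] = {}
    for row in df.itertuples(index=False):
        key = (row.sex, row.task, row.frame)
        grouped.setdefault(key, {}).setdefault(row.factor, {})[row.direction] = (
            float(row.value)
        )
    for key, factors in grouped.items():
        thr = {}
        for factor, dirs in factors.items():
            if FACTOR_DIRECTIONS.get(factor) == "outside":
                if "above" not in dirs or "below" not in dirs:
                    raise ParameterError(
                        f"two-sided factor {factor} needs both bounds in {key}"
                    )
                thr[factor] = FactorThreshold(
                    factor, "outside", lower=dirs["below"], upper=dirs["above"]
                )
            else:
                direction, value = next(iter(dirs.items()))
                thr[factor] = FactorThreshold(factor, direction, value=value)
        sets[key] = ThresholdSet(key[0], key[1], key[2], thr)
    return ThresholdLibrary(sets=sets, provenance="cohort_derived")
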