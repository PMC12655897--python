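"""Shared data model and trial file I/O.

One trial is stored as a single comma-separated text file: a ``#``-prefixed
``key=value`` metadata header block followed by one header row and a wide
numeric table.  Column schema (units s, m, m/s, degrees)::

    time,
    pelvis_pos_x, pelvis_pos_y, pelvis_pos_z,
    pelvis_vel_x, pelvis_vel_y, pelvis_vel_z,        (velocity optional)
    hip_flex_l, hip_flex_r, hip_abd_l, hip_abd_r, hip_rot_l, hip_rot_r,
    knee_flex_l, knee_flex_r, knee_valgus_l, knee_valgus_r,
    ankle_flex_l, ankle_flex_r,
    trunk_lat_bend, trunk_rot

Sign conventions are fixed package-wide and enforced here:

* flexion positive, knee valgus positive,
* hip abduction positive / adduction negative,
* hip internal rotation positive,
* ankle dorsiflexion positive / plantarflexion negative,
* trunk lateral bending positive toward the cutting limb,
* trunk rotation positive away from the cutting limb.

Pelvis position is expressed in a ground-fixed frame with X anteroposterior,
Y mediolateral and Z vertical (up).  All indices are 0-based and windows are
half-open ``[start, end)``.  Missing samples are never interpolated: any NaN
fails validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SchemaError

SEXES = ("male", "female")
TASKS = ("AGTT", "FS")
LIMBS = ("left", "right")

ANGLE_CHANNELS = (
    "hip_flex_l", "hip_flex_r",
    "hip_abd_l", "hip_abd_r",
    "hip_rot_l", "hip_rot_r",
    "knee_flex_l", "knee_flex_r",
    "knee_valgus_l", "knee_valgus_r",
    "ankle_flex_l", "ankle_flex_r",
    "trunk_lat_bend", "trunk_rot",
)

POS_COLUMNS = ("pelvis_pos_x", "pelvis_pos_y", "pelvis_pos_z")
VEL_COLUMNS = ("pelvis_vel_x", "pelvis_vel_y", "pelvis_vel_z")

#: minimum trial duration in seconds (the entry window preceding the final
#: foot stance spans 2 s, so anything shorter cannot be analyzed).
MIN_DURATION_S = 2.0

TIME_UNIFORMITY_TOL_S = 1e-6


@dataclass
class TrialKinematics:
    """Synchronized joint-angle and pelvis time series for one cut trial."""

    sample_rate: float
    t: np.ndarray                  # (n,) seconds, strictly increasing, uniform
    pelvis_pos: np.ndarray         # (n, 3) meters, ground-fixed, Z up
    pelvis_vel: np.ndarray         # (n, 3) m/s
    angles: dict[str, np.ndarray]  # channel name -> (n,) degrees

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def angle(self, joint: str, side: Optional[str] = None) -> np.ndarray:
        """Return an angle channel; ``side`` is 'left'/'right' for limb joints."""
        if side is None:
            key = joint
        else:
            key = f"{joint}_{side[0]}"
        if key not in self.angles:
            raise ParameterError(f"unknown angle channel {key!r}")
        return self.angles[key]

    def horizontal_speed(self) -> np.ndarray:
        """Resultant pelvis speed in the horizontal (XY) plane, m/s."""
        return np.hypot(self.pelvis_vel[:, 0], self.pelvis_vel[:, 1])

    def mirrored(self) -> "TrialKinematics":
        """Left/right mirrored copy: limb channels swapped, pelvis Y negated."""
        sw = {}
        for key, arr in self.angles.items():
            if key.endswith("_l"):
                sw[key[:-2] + "_r"] = arr.copy()
            elif key.endswith("_r"):
                sw[key[:-2] + "_l"] = arr.copy()
            else:
                sw[key] = arr.copy()
        pos = self.pelvis_pos.copy()
        vel = self.pelvis_vel.copy()
        pos[:, 1] *= -1.0
        vel[:, 1] *= -1.0
        return TrialKinematics(self.sample_rate, self.t.copy(), pos, vel, sw)


@dataclass
class TrialMeta:
    """Per-trial acquisition metadata."""

    player_id: str
    sex: str                 # "male" | "female"
    task: str                # "AGTT" | "FS"
    cut_limb: str            # "left" | "right"
    injured_limb: str        # "left" | "right" | "none"
    trial_index: int
    age: Optional[float] = None
    months_post_surgery: Optional[float] = None


@dataclass
class NormativeStats:
    """Mean/SD of one metric over a healthy-control stratum."""

    metric_id: str
    mu: float
    sigma: float
    n: int
    sex: str
    task: str
    frame: Optional[str] = None  # "IC" | "pKF" where the metric is frame-bound

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0 for {self.metric_id}")
        if self.n < 2:
            raise ParameterError(f"n must be >= 2 for {self.metric_id}")


@dataclass
class ValidationReport:
    ok: bool
    issues: list[tuple[str, str]] = field(default_factory=list)


def _meta_to_header(meta: TrialMeta) -> list[str]:
    lines = [
        f"# player_id={meta.player_id}",
        f"# sex={meta.sex}",
        f"# task={meta.task}",
        f"# cut_limb={meta.cut_limb}",
        f"# injured_limb={meta.injured_limb}",
        f"# trial_index={meta.trial_index}",
    ]
    if meta.age is not None:
        lines.append(f"# age={meta.age!r}")
    if meta.months_post_surgery is not None:
        lines.append(f"# months_post_surgery={meta.months_post_surgery!r}")
    return lines


def _parse_meta(pairs: dict[str, str], source: str) -> TrialMeta:
    required = ("player_id", "sex", "task", "cut_limb", "injured_limb", "trial_index")
    for key in required:
        if key not in pairs:
            raise SchemaError(f"metadata key {key!r} missing in {source}")
    return TrialMeta(
        player_id=pairs["player_id"],
        sex=pairs["sex"],
        task=pairs["task"],
        cut_limb=pairs["cut_limb"],
        injured_limb=pairs["injured_limb"],
        trial_index=int(pairs["trial_index"]),
        age=float(pairs["age"]) if "age" in pairs else None,
        months_post_surgery=(
            float(pairs["months_post_surgery"])
            if "months_post_surgery" in pairs else None
        ),
    )


def read_trial(path: str | Path) -> tuple[TrialKinematics, TrialMeta]:
    """Read one trial CSV (with embedded ``#`` metadata header or a
    ``<stem>.meta`` sidecar of ``key=value`` lines)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    pairs: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                pairs[k.strip()] = v.strip()
    sidecar = path.with_suffix(".meta")
    if not pairs and sidecar.exists():
        for line in sidecar.read_text().splitlines():
            line = line.strip()
            if line and "=" in line and not line.startswith("#"):
                k, v = line.split("=", 1)
                pairs[k.strip()] = v.strip()
    meta = _parse_meta(pairs, str(path))

    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed numeric table
        raise FormatError(f"could not parse {path}: {exc}") from exc

    for col in ("time",) + POS_COLUMNS + ANGLE_CHANNELS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing in {path}")

    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: at least 2 samples required")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time must be strictly increasing")
    if np.max(np.abs(dt - dt[0])) > TIME_UNIFORMITY_TOL_S:
        raise FormatError(f"{path}: non-uniform time step (tolerance 1e-6 s)")
    sample_rate = 1.0 / float(np.mean(dt))

    pos = df[list(POS_COLUMNS)].to_numpy(dtype=float)
    vel = np.empty_like(pos)
    for axis, col in enumerate(VEL_COLUMNS):
        if col in df.columns:
            vel[:, axis] = df[col].to_numpy(dtype=float)
        else:
            # central differences of position (one-sided at the edges)
            vel[:, axis] = np.gradient(pos[:, axis], t)

    angles = {c: df[c].to_numpy(dtype=float) for c in ANGLE_CHANNELS}
    trial = TrialKinematics(sample_rate, t, pos, vel, angles)
    return trial, meta


def write_trial(trial: TrialKinematics, meta: TrialMeta, path: str | Path) -> Path:
    """Write one trial to a CSV with an embedded metadata header.

    Numeric fields survive a write/read round trip to 1e-9 relative tolerance
    (17 significant digits are emitted).
    """
    report = validate_trial(trial, meta)
    if not report.ok:
        raise ParameterError(
            "refusing to write invalid trial: "
            + "; ".join(f"{c}: {m}" for c, m in report.issues)
        )
    path = Path(path)
    data = {"time": trial.t}
    for axis, col in enumerate(POS_COLUMNS):
        data[col] = trial.pelvis_pos[:, axis]
    for axis, col in enumerate(VEL_COLUMNS):
        data[col] = trial.pelvis_vel[:, axis]
    for col in ANGLE_CHANNELS:
        data[col] = trial.angles[col]
    df = pd.DataFrame(data)
    header = "\n".join(_meta_to_header(meta)) + "\n"
    try:
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write trial to {path}: {exc}") from exc
    return path


def validate_trial(trial: TrialKinematics, meta: TrialMeta) -> ValidationReport:
    """Check every data-model invariant; issues are reported, never raised."""
    issues: list[tuple[str, str]] = []

    if not trial.sample_rate > 0:
        issues.append(("sample_rate", "sample_rate must be > 0"))
        return ValidationReport(False, issues)

    n = trial.n_samples
    series = {"time": trial.t}
    for axis, col in enumerate(POS_COLUMNS):
        series[col] = trial.pelvis_pos[:, axis]
    for axis, col in enumerate(VEL_COLUMNS):
        series[col] = trial.pelvis_vel[:, axis]
    series.update(trial.angles)

    for name, arr in series.items():
        arr = np.asarray(arr)
        if arr.ndim != 1 or arr.shape[0] != n:
            issues.append(("length", f"series {name!r} length {arr.shape} != {n}"))
            continue
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            issues.append(
                ("nonfinite", f"non-finite value in {name!r} at index {bad[0]}")
            )

    if n < 2:
        issues.append(("n_samples", "at least 2 samples required"))
    else:
        dt = np.diff(trial.t)
        if np.any(dt <= 0):
            issues.append(("time", "time must be strictly increasing"))
        elif np.max(np.abs(dt - dt[0])) > TIME_UNIFORMITY_TOL_S:
            issues.append(("time", "time step not uniform (tolerance 1e-6 s)"))

    if trial.duration_s < MIN_DURATION_S:
        issues.append(
            ("duration",
             f"trial {trial.duration_s:.3f} s too short for 2 s entry window")
        )

    if meta.sex not in SEXES:
        issues.append(("meta", f"sex {meta.sex!r} not in {SEXES}"))
    if meta.task not in TASKS:
        issues.append(("meta", f"task {meta.task!r} not in {TASKS}"))
    if meta.cut_limb not in LIMBS:
        issues.append(("meta", f"cut_limb {meta.cut_limb!r} not in {LIMBS}"))
    if meta.injured_limb not in LIMBS + ("none",):
        issues.append(("meta", f"injured_limb {meta.injured_limb!r} invalid"))
    if meta.trial_index < 1:
        issues.append(("meta", "trial_index must be a positive integer"))

    return ValidationReport(ok=not issues, issues=issues)


def read_norms_table(path: str | Path) -> list[NormativeStats]:
    """Load a delimited normative-statistics table
    (metric_id, sex, task, frame, mu, sigma, n)."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        frame = getattr(row, "frame", None)
        if frame is not None and (pd.isna(frame) or frame == ""):
            frame = None
        out.append(NormativeStats(
            metric_id=row.metric_id, mu=float(row.mu), sigma=float(row.sigma),
            n=int(row.n), sex=row.sex, task=row.task, frame=frame,
        ))
    return out


def write_norms_table(norms: list[NormativeStats], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [{"metric_id": s.metric_id, "sex": s.sex, "task": s.task,
          "frame": s.frame or "", "mu": s.mu, "sigma": s.sigma, "n": s.n}
         for s in norms]
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path
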