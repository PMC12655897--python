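"""Per-player report assembly, rendering and the end-to-end pipeline.

The machine-readable report is a single JSON document holding every number
(the acceptance surface); the HTML rendering is presentation-only and never
computes anything — each displayed number is formatted from the JSON data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .asymmetry import joint_asymmetry
from .config import DEFAULT_CONFIG, PipelineConfig
from .cut_angle import compute_cut_angle
from .datamodel_io import (
    NormativeStats, TrialKinematics, TrialMeta, read_trial, validate_trial,
)
from .errors import (
    AclIrdError, ParameterError, ReportError,
)
from .gait_events import FCWindow, detect_foot_contacts, locate_fc_window
from .normative import CATEGORIES, FACTOR_ORDER, ThresholdLibrary
from .performance import attach_norms, extract_performance
from .risk import (
    FactorRisk, classify_factors, cohort_summary, extract_factor_values,
    player_summary, trial_risk,
)

SCHEMA_VERSION = "1.0"

FRAMES = ("IC", "pKF")


def _clean(obj):
    """Recursively convert numpy scalars/arrays to plain JSON types."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_clean(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def format_number(x) -> str:
    """Canonical display formatting used by the HTML renderer."""
    if isinstance(x, bool):
        return "yes" if x else "no"
    if isinstance(x, int):
        return str(x)
    return f"{x:.2f}"


@dataclass
class PlayerReport:
    """Six-section per-player aggregate."""

    player_id: str
    schema_version: str
    personal: dict
    cod: dict
    performance: dict
    kinematics: dict
    risk: dict
    remarks: str = ""

    def to_dict(self) -> dict:
        return _clean({
            "schema_version": self.schema_version,
            "player_id": self.player_id,
            "section1_personal": self.personal,
            "section2_cod": self.cod,
            "section3_performance": self.performance,
            "section4_kinematics": self.kinematics,
            "section5_risk": self.risk,
            "section6_remarks": self.remarks,
        })

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PlayerReport":
        return cls(
            player_id=d["player_id"],
            schema_version=d["schema_version"],
            personal=d["section1_personal"],
            cod=d["section2_cod"],
            performance=d["section3_performance"],
            kinematics=d["section4_kinematics"],
            risk=d["section5_risk"],
            remarks=d["section6_remarks"],
        )

    @classmethod
    def from_json(cls, text: str) -> "PlayerReport":
        return cls.from_dict(json.loads(text))


@dataclass
class CohortReport:
    n_players: int
    factor_color_counts: dict   # task -> frame -> factor -> color -> count
    overall_risk: dict          # task -> frame -> {n_trials, n_at_risk,
                                #                   injured, noninjured}

    def to_dict(self) -> dict:
        return _clean({
            "schema_version": SCHEMA_VERSION,
            "n_players": self.n_players,
            "factor_color_counts": self.factor_color_counts,
            "overall_risk": self.overall_risk,
        })

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


@dataclass
class TrialAnalysis:
    """All per-trial pipeline outputs for one analyzable trial."""

    trial_id: str
    trial: TrialKinematics
    meta: TrialMeta
    window: FCWindow
    cut_angle_deg: float
    factor_risks: dict[str, FactorRisk]    # frame -> FactorRisk
    trial_risks: dict[str, object]         # frame -> TrialRisk
    performance: object


def _trial_id(meta: TrialMeta) -> str:
    return f"{meta.task}-{meta.trial_index:02d}-{meta.cut_limb}"


def analyze_trial(
    trial: TrialKinematics,
    meta: TrialMeta,
    thresholds: ThresholdLibrary,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> TrialAnalysis:
    """Run the per-trial chain: events -> cut angle -> window -> metrics."""
    contacts = detect_foot_contacts(trial, config)
    result = compute_cut_angle(trial, contacts, config)
    window = locate_fc_window(trial, contacts, result.final_sample,
                              meta.cut_limb, config)
    perf = extract_performance(trial, window, config)
    frs, trs = {}, {}
    for frame in FRAMES:
        values = extract_factor_values(trial, window, frame, config,
                                       sex=meta.sex, task=meta.task)
        fr = classify_factors(values, thresholds.get(meta.sex, meta.task, frame))
        frs[frame] = fr
        trs[frame] = trial_risk(fr)
    return TrialAnalysis(
        trial_id=_trial_id(meta), trial=trial, meta=meta, window=window,
        cut_angle_deg=result.final_angle_deg, factor_risks=frs,
        trial_risks=trs, performance=perf,
    )


def _resample_curve(y: np.ndarray, n_points: int) -> np.ndarray:
    x_old = np.linspace(0.0, 1.0, y.shape[0])
    x_new = np.linspace(0.0, 1.0, n_points)
    return np.interp(x_new, x_old, y)


def _stance_curves(
    analyses: Sequence[TrialAnalysis], limb: str, n_points: int
) -> dict[str, list[float]]:
    from .asymmetry import SAGITTAL_CHANNELS
    curves = {}
    for joint, stem in SAGITTAL_CHANNELS.items():
        resampled = [
            _resample_curve(
                a.trial.angle(stem, limb)[a.window.start:a.window.end], n_points
            )
            for a in analyses
        ]
        curves[joint] = np.mean(resampled, axis=0).tolist()
    return curves


def build_player_report(
    trials: Sequence[tuple[TrialKinematics, TrialMeta]],
    thresholds: ThresholdLibrary,
    norms: Optional[Sequence[NormativeStats]] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> PlayerReport:
    """Aggregate all pipeline outputs for one player into the six sections.

    Trials that fail validation or cut detection are listed in section 1
    (with the failing stage) and excluded from sections 2-5.
    """
    if not trials:
        raise ReportError("no trials supplied")
    metas = [m for _, m in trials]
    player_id = metas[0].player_id
    if any(m.player_id != player_id for m in metas):
        raise ReportError("trials belong to different players")
    sex = metas[0].sex
    injured = metas[0].injured_limb

    norm_index: dict[tuple[str, str, str], NormativeStats] = {}
    for stat in norms or ():
        norm_index[(stat.metric_id, stat.sex, stat.task)] = stat

    analyses: list[TrialAnalysis] = []
    excluded: list[dict] = []
    for trial, meta in trials:
        tid = _trial_id(meta)
        vr = validate_trial(trial, meta)
        if not vr.ok:
            excluded.append({"trial_id": tid, "stage": "validation",
                             "detail": "; ".join(m for _, m in vr.issues)})
            continue
        try:
            analyses.append(analyze_trial(trial, meta, thresholds, config))
        except AclIrdError as exc:
            stage = getattr(exc, "stage", type(exc).__name__)
            excluded.append({"trial_id": tid, "stage": str(stage),
                             "detail": str(exc)})
    if not analyses:
        raise ReportError(
            f"player {player_id}: no analyzable trial "
            f"({len(excluded)} excluded)"
        )

    tasks = sorted({a.meta.task for a in analyses})
    by_task = {task: [a for a in analyses if a.meta.task == task]
               for task in tasks}

    # --- section 1: personal ---
    personal = {
        "player_id": player_id,
        "sex": sex,
        "injured_limb": injured,
        "age": metas[0].age,
        "months_post_surgery": metas[0].months_post_surgery,
        "n_trials_recorded": len(trials),
        "n_trials_analyzed": len(analyses),
        "trials_per_task": {
            task: {
                "n": len(items),
                "left": sum(1 for a in items if a.meta.cut_limb == "left"),
                "right": sum(1 for a in items if a.meta.cut_limb == "right"),
            }
            for task, items in by_task.items()
        },
        "excluded_trials": excluded,
    }

    # --- section 2: change of direction ---
    cod = {}
    for task, items in by_task.items():
        angles = [a.cut_angle_deg for a in items]
        cod[task] = {
            "trials": [
                {"trial_id": a.trial_id, "cut_limb": a.meta.cut_limb,
                 "cut_angle_deg": a.cut_angle_deg,
                 "fc_window_duration_s": a.window.duration_s}
                for a in items
            ],
            "mean_cut_angle_deg": float(np.mean(angles)),
            "sd_cut_angle_deg": float(np.std(angles, ddof=1)) if len(angles) > 1
            else 0.0,
        }

    # --- section 3: performance ---
    performance = {}
    for task, items in by_task.items():
        rows = []
        for a in items:
            perf = a.performance
            task_norms = {
                mid: stat for (mid, s, t), stat in norm_index.items()
                if s == sex and t == task
            }
            attach_norms(perf, task_norms)
            rows.append({
                "trial_id": a.trial_id,
                "metrics": perf.values(),
                "exit_clipped": perf.exit_clipped,
                "z": dict(perf.z),
                "dial": dict(perf.dial),
            })
        performance[task] = {"trials": rows}

    # --- section 4: kinematics (asymmetry + stance curves) ---
    inj_limb = injured if injured in ("left", "right") else "left"
    non_limb = "right" if inj_limb == "left" else "left"
    kinematics = {"limb_labels": {"injured": inj_limb, "noninjured": non_limb}}
    for task, items in by_task.items():
        inj_trials = [(a.trial, a.window) for a in items
                      if a.meta.cut_limb == inj_limb]
        non_trials = [(a.trial, a.window) for a in items
                      if a.meta.cut_limb == non_limb]
        entry: dict = {"asymmetry": None, "curves": {}}
        if inj_trials and non_trials:
            asym_norms = {}
            for joint in ("hip", "knee", "ankle"):
                key = (f"asym_{joint}", sex, task)
                if key in norm_index:
                    asym_norms[joint] = norm_index[key]
            results = joint_asymmetry(inj_trials, non_trials, inj_limb,
                                      non_limb, asym_norms or None, config)
            entry["asymmetry"] = [
                {"joint": r.joint, "pct": r.pct, "direction": r.direction,
                 "score": r.score, "extreme_flag": r.extreme_flag,
                 "injured_summary": r.injured_summary,
                 "noninjured_summary": r.noninjured_summary}
                for r in results
            ]
        n_pts = config.stance_resample_points
        inj_items = [a for a in items if a.meta.cut_limb == inj_limb]
        non_items = [a for a in items if a.meta.cut_limb == non_limb]
        if inj_items:
            entry["curves"]["injured"] = _stance_curves(inj_items, inj_limb, n_pts)
        if non_items:
            entry["curves"]["noninjured"] = _stance_curves(non_items, non_limb,
                                                           n_pts)
        kinematics[task] = entry

    # --- section 5: risk factors ---
    risk_section = {}
    for task, items in by_task.items():
        task_entry = {}
        for frame in FRAMES:
            frs = [a.factor_risks[frame] for a in items]
            trs = [a.trial_risks[frame] for a in items]
            tids = [a.trial_id for a in items]
            summ = player_summary(frs, frame, tids)
            n = len(items)
            n_overall = sum(1 for tr in trs if tr.overall_at_risk)
            inj_overall = sum(
                1 for a, tr in zip(items, trs)
                if tr.overall_at_risk and a.meta.cut_limb == injured
            )
            cat_dash = {}
            for cat in CATEGORIES:
                k = sum(1 for tr in trs if tr.category_at_risk[cat])
                cat_dash[cat] = {
                    "at_risk": k > 0,
                    "n_trials_at_risk": k,
                    "pct_trials_at_risk": 100.0 * k / n,
                }
            task_entry[frame] = {
                "trials": [
                    {
                        "trial_id": tid,
                        "n_factors_at_risk": tr.n_factors_at_risk,
                        "overall_at_risk": tr.overall_at_risk,
                        "factors": {
                            f: {
                                "value": fr[f].value,
                                "threshold": fr[f].threshold_repr,
                                "at_risk": fr[f].at_risk,
                                "deviation_pct": fr[f].deviation_pct,
                                "deviation_abs": fr[f].deviation_abs,
                                "extreme": fr[f].extreme,
                            }
                            for f in FACTOR_ORDER
                        },
                    }
                    for tid, fr, tr in zip(tids, frs, trs)
                ],
                "factor_summary": {
                    f: {
                        "n_at_risk": summ[f].n_at_risk,
                        "pct_trials_at_risk": summ[f].pct_trials_at_risk,
                        "color_bin": summ[f].color_bin,
                        "majority_flag": summ[f].majority_flag,
                        "max_deviation_pct": summ[f].max_deviation_pct,
                        "max_deviation_trial": summ[f].max_deviation_trial,
                    }
                    for f in FACTOR_ORDER
                },
                "category_dashboard": cat_dash,
                "overall": {
                    "n_trials": n,
                    "n_at_risk": n_overall,
                    "pct_at_risk": 100.0 * n_overall / n,
                    "injured_limb_at_risk": inj_overall,
                    "noninjured_limb_at_risk": n_overall - inj_overall,
                },
            }
        risk_section[task] = task_entry

    return PlayerReport(
        player_id=player_id,
        schema_version=SCHEMA_VERSION,
        personal=personal,
        cod=cod,
        performance=performance,
        kinematics=kinematics,
        risk=risk_section,
        remarks="",
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_CSS = """
body{font-family:sans-serif;color:black}
table{border-collapse:collapse;margin-bottom:medium}
td,th{border:thin solid gray;padding:thin medium;text-align:center}
.green{background-color:lightgreen}
.yellow{background-color:khaki}
.orange{background-color:orange}
.red{background-color:lightcoral}
.needle{font-weight:bold}
.remarks{border:thin dashed gray;min-height:fit-content;padding:medium}
"""

_DIAL_COLOR = {0: "green", 1: "yellow", 2: "orange", 3: "red"}
_AS_COLOR = {0: "green", 1: "yellow", 2: "orange", 3: "red"}


def _fmt(x) -> str:
    if x is None:
        return "-"
    return format_number(x)


def _speedometer_row(metric: str, value, z, dial) -> str:
    cells = []
    for level in range(-3, 4):
        color = _DIAL_COLOR[abs(level)]
        mark = "&#9650;" if dial is not None and level == dial else "&nbsp;"
        cells.append(f'<td class="{color}">{mark}</td>')
    ztxt = _fmt(z) if z is not None else "-"
    return (
        f"<tr><th>{metric}</th><td>{_fmt(value)}</td><td>{ztxt}</td>"
        + "".join(cells) + "</tr>"
    )


def render_html(report: PlayerReport) -> str:
    """Standalone human-readable document; every number is formatted from the
    machine-readable report data."""
    d = report.to_dict()
    out = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>Risk report {report.player_id}</title>",
        f"<style>{_CSS}</style></head><body>",
        f"<h1>Cutting-biomechanics risk report: {report.player_id}</h1>",
    ]

    p = d["section1_personal"]
    out.append("<h2>Section one: personal data</h2><table>")
    out.append(f"<tr><th>Player</th><td>{p['player_id']}</td></tr>")
    out.append(f"<tr><th>Sex</th><td>{p['sex']}</td></tr>")
    out.append(f"<tr><th>Injured limb</th><td>{p['injured_limb']}</td></tr>")
    out.append(
        f"<tr><th>Trials analyzed</th><td>{_fmt(p['n_trials_analyzed'])} of "
        f"{_fmt(p['n_trials_recorded'])}</td></tr>"
    )
    out.append("</table>")
    if p["excluded_trials"]:
        out.append("<p>Excluded trials:</p><ul>")
        for e in p["excluded_trials"]:
            out.append(f"<li>{e['trial_id']}: stage {e['stage']}</li>")
        out.append("</ul>")

    out.append("<h2>Section two: change of direction</h2>")
    for task, entry in d["section2_cod"].items():
        out.append(f"<h3>{task}</h3><table><tr><th>Trial</th><th>Limb</th>"
                   "<th>Cut angle (deg)</th><th>Stance duration (s)</th></tr>")
        for row in entry["trials"]:
            out.append(
                f"<tr><td>{row['trial_id']}</td><td>{row['cut_limb']}</td>"
                f"<td>{_fmt(row['cut_angle_deg'])}</td>"
                f"<td>{_fmt(row['fc_window_duration_s'])}</td></tr>"
            )
        out.append(
            f"<tr><th>mean &plusmn; SD</th><td></td>"
            f"<td>{_fmt(entry['mean_cut_angle_deg'])} &plusmn; "
            f"{_fmt(entry['sd_cut_angle_deg'])}</td><td></td></tr></table>"
        )

    out.append("<h2>Section three: performance</h2>")
    for task, entry in d["section3_performance"].items():
        out.append(f"<h3>{task}</h3>")
        for row in entry["trials"]:
            out.append(f"<h4>{row['trial_id']}</h4>")
            out.append("<table><tr><th>Metric</th><th>Value</th><th>z</th>"
                       "<th colspan='7'>Speedometer</th></tr>")
            for mid, value in row["metrics"].items():
                out.append(_speedometer_row(
                    mid, value, row["z"].get(mid), row["dial"].get(mid)))
            out.append("</table>")

    out.append("<h2>Section four: kinematics</h2>")
    for task, entry in d["section4_kinematics"].items():
        if task == "limb_labels":
            continue
        out.append(f"<h3>{task}</h3>")
        if entry.get("asymmetry"):
            out.append("<table><tr><th>Joint</th><th>Asymmetry (&#37;)</th>"
                       "<th>Score</th><th>Direction</th><th>Extreme</th></tr>")
            for r in entry["asymmetry"]:
                color = _AS_COLOR[r["score"]]
                star = "&#42;" if r["extreme_flag"] else ""
                out.append(
                    f"<tr><td>{r['joint']}</td>"
                    f"<td class='{color}'>{_fmt(r['pct'])}{star}</td>"
                    f"<td>{_fmt(r['score'])}</td><td>{r['direction']}</td>"
                    f"<td>{_fmt(bool(r['extreme_flag']))}</td></tr>"
                )
            out.append("</table>")
        else:
            out.append("<p>Asymmetry unavailable (single-limb data).</p>")

    out.append("<h2>Section five: risk factors</h2>")
    for task, frames in d["section5_risk"].items():
        for frame, entry in frames.items():
            out.append(f"<h3>{task} &mdash; {frame}</h3>")
            out.append("<table><tr><th>Factor</th><th>Trials at risk (&#37;)</th>"
                       "<th>Pie color</th><th>Max deviation (&#37;)</th></tr>")
            for f, s in entry["factor_summary"].items():
                star = ""
                if s["max_deviation_pct"] is not None and s["max_deviation_pct"] > 100:
                    star = "&#42;"
                out.append(
                    f"<tr><td>{f}</td><td>{_fmt(s['pct_trials_at_risk'])}</td>"
                    f"<td class='{s['color_bin']}'>{s['color_bin']}</td>"
                    f"<td>{_fmt(s['max_deviation_pct'])}{star}</td></tr>"
                )
            out.append("</table>")
            out.append("<table><tr><th>Category</th><th>Status</th>"
                       "<th>Trials at risk (&#37;)</th></tr>")
            for cat, c in entry["category_dashboard"].items():
                color = "red" if c["at_risk"] else "green"
                out.append(
                    f"<tr><td>{cat}</td><td class='{color}'>{color}</td>"
                    f"<td>{_fmt(c['pct_trials_at_risk'])}</td></tr>"
                )
            out.append("</table>")
            ov = entry["overall"]
            out.append(
                f"<p>Overall risk: {_fmt(ov['n_at_risk'])} of "
                f"{_fmt(ov['n_trials'])} trials "
                f"({_fmt(ov['injured_limb_at_risk'])} injured limb, "
                f"{_fmt(ov['noninjured_limb_at_risk'])} non-injured limb).</p>"
            )

    out.append("<h2>Section six: final remarks</h2>")
    remarks = d["section6_remarks"] or "&nbsp;"
    out.append(f"<div class='remarks'>{remarks}</div>")
    out.append("</body></html>")
    return "\n".join(out)


def render_report(
    report: PlayerReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("json", "html"),
) -> list[Path]:
    """Write the report in the requested formats; rendering never alters
    numbers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fmt in formats:
        if fmt == "json":
            path = out_dir / f"report_{report.player_id}.json"
            path.write_text(report.to_json())
        elif fmt == "html":
            path = out_dir / f"report_{report.player_id}.html"
            path.write_text(render_html(report))
        else:
            raise ParameterError(f"unknown report format {fmt!r}")
        paths.append(path)
    return paths


def build_cohort_report(reports: Sequence[PlayerReport]) -> CohortReport:
    """Aggregate player reports into cohort-level factor and risk counts."""
    if not reports:
        raise ReportError("no player reports")
    tasks = sorted({t for r in reports for t in r.risk})
    colors = ("green", "yellow", "orange", "red")
    color_counts: dict = {}
    overall: dict = {}
    for task in tasks:
        color_counts[task] = {}
        overall[task] = {}
        for frame in FRAMES:
            counts = {f: {c: 0 for c in colors} for f in FACTOR_ORDER}
            n_trials = n_at_risk = injured = 0
            for r in reports:
                entry = r.risk.get(task, {}).get(frame)
                if entry is None:
                    continue
                for f in FACTOR_ORDER:
                    counts[f][entry["factor_summary"][f]["color_bin"]] += 1
                ov = entry["overall"]
                n_trials += ov["n_trials"]
                n_at_risk += ov["n_at_risk"]
                injured += ov["injured_limb_at_risk"]
            color_counts[task][frame] = counts
            overall[task][frame] = {
                "n_trials": n_trials,
                "n_at_risk": n_at_risk,
                "injured": injured,
                "noninjured": n_at_risk - injured,
            }
    return CohortReport(
        n_players=len(reports),
        factor_color_counts=color_counts,
        overall_risk=overall,
    )


def run_pipeline(
    data_dir: str | Path,
    config: PipelineConfig = DEFAULT_CONFIG,
    thresholds: Optional[ThresholdLibrary] = None,
    norms: Optional[Sequence[NormativeStats]] = None,
    out_dir: Optional[str | Path] = None,
    formats: Sequence[str] = ("json", "html"),
) -> tuple[dict[str, PlayerReport], CohortReport, list[str]]:
    """Full chain over a directory of trial CSVs: validate, detect events,
    identify the cut, extract metrics, classify risk, and emit reports."""
    from .normative import bundled_thresholds

    data_dir = Path(data_dir)
    paths = sorted(p for p in data_dir.glob("*.csv"))
    if not paths:
        raise ParameterError(f"no trial CSV files found in {data_dir}")
    if thresholds is None:
        thresholds = bundled_thresholds()

    log: list[str] = []
    by_player: dict[str, list] = {}
    for path in paths:
        try:
            trial, meta = read_trial(path)
        except (AclIrdError, OSError, ValueError) as exc:
            log.append(f"SKIP {path.name}: {exc}")
            continue
        by_player.setdefault(meta.player_id, []).append((trial, meta))
        log.append(f"READ {path.name}: player={meta.player_id} "
                   f"task={meta.task} trial={meta.trial_index}")

    reports: dict[str, PlayerReport] = {}
    for player_id in sorted(by_player):
        try:
            report = build_player_report(by_player[player_id], thresholds,
                                         norms, config)
        except AclIrdError as exc:
            log.append(f"FAIL player {player_id}: {exc}")
            continue
        reports[player_id] = report
        for e in report.personal["excluded_trials"]:
            log.append(f"EXCLUDE {player_id}/{e['trial_id']}: "
                       f"{e['stage']} ({e['detail']})")
        log.append(f"REPORT {player_id}: "
                   f"{report.personal['n_trials_analyzed']} trials analyzed")

    if not reports:
        raise ReportError("no player could be analyzed")
    cohort = build_cohort_report(list(reports.values()))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for report in reports.values():
            render_report(report, out_dir, formats)
        (out_dir / "cohort_report.json").write_text(cohort.to_json())
        (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    return reports, cohort, log
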