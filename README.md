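# aclird

Field-based screening of change-of-direction (cutting) biomechanics from
wearable-sensor joint kinematics. The package ingests per-trial joint-angle
and pelvis time series (100 Hz CSV exports), detects the final foot strike
before the direction change, identifies the cut angle with a multistep
candidate/filter algorithm, extracts entry/exit performance metrics and
inter-limb sagittal asymmetry, classifies nine biomechanical risk factors
against sex-, task- and frame-stratified thresholds, and emits a six-section
per-player risk report plus cohort summaries.

## Layout

| module | role |
| --- | --- |
| `aclird.datamodel_io` | shared data model; trial CSV read/write/validate |
| `aclird.synthgen` | synthetic cut-trial and control-cohort generator with embedded ground truth |
| `aclird.gait_events` | foot-contact detection, step segmentation, final-stance (FC) window, IC/pKF frames |
| `aclird.cut_angle` | multistep cut-angle identification (candidates + 3 eligibility filters) |
| `aclird.performance` | entry/exit velocity–acceleration metrics, z-scores, 7-level speedometer dials |
| `aclird.asymmetry` | inter-limb sagittal asymmetry percentage, 0–3 Asymmetry Score, extreme flags |
| `aclird.normative` | bundled reference threshold table and cohort-derived thresholds (mu ± 1.05·sigma) |
| `aclird.risk` | nine-factor extraction/classification, trial / category / player / cohort aggregation |
| `aclird.report` | six-section player report (JSON + HTML), cohort report, end-to-end pipeline |

All pipeline constants (filter cutoffs, window lengths, bin edges,
tolerances) live in `aclird.config.PipelineConfig` and can be overridden
from a YAML file.

## CLI

```bash
# generate synthetic trials with ground truth
acl-ird synth --out data/ --n-trials 6 --seed 1 --cut-angle 75 --player-id P01

# per-trial cut-angle table
acl-ird cutangle data/*.csv

# dump the bundled threshold table, or derive one from control trials
acl-ird thresholds --out thresholds.csv
acl-ird thresholds --from-controls controls/ --out derived.csv

# full pipeline: reports for every player found in the folder
acl-ird report --data data/ --thresholds bundled --out reports/ --formats json,html
```

Trial files are plain CSV with a `#`-prefixed `key=value` metadata header
(player, sex, task, cutting limb, injured limb, trial index) followed by a
wide numeric table; the column schema and the package-wide angle sign
conventions are documented in `aclird/datamodel_io.py`.

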