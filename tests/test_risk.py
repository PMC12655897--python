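import numpy as np
import pytest

from aclird.datamodel_io import TrialKinematics
from aclird.errors import InsufficientDataError, ParameterError
from aclird.gait_events import FCWindow, detect_foot_contacts, locate_fc_window
from aclird.normative import FACTOR_DIRECTIONS, FACTOR_ORDER, bundled_thresholds
from aclird.risk import (
    FactorValues, classify_factors, cohort_summary, color_bin,
    extract_factor_values, player_summary, trial_risk,
)

from conftest import build_manual_trial

MALE_AGTT_IC = bundled_thresholds().get("male", "AGTT", "IC")

#: values safely inside every male/AGTT/IC threshold
SAFE = {"HK": 0.5, "HF": 40.0, "KF": 40.0, "AF": -5.0, "KV": 1.0,
        "HA": 0.0, "HI": 5.0, "TIB": 5.0, "TCR": 5.0}

#: per-factor clearly violating values for the same stratum
VIOLATE = {"HK": 1.0, "HF": 50.0, "KF": 25.0, "AF": -15.0, "KV": 4.0,
           "HA": -9.0, "HI": 20.0, "TIB": 12.0, "TCR": 9.0}


def _values(at_risk_factors=(), frame="IC"):
    vals = dict(SAFE)
    for f in at_risk_factors:
        vals[f] = VIOLATE[f]
    return FactorValues(frame=frame, values=vals)


class TestExtractFactorValues:
    def _window_for(self, make_trial, **kwargs):
        trial, meta, truth = make_trial(**kwargs)
        contacts = detect_foot_contacts(trial)
        w = locate_fc_window(trial, contacts, truth.cut_contact_index,
                             meta.cut_limb)
        return trial, meta, truth, w

    def test_targets_recovered(self, make_trial, cfg):
        trial, meta, truth, w = self._window_for(
            make_trial, factor_targets={"KF@IC": 30.0, "KV@IC": 3.0}, seed=2)
        fv = extract_factor_values(trial, w, "IC", cfg)
        assert fv["KF"] == pytest.approx(30.0, abs=0.1)
        assert fv["KV"] == pytest.approx(3.0, abs=0.1)

    def test_constant_signals_hk_ratio(self, cfg):
        trial = build_manual_trial(
            angle_const={"knee_flex_r": 50.0, "hip_flex_r": 40.0})
        w = FCWindow(start=300, end=340, ic=300, pkf=320,
                     stance_limb="right", duration_s=0.4)
        for frame in ("IC", "pKF"):
            fv = extract_factor_values(trial, w, frame, cfg)
            assert fv["HK"] == pytest.approx(1.25)

    def test_mirror_symmetry(self, make_trial, cfg):
        trial, meta, truth, w = self._window_for(
            make_trial, seed=4, factor_targets={"KV@IC": 2.9, "HF@pKF": 47.0})
        mirrored = trial.mirrored()
        w_m = FCWindow(start=w.start, end=w.end, ic=w.ic, pkf=w.pkf,
                       stance_limb="left", duration_s=w.duration_s)
        for frame in ("IC", "pKF"):
            a = extract_factor_values(trial, w, frame, cfg)
            b = extract_factor_values(mirrored, w_m, frame, cfg)
            for f in FACTOR_ORDER:
                assert b[f] == pytest.approx(a[f], rel=1e-12)

    def test_bad_frame_rejected(self, make_trial, cfg):
        trial, meta, truth, w = self._window_for(make_trial, seed=1)
        with pytest.raises(ParameterError):
            extract_factor_values(trial, w, "mid", cfg)


class TestClassifyFactors:
    def test_kf_below_threshold_at_risk(self):
        fr = classify_factors(_values(["KF"]), MALE_AGTT_IC)
        assert fr["KF"].at_risk
        assert not fr["HF"].at_risk

    def test_kv_double_threshold_is_100_pct(self):
        vals = _values()
        vals.values["KV"] = 4.6  # threshold 2.3
        fr = classify_factors(vals, MALE_AGTT_IC)
        assert fr["KV"].at_risk
        assert fr["KV"].deviation_pct == pytest.approx(100.0)
        assert not fr["KV"].extreme  # boundary: deviation must exceed 100%

    def test_ha_adduction_bound(self):
        vals = _values()
        vals.values["HA"] = -9.0  # bounds [-7.8, 10.3]
        fr = classify_factors(vals, MALE_AGTT_IC)
        assert fr["HA"].at_risk
        vals.values["HA"] = 11.0
        assert classify_factors(vals, MALE_AGTT_IC)["HA"].at_risk
        vals.values["HA"] = 0.0
        assert not classify_factors(vals, MALE_AGTT_IC)["HA"].at_risk

    def test_zero_threshold_deviation_undefined(self):
        ts = bundled_thresholds().get("male", "FS", "IC")  # HK > 0.0
        vals = _values(frame="IC")
        vals.values["HK"] = 0.4
        fr = classify_factors(vals, ts)
        assert fr["HK"].at_risk
        assert fr["HK"].deviation_pct is None
        assert fr["HK"].deviation_abs == pytest.approx(0.4)
        assert not fr["HK"].extreme

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            classify_factors(_values(frame="pKF"), MALE_AGTT_IC)

    def test_stratum_mismatch_rejected(self):
        vals = _values()
        vals.sex, vals.task = "female", "AGTT"
        with pytest.raises(ParameterError):
            classify_factors(vals, MALE_AGTT_IC)

    def test_oracle_equivalence_fuzzed(self):
        """Independent brute-force classifier agrees on fuzzed vectors."""
        lib = bundled_thresholds()
        rng = np.random.default_rng(7)
        for _ in range(200):
            vals = {
                "HK": float(rng.uniform(-1, 2)),
                "HF": float(rng.uniform(10, 70)),
                "KF": float(rng.uniform(0, 100)),
                "AF": float(rng.uniform(-40, 20)),
                "KV": float(rng.uniform(-5, 10)),
                "HA": float(rng.uniform(-20, 20)),
                "HI": float(rng.uniform(-5, 25)),
                "TIB": float(rng.uniform(-5, 20)),
                "TCR": float(rng.uniform(-5, 15)),
            }
            for key, ts in lib.sets.items():
                fv = FactorValues(frame=key[2], values=vals)
                fr = classify_factors(fv, ts)
                for f in FACTOR_ORDER:
                    expected = brute_force_at_risk(vals[f], ts[f])
                    assert fr[f].at_risk == expected, (key, f, vals[f])

    def test_kv_monotonicity(self):
        vals = _values(["KF", "HF"])
        previous = -1
        for kv in np.linspace(-3.0, 8.0, 23):
            vals.values["KV"] = float(kv)
            n = trial_risk(classify_factors(vals, MALE_AGTT_IC)).n_factors_at_risk
            assert n >= previous
            previous = n


def brute_force_at_risk(value, threshold):
    """Deliberately naive re-statement of the directional rules."""
    if threshold.direction == "above":
        return value > threshold.value
    if threshold.direction == "below":
        return value < threshold.value
    return value > threshold.upper or value < threshold.lower


class TestTrialRisk:
    def test_exactly_four_factors_overall(self):
        fr = classify_factors(_values(["KF", "KV", "HA", "TIB"]), MALE_AGTT_IC)
        tr = trial_risk(fr)
        assert tr.n_factors_at_risk == 4
        assert tr.overall_at_risk

    def test_three_factors_not_overall(self):
        fr = classify_factors(_values(["KF", "KV", "TIB"]), MALE_AGTT_IC)
        tr = trial_risk(fr)
        assert tr.n_factors_at_risk == 3
        assert not tr.overall_at_risk

    def test_tpi_category_flag(self):
        fr = classify_factors(_values(["TIB", "TCR"]), MALE_AGTT_IC)
        tr = trial_risk(fr)
        assert tr.category_at_risk["TPI"]
        assert not tr.category_at_risk["SKL"]
        assert not tr.category_at_risk["KVC"]

    def test_skl_requires_all_four(self):
        fr = classify_factors(_values(["HK", "HF", "KF"]), MALE_AGTT_IC)
        assert not trial_risk(fr).category_at_risk["SKL"]
        fr = classify_factors(_values(["HK", "HF", "KF", "AF"]), MALE_AGTT_IC)
        assert trial_risk(fr).category_at_risk["SKL"]


class TestPlayerSummary:
    def _risks(self, n_at_risk, n_total, factor="KV"):
        out = []
        for i in range(n_total):
            fv = _values([factor] if i < n_at_risk else [])
            out.append(classify_factors(fv, MALE_AGTT_IC))
        return out

    @pytest.mark.parametrize("k,n,color", [
        (4, 6, "orange"),   # 66.7%
        (0, 6, "green"),
        (5, 6, "red"),      # 83.3%
        (2, 6, "yellow"),   # 33.3%
        (3, 6, "yellow"),   # exactly 50% -> lower bin
    ])
    def test_color_bins(self, k, n, color):
        summ = player_summary(self._risks(k, n), "IC")
        assert summ["KV"].color_bin == color
        assert summ["KV"].pct_trials_at_risk == pytest.approx(100.0 * k / n)

    def test_majority_flag(self):
        assert player_summary(self._risks(3, 6), "IC")["KV"].majority_flag
        assert not player_summary(self._risks(2, 6), "IC")["KV"].majority_flag

    def test_max_deviation_with_provenance(self):
        risks = self._risks(2, 3)
        summ = player_summary(risks, "IC", trial_ids=["a", "b", "c"])
        assert summ["KV"].max_deviation_pct == pytest.approx(
            100.0 * (4.0 - 2.3) / 2.3)
        assert summ["KV"].max_deviation_trial in ("a", "b")

    def test_no_trials(self):
        with pytest.raises(InsufficientDataError):
            player_summary([], "IC")

    def test_color_bin_edges(self):
        assert color_bin(19.99) == "green"
        assert color_bin(20.0) == "yellow"
        assert color_bin(50.0) == "yellow"
        assert color_bin(50.1) == "orange"
        assert color_bin(70.0) == "orange"
        assert color_bin(70.1) == "red"


class TestCohortSummary:
    def test_single_player_all_green(self):
        summ = player_summary(
            [classify_factors(_values(), MALE_AGTT_IC) for _ in range(4)], "IC")
        counts = cohort_summary([summ])
        for f in FACTOR_ORDER:
            assert counts[f]["green"] == 1
            assert sum(counts[f].values()) == 1

    def test_counts_partition_players(self):
        rng = np.random.default_rng(0)
        summaries = []
        for _ in range(9):
            k = int(rng.integers(0, 7))
            risks = [
                classify_factors(_values(["KV"] if i < k else []),
                                 MALE_AGTT_IC)
                for i in range(6)
            ]
            summaries.append(player_summary(risks, "IC"))
        counts = cohort_summary(summaries)
        for f in FACTOR_ORDER:
            assert sum(counts[f].values()) == 9

    def test_constructed_red_count(self):
        summaries = []
        for player in range(5):
            k = 5 if player < 3 else 1   # 3 players at 83% -> red
            risks = [
                classify_factors(_values(["KV"] if i < k else []),
                                 MALE_AGTT_IC)
                for i in range(6)
            ]
            summaries.append(player_summary(risks, "IC"))
        assert cohort_summary(summaries)["KV"]["red"] == 3
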