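import math

import numpy as np
import pandas as pd
import pytest

import plateletmir as pm
from plateletmir import expression, simulate
from plateletmir.reference import MIR127, MIR320A, REFERENCE_CONTROL
from plateletmir.simulate import BagEffect, DecayParams, SimulationConfig


class TestTypes:
    @pytest.mark.parametrize("kwargs", [
        {"initial_rpm": 0.0}, {"initial_rpm": -5.0},
        {"decay_rate": -0.1}, {"rebound_fraction": 1.5},
    ])
    def test_decay_params_invariants(self, kwargs):
        base = {"mirna_id": "m", "initial_rpm": 10.0}
        with pytest.raises(ValueError):
            DecayParams(**{**base, **kwargs})

    def test_expected_abundance_nonincreasing_through_day_5(self):
        p = DecayParams("m", 100.0, decay_rate=0.3, rebound_fraction=0.5)
        values = [simulate.expected_rpm(p, d) for d in (1, 2, 3, 4, 5)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert simulate.expected_rpm(p, 7) > simulate.expected_rpm(p, 5)

    def test_bag_effect_requires_nondecreasing_scales(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            BagEffect("b", {1: 1.0, 2: 0.5})

    @pytest.mark.parametrize("kwargs", [
        {"n_bags": 0}, {"days": (1, 1, 2)}, {"days": ()},
        {"library_size": 0}, {"ct_replicates": 1}, {"count_noise": "gauss"},
    ])
    def test_config_invariants(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestCalibrationPreset:
    def test_mir191_dominates_day_1(self, calibration):
        params, _ = calibration
        top = max(params, key=lambda p: p.initial_rpm)
        assert top.mirna_id == "hsa-mir-191"

    def test_rq_preset_matches_reference_table(self, calibration):
        _, rq_cal = calibration
        cell = rq_cal.set_index(["target", "day"])
        assert tuple(cell.loc[(MIR127, 1)]) == (0.29, 0.06)
        assert tuple(cell.loc[(MIR320A, 7)]) == (0.60, 0.23)


class TestSimulateCounts:
    def test_deterministic_under_fixed_seed(self, calibration):
        params, _ = calibration
        config = SimulationConfig(n_bags=2, seed=7)
        a = simulate.simulate_counts(config, params)
        b = simulate.simulate_counts(config, params)
        pd.testing.assert_frame_equal(a, b)

    def test_no_decay_no_noise_day7_equals_day1(self):
        params = [DecayParams(f"m{i}", rpm0) for i, rpm0 in enumerate([500.0, 100.0, 5.0])]
        config = SimulationConfig(n_bags=1, count_noise="none")
        counts = simulate.simulate_counts(config, params)
        assert counts["bag001_day1"].tolist() == counts["bag001_day7"].tolist()

    def test_detection_declines_to_day5_and_rebounds(self, calibration):
        """Per-bag detected miRNAs (reads >= 10) drop from day 1 to
        day 5 and recover partially at day 7 under the calibration."""
        params, _ = calibration
        config = SimulationConfig(n_bags=16, seed=1)
        counts = simulate.simulate_counts(config, params)
        for bag in ("bag001", "bag009", "bag016"):
            det = {d: len(expression.detect_expressed(counts, f"{bag}_day{d}"))
                   for d in (1, 5, 7)}
            assert det[5] < det[1]
            assert det[5] < det[7]

    def test_sub_detection_mirna_never_detected(self):
        params = [DecayParams("rare", 4.0, decay_rate=0.1),
                  DecayParams("filler", 999_996.0)]
        config = SimulationConfig(n_bags=1, count_noise="none")
        counts = simulate.simulate_counts(config, params)
        for col in counts.columns:
            assert "rare" not in expression.detect_expressed(counts, col)

    def test_empty_params_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_counts(SimulationConfig(), [])

    def test_pool_bags_sums_columns(self, calibration):
        params, _ = calibration
        config = SimulationConfig(n_bags=3, seed=0, days=(1, 5))
        counts = simulate.simulate_counts(config, params)
        pooled = simulate.pool_bags(counts)
        assert list(pooled.columns) == [1, 5]
        expected = counts[[c for c in counts.columns if c.endswith("_day5")]].sum(axis=1)
        assert pooled[5].equals(expected)


class TestSimulateCt:
    def test_bit_identical_under_fixed_seed(self, calibration):
        _, rq_cal = calibration
        config = SimulationConfig(n_bags=3, seed=11)
        a = simulate.simulate_ct(config, rq_cal)
        b = simulate.simulate_ct(config, rq_cal)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_limit_recovers_calibrated_mean_exactly(self, calibration):
        _, rq_cal = calibration
        config = SimulationConfig(n_bags=5, ct_tech_sd=0.0)
        effects = [BagEffect(f"bag{i + 1:03d}", {d: 0.0 for d in config.days})
                   for i in range(config.n_bags)]
        ct = simulate.simulate_ct(config, rq_cal, bag_effects=effects)
        rq = pm.compute_rq(ct)
        day5_127 = rq[(rq["day"] == 5) & (rq["target"] == MIR127)]["rq"]
        assert day5_127.tolist() == pytest.approx([0.24] * 5, rel=1e-9)

    def test_replicate_layout(self, calibration):
        _, rq_cal = calibration
        config = SimulationConfig(n_bags=2, days=(1, 5), ct_replicates=3)
        ct = simulate.simulate_ct(config, rq_cal)
        # 2 bags x 2 days x (control + 2 targets) x 3 replicates
        assert len(ct) == 2 * 2 * 3 * 3
        counts = ct.groupby(["bag_id", "day", "target"]).size()
        assert (counts == 3).all()
        assert REFERENCE_CONTROL in set(ct["target"])

    def test_reference_cannot_be_a_calibrated_target(self, calibration):
        _, rq_cal = calibration
        bad = pd.concat([rq_cal, pd.DataFrame(
            [{"target": REFERENCE_CONTROL, "day": d, "mean": 1.0, "sd": 0.0}
             for d in (1, 2, 3, 4, 5, 7)])])
        with pytest.raises(ValueError, match="reference"):
            simulate.simulate_ct(SimulationConfig(n_bags=1), bad)

    def test_missing_day_calibration_rejected(self, calibration):
        _, rq_cal = calibration
        with pytest.raises(ValueError, match="day 6"):
            simulate.simulate_ct(SimulationConfig(n_bags=1, days=(1, 6)), rq_cal)

    def test_bag_effect_count_mismatch_rejected(self, calibration):
        _, rq_cal = calibration
        with pytest.raises(ValueError, match="BagEffect"):
            simulate.simulate_ct(SimulationConfig(n_bags=3), rq_cal,
                                 bag_effects=[BagEffect("b1", {1: 1.0})])


class TestCohortStatistics:
    def test_parameter_recovery_within_two_se(self, calibration, rq_cohort):
        """At 100 bags every per-day/target RQ mean lands within two
        standard errors of its calibrated value."""
        _, rq_cal = calibration
        _, summary = rq_cohort
        merged = summary.merge(rq_cal, on=["day", "target"],
                               suffixes=("_sim", "_cal"))
        assert len(merged) == 12
        z = (merged["mean_sim"] - merged["mean_cal"]) / (
            merged["sd_cal"] / np.sqrt(merged["n"]))
        assert (z.abs() < 2).all(), merged.assign(z=z).to_string()

    def test_dispersion_grows_with_storage_time(self, rq_cohort):
        """Cross-bag RQ spread widens over storage: day-7 sample SD
        exceeds day-1 for both biomarkers."""
        _, summary = rq_cohort
        for target in (MIR127, MIR320A):
            sub = summary[summary["target"] == target].set_index("day")["sd"]
            assert sub[7] > sub[1]
            assert sub[5] > sub[1]
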