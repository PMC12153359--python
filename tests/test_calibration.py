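import numpy as np
import pandas as pd
import pytest

from virorules import (
    CalibrationConfig,
    CalibrationTable,
    MiningConfig,
    PresenceAbsenceMatrix,
    build_null_lift_distribution,
    calibrate_dynamic_thresholds,
    filter_significant_rules,
    permute_matrix_columns,
    upper_quantile,
)
from .conftest import make_random_matrix


class TestPermutation:
    def test_column_sums_preserved(self):
        rng = np.random.default_rng(0)
        m = make_random_matrix(rng, 50, 8)
        p = permute_matrix_columns(m, seed=1)
        assert p.virus_counts().equals(m.virus_counts())

    def test_single_strain_matrix_unchanged(self):
        m = PresenceAbsenceMatrix(pd.DataFrame({"A": [1], "B": [0]}, index=["s1"]))
        p = permute_matrix_columns(m, seed=3)
        pd.testing.assert_frame_equal(p.data, m.data)

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(2)
        m = make_random_matrix(rng, 40, 6)
        pd.testing.assert_frame_equal(
            permute_matrix_columns(m, seed=9).data,
            permute_matrix_columns(m, seed=9).data,
        )


class TestUpperQuantile:
    def test_documented_convention_on_1_to_100(self):
        x = np.arange(1, 101) * 0.01
        assert upper_quantile(x, 0.95) == pytest.approx(0.95)
        # exactly 5% of the sample lies strictly above the threshold
        assert (x > upper_quantile(x, 0.95)).mean() == pytest.approx(0.05)

    def test_constant_sample(self):
        assert upper_quantile(np.ones(100), 0.95) == 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            upper_quantile([], 0.95)


def _pool(support, confidence, lift):
    return pd.DataFrame({"support": support, "confidence": confidence, "lift": lift})


class TestCalibrationTable:
    def test_stratum_threshold_is_null_quantile(self):
        lifts = np.arange(1, 101) * 0.01
        pool = _pool(np.full(100, 0.5), np.full(100, 0.5), lifts)
        table = calibrate_dynamic_thresholds(pool, CalibrationConfig(alpha=0.05),
                                             support_edges=[], confidence_edges=[])
        assert table.thresholds.shape == (1, 1)
        assert table.thresholds[0, 0] == pytest.approx(0.95)

    def test_constant_null_gives_threshold_at_constant(self):
        pool = _pool(np.full(100, 0.5), np.full(100, 0.5), np.ones(100))
        table = calibrate_dynamic_thresholds(pool, CalibrationConfig(alpha=0.05),
                                             support_edges=[], confidence_edges=[])
        assert table.thresholds[0, 0] == 1.0
        # strict comparison: a candidate at lift exactly 1.0 is rejected
        assert not table.pass_mask([0.5], [0.5], [1.0])[0]

    def test_empty_stratum_falls_back_to_global_and_is_flagged(self):
        pool = _pool(np.full(50, 0.1), np.full(50, 0.5), np.linspace(0.5, 1.5, 50))
        table = calibrate_dynamic_thresholds(
            pool, CalibrationConfig(alpha=0.05),
            support_edges=[0.5], confidence_edges=[],
        )
        assert table.usable[0, 0] and not table.usable[1, 0]
        assert table.thresholds[1, 0] == table.global_threshold

    def test_strata_cover_unit_interval(self):
        pool = _pool(np.random.default_rng(0).random(200),
                     np.random.default_rng(1).random(200),
                     np.random.default_rng(2).random(200) + 0.5)
        table = calibrate_dynamic_thresholds(pool, CalibrationConfig())
        for s in (0.0, 0.5, 1.0):
            for c in (0.0, 0.5, 1.0):
                assert np.isfinite(table.threshold_for([s], [c])[0])

    def test_raising_alpha_never_shrinks_retained_set(self):
        rng = np.random.default_rng(7)
        pool = _pool(rng.random(500), rng.random(500), rng.lognormal(0, 0.3, 500))
        cand = _pool(rng.random(200), rng.random(200), rng.lognormal(0, 0.3, 200))
        retained = []
        for alpha in (0.01, 0.05, 0.2):
            t = calibrate_dynamic_thresholds(pool, CalibrationConfig(alpha=alpha),
                                             support_edges=[0.5], confidence_edges=[0.5])
            retained.append(set(np.flatnonzero(
                t.pass_mask(cand["support"], cand["confidence"], cand["lift"]))))
        assert retained[0] <= retained[1] <= retained[2]

    def test_json_round_trip(self, tmp_path):
        pool = _pool(np.full(100, 0.3), np.full(100, 0.6), np.arange(1, 101) * 0.01)
        table = calibrate_dynamic_thresholds(pool, CalibrationConfig())
        path = tmp_path / "calib.json"
        table.to_json(path)
        back = CalibrationTable.from_json(path)
        np.testing.assert_array_equal(back.thresholds, table.thresholds)
        np.testing.assert_array_equal(back.support_edges, table.support_edges)
        assert back.global_threshold == table.global_threshold


class TestNullDistribution:
    def test_zero_permutations_is_an_error(self):
        with pytest.raises(ValueError, match="[Ee]mpty null"):
            build_null_lift_distribution(
                make_random_matrix(np.random.default_rng(0), 30, 5),
                MiningConfig(), CalibrationConfig(n_permutations=0),
            )

    def test_same_seed_gives_identical_pool(self):
        m = make_random_matrix(np.random.default_rng(1), 60, 8)
        cfg = CalibrationConfig(n_permutations=5, seed=42)
        p1 = build_null_lift_distribution(m, MiningConfig(), cfg)
        p2 = build_null_lift_distribution(m, MiningConfig(), cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_null_pool_median_lift_near_one(self):
        rng = np.random.default_rng(3)
        vals = (rng.random((300, 10)) < 0.5).astype(np.int8)
        m = PresenceAbsenceMatrix(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(300)],
                         columns=[f"V{j}" for j in range(10)])
        )
        pool = build_null_lift_distribution(
            m, MiningConfig(min_support=0.01, min_confidence=0.01),
            CalibrationConfig(n_permutations=50, seed=0),
        )
        assert abs(np.median(pool["lift"]) - 1.0) < 0.05

    def test_calibration_is_deterministic_end_to_end(self):
        m = make_random_matrix(np.random.default_rng(4), 80, 8)
        mcfg = MiningConfig()
        ccfg = CalibrationConfig(n_permutations=10, seed=5)
        t1 = calibrate_dynamic_thresholds(build_null_lift_distribution(m, mcfg, ccfg), ccfg)
        t2 = calibrate_dynamic_thresholds(build_null_lift_distribution(m, mcfg, ccfg), ccfg)
        np.testing.assert_array_equal(t1.thresholds, t2.thresholds)


class TestFilter:
    def test_retained_rules_record_threshold_beaten(self):
        pool = _pool(np.full(200, 0.4), np.full(200, 0.6), np.ones(200))
        table = calibrate_dynamic_thresholds(pool, CalibrationConfig(),
                                             support_edges=[], confidence_edges=[])
        cand = pd.DataFrame({
            "lhs_items": [(("A", True),), (("B", True),)],
            "rhs_virus": ["B", "A"], "rhs_state": [True, True],
            "rule_form": ["one_to_one"] * 2,
            "support": [0.4, 0.4], "confidence": [0.6, 0.6], "lift": [1.5, 1.0],
        })
        sig = filter_significant_rules(cand, table)
        assert len(sig) == 1
        assert sig.iloc[0]["lift"] == 1.5
        assert sig.iloc[0]["lift_threshold_applied"] == 1.0
        assert bool(sig.iloc[0]["significant"])

    def test_global_floors_apply(self):
        pool = _pool(np.full(100, 0.4), np.full(100, 0.6), np.full(100, 0.9))
        table = calibrate_dynamic_thresholds(pool, CalibrationConfig(),
                                             support_edges=[], confidence_edges=[])
        cand = pd.DataFrame({
            "lhs_items": [(("A", True),)] * 2, "rhs_virus": ["B", "B"],
            "rhs_state": [True, False], "rule_form": ["one_to_one"] * 2,
            "support": [0.05, 0.4], "confidence": [0.6, 0.6], "lift": [1.5, 1.5],
        })
        sig = filter_significant_rules(cand, table, min_support=0.073)
        assert len(sig) == 1 and sig.iloc[0]["support"] == 0.4
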