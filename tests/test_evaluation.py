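import numpy as np
import pytest

from glyrisk.errors import DomainError, UndefinedMetricError
from glyrisk.evaluation import (
    ClarkeZoneCounts,
    EvaluationReport,
    ForecastResult,
    clarke_analysis,
    clarke_zone,
    clarke_zones,
    lm_ratio,
    rmse,
    weighted_rmse,
    zone_ratio,
)
from glyrisk.risk_scale import glucose_to_risk, risk_to_glucose


def oracle_zone(r, p):
    """Hand-coded scalar Clarke classifier, written independently as
    ordered region membership checks over the published boundaries."""
    within_20pct = abs(p - r) <= 0.2 * r
    both_hypo_ok = r <= 70 and p <= 70
    if both_hypo_ok or within_20pct:
        return "A"
    grossly_wrong_low = r >= 180 and p <= 70
    grossly_wrong_high = r <= 70 and p >= 180
    if grossly_wrong_low or grossly_wrong_high:
        return "E"
    overcorrect_up = 70 <= r <= 290 and p >= r + 110
    overcorrect_down = 130 <= r <= 180 and p <= 1.4 * r - 182
    if overcorrect_up or overcorrect_down:
        return "C"
    miss_high = r >= 240 and 70 <= p <= 180
    miss_low_a = r <= 175 / 3 and 70 <= p <= 180
    miss_low_b = 175 / 3 <= r <= 70 and p >= 1.2 * r
    if miss_high or miss_low_a or miss_low_b:
        return "D"
    return "B"


def glucose_result(truth, pred, **kw):
    return ForecastResult(np.asarray(truth, float), np.asarray(pred, float),
                          "glucose", 30, **kw)


class TestRMSE:
    def test_perfect_prediction(self):
        assert rmse(glucose_result([100, 150], [100, 150])) == 0.0

    def test_hand_case(self):
        r = ForecastResult([0.0, 0.0], [3.0, 4.0], "xi", 30)
        assert rmse(r) == pytest.approx(np.sqrt(25 / 2))

    def test_permutation_invariant(self, rng):
        t = rng.uniform(40, 400, 50)
        p = rng.uniform(40, 400, 50)
        order = rng.permutation(50)
        assert rmse(glucose_result(t, p)) == pytest.approx(
            rmse(glucose_result(t[order], p[order]))
        )


class TestWeightedRMSE:
    def test_constant_weights_equal_plain_rmse(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            res = glucose_result(rng.uniform(40, 400, n), rng.uniform(40, 400, n))
            w = np.full(n, float(rng.uniform(0.1, 5)))
            assert weighted_rmse(res, weights=w) == pytest.approx(rmse(res))

    def test_single_nonzero_weight(self):
        res = glucose_result([100, 200], [110, 250])
        assert weighted_rmse(res, weights=np.array([0.0, 0.7])) == pytest.approx(50.0)

    def test_hand_case(self):
        res = glucose_result([100, 200], [110, 200])  # errors [10, 0]
        w = np.array([0.1, 0.4])
        assert weighted_rmse(res, weights=w) == pytest.approx(np.sqrt(10 / 0.5))

    def test_all_zero_weights_undefined(self):
        res = glucose_result([100, 100], [110, 90])
        with pytest.raises(UndefinedMetricError):
            weighted_rmse(res, weights=np.zeros(2))

    def test_default_weights_are_truth_risk(self, rng):
        t = rng.uniform(40, 400, 30)
        p = rng.uniform(40, 400, 30)
        res = glucose_result(t, p)
        w = glucose_to_risk(t) ** 2 / 10.0
        assert weighted_rmse(res) == pytest.approx(weighted_rmse(res, weights=w))

    def test_prediction_weighting_flag(self, rng):
        t = rng.uniform(40, 400, 30)
        p = rng.uniform(40, 400, 30)
        res = glucose_result(t, p)
        w = glucose_to_risk(p) ** 2 / 10.0
        assert weighted_rmse(res, weight_on="prediction") == pytest.approx(
            weighted_rmse(res, weights=w)
        )

    def test_permutation_invariant(self, rng):
        t = rng.uniform(40, 400, 50)
        p = rng.uniform(40, 400, 50)
        order = rng.permutation(50)
        assert weighted_rmse(glucose_result(t, p)) == pytest.approx(
            weighted_rmse(glucose_result(t[order], p[order]))
        )


class TestLMRatio:
    def test_equal_is_one(self):
        assert lm_ratio(10.0, 10.0) == 1.0

    def test_better_below_one(self):
        assert lm_ratio(8.0, 10.0) == pytest.approx(0.8)

    def test_zero_lm_rejected(self):
        with pytest.raises(DomainError):
            lm_ratio(1.0, 0.0)


class TestClarkeZone:
    @pytest.mark.parametrize("r,p,zone", [
        (100, 100, "A"),
        (200, 60, "E"),
        (65, 190, "E"),
        (100, 215, "C"),
        (150, 25, "C"),
        (250, 100, "D"),
        (50, 120, "D"),
        (65, 85, "D"),
        (110, 150, "B"),
        (60, 60, "A"),
    ])
    def test_examples(self, r, p, zone):
        assert clarke_zone(r, p) == zone

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            clarke_zone(0, 100)
        with pytest.raises(DomainError):
            clarke_zones(np.array([100.0]), np.array([-1.0]))

    def test_scalar_matches_oracle_on_50x50_grid(self):
        grid = np.linspace(40, 400, 50)
        for r in grid:
            for p in grid:
                assert clarke_zone(r, p) == oracle_zone(r, p)

    def test_vectorized_matches_scalar(self, rng):
        r = rng.uniform(1, 600, 500)
        p = rng.uniform(1, 600, 500)
        vec = clarke_zones(r, p)
        assert all(vec[i] == clarke_zone(r[i], p[i]) for i in range(500))

    def test_partition_every_point_classified(self):
        g = np.linspace(0.5, 600, 120)
        rr, pp = np.meshgrid(g, g)
        zones = clarke_zones(rr.ravel(), pp.ravel())
        assert set(np.unique(zones)) <= set("ABCDE")


class TestClarkeAnalysis:
    def test_perfect_predictions_all_zone_a(self, rng):
        t = rng.uniform(40, 400, 200)
        counts = clarke_analysis(glucose_result(t, t))
        assert counts.fractions["A"] == 1.0

    def test_fractions_sum_to_one(self, rng):
        t = rng.uniform(40, 400, 500)
        p = rng.uniform(40, 400, 500)
        counts = clarke_analysis(glucose_result(t, p))
        assert sum(counts.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert counts.total == 500

    def test_requires_glucose_scale(self):
        res = ForecastResult([0.1], [0.1], "xi", 30)
        with pytest.raises(DomainError):
            clarke_analysis(res)


class TestZoneRatio:
    def test_identical_counts_ratio_one(self):
        c = ClarkeZoneCounts({"A": 10, "B": 5, "C": 1, "D": 2, "E": 1})
        assert all(v == 1.0 for v in zone_ratio(c, c).values())

    def test_example(self):
        m = ClarkeZoneCounts({"A": 90, "B": 0, "C": 0, "D": 0, "E": 0})
        l = ClarkeZoneCounts({"A": 100, "B": 0, "C": 0, "D": 0, "E": 0})
        ratios = zone_ratio(m, l)
        assert ratios["A"] == pytest.approx(0.9)

    def test_undefined_zones_flagged_none(self):
        m = ClarkeZoneCounts({"A": 1, "B": 0, "C": 0, "D": 0, "E": 0})
        l = ClarkeZoneCounts({"A": 1, "B": 0, "C": 0, "D": 0, "E": 0})
        assert zone_ratio(m, l)["B"] is None


class TestScaleChaining:
    def test_xi_to_glucose_rmse_consistency(self, rng):
        """Converting a xi result to glucose must equal transforming the
        raw sequences first and computing RMSE directly."""
        t_glucose = rng.uniform(45, 390, 100)
        p_glucose = rng.uniform(45, 390, 100)
        xi_t = glucose_to_risk(t_glucose) / 10.0
        xi_p = glucose_to_risk(p_glucose) / 10.0
        res_xi = ForecastResult(xi_t, xi_p, "xi", 30)
        converted = res_xi.to_glucose()
        direct = glucose_result(t_glucose, p_glucose)
        assert rmse(converted) == pytest.approx(rmse(direct), rel=1e-9)
        assert weighted_rmse(converted) == pytest.approx(weighted_rmse(direct), rel=1e-9)

    def test_roundtrip_through_risk(self, rng):
        xs = rng.uniform(40, 400, 50)
        back = risk_to_glucose(glucose_to_risk(xs))
        np.testing.assert_allclose(back, xs, rtol=1e-9)


class TestForecastResult:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ForecastResult([1.0, 2.0], [1.0], "xi", 30)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ForecastResult([1.0, np.nan], [1.0, 2.0], "xi", 30)


class TestEvaluationReport:
    def test_from_records_and_summary(self):
        records = [
            {"individual_id": "a", "model_name": "GRU_1", "arch": "GRU", "horizon": 30,
             "replica": 1, "xi_rmse": 0.02, "cgm_rmse": 20.0,
             "weighted_cgm_rmse": 25.0, "lm_ratio": 0.9},
            {"individual_id": "b", "model_name": "GRU_1", "arch": "GRU", "horizon": 30,
             "replica": 1, "xi_rmse": 0.03, "cgm_rmse": 30.0,
             "weighted_cgm_rmse": 35.0, "lm_ratio": 1.1},
        ]
        rep = EvaluationReport.from_records(records)
        summary = rep.summary()
        assert summary.loc[("GRU_1", 30)][("cgm_rmse", 0.5)] == pytest.approx(25.0)

    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd

        rep = EvaluationReport.from_records([
            {"individual_id": "a", "model_name": "LM", "arch": "LM", "horizon": 30,
             "replica": 0, "xi_rmse": 0.02, "cgm_rmse": 20.0,
             "weighted_cgm_rmse": 25.0, "lm_ratio": 1.0},
        ])
        p = tmp_path / "report.csv"
        rep.to_csv(p)
        back = pd.read_csv(p)
        assert back.loc[0, "cgm_rmse"] == 20.0
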