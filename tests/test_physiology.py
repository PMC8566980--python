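"""Leaf-temperature contrasts, the signed significant-area statistic,
Granier sap-flow conversion and daily-window comparisons."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_delta_frame
from holopheno.physiology import (
    GranierCalibration,
    TreatmentContrast,
    aggregate_plant_series,
    daily_window_compare,
    delta_tleaf_series,
    granier_sap_flow,
    significant_area_summary,
    star_code,
    swc_contrast,
)


def plant_records(values_by_plant, hybrid="H1", regime="WW", start="2018-09-01",
                  cadence_min=5):
    """Long records: {plant_id: (inoculated, values)} on a shared 5-min grid."""
    frames = []
    for pid, (inoc, vals) in values_by_plant.items():
        ts = pd.date_range(start, periods=len(vals), freq=f"{cadence_min}min")
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "plant_id": pid,
                    "hybrid": hybrid,
                    "inoculated": inoc,
                    "regime": regime,
                    "tleaf_c": vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def arm_matrix(values, n_bins=1, start="2018-09-01"):
    """bins x replicates matrix with a 30-min bin index."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] != n_bins:
        arr = np.tile(arr, (n_bins, 1))
    idx = pd.date_range(start, periods=n_bins, freq="30min")
    return pd.DataFrame(arr, index=idx)


class TestAggregation:
    def test_constant_replicates(self):
        recs = plant_records({f"p{i}": (1, [25.0] * 6) for i in range(4)})
        agg = aggregate_plant_series(recs)
        mat = agg.cell_matrix("H1", 1, "WW")
        assert mat.shape == (1, 4)
        assert (mat.to_numpy() == 25.0).all()
        means = agg.cell_means()
        assert means["mean"].iloc[0] == 25.0 and means["n_retained"].iloc[0] == 4

    def test_gross_replicate_removed(self):
        vals = {f"p{i}": (1, [v] * 6) for i, v in enumerate([24.0, 25.0, 26.0, 80.0])}
        agg = aggregate_plant_series(plant_records(vals))
        means = agg.cell_means()
        assert means["mean"].iloc[0] == pytest.approx(25.0)
        assert means["n_removed"].iloc[0] == 1

    def test_unknown_labels_rejected(self):
        recs = plant_records({"p0": (1, [20.0] * 6)}, regime="BAD")
        with pytest.raises(ValueError, match="regime"):
            aggregate_plant_series(recs)

    def test_twenty_days_gives_960_bins_per_cell(self):
        n = 20 * 288  # 5-min cadence
        recs = plant_records({"p0": (1, np.full(n, 20.0)), "p1": (1, np.full(n, 21.0))})
        agg = aggregate_plant_series(recs)
        assert agg.cell_matrix("H1", 1, "WW").shape[0] == 960


class TestDeltaSeries:
    def test_identical_arms_no_signal(self, rng):
        a = arm_matrix(rng.normal(25, 1, (10, 4)), n_bins=10)
        delta = delta_tleaf_series(a, a.copy())
        assert np.allclose(delta["delta"], 0.0)
        assert not delta["significant"].any()

    def test_antisymmetry_under_arm_swap(self, rng):
        a = arm_matrix(rng.normal(25, 0.3, (20, 4)), n_bins=20)
        b = arm_matrix(rng.normal(24, 0.3, (20, 4)), n_bins=20)
        fwd = delta_tleaf_series(a, b)
        rev = delta_tleaf_series(b, a)
        np.testing.assert_allclose(fwd["delta"], -rev["delta"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])

    def test_noise_free_offset_recovered(self):
        a = arm_matrix([23.5] * 4, n_bins=5)
        b = arm_matrix([25.0] * 4, n_bins=5)
        delta = delta_tleaf_series(a, b)
        np.testing.assert_allclose(delta["delta"], -1.5)

    def test_untestable_bins_flagged_missing(self, rng):
        a = arm_matrix(rng.normal(25, 0.3, (3, 4)), n_bins=3)
        a.iloc[1, 1:] = np.nan  # one retained replicate only
        b = arm_matrix(rng.normal(24, 0.3, (3, 4)), n_bins=3)
        delta = delta_tleaf_series(a, b)
        assert np.isnan(delta.loc[1, "p_value"])
        assert not delta.loc[1, "significant"]
        assert len(delta) == 3  # still counted in the temporal denominator

    def test_misaligned_bins_rejected(self, rng):
        a = arm_matrix(rng.normal(size=(3, 4)), n_bins=3)
        b = arm_matrix(rng.normal(size=(3, 4)), n_bins=3, start="2018-09-02")
        with pytest.raises(ValueError, match="misaligned"):
            delta_tleaf_series(a, b)

    def test_swc_contrast_shares_machinery(self, rng):
        ww = arm_matrix(rng.normal(500, 5, (8, 4)), n_bins=8)
        ds = arm_matrix(rng.normal(350, 5, (8, 4)), n_bins=8)
        out = swc_contrast(ww, ds)
        assert (out["delta"] < 0).all()
        assert out["significant"].all()


class TestAreaSummary:
    def test_all_zero(self):
        frame = make_delta_frame([0.0] * 5, [False] * 5)
        s = significant_area_summary(frame)
        assert (s.pos_area, s.neg_area, s.n_significant) == (0.0, 0.0, 0)

    def test_hand_computed_mixed_bins(self):
        frame = make_delta_frame([1.0, -2.0, 0.5], [True, True, False])
        s = significant_area_summary(frame)
        assert s.pos_area == pytest.approx(1.0)
        assert s.neg_area == pytest.approx(2.0)
        assert s.n_significant == 2 and s.n_bins == 3
        assert s.pct_significant == 66.7

    def test_printed_significant_fraction(self):
        sig = [True] * 763 + [False] * (960 - 763)
        frame = make_delta_frame([-1.0] * 960, sig)
        s = significant_area_summary(frame)
        assert s.pct_significant == 79.5

    def test_additivity_at_any_split(self, rng):
        deltas = rng.normal(0, 1, 40)
        sig = rng.random(40) < 0.5
        frame = make_delta_frame(deltas, sig)
        whole = significant_area_summary(frame)
        for cut in (1, 13, 20, 39):
            left = significant_area_summary(frame.iloc[:cut])
            right = significant_area_summary(frame.iloc[cut:])
            assert left.pos_area + right.pos_area == pytest.approx(whole.pos_area)
            assert left.neg_area + right.neg_area == pytest.approx(whole.neg_area)
            assert left.n_significant + right.n_significant == whole.n_significant

    def test_bin_width_scales_area(self):
        frame = make_delta_frame([-1.0], [True])
        assert significant_area_summary(frame, width_min=60).neg_area == 2.0


class TestScaleEquivariance:
    def test_scaling_both_arms_scales_areas(self, rng):
        a = rng.normal(25, 0.3, (30, 4))
        b = rng.normal(26, 0.3, (30, 4))
        d1 = delta_tleaf_series(arm_matrix(a, 30), arm_matrix(b, 30))
        d2 = delta_tleaf_series(arm_matrix(3 * a, 30), arm_matrix(3 * b, 30))
        np.testing.assert_allclose(d1["p_value"], d2["p_value"], rtol=1e-9)
        s1 = significant_area_summary(d1)
        s2 = significant_area_summary(d2)
        assert s2.neg_area == pytest.approx(3 * s1.neg_area)
        assert s2.pos_area == pytest.approx(3 * s1.pos_area)


class TestGranier:
    def test_no_flow_reference(self):
        cal = GranierCalibration()
        assert granier_sap_flow(cal.delta_t_max_c, cal) == 0.0

    def test_unit_flow_index_default_calibration(self):
        cal = GranierCalibration(delta_t_max_c=10.0)
        # K = 1 at dT = dT_max / 2
        assert granier_sap_flow(5.0, cal) == pytest.approx(42.84, abs=0.01)

    def test_monotone_in_flow_index(self):
        cal = GranierCalibration()
        dts = np.linspace(0.5, 10.0, 50)  # decreasing dT = increasing K
        flows = granier_sap_flow(dts, cal)
        assert (np.diff(flows) < 0).all()

    @pytest.mark.parametrize("dt", [0.0, -1.0, 10.5])
    def test_sensor_range_enforced(self, dt):
        with pytest.raises(ValueError):
            granier_sap_flow(dt, GranierCalibration(delta_t_max_c=10.0))


def window_records(mean_by_arm, sd, n_plants, days=3, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    ts = pd.date_range("2018-09-01", periods=days * 288, freq="5min")
    for inoc, mean in mean_by_arm.items():
        for k in range(n_plants):
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp": ts,
                        "plant_id": f"a{inoc}p{k}",
                        "hybrid": "H1",
                        "inoculated": inoc,
                        "regime": "WW",
                        "sapflow": mean + rng.normal(0, sd, len(ts)),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


class TestDailyWindow:
    def test_window_point_count(self):
        recs = window_records({1: 5.0, 0: 5.0}, sd=0.0, n_plants=2, days=1)
        ts = pd.to_datetime(recs["timestamp"])
        tod = ts - ts.dt.normalize()
        in_window = recs[(tod >= pd.Timedelta("10:00:00")) & (tod < pd.Timedelta("16:00:00"))]
        assert in_window.groupby("plant_id").size().eq(72).all()  # 6 h x 12/h

    def test_identical_arms_no_stars(self):
        recs = window_records({1: 5.0, 0: 5.0}, sd=0.0, n_plants=4)
        out = daily_window_compare(recs)
        assert (out["stars"] == "").all()

    def test_contrasting_arms_flagged(self):
        # arm means mimicking a strong midday sap-flow contrast
        recs = window_records({1: 5.0, 0: 2.2}, sd=0.2, n_plants=4)
        out = daily_window_compare(recs)
        assert (out["mean_a"] / out["mean_b"]).mean() == pytest.approx(2.27, rel=0.05)
        assert (out["p_value"] <= 0.05).all()
        assert (out["stars"] != "").all()

    def test_empty_window_rejected(self):
        recs = window_records({1: 5.0, 0: 2.0}, sd=0.1, n_plants=2, days=1)
        with pytest.raises(ValueError):
            daily_window_compare(recs, window=("16:00", "10:00"))

    def test_star_thresholds(self):
        assert star_code(0.04) == "*"
        assert star_code(0.009) == "**"
        assert star_code(0.0009) == "***"
        assert star_code(0.2) == ""
        assert star_code(float("nan")) == ""


class TestTreatmentContrastModel:
    def test_fit_recovers_injected_offset(self, sim, small_design):
        model = TreatmentContrast(sim["plants"], value_col="tleaf_c",
                                  hybrid="DKB177", regime="WW")
        res = model.fit()
        assert res.area.n_bins == small_design.duration_das * 48
        assert res.area.neg_area > 10 * res.area.pos_area
        assert "significant" in res.summary()

    def test_requires_single_cell(self, sim):
        with pytest.raises(ValueError, match="single hybrid"):
            TreatmentContrast(sim["plants"], value_col="tleaf_c").fit()
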