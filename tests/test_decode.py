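"""Quality filtering, dye calibration, and ratio-to-ribosome decoding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gradecode.decode import (decode_experiment, fit_dye_calibration,
                              normalize_abundance, position_to_time,
                              quality_filter, ratio_to_position)
from gradecode.encoding import assign_doping_controls, make_encoding_scheme
from gradecode.gradient import GradientGeometry, RibosomeCalibration
from gradecode.simulate import SimConfig, simulate_gradient_run, simulate_truth


def feature_row(feature_id="f1", pixel_r=0.9, ib_cy5=10.0, ib_cy3=10.0,
                log2_ratio=0.0, is_control=False, control_fraction=np.nan):
    cy3 = 1000.0
    return {"feature_id": feature_id, "gene_id": "g", "transcript_id": "t",
            "cy5": cy3 * 2 ** log2_ratio, "cy3": cy3, "log2_ratio": log2_ratio,
            "pixel_r": pixel_r, "ib_cy5": ib_cy5, "ib_cy3": ib_cy3,
            "is_control": is_control, "control_fraction": control_fraction}


class TestQualityFilter:
    @pytest.mark.parametrize("pixel_r,ib5,ib3,kept", [
        (0.55, 2.0, 2.4, False),   # fails both criteria
        (0.55, 2.6, 1.0, True),    # I/B >= 2.5 in one channel suffices
        (0.60, 1.0, 1.0, True),    # regression threshold is inclusive
        (0.59, 2.5, 1.0, True),    # I/B threshold is inclusive
        (0.95, 0.5, 0.5, True),    # regression alone suffices
    ])
    def test_threshold_semantics(self, pixel_r, ib5, ib3, kept):
        table = pd.DataFrame([feature_row(pixel_r=pixel_r, ib_cy5=ib5, ib_cy3=ib3)])
        kept_df, rejected = quality_filter(table)
        assert (len(kept_df) == 1) == kept
        assert len(kept_df) + len(rejected) == 1

    def test_partition_is_exact(self, rng):
        rows = [feature_row(feature_id=f"f{i}", pixel_r=rng.uniform(0.3, 1.0),
                            ib_cy5=rng.uniform(0.5, 5.0), ib_cy3=rng.uniform(0.5, 5.0))
                for i in range(200)]
        table = pd.DataFrame(rows)
        kept, rejected = quality_filter(table)
        assert len(kept) + len(rejected) == len(table)
        assert set(kept["feature_id"]).isdisjoint(rejected["feature_id"])
        assert set(kept["feature_id"]) | set(rejected["feature_id"]) \
            == set(table["feature_id"])
        assert (rejected["reason"] != "").all()

    def test_missing_quality_field_named(self):
        table = pd.DataFrame([feature_row()])
        table.loc[0, "pixel_r"] = np.nan
        with pytest.raises(ValueError, match="pixel_r"):
            quality_filter(table)


class TestDyeCalibration:
    def _control_table(self, dope, measured):
        rows = []
        for (_, c), m in zip(dope.controls.iterrows(), measured):
            rows.append(feature_row(feature_id=c["control_id"], log2_ratio=m,
                                    is_control=True,
                                    control_fraction=float(c["fraction"])))
        return pd.DataFrame(rows)

    def test_pure_offset(self, scheme15, dope15):
        measured = dope15.controls["expected_log2_ratio"] + 0.3
        cal = fit_dye_calibration(self._control_table(dope15, measured), dope15)
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.3)
        assert np.allclose(cal.calibrate(measured),
                           dope15.controls["expected_log2_ratio"])

    def test_affine_distortion(self, scheme15, dope15):
        measured = 1.2 * dope15.controls["expected_log2_ratio"] - 0.1
        cal = fit_dye_calibration(self._control_table(dope15, measured), dope15)
        assert cal.slope == pytest.approx(1.2)
        assert cal.intercept == pytest.approx(-0.1)

    def test_slope_recovery_under_noise(self, dope15):
        expected = dope15.controls["expected_log2_ratio"].to_numpy()
        for seed in range(100):
            rng = np.random.default_rng(seed)
            measured = expected + rng.normal(0, 0.05, expected.size)
            cal = fit_dye_calibration(self._control_table(dope15, measured), dope15)
            assert abs(cal.slope - 1.0) < 0.05

    def test_single_fraction_degenerate(self, dope15):
        one = dope15.controls.loc[dope15.controls["fraction"] == 3]
        table = pd.DataFrame([feature_row(feature_id=c["control_id"], is_control=True,
                                          control_fraction=3.0)
                              for _, c in one.iterrows()])
        with pytest.raises(ValueError):
            fit_dye_calibration(table, dope15)


class TestRatioToPosition:
    def test_symmetric_zero_maps_to_middle(self, scheme15):
        pos, clamped, _ = ratio_to_position(0.0, scheme15)
        assert pos == pytest.approx(8.0)
        assert not clamped

    def test_endpoint(self, scheme15):
        pos, clamped, _ = ratio_to_position(scheme15.expected_log2_ratio()[-1], scheme15)
        assert pos == pytest.approx(15.0)
        assert not clamped

    def test_midway_in_log2_space(self, scheme15):
        r = scheme15.expected_log2_ratio()
        mid = 0.5 * (r[2] + r[3])
        pos, _, _ = ratio_to_position(mid, scheme15)
        assert pos == pytest.approx(3.5)

    def test_out_of_range_clamps_with_flag(self, scheme15):
        pos, clamped, unclamped = ratio_to_position(np.array([-10.0, 10.0]), scheme15)
        assert np.allclose(pos, [1.0, 15.0])
        assert clamped.all()
        assert unclamped[0] < 1.0 and unclamped[1] > 15.0

    def test_strictly_increasing_inside_range(self, scheme15):
        r = np.linspace(scheme15.expected_log2_ratio()[0],
                        scheme15.expected_log2_ratio()[-1], 101)
        pos, _, _ = ratio_to_position(r, scheme15)
        assert np.all(np.diff(pos) > 0)


class TestPositionToTime:
    def test_midpoint_interpolation_and_extrapolation(self):
        geom = GradientGeometry.equal_fractions(15, 900.0)
        assert position_to_time(1.0, geom) == pytest.approx(30.0)
        assert position_to_time(3.5, geom) == pytest.approx(180.0)
        assert position_to_time(0.5, geom) == pytest.approx(0.0)     # linear below
        assert position_to_time(15.5, geom) == pytest.approx(900.0)  # linear above


class TestDecodeExperiment:
    def test_single_fraction_transcript_round_trip(self, scheme15, dope15):
        geom = GradientGeometry.equal_fractions(15, 900.0)
        calib = RibosomeCalibration(alpha=-17.0, beta=3.6)
        rows = [feature_row(feature_id=c["control_id"],
                            log2_ratio=c["expected_log2_ratio"], is_control=True,
                            control_fraction=float(c["fraction"]))
                for _, c in dope15.controls.iterrows()]
        f = 9
        rows.append(feature_row(feature_id="gene1",
                                log2_ratio=float(scheme15.expected_log2_ratio(f))))
        est = decode_experiment(pd.DataFrame(rows), scheme15, dope15, geom, calib)
        assert len(est) == 1
        expected_k = calib(geom.midpoints()[f - 1])
        assert est["position"].iloc[0] == pytest.approx(float(f), abs=1e-9)
        assert est["avg_ribosomes"].iloc[0] == pytest.approx(expected_k, abs=1e-9)

    def test_noiseless_cohort_correlates_with_truth(self, noiseless_config):
        truth = simulate_truth(noiseless_config)
        run = simulate_gradient_run(truth, noiseless_config, 1, "untreated")
        scheme = noiseless_config.scheme()
        dope = assign_doping_controls(scheme, noiseless_config.controls_per_fraction)
        est = decode_experiment(run.feature_table, scheme, dope,
                                run.geometry, run.calibration).set_index("feature_id")
        tt = run.truth_table.set_index("feature_id")
        r = stats.pearsonr(est["avg_ribosomes"], tt["true_avg_ribosomes"]).statistic
        assert r >= 0.999

    def test_controls_decode_to_their_fractions(self, default_config):
        truth = simulate_truth(default_config)
        run = simulate_gradient_run(truth, default_config.noiseless(), 1, "treated")
        scheme = default_config.scheme()
        dope = assign_doping_controls(scheme, default_config.controls_per_fraction)
        controls = run.feature_table.loc[run.feature_table["is_control"]]
        cal = fit_dye_calibration(controls, dope)
        pos, _, _ = ratio_to_position(cal.calibrate(controls["log2_ratio"]), scheme)
        assert np.allclose(pos, controls["control_fraction"], atol=0.01)


class TestNormalizeAbundance:
    def _table(self, gene_ratios, spike_measured, spike_expected):
        rows = [{"feature_id": f"g{i}", "gene_id": f"g{i}", "log2_ratio": v}
                for i, v in enumerate(gene_ratios)]
        rows += [{"feature_id": fid, "gene_id": fid, "log2_ratio": m}
                 for fid, m in spike_measured.items()]
        return pd.DataFrame(rows), spike_expected

    def test_offset_correction(self):
        spikes = {"s-1": -0.6, "s0": 0.4, "s1": 1.4}
        expected = {"s-1": -1.0, "s0": 0.0, "s1": 1.0}
        table, exp = self._table([0.4, 1.4], spikes, expected)
        genes, cal = normalize_abundance(table, exp)
        assert cal.intercept == pytest.approx(0.4)
        assert np.allclose(genes["log2_abundance_ratio"], [0.0, 1.0])

    def test_self_vs_self_centers_at_zero(self, rng):
        gene_ratios = rng.normal(0.1, 0.05, 500)  # small shared offset + noise
        spikes = {f"s{k}": k + rng.normal(0.1, 0.01) for k in (-1.0, 0.0, 1.0)}
        expected = {f"s{k}": k for k in (-1.0, 0.0, 1.0)}
        table, exp = self._table(gene_ratios, spikes, expected)
        genes, _ = normalize_abundance(table, exp)
        assert abs(genes["log2_abundance_ratio"].median()) <= 0.02

    def test_slope_compression_restored(self, rng):
        levels = (-2.0, -1.0, 0.0, 1.0, 2.0)
        spikes = {f"s{k}": 0.8 * k + rng.normal(0, 0.005) for k in levels}
        expected = {f"s{k}": k for k in levels}
        table, exp = self._table([0.8 * 1.5], spikes, expected)
        genes, cal = normalize_abundance(table, exp)
        corrected = {fid: (m - cal.intercept) / cal.slope for fid, m in spikes.items()}
        slope = stats.linregress(list(expected.values()),
                                 list(corrected.values())).slope
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_requires_two_spike_levels(self):
        table, exp = self._table([0.0], {"s0": 0.0}, {"s0": 0.0})
        with pytest.raises(ValueError):
            normalize_abundance(table, exp)
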