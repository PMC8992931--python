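"""Unit tests for the commissioning-data layer and dosimetry primitives."""
import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stereomu import beam_model as bm
from stereomu.exceptions import ConfigurationError, FitError, InputError


# -- equivalent square ------------------------------------------------------

class TestEquivalentSquare:
    def test_smallest_cone_worked_example(self):
        """The 4 mm cone corresponds to a 3.54 x 3.54 mm equivalent square."""
        assert round(bm.equivalent_square(4.0), 2) == 3.54

    def test_high_precision_value(self):
        # 5 * sqrt(pi) for the 10 mm cone
        assert bm.equivalent_square(10.0) == pytest.approx(8.8622692545, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_non_positive_diameter_rejected(self, bad):
        with pytest.raises(InputError):
            bm.equivalent_square(bad)

    @given(
        st.floats(min_value=0.5, max_value=50.0),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_linear_in_diameter(self, diameter, k):
        assert bm.equivalent_square(k * diameter) == pytest.approx(
            k * bm.equivalent_square(diameter), rel=1e-12
        )


# -- two-term exponential correction-factor fit -----------------------------

def _sample_curve(a, b, c, d, s):
    return a * np.exp(b * s) + c * np.exp(d * s)


class TestCorrectionCurveFit:
    GEN = (0.93, 0.004, 0.12, -0.25)

    def test_noise_free_recovery(self):
        """Fitting exact samples reproduces the generating curve values.

        Only curve evaluations are compared (the two terms are exchangeable,
        so parameter identity is not asserted).
        """
        s = np.linspace(3.0, 18.0, 10)
        k = _sample_curve(*self.GEN, s)
        fit = bm.fit_correction_curve(np.column_stack([s, k]))
        assert fit(s) == pytest.approx(k, rel=1e-6)
        # extrapolation below the smallest fitted s stays close to the model
        assert fit(2.0) == pytest.approx(_sample_curve(*self.GEN, 2.0), rel=1e-4)

    def test_constant_data(self):
        s = np.linspace(3.0, 18.0, 7)
        fit = bm.fit_correction_curve(np.column_stack([s, np.ones_like(s)]))
        assert fit(s) == pytest.approx(np.ones_like(s), rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_fit_quality(self):
        rng = np.random.default_rng(0)
        s = np.linspace(3.0, 18.0, 8)
        k = _sample_curve(*self.GEN, s) + rng.normal(0.0, 0.002, size=s.shape)
        fit = bm.fit_correction_curve(np.column_stack([s, k]))
        # independent residual computation
        resid = k - fit(s)
        r2 = 1.0 - float(resid @ resid) / float(np.sum((k - k.mean()) ** 2))
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)
        assert r2 > 0.99

    def test_too_few_points(self):
        s = np.array([3.0, 5.0, 8.0, 12.0])
        with pytest.raises(FitError):
            bm.fit_correction_curve(np.column_stack([s, np.ones_like(s)]))

    def test_invalid_s_values(self):
        with pytest.raises(InputError):
            bm.fit_correction_curve([(0.0, 1.0), (1, 1), (2, 1), (3, 1), (4, 1)])
        with pytest.raises(InputError):
            bm.fit_correction_curve([(1.0, 1.0), (1.0, 1.0), (2, 1), (3, 1), (4, 1)])


# -- TMR resampling / lookup / PDD ------------------------------------------

def _linear_tmr(dmax=15.0):
    depths = np.arange(0.0, 201.0, 1.0)
    vals = np.where(depths < dmax, (depths / dmax) ** 2, np.exp(-0.004 * (depths - dmax)))
    return bm.resample_and_normalize_tmr(depths, np.maximum(vals, 1e-4), dmax=dmax)


class TestTMRTable:
    def test_pure_normalization(self):
        depths = np.arange(0.0, 51.0)
        vals = np.full_like(depths, 2.0)
        t = bm.resample_and_normalize_tmr(depths, vals, dmax=15.0)
        assert t.values == pytest.approx(np.ones_like(depths))

    def test_linear_midpoint_before_normalization(self):
        t = bm.resample_and_normalize_tmr([10.0, 20.0], [0.9, 0.7], dmax=15.0)
        # grid node 15 mm is the linear midpoint 0.8; it is also dmax here,
        # so after normalization the neighbours sit at 0.85/0.8 and 0.75/0.8
        assert t.lookup(15.0) == pytest.approx(1.0)
        assert t.lookup(10.0) == pytest.approx(0.9 / 0.8)

    def test_dmax_recorded(self):
        t = _linear_tmr(dmax=15.0)
        assert t.dmax == 15.0
        assert t.lookup(t.dmax) == pytest.approx(1.0)

    def test_dmax_outside_range_rejected(self):
        with pytest.raises(InputError):
            bm.resample_and_normalize_tmr([10.0, 20.0], [1.0, 0.9], dmax=30.0)

    def test_lookup_exact_at_all_grid_nodes(self):
        t = _linear_tmr()
        assert t.lookup(t.depths) == pytest.approx(t.values, rel=0, abs=0)

    def test_lookup_negative_depth_rejected(self):
        with pytest.raises(InputError):
            _linear_tmr().lookup(-1.0)

    @given(st.integers(min_value=16, max_value=199))
    def test_piecewise_linear_between_nodes(self, node):
        t = _linear_tmr()
        mid = t.depths[node] + 0.5
        assert t.lookup(mid) == pytest.approx(
            0.5 * (t.values[node] + t.values[node + 1]), rel=1e-12
        )

    def test_log_linear_extrapolation_beyond_grid(self):
        t = _linear_tmr()
        slope = np.log(t.values[-1] / t.values[-2])
        assert t.lookup(210.0) == pytest.approx(t.values[-1] * np.exp(10 * slope))
        assert t.lookup(210.0) > 0

    def test_smoothing_window_validation(self):
        with pytest.raises(InputError):
            bm.resample_and_normalize_tmr(
                np.arange(0.0, 40.0), np.ones(40), dmax=15.0, smooth_window=4
            )


class TestTMRtoPDD:
    def test_unity_at_dmax(self):
        t = _linear_tmr()
        assert bm.tmr_to_pdd(t, 900.0, t.dmax) == pytest.approx(100.0)

    def test_inverse_square_arithmetic(self):
        # constant TMR isolates the inverse-square factor
        depths = np.arange(0.0, 101.0)
        t = bm.resample_and_normalize_tmr(depths, np.ones_like(depths), dmax=15.0)
        assert bm.tmr_to_pdd(t, 900.0, 50.0) == pytest.approx(
            100.0 * (915.0 / 950.0) ** 2
        )

    def test_pdd_below_tmr_beyond_dmax(self):
        t = _linear_tmr()
        for d in (20.0, 50.0, 120.0):
            assert bm.tmr_to_pdd(t, 900.0, d) < 100.0 * t.lookup(d)

    def test_round_trip_recovers_tmr(self):
        """Undoing the inverse-square factor recovers TMR to machine precision."""
        t = _linear_tmr()
        ssd = 900.0
        d = np.arange(0.0, 200.0, 7.0)
        pdd = bm.tmr_to_pdd(t, ssd, d)
        back = pdd / 100.0 * ((ssd + d) / (ssd + t.dmax)) ** 2
        assert back == pytest.approx(t.lookup(d), rel=1e-14)


# -- OF at TMR max -----------------------------------------------------------

class TestOfAtTMRmax:
    def _archive_with(self, tmr_values_const=None, ssd=985.0, d_meas=15.0, of=0.5):
        depths = np.arange(0.0, 201.0)
        if tmr_values_const is not None:
            vals = np.full_like(depths, tmr_values_const)
        else:
            vals = np.maximum(
                np.where(depths < 15.0, (depths / 15.0) ** 2,
                         np.exp(-0.004 * (depths - 15.0))), 1e-4,
            )
        table = bm.resample_and_normalize_tmr(depths, vals, dmax=15.0, cone_id=10.0)
        return bm.BeamDataArchive(
            machine="m", energy="e",
            cones={10.0: bm.ConeRecord(10.0, table, of)},
            output_geometry_ssd_mm=ssd,
            output_geometry_depth_mm=d_meas,
            calibration=bm.AbsoluteCalibration(
                dr_ref_gy_per_mu=0.01, depth_mm=15.0, ssd_mm=985.0, sad_mm=1000.0
            ),
            ct_curve=bm.CTCalibrationCurve([-1000.0, 0.0, 1000.0], [0.0, 1.0, 1.6]),
        )

    def test_all_factors_unity(self):
        """TMR == 1, measurement at dmax, SSD + dmax = SAD gives OF unchanged."""
        a = self._archive_with(tmr_values_const=1.0, ssd=985.0, d_meas=15.0, of=1 - 1e-9)
        assert bm.of_at_tmrmax(a, 10.0) == pytest.approx(1.0, rel=1e-6)

    def test_factor_by_factor_oracle(self):
        a = self._archive_with(ssd=950.0, d_meas=50.0, of=0.7)
        t = a.cone(10.0).tmr
        pdd_ratio = bm.tmr_to_pdd(t, 950.0, 15.0) / bm.tmr_to_pdd(t, 950.0, 50.0)
        expected = 0.7 * pdd_ratio * ((950.0 + 15.0) / 1000.0) ** 2
        assert bm.of_at_tmrmax(a, 10.0) == pytest.approx(expected, rel=1e-12)

    def test_algebraic_identity(self):
        """OF_TMRmax/OF = (1/TMR(d)) * ((SSD+d)/(SSD+dmax))^2 * ((SSD+dmax)/SAD)^2."""
        a = self._archive_with(ssd=950.0, d_meas=50.0, of=0.7)
        t = a.cone(10.0).tmr
        lhs = bm.of_at_tmrmax(a, 10.0) / 0.7
        rhs = (
            (1.0 / t.lookup(50.0))
            * ((950.0 + 50.0) / (950.0 + 15.0)) ** 2
            * ((950.0 + 15.0) / 1000.0) ** 2
        )
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_missing_cone(self):
        a = self._archive_with()
        with pytest.raises(LookupError):
            bm.of_at_tmrmax(a, 7.5)


# -- CT calibration curve -----------------------------------------------------

class TestCTCalibrationCurve:
    def test_clamps_and_interpolates(self):
        c = bm.CTCalibrationCurve([-1000.0, 0.0, 1000.0], [0.0, 1.0, 1.6])
        assert c.red_at(-2000.0) == 0.0
        assert c.red_at(500.0) == pytest.approx(1.3)
        assert c.red_at(4000.0) == pytest.approx(1.6)

    def test_water_anchor_required(self):
        with pytest.raises(ConfigurationError):
            bm.CTCalibrationCurve([-1000.0, 0.0, 1000.0], [0.0, 0.5, 1.0])

    def test_monotonicity_required(self):
        with pytest.raises(ConfigurationError):
            bm.CTCalibrationCurve([-1000.0, 0.0, 1000.0], [0.0, 1.0, 0.9])


# -- archive build / round trip ----------------------------------------------

def _write_commissioning_csvs(tmp_path, cones=(4.0, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5)):
    depths = np.arange(0.0, 201.0)
    tmr_csvs = {}
    for c in cones:
        vals = np.maximum(
            np.where(depths < 15.0, (depths / 15.0) ** 2,
                     np.exp(-0.004 * (depths - 15.0))), 1e-4,
        )
        p = tmp_path / f"tmr_{c:g}.csv"
        p.write_text(
            "depth_mm,value\n"
            + "\n".join(f"{d:g},{v:.9g}" for d, v in zip(depths, vals))
        )
        tmr_csvs[c] = str(p)
    of_path = tmp_path / "of.csv"
    of_path.write_text(
        "cone_mm,of\n" + "\n".join(f"{c:g},{0.88 - 0.3 * np.exp(-0.12 * c):.6f}" for c in cones)
    )
    ct_path = tmp_path / "ct.csv"
    ct_path.write_text("hu,red\n-1000,0\n0,1\n1000,1.6\n3000,2.5\n")
    return {
        "machine": "TB1",
        "energy": "6FFF",
        "dmax_mm": 15.0,
        "tmr_csvs": tmr_csvs,
        "of_csv": str(of_path),
        "ct_csv": str(ct_path),
        "dr_ref_gy_per_mu": 0.01,
    }


class TestArchive:
    def test_seven_cone_build_and_round_trip(self, tmp_path):
        cfg = _write_commissioning_csvs(tmp_path)
        a = bm.build_archive(cfg)
        assert sorted(a.cones) == [4.0, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5]
        p1, p2 = tmp_path / "a1.json", tmp_path / "a2.json"
        a.save(p1)
        b = bm.BeamDataArchive.load(p1)
        b.save(p2)
        assert p1.read_bytes() == p2.read_bytes()  # byte-identical re-serialization
        for c in a.cones:
            assert b.cones[c].tmr.values == pytest.approx(
                a.cones[c].tmr.values, rel=0, abs=0
            )

    def test_missing_cone_file_names_the_field(self, tmp_path):
        cfg = _write_commissioning_csvs(tmp_path)
        del cfg["tmr_csvs"][4.0]
        with pytest.raises(ConfigurationError, match="cone 4"):
            bm.build_archive(cfg)

    def test_empty_cone_list_rejected(self, tmp_path):
        cfg = _write_commissioning_csvs(tmp_path)
        (tmp_path / "of.csv").write_text("cone_mm,of\n")
        with pytest.raises(ConfigurationError):
            bm.build_archive(cfg)

    def test_calibration_without_drref_rejected(self, tmp_path):
        cfg = _write_commissioning_csvs(tmp_path)
        cfg["dr_ref_gy_per_mu"] = None
        with pytest.raises(ConfigurationError, match="dr_ref"):
            bm.build_archive(cfg)

    def test_non_monotone_depth_grid_rejected(self, tmp_path):
        cfg = _write_commissioning_csvs(tmp_path)
        bad = tmp_path / "bad.csv"
        bad.write_text("depth_mm,value\n0,0.1\n10,0.5\n5,0.4\n20,1.0\n")
        cfg["tmr_csvs"][4.0] = str(bad)
        with pytest.raises(InputError):
            bm.build_archive(cfg)

    def test_archive_json_schema(self, tmp_path):
        cfg = _write_commissioning_csvs(tmp_path)
        a = bm.build_archive(cfg)
        p = tmp_path / "a.json"
        a.save(p)
        d = json.loads(p.read_text())
        assert set(d) >= {"format_version", "machine", "energy", "calibration",
                          "ct_curve", "cones"}
        cone = d["cones"][0]
        assert set(cone) >= {"diameter_mm", "dmax_mm", "of", "of_geometry", "tmr"}
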