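"""Ray construction, arc segmentation, traversal and depth computations."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stereomu import fixtures as fx
from stereomu import geometry as geo
from stereomu.exceptions import GeometryError, InputError

from conftest import fine_step_epl, volume_entry_parameter


def _rotation_oracle(gantry_deg, couch_deg, sad):
    """Independent rotation-matrix construction of the source position.

    Build the source in the IEC fixed frame (z up, y toward the gantry),
    rotate the patient support about the vertical axis, then map the fixed
    frame onto LPS for a head-first supine patient.
    """
    g, c = math.radians(gantry_deg), math.radians(couch_deg)
    src_fixed = sad * np.array([math.sin(g), 0.0, math.cos(g)])
    rz = np.array(
        [[math.cos(-c), -math.sin(-c), 0.0],
         [math.sin(-c), math.cos(-c), 0.0],
         [0.0, 0.0, 1.0]]
    )
    src_fixed = rz @ src_fixed
    # fixed -> LPS (HFS): Xf -> +x, Yf -> +z, Zf -> -y
    to_lps = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
    return to_lps @ src_fixed


class TestRayForAngles:
    def test_gantry_zero_source_anterior(self):
        ray = geo.ray_for_angles(np.zeros(3), 0.0, 0.0, 1000.0)
        assert ray.source == pytest.approx([0.0, -1000.0, 0.0], abs=1e-9)

    def test_gantry_90_source_patient_left(self):
        ray = geo.ray_for_angles(np.zeros(3), 90.0, 0.0, 1000.0)
        assert ray.source == pytest.approx([1000.0, 0.0, 0.0], abs=1e-9)

    @given(
        st.floats(min_value=0.0, max_value=360.0),
        st.floats(min_value=-90.0, max_value=90.0),
    )
    def test_source_at_sad_any_angles(self, gantry, couch):
        iso = np.array([10.0, -20.0, 5.0])
        ray = geo.ray_for_angles(iso, gantry, couch, 1000.0)
        assert np.linalg.norm(ray.source - iso) == pytest.approx(1000.0, abs=1e-6)
        assert np.linalg.norm(ray.direction) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("gantry", [0.0, 37.0, 90.0, 180.0, 271.5])
    @pytest.mark.parametrize("couch", [0.0, 30.0, 90.0, -45.0])
    def test_matches_rotation_matrix_oracle(self, gantry, couch):
        ray = geo.ray_for_angles(np.zeros(3), gantry, couch, 1000.0)
        assert ray.source == pytest.approx(
            _rotation_oracle(gantry, couch, 1000.0), abs=1e-9
        )

    def test_non_positive_sad_rejected(self):
        with pytest.raises(InputError):
            geo.ray_for_angles(np.zeros(3), 0.0, 0.0, 0.0)


class TestSegmentArc:
    def test_half_rotation_cw_has_181_angles(self):
        angles = geo.segment_arc(0.0, 180.0, "CW", 1.0)
        assert len(angles) == 181
        assert angles[0] == 0.0 and angles[-1] == 180.0

    def test_static_beam_single_angle(self):
        assert geo.segment_arc(42.0, 42.0, "NONE", 1.0) == pytest.approx([42.0])

    def test_wraparound_through_zero(self):
        angles = geo.segment_arc(350.0, 10.0, "CW", 1.0)
        assert len(angles) == 21
        assert 0.0 in angles and angles[0] == 350.0 and angles[-1] == 10.0

    def test_counterclockwise_direction(self):
        angles = geo.segment_arc(10.0, 350.0, "CC", 1.0)
        assert len(angles) == 21
        assert angles[1] == pytest.approx(9.0)

    def test_non_integer_span_still_includes_stop(self):
        angles = geo.segment_arc(0.0, 10.5, "CW", 1.0)
        assert angles[-1] == pytest.approx(10.5)

    def test_invalid_resolution(self):
        with pytest.raises(InputError):
            geo.segment_arc(0.0, 180.0, "CW", 0.0)

    @given(
        st.floats(min_value=0.0, max_value=359.0),
        st.integers(min_value=1, max_value=359),
    )
    def test_fencepost_count(self, start, span):
        angles = geo.segment_arc(start, (start + span) % 360.0, "CW", 1.0)
        assert len(angles) == span + 1


class TestGeometricDepth:
    def test_cylinder_depth_all_axial_angles(self, cylinder_phantom_raw):
        """Any axial beam into a centred 80 mm cylinder sees d = 80 mm."""
        ct, sset = cylinder_phantom_raw
        for gantry in range(0, 360, 15):
            ray = geo.ray_for_angles(np.zeros(3), gantry, 0.0, 1000.0)
            d = geo.geometric_depth(ray, sset)
            assert d == pytest.approx(80.0, abs=0.05)

    def test_mask_based_depth_within_half_voxel(self, cylinder_phantom_raw):
        ct, sset = cylinder_phantom_raw
        mask = sset.body_mask(ct)
        for gantry in (0, 45, 90, 210):
            ray = geo.ray_for_angles(np.zeros(3), gantry, 0.0, 1000.0)
            d = geo.geometric_depth(ray, (mask, ct))
            assert d == pytest.approx(80.0, abs=ct.spacing[0])

    def test_isocenter_near_surface_small_depth(self, cylinder_phantom_raw):
        ct, sset = cylinder_phantom_raw
        iso = np.array([0.0, -79.5, 0.0])  # 0.5 mm inside the anterior surface
        ray = geo.ray_for_angles(iso, 0.0, 0.0, 1000.0)
        assert geo.geometric_depth(ray, sset) == pytest.approx(0.5, abs=0.05)

    def test_opposing_beams_symmetric(self, cylinder_phantom_raw):
        ct, sset = cylinder_phantom_raw
        for g in (0, 30, 75):
            d1 = geo.geometric_depth(geo.ray_for_angles(np.zeros(3), g, 0.0, 1000.0), sset)
            d2 = geo.geometric_depth(
                geo.ray_for_angles(np.zeros(3), g + 180.0, 0.0, 1000.0), sset
            )
            assert d1 == pytest.approx(d2, abs=0.05)

    def test_isocenter_outside_body_rejected(self, cylinder_phantom_raw):
        ct, sset = cylinder_phantom_raw
        ray = geo.ray_for_angles(np.array([0.0, -200.0, 0.0]), 0.0, 0.0, 1000.0)
        with pytest.raises(GeometryError):
            geo.geometric_depth(ray, sset)


class TestEffectiveDepth:
    def test_all_water_ct_deff_equals_d(self, cylinder_phantom_raw):
        """With water HU everywhere, the RED weighting is unity and the EPL
        collapses to the geometric depth."""
        _, sset = cylinder_phantom_raw
        ct = fx.build_phantom(fx.homogeneous_phantom())[0]
        ct.hu[:] = 0.0
        curve = fx.FIXTURE_CT_CURVE
        for g in (0, 40, 90, 200):
            ray = geo.ray_for_angles(np.zeros(3), g, 0.0, 1000.0)
            res = geo.compute_depths(ray, ct, curve, sset, include_couch=False)
            assert res.deff_mm == pytest.approx(res.d_mm, abs=0.1)

    def test_partial_volume_water_cylinder_within_half_voxel(self, cylinder_phantom_raw):
        """On a CT with air outside the body, the surface voxel's
        partial-volume HU leaves at most ~half a voxel of ambiguity."""
        ct, sset = cylinder_phantom_raw
        ray = geo.ray_for_angles(np.zeros(3), 90.0, 0.0, 1000.0)
        res = geo.compute_depths(ray, ct, fx.FIXTURE_CT_CURVE, sset,
                                 include_couch=False)
        assert res.deff_mm == pytest.approx(res.d_mm, abs=0.5 * ct.spacing[0])

    def test_dense_slab_adds_its_excess_path(self):
        """A 20 mm slab of RED 2 crossed perpendicularly adds 20 mm to deff."""
        ph = fx.PhantomSpec(body_shape="cylinder", semiaxes=(80.0, 80.0, 30.0),
                            spacing_mm=2.0)
        ct, sset = fx.build_phantom(ph)
        ct.hu[:] = 0.0  # water throughout; isolate the slab arithmetic
        curve = fx.FIXTURE_CT_CURVE
        # 20 mm slab aligned to voxel boundaries (centres -48..-30), RED 2
        hu_slab = curve.hu_for_red(2.0)
        ys = ct.index_to_world(
            np.column_stack([np.zeros(ct.shape[1]), np.arange(ct.shape[1]),
                             np.zeros(ct.shape[1])])
        )[:, 1]
        rows = (ys > -49.0) & (ys < -29.0)
        ct.hu[:, rows, :] = hu_slab
        ray = geo.ray_for_angles(np.zeros(3), 0.0, 0.0, 1000.0)  # anterior, crosses slab
        res = geo.compute_depths(ray, ct, curve, sset, include_couch=False)
        assert res.deff_mm == pytest.approx(res.d_mm + 20.0, abs=0.5)

    def test_siddon_matches_fine_step_sampling(self, thorax_bundle):
        ct = thorax_bundle.ct
        curve = fx.FIXTURE_CT_CURVE
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = rng.uniform(0.0, 360.0)
            ray = geo.ray_for_angles(np.zeros(3), g, 0.0, 1000.0)
            t0 = volume_entry_parameter(ct, ray.source, ray.isocenter)
            deff = geo.effective_depth(ray, ct, curve, include_couch=True)
            oracle = fine_step_epl(ct, curve, ray.source, ray.isocenter, t0)
            assert deff == pytest.approx(oracle, abs=0.2)

    def test_monotone_in_traversed_red(self, cylinder_phantom_raw):
        ct, sset = cylinder_phantom_raw
        curve = fx.FIXTURE_CT_CURVE
        ray = geo.ray_for_angles(np.zeros(3), 0.0, 0.0, 1000.0)
        base = geo.compute_depths(ray, ct, curve, sset, include_couch=False).deff_mm
        ct2 = fx.build_phantom(fx.homogeneous_phantom())[0]
        ct2.hu[ct2.hu > -100] = 500.0  # raise RED of every body voxel
        denser = geo.compute_depths(ray, ct2, curve, sset, include_couch=False).deff_mm
        assert denser > base

    def test_traversal_length_conservation(self, cylinder_phantom_raw):
        """Sum of in-body voxel intersection lengths equals the in-body chord
        measured independently by dense sampling of the same mask."""
        ct, sset = cylinder_phantom_raw
        mask = sset.body_mask(ct)
        for g in (0, 90, 135):
            ray = geo.ray_for_angles(np.zeros(3), g, 0.0, 1000.0)
            res = geo.compute_depths(
                ray, ct, fx.FIXTURE_CT_CURVE, sset, include_couch=False, mask=mask
            )
            # fine-step membership integration over the same domain
            t0 = 1.0 - res.d_mm / 1000.0
            n = 20000
            ts = t0 + (1.0 - t0) * (np.arange(n) + 0.5) / n
            pts = ray.source[None, :] + ts[:, None] * (ray.isocenter - ray.source)
            idx = np.floor(ct.world_to_index(pts) + 0.5).astype(int)
            inside = mask[idx[:, 2], idx[:, 1], idx[:, 0]]
            chord = float(inside.mean() * res.d_mm)
            assert res.in_body_path_mm == pytest.approx(chord, abs=0.1)

    def test_insufficient_coverage_rejected(self, cylinder_phantom_raw):
        ct, sset = cylinder_phantom_raw
        # couch 90 deg sends the ray along z; truncate the volume so the body
        # surface lies outside the scan
        ray = geo.ray_for_angles(np.zeros(3), 90.0, 90.0, 1000.0)
        ct_short = fx.build_phantom(fx.homogeneous_phantom())[0]
        ct_short.hu = ct_short.hu[20:-20]
        ct_short.origin = ct_short.index_to_world(np.array([0.0, 0.0, 20.0]))
        with pytest.raises(GeometryError, match="coverage"):
            geo.effective_depth(ray, ct_short, fx.FIXTURE_CT_CURVE, sset,
                                include_couch=False)

    def test_rotational_symmetry_of_depths(self, cylinder_phantom_raw):
        ct, sset = cylinder_phantom_raw
        ds, deffs = [], []
        for g in range(0, 360, 10):
            ray = geo.ray_for_angles(np.zeros(3), g, 0.0, 1000.0)
            res = geo.compute_depths(ray, ct, fx.FIXTURE_CT_CURVE, sset,
                                     include_couch=False)
            ds.append(res.d_mm)
            deffs.append(res.deff_mm)
        assert np.ptp(ds) < 0.5
        assert np.ptp(deffs) < 0.5
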