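import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conetomo.membranes import MembranePlane
from conetomo.morphometry import (Point3D, SpheruleMorphometry, VesicleRecord,
                                  classify_fusion_state, count_weight,
                                  density_from_spacing, equivalent_sphere,
                                  fraction_inside_slab, percent_of_baseline,
                                  point_distance, summarize_conditions,
                                  surface_area_slab, triplet_angle,
                                  vesicle_volume_um3, vesicles_for_area,
                                  vesicles_for_volume, vesicles_per_spherule,
                                  weighted_count)
from conetomo.phantom import (docked_center_offset, omega_center_offset,
                              render_vesicle)
from conetomo.volume import DensityVolume

finite = st.floats(-1e3, 1e3)
points = st.tuples(finite, finite, finite).map(lambda t: Point3D(*t))


class TestCountingRule:
    @pytest.mark.parametrize("fraction,weight", [
        (0.8, 1.0), (0.5, 0.5), (0.3, 0.0),
        (2.0 / 3.0, 1.0),           # boundary: exactly 2/3 counts whole
        (0.5 + 1e-12, 0.5), (1.0, 1.0), (0.0, 0.0)])
    def test_weights(self, fraction, weight):
        assert count_weight(fraction) == weight

    def test_quoted_example_sums_to_1p5(self):
        assert weighted_count([0.8, 0.5, 0.3]) == 1.5

    def test_all_whole_gives_n(self):
        assert weighted_count([1.0] * 7) == 7.0

    def test_empty_is_zero(self):
        assert weighted_count([]) == 0.0

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            count_weight(1.2)

    @given(st.lists(st.floats(0, 1), max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_never_exceeds_record_count(self, fracs):
        total = weighted_count(fracs)
        assert total <= len(fracs)
        if fracs and all(f > 2.0 / 3.0 for f in fracs):
            assert total == len(fracs)

    def test_fraction_inside_slab_geometry(self):
        # 40 nm vesicle centered at the slab top: half inside
        assert fraction_inside_slab(0.050, 40.0, (0.0, 50.0)) == \
            pytest.approx(0.5)
        assert fraction_inside_slab(0.025, 40.0, (0.0, 50.0)) == 1.0


class TestDistanceAndAngle:
    def test_345_triangle(self):
        assert point_distance(Point3D(0, 0, 0), Point3D(3, 4, 0)) == 5.0

    def test_self_distance_zero(self):
        p = Point3D(1.2, -3.4, 5.6)
        assert point_distance(p, p) == 0.0

    @given(points, points)
    @settings(deadline=None, max_examples=50)
    def test_symmetric(self, a, b):
        assert point_distance(a, b) == pytest.approx(point_distance(b, a))

    def test_collinear_is_180(self):
        assert triplet_angle(Point3D(-1, 0, 0), Point3D(0, 0, 0),
                             Point3D(2, 0, 0)) == pytest.approx(180.0)

    def test_right_angle(self):
        assert triplet_angle(Point3D(1, 0, 0), Point3D(0, 0, 0),
                             Point3D(0, 1, 0)) == pytest.approx(90.0)

    def test_zero_length_vector_rejected(self):
        p = Point3D(0, 0, 0)
        with pytest.raises(ValueError):
            triplet_angle(p, p, Point3D(1, 1, 1))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, (3, 3))
        if min(np.linalg.norm(pts[0] - pts[1]),
               np.linalg.norm(pts[2] - pts[1])) < 1e-3:
            return
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=int(seed % 2**16)).as_matrix()
        t = rng.uniform(-10, 10, 3)
        moved = pts @ R.T + t
        a0 = triplet_angle(*(Point3D(*q) for q in pts))
        a1 = triplet_angle(*(Point3D(*q) for q in moved))
        assert a1 == pytest.approx(a0, abs=1e-6)
        d0 = point_distance(Point3D(*pts[0]), Point3D(*pts[1]))
        d1 = point_distance(Point3D(*moved[0]), Point3D(*moved[1]))
        assert d1 == pytest.approx(d0, rel=1e-9)


class TestDensityArithmetic:
    def test_spacing_endpoints_bracket_reported_density(self):
        assert density_from_spacing(0.120) == pytest.approx(578.7, abs=0.05)
        assert density_from_spacing(0.110) == pytest.approx(751.3, abs=0.05)

    def test_unit_spacing(self):
        assert density_from_spacing(1.0) == 1.0

    def test_identity_and_monotonicity(self):
        for d in (0.05, 0.11, 0.12, 0.5):
            assert density_from_spacing(d) * d**3 == pytest.approx(1.0)
        assert density_from_spacing(0.110) > density_from_spacing(0.120)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            density_from_spacing(0.0)

    def test_per_spherule_budget_brackets_reported_range(self):
        # 580-750 /um^3 over ~10 um^3 of populated cytoplasm: 5,800-7,500
        lo = vesicles_per_spherule(density_from_spacing(0.120), 13.0, 0.75)
        hi = vesicles_per_spherule(density_from_spacing(0.110), 13.0, 0.75)
        assert 5400 < lo < 6000
        assert 7000 < hi < 7700


class TestEquivalentSphere:
    def test_unit_circle(self):
        r, a, v = equivalent_sphere(2 * math.pi)
        assert (r, a, v) == pytest.approx((1.0, 4 * math.pi,
                                           4 * math.pi / 3))

    def test_terminal_scale_matches_reported_dimensions(self):
        # a 1.5 um-radius terminal: area ~27, volume ~13 as reported
        r, a, v = equivalent_sphere(2 * math.pi * 1.5)
        assert r == pytest.approx(1.5)
        assert a == pytest.approx(28.27, abs=0.01)
        assert v == pytest.approx(14.14, abs=0.01)

    @given(st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_volume_area_ratio_is_r_over_3(self, perim):
        r, a, v = equivalent_sphere(perim)
        assert v / a == pytest.approx(r / 3.0)

    def test_nonpositive_perimeter_rejected(self):
        with pytest.raises(ValueError):
            equivalent_sphere(0.0)


class TestSlabArea:
    def test_ten_slices(self):
        assert surface_area_slab([1.0] * 10, 0.005) == pytest.approx(0.05)

    def test_empty_is_zero(self):
        assert surface_area_slab([], 0.005) == 0.0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            surface_area_slab([1.0, -0.1], 0.005)

    def test_cylinder_membrane_oracle(self):
        # analytic oracle: lateral surface of a cylinder of radius R and
        # height H equals the sum of per-slice circumferences x thickness
        R, H, dz = 0.5, 0.2, 0.005
        n = int(round(H / dz))
        lengths = [2 * math.pi * R] * n
        est = surface_area_slab(lengths, dz)
        assert est == pytest.approx(2 * math.pi * R * H, rel=1e-9)


class TestVesicleBudgets:
    def test_volume_loss_needs_over_200k_vesicles(self):
        n = vesicles_for_volume(9.2 - 2.4, 40.0)
        assert n > 200_000
        assert n == pytest.approx(202_916, rel=0.001)

    def test_one_vesicle_volume_is_one(self):
        assert vesicles_for_volume(vesicle_volume_um3(40.0), 40.0) == \
            pytest.approx(1.0)

    def test_volume_linearity(self):
        assert vesicles_for_volume(2.0, 40.0) == \
            pytest.approx(2 * vesicles_for_volume(1.0, 40.0))

    def test_area_of_one_vesicle_membrane_is_one(self):
        assert vesicles_for_area(math.pi * 0.04**2, 40.0) == pytest.approx(1.0)

    def test_expected_area_increase(self):
        assert vesicles_for_area(0.18, 40.0) == pytest.approx(35.81, abs=0.02)

    def test_area_linearity(self):
        assert vesicles_for_area(0.36, 40.0) == \
            pytest.approx(2 * vesicles_for_area(0.18, 40.0))


class TestPercent:
    def test_15min_omega_increase(self):
        assert percent_of_baseline(1280, 187) == pytest.approx(684.5, abs=0.05)

    def test_3to5min_omega_increase(self):
        assert percent_of_baseline(470, 187) == pytest.approx(251.3, abs=0.05)

    def test_self_is_100(self):
        assert percent_of_baseline(42.0, 42.0) == 100.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_of_baseline(1.0, 0.0)


class TestSummaries:
    def test_single_record_sd_zero(self):
        rec = SpheruleMorphometry("light", terminal_volume_um3=13.0,
                                  hc_volume_um3=2.4, hc_area_um2=8.7,
                                  omega_count=187)
        out = summarize_conditions([rec])
        assert out.loc["light", "terminal_volume_um3_mean"] == 13.0
        assert out.loc["light", "terminal_volume_um3_sd"] == 0.0
        assert out.loc["light", "n"] == 1

    def test_two_records_mean_and_sample_sd(self):
        recs = [SpheruleMorphometry("dark 15 min", omega_count=12),
                SpheruleMorphometry("dark 15 min", omega_count=14)]
        out = summarize_conditions(recs, fields=("omega_count",))
        assert out.loc["dark 15 min", "omega_count_mean"] == 13.0
        assert out.loc["dark 15 min", "omega_count_sd"] == \
            pytest.approx(math.sqrt(2))

    def test_condition_order_light_then_dark_times(self):
        recs = [SpheruleMorphometry(c) for c in
                ("dark 30 min", "light", "dark 3-5 min")]
        out = summarize_conditions(recs)
        assert list(out.index) == ["light", "dark 3-5 min", "dark 30 min"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_conditions([])

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            SpheruleMorphometry("light", omega_count=-1)


class TestFusionClassification:
    VOX = 2.0

    def _patch_volume(self, state, membrane=None, center=None):
        shape = (48, 32, 32)
        c = center or (32.0, 32.0, 32.0)
        patch = render_vesicle(state, c, 40.0, membrane, shape_xyz=shape,
                               voxel_size=self.VOX)
        return DensityVolume(patch, self.VOX)

    def test_omega_recognized(self):
        mem = MembranePlane("x", position=50.0, layer_spacing=6.0)
        h = omega_center_offset(40.0, 6.0)
        vol = self._patch_volume("omega", mem, (50.0 - h, 32, 32))
        assert classify_fusion_state((50.0 - h, 32, 32), vol, mem) == "omega"

    def test_docked_recognized(self):
        mem = MembranePlane("x", position=50.0, layer_spacing=6.0)
        h = docked_center_offset(40.0, 6.0)
        vol = self._patch_volume("docked", mem, (50.0 - h, 32, 32))
        assert classify_fusion_state((50.0 - h, 32, 32), vol, mem) == "docked"

    def test_coated_recognized(self):
        mem = MembranePlane("x", position=90.0, layer_spacing=6.0)
        vol = self._patch_volume("coated", None, (32.0, 32, 32))
        assert classify_fusion_state((32.0, 32, 32), vol, mem) == "coated"

    def test_cytoplasmic_fallback(self):
        mem = MembranePlane("x", position=90.0, layer_spacing=6.0)
        vol = self._patch_volume("cytoplasmic", None, (32.0, 32, 32))
        assert classify_fusion_state((32.0, 32, 32), vol, mem) == \
            "cytoplasmic"

    def test_tethered_near_ribbon(self):
        mem = MembranePlane("x", position=90.0, layer_spacing=6.0)
        vol = self._patch_volume("cytoplasmic", None, (32.0, 32, 32))
        ribbon = ((54.0, 70.0), (20.0, 44.0), (10.0, 54.0))
        assert classify_fusion_state((32.0, 32, 32), vol, mem,
                                     ribbon_box_nm=ribbon) == "tethered"


class TestVesicleRecord:
    def test_count_weight_derived_from_fraction(self):
        rec = VesicleRecord(center=Point3D(0, 0, 0), diameter=40.0,
                            fraction_inside=0.55)
        assert rec.count_weight == 0.5

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            VesicleRecord(center=Point3D(0, 0, 0), diameter=40.0,
                          state="hovering")
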