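import numpy as np
import pytest
from scipy.signal import find_peaks

from conetomo.membranes import MembranePlane
from conetomo.phantom import (DENSITY, GeometryError, PackingError,
                              PhantomParams, docked_center_offset,
                              generate_phantom, omega_center_offset,
                              place_fiducials, render_vesicle)


class TestParams:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(n_docked=-1)

    def test_vesicle_must_fit_in_slab(self):
        with pytest.raises(ValueError):
            PhantomParams(vesicle_diameter=60.0, slab_thickness=50.0)

    def test_spacing_must_exceed_diameter(self):
        with pytest.raises(ValueError):
            PhantomParams(spacing_range=(30.0, 40.0))


class TestGeneratePhantom:
    def test_counts_match_params_exactly(self, default_phantom):
        params, _, truth = default_phantom
        counts = truth.state_counts()
        assert counts["cytoplasmic"] == params.n_cytoplasmic
        assert counts["tethered"] == params.n_tethered
        assert counts["docked"] == params.n_docked
        assert counts["omega"] == params.n_omega
        assert counts["coated"] == params.n_coated

    def test_omega_only_phantom_has_exact_omega_count(self):
        # a phantom configured with only fully fused vesicles carries
        # exactly that many omega records (light-adapted per-terminal count
        # scaled to the patch area)
        p = PhantomParams(voxel_size=4.0, shape=(160, 160, 26),
                          membrane_normal="z", membrane_frac=0.33,
                          cytoplasm_side=1, include_ribbon=False,
                          n_cytoplasmic=0, n_tethered=0, n_docked=0,
                          n_coated=0, n_omega=30, n_gold=3, seed=8)
        _, truth = generate_phantom(p)
        assert truth.state_counts()["omega"] == 30
        assert len(truth.vesicles) == 30

    def test_all_zero_counts_gives_empty_vesicle_list(self):
        p = PhantomParams(n_cytoplasmic=0, n_tethered=0, n_docked=0,
                          n_omega=0, n_coated=0, seed=1)
        vol, truth = generate_phantom(p)
        assert truth.vesicles == []
        assert vol.data.max() > 0  # membranes / ribbon / gold still present

    def test_same_seed_bit_identical_different_seed_differs(self):
        a, _ = generate_phantom(PhantomParams(seed=11))
        b, _ = generate_phantom(PhantomParams(seed=11))
        c, _ = generate_phantom(PhantomParams(seed=12))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_pairwise_spacing_invariants(self, default_phantom):
        params, _, truth = default_phantom
        centers = truth.centers_nm()
        states = [v.state for v in truth.vesicles]
        d = np.linalg.norm(centers[:, None] - centers[None], axis=2)
        iu = np.triu_indices(len(centers), 1)
        assert d[iu].min() >= params.surface_spacing - 1e-6
        cyto = [i for i, s in enumerate(states) if s == "cytoplasmic"]
        if len(cyto) > 1:
            dc = d[np.ix_(cyto, cyto)]
            assert dc[np.triu_indices(len(cyto), 1)].min() >= \
                params.spacing_range[0] - 1e-6

    def test_centers_inside_volume(self, default_phantom):
        params, vol, truth = default_phantom
        ext = np.array(vol.extent_nm)
        c = truth.centers_nm()
        assert (c >= 0).all() and (c <= ext).all()

    def test_docked_areal_density_near_150_per_um2(self):
        # configured to the reported areal density: ~150 docked/um^2 over
        # the active zone
        p = PhantomParams(voxel_size=4.0, shape=(433, 433, 26),
                          slab_thickness=50.0, membrane_normal="z",
                          membrane_frac=35.0 / 104.0, cytoplasm_side=1,
                          n_cytoplasmic=0, n_tethered=0, n_docked=470,
                          n_omega=187, n_coated=0, include_ribbon=False,
                          n_gold=6, seed=12)
        _, truth = generate_phantom(p)
        density = truth.state_counts()["docked"] / truth.true_active_zone_area_um2
        assert density == pytest.approx(150.0, rel=0.10)

    def test_infeasible_packing_raises(self):
        p = PhantomParams(shape=(48, 48, 20), n_cytoplasmic=200, seed=0)
        with pytest.raises(PackingError):
            generate_phantom(p)


class TestRenderVesicle:
    VOX = 2.0

    def test_cytoplasmic_profile_two_peaks_at_diameter_minus_spacing(self):
        patch = render_vesicle("cytoplasmic", (32, 32, 32), 40.0, None,
                               shape_xyz=(32, 32, 32), voxel_size=self.VOX,
                               layer_spacing=6.0)
        from scipy.ndimage import gaussian_filter1d
        prof = gaussian_filter1d(patch[16, 16, :].astype(float), 1.5)
        peaks, props = find_peaks(prof, height=0.3 * prof.max())
        top2 = np.sort(peaks[np.argsort(props["peak_heights"])[::-1][:2]])
        sep = (top2[1] - top2[0]) * self.VOX
        assert sep == pytest.approx(40.0 - 6.0, abs=3.0)

    def test_omega_pore_is_open(self):
        mem = MembranePlane("x", position=50.0, layer_spacing=6.0)
        h = omega_center_offset(40.0, 6.0)
        patch = render_vesicle("omega", (50.0 - h, 32, 32), 40.0, mem,
                               shape_xyz=(48, 32, 32), voxel_size=self.VOX)
        # ray from the lumen center through the membrane into the
        # extracellular space crosses no membrane density
        cx = int((50.0 - h) / self.VOX)
        ray = patch[16, 16, cx:int(60 / self.VOX)]
        assert ray.max() < 0.3

    def test_docked_single_merged_leaflet_at_contact(self):
        mem = MembranePlane("x", position=50.0, layer_spacing=6.0)
        h = docked_center_offset(40.0, 6.0)
        patch = render_vesicle("docked", (50.0 - h, 32, 32), 40.0, mem,
                               shape_xyz=(48, 32, 32), voxel_size=self.VOX)
        s = 6.0
        # at the contact point: exactly one peak within the membrane zone
        lo, hi = int((50 - s - 2) / self.VOX), int((50 + s + 2) / self.VOX) + 1
        contact = patch[16, 16, lo:hi]
        peaks, _ = find_peaks(contact, height=0.4)
        assert len(peaks) == 1
        # away from the vesicle: the bilayer's two peaks are intact
        away = patch[16, 2, lo:hi]
        peaks_away, _ = find_peaks(away, height=0.4)
        assert len(peaks_away) == 2
        # and the docked lumen stays sealed (ray into the cleft blocked)
        cx = int((50.0 - h) / self.VOX)
        ray = patch[16, 16, cx:int(60 / self.VOX)]
        assert ray.max() > 0.5

    def test_coated_vesicle_has_outer_shell(self):
        plain = render_vesicle("cytoplasmic", (32, 32, 32), 40.0, None,
                               shape_xyz=(32, 32, 32), voxel_size=self.VOX)
        coated = render_vesicle("coated", (32, 32, 32), 40.0, None,
                                shape_xyz=(32, 32, 32), voxel_size=self.VOX)
        # density in the coat band (just outside the vesicle membrane)
        idx = int((32 + 28) / self.VOX)
        assert coated[16, 16, idx] > plain[16, 16, idx] + 0.2

    def test_docked_far_from_membrane_is_geometry_error(self):
        mem = MembranePlane("x", position=90.0, layer_spacing=6.0)
        with pytest.raises(GeometryError):
            render_vesicle("docked", (10.0, 32, 32), 40.0, mem,
                           shape_xyz=(48, 32, 32), voxel_size=self.VOX)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            render_vesicle("floating", (32, 32, 32), 40.0, None)


class TestFiducials:
    def test_fewer_than_three_rejected(self, default_phantom):
        _, vol, _ = default_phantom
        with pytest.raises(ValueError):
            place_fiducials(vol, 2)

    def test_six_gold_on_slab_faces(self, default_phantom):
        _, vol, _ = default_phantom
        out, pos = place_fiducials(vol, 6, seed=4)
        assert len(pos) == 6
        z0, z1 = vol.slab
        assert set(np.round(pos[:, 2], 3)) <= {round(z0, 3), round(z1, 3)}

    def test_gold_denser_than_any_biology(self, default_phantom):
        _, vol, _ = default_phantom
        # the session phantom already contains gold at the maximal level
        assert vol.data.max() == pytest.approx(DENSITY["gold"], rel=0.05)
        assert DENSITY["gold"] > max(v for k, v in DENSITY.items()
                                     if k != "gold")
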