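import numpy as np
import pytest

from conetomo.alignment import AlignmentSolution
from conetomo.geometry import view_matrix, volume_center_xyz
from conetomo.phantom import PhantomParams, generate_phantom
from conetomo.projection import ConicalGeometry, simulate_series
from conetomo.reconstruct import (estimate_resolution, refine_global,
                                  refine_local, shift_gauge_residual,
                                  weighted_back_projection)
from conetomo.volume import DensityVolume


@pytest.fixture(scope="module")
def point_series():
    n = 48
    vol = np.zeros((n, n, n), np.float32)
    vol[30, 20, 25] = 1.0
    dv = DensityVolume(vol, 2.0)
    geo = ConicalGeometry(azimuth_step_deg=10.0)
    return dv, simulate_series(dv, geo, image_shape=(73, 73))


class TestWBP:
    def test_point_source_localized_within_one_voxel(self, point_series):
        dv, ser = point_series
        rec = weighted_back_projection(ser, output_shape_zyx=dv.data.shape)
        z, y, x = np.unravel_index(rec.data.argmax(), rec.data.shape)
        assert abs(z - 30) <= 1 and abs(y - 20) <= 1 and abs(x - 25) <= 1

    def test_linearity_in_projections(self, point_series):
        import dataclasses
        dv, ser = point_series
        rng = np.random.default_rng(0)
        other = dataclasses.replace(
            ser, projections=rng.random(ser.projections.shape).astype(
                np.float32))
        both = dataclasses.replace(
            ser, projections=ser.projections + other.projections)
        shape = dv.data.shape
        r1 = weighted_back_projection(ser, output_shape_zyx=shape).data
        r2 = weighted_back_projection(other, output_shape_zyx=shape).data
        r12 = weighted_back_projection(both, output_shape_zyx=shape).data
        assert np.allclose(r12, r1 + r2, atol=1e-4 * np.abs(r12).max())

    def test_missing_cone_elongates_z(self):
        n = 48
        z, y, x = np.indices((n, n, n))
        c = (n - 1) / 2
        sph = (((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= 36).astype(
            np.float32)
        dv = DensityVolume(sph, 2.0)
        ser = simulate_series(dv, ConicalGeometry(azimuth_step_deg=10.0),
                              image_shape=(73, 73))
        rec = weighted_back_projection(ser, output_shape_zyx=(n, n, n)).data

        def fwhm(p):
            p = p - p.min()
            idx = np.where(p >= p.max() / 2)[0]
            return idx[-1] - idx[0]

        ratio = fwhm(rec[:, 23, 23]) / fwhm(rec[23, 23, :])
        assert ratio > 1.0

    def test_mismatched_counts_rejected(self, point_series):
        dv, ser = point_series
        bad = AlignmentSolution.nominal(ser.views[:-1])
        with pytest.raises(ValueError):
            weighted_back_projection(ser, bad)

    def test_unknown_weighting_rejected(self, point_series):
        dv, ser = point_series
        with pytest.raises(ValueError):
            weighted_back_projection(ser, weighting="sinc-exact")


class TestRefineGlobal:
    def test_fixed_point_and_monotone_correlation(self, small_recon_phantom,
                                                  coarse_geometry):
        _, vol, _ = small_recon_phantom
        ser = simulate_series(vol, coarse_geometry, shift_jitter_px=1.0,
                              seed=3, image_shape=(145, 145))
        truth_sol = AlignmentSolution.nominal(ser.views)
        truth_sol.shifts_px = ser.distortion_truth["shifts"].copy()
        refined, log = refine_global(ser, truth_sol,
                                     output_shape_zyx=vol.data.shape,
                                     max_iter=2)
        ti = ser.tilted_indices
        # already-true alignment is a fixed point
        assert np.abs(refined.shifts_px[ti]
                      - truth_sol.shifts_px[ti]).max() < 0.05
        corrs = log.mean_correlations()
        accepted = [it for it in log.iterations
                    if it.get("accepted", True)]
        vals = [it["mean_correlation"] for it in accepted]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_recovers_1px_shift_perturbations(self, small_recon_phantom,
                                              coarse_geometry):
        _, vol, _ = small_recon_phantom
        ser = simulate_series(vol, coarse_geometry, shift_jitter_px=1.0,
                              seed=3, image_shape=(145, 145))
        truth_sol = AlignmentSolution.nominal(ser.views)
        truth_sol.shifts_px = ser.distortion_truth["shifts"].copy()
        start = AlignmentSolution.nominal(ser.views)  # 1 px rms off truth
        refined, _ = refine_global(ser, start,
                                   output_shape_zyx=vol.data.shape,
                                   max_iter=4)
        ti = ser.tilted_indices
        res = shift_gauge_residual(refined.shifts_px, truth_sol.shifts_px,
                                   refined, indices=ti)
        assert res.max() < 0.3


class TestRefineLocal:
    def test_undistorted_series_null_corrections(self, small_recon_phantom,
                                                 small_series):
        _, vol, _ = small_recon_phantom
        sol = AlignmentSolution.nominal(small_series.views)
        ld = refine_local(vol, small_series, sol, grid=(2, 2, 1))
        c = ld.shift_corrections[:, small_series.tilted_indices]
        assert np.abs(c).max() < 0.2

    def test_known_stretch_field_recovered(self, small_recon_phantom,
                                           coarse_geometry):
        _, vol, _ = small_recon_phantom
        ser = simulate_series(vol, coarse_geometry, stretch=(1.03, 1.0),
                              image_shape=(145, 145))
        sol = AlignmentSolution.nominal(ser.views)
        ld = refine_local(vol, ser, sol, grid=(2, 2, 1))
        c_vol = volume_center_xyz(vol.data.shape)
        xs, ys = [], []
        for k in range(len(ld.centers_vox)):
            for i in ser.tilted_indices:
                R = view_matrix(sol.alpha_deg[i], sol.beta_deg[i],
                                sol.gamma_deg[i])
                u = (R[:2] @ (ld.centers_vox[k] - c_vol))[0]
                xs.append(u)
                ys.append(ld.shift_corrections[k, i, 0])
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(0.03, rel=0.20)

    def test_degenerate_grid_equals_global_deltas(self, small_recon_phantom,
                                                  coarse_geometry):
        from skimage.registration import phase_cross_correlation
        from conetomo.reconstruct import _bandpass, reproject
        _, vol, _ = small_recon_phantom
        ser = simulate_series(vol, coarse_geometry, shift_jitter_px=0.8,
                              seed=3, image_shape=(145, 145))
        sol = AlignmentSolution.nominal(ser.views)
        ld = refine_local(vol, ser, sol, grid=(1, 1, 1))
        for i in ser.tilted_indices[:5]:
            rp = reproject(vol, sol, i, ser.projections.shape[1:])
            sh, _, _ = phase_cross_correlation(
                _bandpass(ser.projections[i]), _bandpass(rp),
                upsample_factor=20, normalization=None)
            assert np.allclose(ld.shift_corrections[0, i],
                               (sh[1], sh[0]), atol=0.35)

    def test_flat_subvolume_flagged(self, coarse_geometry):
        vol = DensityVolume(np.zeros((20, 64, 64), np.float32), 3.0)
        vol.data[10, 30:34, 10:14] = 1.0  # signal only in one corner
        ser = simulate_series(vol, ConicalGeometry(azimuth_step_deg=90.0),
                              image_shape=(145, 145))
        sol = AlignmentSolution.nominal(ser.views)
        ld = refine_local(vol, ser, sol, grid=(2, 2, 1))
        assert len(ld.flat_subvolumes) >= 1
        for k in ld.flat_subvolumes:
            assert np.all(ld.shift_corrections[k] == 0)


class TestResolution:
    @staticmethod
    def _membrane_phantom(spacing, vox, n=64):
        p = PhantomParams(voxel_size=vox, shape=(n, n, max(20, int(56 / vox))),
                          slab_thickness=50.0,
                          membrane_layer_spacing=spacing,
                          n_cytoplasmic=0, n_tethered=0, n_docked=0,
                          n_omega=0, n_coated=0, n_gold=0,
                          include_ribbon=False, include_hc_membrane=False,
                          membrane_frac=0.5, texture=0.0, seed=1)
        return generate_phantom(p)

    def test_probes_straddling_membrane_recover_spacing(self):
        vol, truth = self._membrane_phantom(6.0, 2.0)
        probes = [((truth.membranes[0].position / 2.0 - 7, y, 14),
                   (truth.membranes[0].position / 2.0 + 7, y, 14))
                  for y in (16, 32, 48)]
        out = estimate_resolution(vol, probes)
        assert out["resolution_nm"] == pytest.approx(6.0, abs=0.5)

    def test_uniform_profile_excluded(self):
        vol, truth = self._membrane_phantom(6.0, 2.0)
        xpos = truth.membranes[0].position / 2.0
        probes = [((xpos - 7, y, 14), (xpos + 7, y, 14)) for y in (16, 32)]
        probes.append(((2, 10, 14), (9, 10, 14)))  # through background
        out = estimate_resolution(vol, probes)
        assert out["n_excluded"] == 1

    def test_fewer_than_three_probes_rejected(self):
        vol, _ = self._membrane_phantom(6.0, 2.0)
        with pytest.raises(ValueError):
            estimate_resolution(vol, [((0, 0, 0), (1, 1, 1))] * 2)
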