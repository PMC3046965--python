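"""Weighted back projection for conical geometry, projection-matching
refinement (global and local), and the membrane-spacing resolution proxy.

WBP filters each projection to compensate the sampling density of the
conical tilt scheme (analytic radial r-weighting by default) and smears it
back along its beam direction.  Refinement iterates re-projection of the
current map against the measured images, updating per-image parameters;
accepted iterations never decrease the mean projection correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.registration import phase_cross_correlation

from .alignment import AlignmentSolution
from .geometry import view_matrix, volume_center_xyz
from .projection import TiltSeries, project
from .volume import DensityVolume


def _weight_filter(shape, scheme: str, cutoff: float = 0.9) -> np.ndarray:
    """2D Fourier weighting.  'ramp': radial |nu| (the conical sampling-
    density correction) with a raised-cosine rolloff at ``cutoff`` x
    Nyquist; 'flat': plain (unweighted) back projection."""
    H, W = shape
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    nu = np.hypot(fy, fx)
    if scheme == "flat":
        w = np.ones_like(nu)
    elif scheme == "ramp":
        w = nu / 0.5  # normalized to 1 at Nyquist
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    nyq = 0.5
    lo = cutoff * nyq * 0.75
    hi = cutoff * nyq
    roll = np.ones_like(nu)
    band = (nu > lo) & (nu < hi)
    roll[band] = 0.5 * (1 + np.cos(np.pi * (nu[band] - lo) / (hi - lo)))
    roll[nu >= hi] = 0.0
    return w * roll


def filter_projection(image: np.ndarray, scheme: str = "ramp",
                      cutoff: float = 0.9) -> np.ndarray:
    F = np.fft.fft2(image)
    return np.real(np.fft.ifft2(F * _weight_filter(image.shape, scheme, cutoff)))


def weighted_back_projection(series: TiltSeries,
                             alignment: AlignmentSolution | None = None,
                             output_shape_zyx: tuple[int, int, int] | None = None,
                             weighting: str = "ramp", cutoff: float = 0.9,
                             use_views: list[int] | None = None,
                             chunk_z: int = 16) -> DensityVolume:
    """Reconstruct a volume by weighted back projection.

    Only the tilted views are used by default (the untilted views serve
    centering and shrinkage estimation).  Output voxel size equals the
    pixel size; the operator is linear in the projections and translation-
    equivariant.
    """
    if alignment is None:
        alignment = AlignmentSolution.nominal(series.views)
    if alignment.n_images != series.n_images:
        raise ValueError("alignment and series image counts differ")
    if use_views is None:
        use_views = series.tilted_indices or list(range(series.n_images))
    n, H, W = series.projections.shape
    if output_shape_zyx is None:
        m = min(H, W)
        output_shape_zyx = (m, m, m)
    nz, ny, nx = output_shape_zyx
    c_vol = volume_center_xyz(output_shape_zyx)
    ic = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    out = np.zeros(output_shape_zyx, dtype=np.float32)

    filtered = {i: filter_projection(series.projections[i], weighting, cutoff)
                for i in use_views}
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
    pts = np.stack([(xx - c_vol[0]).ravel(), (yy - c_vol[1]).ravel(),
                    (zz - c_vol[2]).ravel()])
    for i in use_views:
        R = view_matrix(alignment.alpha_deg[i], alignment.beta_deg[i],
                        alignment.gamma_deg[i])
        s = alignment.scales[i]
        uv = (R[:2] @ pts)
        u = s * uv[0] + alignment.shifts_px[i, 0] + ic[0]
        v = s * uv[1] + alignment.shifts_px[i, 1] + ic[1]
        vals = ndimage.map_coordinates(filtered[i], [v, u], order=1,
                                       mode="constant", cval=0.0)
        out += vals.reshape(output_shape_zyx).astype(np.float32)
    out *= np.pi / (2.0 * len(use_views))
    return DensityVolume(out, series.pixel_size, provenance="wbp")


def reproject(volume: DensityVolume, alignment: AlignmentSolution, i: int,
              image_shape, step: float = 0.5) -> np.ndarray:
    return project(volume, alignment.beta_deg[i], alignment.alpha_deg[i],
                   gamma=alignment.gamma_deg[i],
                   shift=tuple(alignment.shifts_px[i]),
                   scale=alignment.scales[i],
                   image_shape=image_shape, step=step)


def _bandpass(img, lo=1.0, hi=8.0):
    return ndimage.gaussian_filter(img, lo) - ndimage.gaussian_filter(img, hi)


def _ncc(a, b):
    a = a - a.mean()
    b = b - b.mean()
    d = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / d) if d > 0 else 0.0


@dataclass
class RefinementLog:
    iterations: list[dict] = field(default_factory=list)
    status: str = "converged"

    def mean_correlations(self) -> list[float]:
        return [it["mean_correlation"] for it in self.iterations]


def refine_global(series: TiltSeries, alignment: AlignmentSolution,
                  output_shape_zyx=None, max_iter: int = 4,
                  tol: float = 1e-3, upsample: int = 20,
                  weighting: str = "ramp",
                  trust_px: float = 5.0) -> tuple[AlignmentSolution, RefinementLog]:
    """Global projection matching.

    Iterates: reconstruct -> re-project per current parameters -> register
    each measured image to its re-projection by upsampled phase correlation
    -> update shifts.  An iteration is accepted only if the mean normalized
    cross-correlation (on band-passed images) does not decrease; two
    consecutive drops stop the refinement with the best solution so far.
    """
    cur = _copy_solution(alignment)
    log = RefinementLog()
    best = cur
    H, W = series.projections.shape[1:]
    use = series.tilted_indices or list(range(series.n_images))

    def mean_corr(sol):
        vol = weighted_back_projection(series, sol, output_shape_zyx,
                                       weighting=weighting)
        cs = []
        for i in use:
            rp = reproject(vol, sol, i, (H, W))
            cs.append(_ncc(_bandpass(series.projections[i]), _bandpass(rp)))
        return float(np.mean(cs)), vol

    prev_c, vol = mean_corr(cur)
    log.iterations.append({"iteration": 0, "mean_correlation": prev_c,
                           "max_shift_update_px": 0.0})
    best_c = prev_c
    drops = 0
    for it in range(1, max_iter + 1):
        cand = _copy_solution(cur)
        max_upd = 0.0
        for i in use:
            rp = reproject(vol, cur, i, (H, W))
            shift, _, _ = phase_cross_correlation(
                _bandpass(series.projections[i]), _bandpass(rp),
                upsample_factor=upsample, normalization=None)
            dv, du = shift  # (row, col): measured = reproj shifted by this
            du = float(np.clip(du, -trust_px, trust_px))
            dv = float(np.clip(dv, -trust_px, trust_px))
            cand.shifts_px[i] += (du, dv)
            max_upd = max(max_upd, abs(du), abs(dv))
        c, vol_cand = mean_corr(cand)
        accepted = c >= prev_c - 1e-12
        log.iterations.append({"iteration": it, "mean_correlation": c,
                               "max_shift_update_px": max_upd,
                               "accepted": bool(accepted)})
        if accepted:
            cur, vol = cand, vol_cand
            if c > best_c:
                best, best_c = cand, c
            if c - prev_c < tol:
                prev_c = c
                break
            prev_c = c
            drops = 0
        else:
            drops += 1
            if drops >= 2:
                log.status = "diverged: correlation dropped twice"
                break
    return (best if best_c >= prev_c else cur), log


def _copy_solution(sol: AlignmentSolution) -> AlignmentSolution:
    return AlignmentSolution(
        alpha_deg=sol.alpha_deg.copy(), beta_deg=sol.beta_deg.copy(),
        gamma_deg=sol.gamma_deg.copy(), shifts_px=sol.shifts_px.copy(),
        residual_rms_px=sol.residual_rms_px.copy(), shrinkage=sol.shrinkage,
        scales=sol.scales.copy(),
        marker_positions=None if sol.marker_positions is None
        else sol.marker_positions.copy())


def shift_gauge_residual(shifts: np.ndarray, ref_shifts: np.ndarray,
                         alignment: AlignmentSolution,
                         indices=None) -> np.ndarray:
    """Per-image shift differences after removing the volume-translation
    gauge.

    Projection matching determines shifts only up to a global translation
    of the reconstructed volume: ``t_vol`` adds ``s_i (R_i t_vol)_xy`` to
    every image shift.  The best-fit ``t_vol`` is removed by least squares
    and the residual per-image differences (px) returned.
    """
    idx = list(indices) if indices is not None else list(range(len(shifts)))
    d = np.asarray(shifts)[idx] - np.asarray(ref_shifts)[idx]
    A = []
    for i in idx:
        R = view_matrix(alignment.alpha_deg[i], alignment.beta_deg[i],
                        alignment.gamma_deg[i])[:2]
        A.append(alignment.scales[i] * R)
    A = np.vstack(A)
    t_vol = np.linalg.lstsq(A, d.ravel(), rcond=None)[0]
    res = d - (A @ t_vol).reshape(-1, 2)
    return np.linalg.norm(res, axis=1)


@dataclass
class LocalDeformation:
    """Per-sub-volume parameter corrections from local projection matching."""

    grid: tuple[int, int, int]
    overlap: float
    centers_vox: np.ndarray            # (n_sub, 3) xyz voxel coordinates
    shift_corrections: np.ndarray      # (n_sub, n_images, 2) px
    correlations: np.ndarray           # (n_sub, n_images)
    flat_subvolumes: list[int] = field(default_factory=list)

    def mean_correction(self) -> np.ndarray:
        return self.shift_corrections.mean(axis=1)


def refine_local(volume: DensityVolume, series: TiltSeries,
                 alignment: AlignmentSolution, grid=(4, 4, 1),
                 overlap: float = 0.25, upsample: int = 20,
                 trust_px: float = 5.0,
                 min_signal_std: float = 1e-6) -> LocalDeformation:
    """Local projection matching over a sub-volume grid.

    Each sub-volume (soft-edged box crop of the reconstruction) is
    re-projected per the current parameters and registered against the
    corresponding crop of each measured image; the per-sub-volume,
    per-image shift corrections describe the residual deformation field.
    Flat sub-volumes get zero correction and are flagged.  With a 1x1x1
    grid the corrections reduce to the global refinement deltas.
    """
    data = volume.data
    nz, ny, nx = data.shape
    gx, gy, gz = grid
    H, W = series.projections.shape[1:]
    ic = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    c_vol = volume_center_xyz(data.shape)
    use = series.tilted_indices or list(range(series.n_images))

    def edges(n, g):
        size = n / (1 + (g - 1) * (1 - overlap)) if g > 1 else n
        starts = [i * size * (1 - overlap) for i in range(g)]
        return [(s, min(s + size, n)) for s in starts], size

    ex, sx = edges(nx, gx)
    ey, sy = edges(ny, gy)
    ez, sz = edges(nz, gz)
    subs = [(a, b, c) for c in ez for b in ey for a in ex]
    centers = np.array([[(a[0] + a[1]) / 2, (b[0] + b[1]) / 2,
                         (c[0] + c[1]) / 2] for (a, b, c) in subs])
    n_sub = len(subs)
    n_img = series.n_images
    corr = np.zeros((n_sub, n_img, 2))
    ccs = np.zeros((n_sub, n_img))
    flat_mask = np.zeros(n_sub, dtype=bool)
    win = min(int(np.ceil(np.hypot(sx, sy) * 0.75)) + 8, min(H, W))
    hann = np.hanning(win)[:, None] * np.hanning(win)[None, :]

    zi, yi, xi = np.mgrid[0:nz, 0:ny, 0:nx]
    for k, ((x0, x1), (y0, y1), (z0, z1)) in enumerate(subs):
        box = data[int(z0):int(np.ceil(z1)), int(y0):int(np.ceil(y1)),
                   int(x0):int(np.ceil(x1))]
        if box.std() < min_signal_std:
            flat_mask[k] = True
    for i in use:
        rp = reproject(volume, alignment, i, (H, W))
        R = view_matrix(alignment.alpha_deg[i], alignment.beta_deg[i],
                        alignment.gamma_deg[i])
        for k in range(n_sub):
            if flat_mask[k]:
                continue
            # window centered on the projected footprint of this sub-volume
            uv = R[:2] @ (centers[k] - c_vol)
            u = alignment.scales[i] * uv[0] + alignment.shifts_px[i, 0] + ic[0]
            v = alignment.scales[i] * uv[1] + alignment.shifts_px[i, 1] + ic[1]
            j0 = int(np.clip(round(v - win / 2), 0, H - win))
            i0 = int(np.clip(round(u - win / 2), 0, W - win))
            meas = _bandpass(series.projections[i][j0:j0 + win,
                                                   i0:i0 + win]) * hann
            rpc = _bandpass(rp[j0:j0 + win, i0:i0 + win]) * hann
            if rpc.std() < min_signal_std:
                continue
            shift, _, _ = phase_cross_correlation(meas, rpc,
                                                  upsample_factor=upsample,
                                                  normalization=None)
            dv, du = shift
            corr[k, i] = (np.clip(du, -trust_px, trust_px),
                          np.clip(dv, -trust_px, trust_px))
            ccs[k, i] = _ncc(meas, rpc)
    return LocalDeformation(grid=grid, overlap=overlap, centers_vox=centers,
                            shift_corrections=corr, correlations=ccs,
                            flat_subvolumes=list(np.where(flat_mask)[0]))


def estimate_resolution(volume: DensityVolume,
                        probes: list[tuple], n_samples: int = 81,
                        min_peak_rel: float = 0.25) -> dict:
    """Membrane layer-center spacing as a resolution proxy.

    Each probe is a (start, end) pair of (x, y, z) voxel coordinates for a
    line crossing a membrane.  For each profile the two strongest density
    peaks are located with sub-sample quadratic refinement; the peak-center
    distance (nm) is the per-probe estimate and the median over resolvable
    probes is the reported proxy.  Profiles without two resolvable peaks
    are excluded and counted.
    """
    if len(probes) < 3:
        raise ValueError("need at least 3 membrane probes")
    per_probe = []
    excluded = 0
    for p0, p1 in probes:
        p0 = np.asarray(p0, float)
        p1 = np.asarray(p1, float)
        ts = np.linspace(0.0, 1.0, n_samples)
        pts = p0[None] + ts[:, None] * (p1 - p0)[None]
        # cubic spline sampling: peak centers between voxel centers must be
        # recoverable, a piecewise-linear profile pins them to the grid
        prof = ndimage.map_coordinates(
            volume.data.astype(np.float64),
            [pts[:, 2], pts[:, 1], pts[:, 0]], order=3, mode="nearest")
        prof = prof - np.median(prof)
        if prof.max() <= 0:
            excluded += 1
            continue
        peaks, props = signal.find_peaks(prof, height=min_peak_rel * prof.max(),
                                         distance=2)
        if len(peaks) < 2:
            excluded += 1
            continue
        order = np.argsort(props["peak_heights"])[::-1][:2]
        two = np.sort(peaks[order])
        locs = []
        for pk in two:
            if 0 < pk < len(prof) - 1:
                y0, y1, y2 = prof[pk - 1], prof[pk], prof[pk + 1]
                den = (y0 - 2 * y1 + y2)
                d = 0.5 * (y0 - y2) / den if den != 0 else 0.0
            else:
                d = 0.0
            locs.append(pk + d)
        seg_nm = np.linalg.norm(p1 - p0) * volume.voxel_size / (n_samples - 1)
        per_probe.append(abs(locs[1] - locs[0]) * seg_nm)
    if not per_probe:
        raise ValueError("no probe yielded two resolvable membrane peaks")
    return {"resolution_nm": float(np.median(per_probe)),
            "per_probe_nm": per_probe, "n_excluded": excluded}
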