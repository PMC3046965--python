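"""Pipeline orchestration: phantom -> tilt series -> alignment ->
reconstruction -> segmentation -> morphometry, with artifacts and a
reproducible JSON + CSV report.

Every stage is also usable on its own; this module only composes them,
fans one root seed out to the per-stage generators, and writes artifacts
(MRC volumes, CSV tables, JSON reports) so any number in the final report
traces back to a stage output on disk.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import mrc
from .alignment import (AlignmentSolution, detect_fiducials, solve_alignment,
                        track_fiducials, match_untilted_points,
                        estimate_shrinkage)
from .membranes import MembranePlane
from .morphometry import (FusionThresholds, SpheruleMorphometry,
                          count_fusion_states, equivalent_sphere,
                          summarize_conditions, weighted_count)
from .phantom import PhantomParams, add_noise, generate_phantom
from .projection import ConicalGeometry, TiltSeries, simulate_series
from .reconstruct import (estimate_resolution, refine_global,
                          weighted_back_projection)
from .segmentation import (attach_vesicle_centers, classify_segments,
                           detect_vesicle_centers, estimate_membrane_plane,
                           match_detections, resolve_conflicts,
                           watershed_labels)
from .volume import DensityVolume


class PipelineConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """Stage toggles and per-stage parameters; one root seed feeds every
    stochastic stage."""

    outdir: str = "conetomo_out"
    seed: int = 0
    stages: tuple[str, ...] = ("phantom", "simulate", "align", "reconstruct",
                               "segment", "measure")
    phantom: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)   # jitter, shrinkage, snr
    align: dict = field(default_factory=dict)
    reconstruct: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    measure: dict = field(default_factory=dict)

    ORDER = ("phantom", "simulate", "align", "reconstruct", "segment",
             "measure")
    DEPS = {"simulate": ("phantom",), "align": ("simulate",),
            "reconstruct": ("align",), "segment": (),
            "measure": ("segment",)}

    def validate(self) -> None:
        unknown = set(self.stages) - set(self.ORDER)
        if unknown:
            raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")
        for s in self.stages:
            for dep in self.DEPS.get(s, ()):
                if dep not in self.stages:
                    raise PipelineConfigError(
                        f"stage '{s}' requires stage '{dep}'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(obj) - known
        if bad:
            raise PipelineConfigError(f"unknown config keys: {sorted(bad)}")
        if "stages" in obj:
            obj["stages"] = tuple(obj["stages"])
        return cls(**obj)


def derive_seed(root: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (stable across processes)."""
    import zlib
    return int(np.random.SeedSequence([root, zlib.crc32(stage.encode())])
               .generate_state(1)[0] % (2**31))


def align_series(series: TiltSeries, gold_diameter_px: float,
                 refine_tilt: bool = True,
                 angle_prior_weight: float = 0.5) -> AlignmentSolution:
    """Fiducial-based alignment of a series.

    Detects gold in every image, links tracks, estimates shrinkage from
    the untilted view pair, removes the shrinkage ramp and the image-
    center offset from the track coordinates, then solves the bundle.
    The returned shifts and per-image scales are in the convention of
    :func:`conetomo.projection.project` (u = s·(R r)_xy + shift + center),
    so they feed straight into back projection and re-projection.
    """
    from .alignment import FiducialTracks, robust_shrinkage
    dets = [detect_fiducials(img, gold_diameter_px)
            for img in series.projections]
    tracks = track_fiducials(series, dets)
    n = series.n_images
    scales = np.ones(n)
    shrink = 1.0
    unt = series.untilted_indices
    if len(unt) >= 2:
        a, b = match_untilted_points(dets[unt[0]], dets[unt[-1]])
        if len(a) >= 2:
            shrink = robust_shrinkage(a, b)
            scales = 1.0 - (1.0 - shrink) * np.arange(n) / (n - 1)
    H, W = series.projections.shape[1:]
    ic = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    demag = (tracks.coords - ic) / scales[None, :, None]
    sol = solve_alignment(
        FiducialTracks(coords=demag, views=tracks.views,
                       center_marker=tracks.center_marker,
                       flagged=tracks.flagged),
        refine_tilt=refine_tilt, angle_prior_weight=angle_prior_weight)
    sol.shifts_px = scales[:, None] * sol.shifts_px
    sol.scales = scales
    sol.shrinkage = shrink
    # re-center the reconstruction frame on the fiducial centroid: the
    # center-marker origin can sit far from the field center, which would
    # push the specimen outside the reconstruction box
    if sol.marker_positions is not None and len(sol.marker_positions) >= 2:
        from .geometry import view_matrix
        t_vol = sol.marker_positions.mean(axis=0)
        for i in range(n):
            R = view_matrix(sol.alpha_deg[i], sol.beta_deg[i],
                            sol.gamma_deg[i])
            sol.shifts_px[i] += sol.scales[i] * (R[:2] @ t_vol)
        sol.marker_positions = sol.marker_positions - t_vol
    return sol


def segment_volume(volume: DensityVolume, smoothing_sigma: float = 1.5,
                   merge_depth: float = 0.15,
                   vesicle_diameter_nm: float = 40.0,
                   layer_spacing_nm: float = 6.0):
    """Watershed map + classification + matched-filter vesicle centers +
    conflict resolution, in one call."""
    labels = watershed_labels(volume, smoothing_sigma=smoothing_sigma,
                              merge_depth=merge_depth)
    seg = classify_segments(labels, volume)
    centers = detect_vesicle_centers(volume, diameter_nm=vesicle_diameter_nm,
                                     layer_spacing_nm=layer_spacing_nm)
    seg = attach_vesicle_centers(seg, centers,
                                 diameter_nm=vesicle_diameter_nm,
                                 layer_spacing_nm=layer_spacing_nm)
    return resolve_conflicts(seg)


def measure_volume(volume: DensityVolume, seg, truth=None,
                   vesicle_diameter_nm: float = 40.0,
                   layer_spacing_nm: float = 6.0,
                   condition: str = "light") -> dict:
    """Morphometry stage: fusion-state counts under the counting rule plus
    geometric summaries; adds recovery-vs-truth deltas when ground truth
    is available."""
    centers = seg.centroids_nm("vesicle")
    report: dict = {"condition": condition,
                    "n_vesicle_centers": int(len(centers))}
    if len(centers):
        membrane = estimate_membrane_plane(seg, volume,
                                           toward_centers_nm=centers,
                                           layer_spacing_nm=layer_spacing_nm)
        counts = count_fusion_states(centers, volume, membrane,
                                     diameter_nm=vesicle_diameter_nm,
                                     layer_spacing_nm=layer_spacing_nm)
        records = counts.pop("records")
        report["weighted_counts"] = counts
        report["membrane"] = {"axis": membrane.axis,
                              "position_nm": membrane.position}
        report["records"] = [
            {"x_um": r.center.x, "y_um": r.center.y, "z_um": r.center.z,
             "state": r.state, "fraction_inside": r.fraction_inside,
             "count_weight": r.count_weight} for r in records]
    if truth is not None:
        tc = truth.centers_nm()
        m, miss, spur = match_detections(tc, centers, vesicle_diameter_nm / 2)
        report["recovery"] = {
            "true_vesicles": int(len(tc)),
            "matched": int(m),
            "recall": float(m / len(tc)) if len(tc) else 1.0,
            "precision": float(m / len(centers)) if len(centers) else 1.0,
            "true_counts": truth.state_counts(),
        }
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; write per-stage artifacts and a
    final JSON report.  Raises on stage failure with the stage name; any
    artifacts written before the failure are retained."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {},
                    "config": {k: v for k, v in asdict(config).items()}}
    state: dict = {}

    def stage(name):
        return name in config.stages

    try:
        if stage("phantom"):
            t0 = time.time()
            params = PhantomParams(**{"seed": derive_seed(config.seed, "phantom"),
                                      **config.phantom})
            vol, truth = generate_phantom(params)
            mrc.write_mrc(out / "phantom.mrc", vol.data, vol.voxel_size)
            truth.to_json(out / "ground_truth.json")
            truth.vesicle_table().to_csv(out / "ground_truth_vesicles.csv",
                                         index=False)
            state.update(volume=vol, truth=truth, params=params)
            report["stages"]["phantom"] = {
                "seconds": round(time.time() - t0, 2),
                "counts": truth.state_counts(),
                "voxel_size_nm": vol.voxel_size}

        if stage("simulate"):
            t0 = time.time()
            geo = ConicalGeometry(**config.geometry)
            sim = dict(config.simulate)
            snr = sim.pop("snr", None)
            noise = None
            if snr is not None:
                ref = float(np.std(state["volume"].data)) * \
                    state["volume"].data.shape[0] * 0.5
                noise = ("gaussian", ref / snr)
            series = simulate_series(state["volume"], geo, noise=noise,
                                     seed=derive_seed(config.seed, "simulate"),
                                     **sim)
            series.save(out / "tilt_series.mrc", out / "tilt_series.json")
            state.update(series=series, geometry=geo)
            report["stages"]["simulate"] = {
                "seconds": round(time.time() - t0, 2),
                "n_images": series.n_images,
                "noise": None if noise is None else list(noise)}

        if stage("align"):
            t0 = time.time()
            gold_px = config.align.get(
                "gold_diameter_px",
                state["params"].gold_diameter / state["volume"].voxel_size
                if "params" in state else 4.0)
            sol = align_series(state["series"], gold_px,
                               refine_tilt=config.align.get("refine_tilt", True))
            with open(out / "alignment.json", "w") as fh:
                json.dump(sol.to_json_dict(), fh, indent=1)
            state["alignment"] = sol
            report["stages"]["align"] = {
                "seconds": round(time.time() - t0, 2),
                "mean_residual_px": float(sol.residual_rms_px.mean()),
                "shrinkage": sol.shrinkage}

        if stage("reconstruct"):
            t0 = time.time()
            shape = tuple(config.reconstruct.get(
                "output_shape_zyx", state["volume"].data.shape))
            rec = weighted_back_projection(
                state["series"], state["alignment"], output_shape_zyx=shape,
                weighting=config.reconstruct.get("weighting", "ramp"))
            n_iter = config.reconstruct.get("refine_iterations", 0)
            if n_iter > 0:
                sol, log = refine_global(state["series"], state["alignment"],
                                         output_shape_zyx=shape,
                                         max_iter=n_iter)
                state["alignment"] = sol
                with open(out / "refinement_log.json", "w") as fh:
                    json.dump(log.iterations, fh, indent=1)
                rec = weighted_back_projection(state["series"], sol,
                                               output_shape_zyx=shape)
            if "volume" in state:
                # place the reconstruction in the phantom frame (the
                # alignment frame is centered on the center gold marker) so
                # recovery-vs-truth metrics are meaningful
                from skimage.registration import phase_cross_correlation
                shift, _, _ = phase_cross_correlation(
                    state["volume"].data.astype(np.float64),
                    rec.data.astype(np.float64), upsample_factor=4,
                    normalization=None)
                rec.data = ndimage.shift(rec.data, shift, order=1,
                                         mode="constant").astype(np.float32)
                rec.slab = state["volume"].slab
            mrc.write_mrc(out / "reconstruction.mrc", rec.data, rec.voxel_size)
            state["reconstruction"] = rec
            report["stages"]["reconstruct"] = {
                "seconds": round(time.time() - t0, 2), "shape": list(shape)}

        if stage("segment"):
            t0 = time.time()
            target = state.get("reconstruction", state.get("volume"))
            if target is None:
                raise PipelineConfigError("segment stage has no input volume")
            seg = segment_volume(target, **config.segment)
            seg.to_csv(out / "regions.csv")
            mrc.write_mrc(out / "labels.mrc",
                          seg.labels.astype(np.int16), seg.voxel_size)
            if seg.vesicle_centers is not None:
                seg.vesicle_centers.to_csv(out / "vesicle_centers.csv",
                                           index=False)
            state["segmentation"] = seg
            cc = seg.regions["class"].value_counts().to_dict()
            report["stages"]["segment"] = {
                "seconds": round(time.time() - t0, 2),
                "n_regions": int(seg.n_regions),
                "class_counts": {k: int(v) for k, v in cc.items()}}

        if stage("measure"):
            t0 = time.time()
            target = state.get("reconstruction", state.get("volume"))
            meas = measure_volume(target, state["segmentation"],
                                  truth=state.get("truth"),
                                  **config.measure)
            records = meas.pop("records", [])
            pd.DataFrame(records).to_csv(out / "vesicles.csv", index=False)
            report["stages"]["measure"] = {
                "seconds": round(time.time() - t0, 2), **meas}
    except Exception as exc:
        report["error"] = {"stage": _current_stage(report, config),
                           "message": str(exc)}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default)
        raise
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    return report


def _current_stage(report, config):
    done = set(report["stages"])
    for s in config.stages:
        if s not in done:
            return s
    return "unknown"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def cone_mask_correlation(reconstruction: DensityVolume,
                          truth_volume: DensityVolume,
                          tilt_deg: float = 55.0,
                          lowpass_frac: float = 0.6,
                          register: bool = True) -> float:
    """Pearson correlation of a reconstruction with the ground-truth
    volume after restricting the truth to the sampled conical region.

    Conical tomography never samples Fourier components within
    (90° - tilt) of the z axis (the missing cone); those components are
    removed from the truth (and a matching low-pass applied to both) before
    correlating, since no reconstruction can recover them.  With
    ``register`` the reconstruction is first rigidly translated onto the
    truth (the alignment reference frame is centered on the center gold
    marker, not on the phantom volume).
    """
    a = reconstruction.data.astype(np.float64)
    b = truth_volume.data.astype(np.float64)
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    if register:
        from skimage.registration import phase_cross_correlation
        from scipy.ndimage import shift as nd_shift
        shift, _, _ = phase_cross_correlation(b, a, upsample_factor=10,
                                              normalization=None)
        a = nd_shift(a, shift, order=1, mode="constant")
    nz, ny, nx = a.shape
    fz = np.fft.fftfreq(nz)[:, None, None]
    fy = np.fft.fftfreq(ny)[None, :, None]
    fx = np.fft.fftfreq(nx)[None, None, :]
    f_perp = np.sqrt(fy**2 + fx**2)
    f_abs = np.sqrt(f_perp**2 + fz**2)
    half_cone = np.deg2rad(90.0 - tilt_deg)
    with np.errstate(invalid="ignore"):
        in_cone = np.arctan2(f_perp, np.abs(fz)) < half_cone
    in_cone &= f_abs > 0
    lp = f_abs <= lowpass_frac * 0.5
    mask = (~in_cone) & lp
    A = np.fft.fftn(a) * mask
    B = np.fft.fftn(b) * mask
    ar = np.real(np.fft.ifftn(A)).ravel()
    br = np.real(np.fft.ifftn(B)).ravel()
    ar -= ar.mean()
    br -= br.mean()
    den = np.sqrt((ar @ ar) * (br @ br))
    return float((ar @ br) / den) if den > 0 else 0.0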