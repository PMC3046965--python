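"""Conical tilt-series forward model.

Projection is a parallel-beam line integral: the specimen is rotated by an
azimuth ``alpha`` about its z axis, tilted by ``beta`` about the laboratory
x axis, and integrated along the beam (laboratory z).  The same forward
model is reused by the reconstruction module for re-projection during
projection matching, so interpolation choices (trilinear sampling, ray
step 0.5 voxel) are fixed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import view_matrix, volume_center_xyz
from .volume import DensityVolume
from . import mrc


@dataclass
class ConicalGeometry:
    """Acquisition geometry: fixed tilt, full 360° azimuth sweep, plus a
    leading and trailing untilted view (the trailing one is used only for
    shrinkage estimation)."""

    tilt_deg: float = 55.0
    azimuth_step_deg: float = 5.0
    include_untilted: bool = True

    def __post_init__(self):
        if not 0.0 < self.tilt_deg < 90.0:
            raise ValueError("tilt must be in (0, 90) degrees")
        if self.azimuth_step_deg <= 0 or 360.0 % self.azimuth_step_deg != 0:
            raise ValueError("360 must be divisible by azimuth_step_deg")

    @property
    def azimuths(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.azimuth_step_deg)

    def views(self) -> list[tuple[float, float]]:
        """Ordered (tilt, azimuth) pairs in exposure order."""
        tilted = [(self.tilt_deg, az) for az in self.azimuths]
        if self.include_untilted:
            return [(0.0, 0.0)] + tilted + [(0.0, 0.0)]
        return tilted

    @property
    def n_views(self) -> int:
        return len(self.views())


@dataclass
class TiltSeries:
    """Ordered projections with nominal view parameters and, for simulated
    series, the applied distortion truth."""

    projections: np.ndarray                 # (n, H, W)
    views: list[tuple[float, float]]        # nominal (tilt, azimuth) per image
    pixel_size: float                       # nm
    distortion_truth: dict | None = None
    geometry: ConicalGeometry | None = None

    def __post_init__(self):
        self.projections = np.asarray(self.projections)
        if self.projections.ndim != 3:
            raise ValueError("projections must be (n, H, W)")
        if len(self.views) != self.projections.shape[0]:
            raise ValueError("one nominal view per projection required")

    @property
    def n_images(self) -> int:
        return self.projections.shape[0]

    @property
    def untilted_indices(self) -> list[int]:
        return [i for i, (t, _) in enumerate(self.views) if t == 0.0]

    @property
    def tilted_indices(self) -> list[int]:
        return [i for i, (t, _) in enumerate(self.views) if t != 0.0]

    def save(self, path_mrc, path_json=None) -> None:
        mrc.write_mrc(path_mrc, self.projections.astype(np.float32),
                      self.pixel_size)
        if path_json is not None:
            truth = self.distortion_truth
            obj = {"views": [list(v) for v in self.views],
                   "pixel_size": self.pixel_size,
                   "distortion_truth": _jsonable(truth)}
            with open(path_json, "w") as fh:
                json.dump(obj, fh, indent=1)

    @classmethod
    def load(cls, path_mrc, path_json) -> "TiltSeries":
        data, voxel = mrc.read_mrc(path_mrc)
        with open(path_json) as fh:
            obj = json.load(fh)
        truth = obj.get("distortion_truth")
        if truth is not None:
            for key in ("shifts", "scales"):
                if truth.get(key) is not None:
                    truth[key] = np.asarray(truth[key])
        return cls(projections=data, views=[tuple(v) for v in obj["views"]],
                   pixel_size=float(obj.get("pixel_size", voxel)),
                   distortion_truth=truth)


def _jsonable(obj):
    if obj is None:
        return None
    out = {}
    for k, v in obj.items():
        out[k] = v.tolist() if isinstance(v, np.ndarray) else v
    return out


def default_image_size(shape_zyx) -> int:
    nz, ny, nx = shape_zyx
    return int(np.ceil(np.hypot(nx, ny) + nz)) | 1  # odd: symmetric center


def project(volume: DensityVolume | np.ndarray, tilt: float, azimuth: float,
            gamma: float = 0.0, shift=(0.0, 0.0), scale: float = 1.0,
            image_shape: tuple[int, int] | None = None,
            step: float = 0.5, order: int = 1) -> np.ndarray:
    """Parallel-beam projection of a volume for one conical view.

    Trilinear sampling along the beam with ray step ``step`` voxels; the
    operator is linear in the volume and mass-conserving for objects fully
    inside the field of view.  ``shift`` is the in-plane image translation
    (px) and ``scale`` the in-plane magnification (shrinkage < 1).
    """
    data = volume.data if isinstance(volume, DensityVolume) else np.asarray(volume)
    if not -90.0 < tilt < 90.0:
        raise ValueError("tilt must be in (-90, 90) degrees")
    if image_shape is None:
        n = default_image_size(data.shape)
        image_shape = (n, n)
    H, W = image_shape
    R = view_matrix(azimuth, tilt, gamma)
    c_vol = volume_center_xyz(data.shape)

    # beam-direction extent of the volume: |R_z row| . half-sizes
    nz, ny, nx = data.shape
    half = np.array([nx, ny, nz]) / 2.0
    hz = float(np.abs(R[2]) @ half) + 1.0
    K = int(np.ceil(2 * hz / step)) + 3
    ck = (K - 1) / 2.0

    # output index (k, j, i) -> lab xyz -> specimen xyz -> input index (z,y,x)
    S = np.diag([1.0 / scale, 1.0 / scale, step])   # columns: d(xlab)/di etc.
    M_xyz = R.T @ S
    M_idx = M_xyz[::-1, ::-1]
    p0 = np.array([(-(W - 1) / 2.0 - shift[0]) / scale,
                   (-(H - 1) / 2.0 - shift[1]) / scale,
                   -ck * step])
    off_xyz = R.T @ p0 + c_vol
    out = ndimage.affine_transform(
        data, M_idx, offset=off_xyz[::-1], output_shape=(K, H, W),
        order=order, mode="constant", cval=0.0, prefilter=(order > 1))
    return out.sum(axis=0, dtype=np.float64) * step


def simulate_series(volume: DensityVolume, geometry: ConicalGeometry,
                    shift_jitter_px: float = 0.0, shrinkage: float = 1.0,
                    stretch: tuple[float, float] | None = None,
                    noise: tuple[str, float] | None = None,
                    seed: int = 0, image_shape=None,
                    step: float = 0.5) -> TiltSeries:
    """Simulate a conical series with optional distortions and noise.

    Shrinkage ramps linearly with exposure index from 1 at the first view
    to ``shrinkage`` at the last (radiation damage accumulates with dose);
    per-image shift jitter is Gaussian.  ``stretch`` applies a constant
    anisotropic in-plane scale (sx, sy) to every image, for local-
    deformation tests.  Noise is ``("gaussian", sigma)`` or
    ``("poisson-gaussian", (gain, sigma))``.  All applied truth is recorded
    so a series can be regenerated bit-identically.
    """
    if noise is not None:
        kind, level = noise
        levels = np.atleast_1d(np.asarray(level, dtype=float))
        if np.any(levels < 0):
            raise ValueError("noise level must be >= 0")
    rng = np.random.default_rng(seed)
    views = geometry.views()
    n = len(views)
    scales = 1.0 - (1.0 - shrinkage) * np.arange(n) / max(n - 1, 1)
    shifts = (rng.normal(0.0, shift_jitter_px, size=(n, 2))
              if shift_jitter_px > 0 else np.zeros((n, 2)))
    if image_shape is None:
        m = default_image_size(volume.data.shape)
        image_shape = (m, m)
    imgs = np.empty((n, *image_shape), dtype=np.float32)
    for i, (tilt, az) in enumerate(views):
        sc = scales[i]
        if stretch is None:
            img = project(volume, tilt, az, shift=shifts[i], scale=sc,
                          image_shape=image_shape, step=step)
        else:
            img = _project_aniso(volume, tilt, az, shifts[i],
                                 (sc * stretch[0], sc * stretch[1]),
                                 image_shape, step)
        imgs[i] = img
    if noise is not None:
        kind, level = noise
        if kind == "gaussian":
            imgs = imgs + rng.normal(0.0, level, imgs.shape).astype(np.float32)
        elif kind == "poisson-gaussian":
            gain, sigma = level
            lam = np.clip(imgs, 0.0, None) * gain
            imgs = (rng.poisson(lam) / gain).astype(np.float32)
            imgs = imgs + rng.normal(0.0, sigma, imgs.shape).astype(np.float32)
        else:
            raise ValueError(f"unknown noise model {kind!r}")
    truth = {"shifts": shifts, "scales": scales, "shrinkage": shrinkage,
             "stretch": stretch, "noise": noise, "seed": seed, "step": step}
    return TiltSeries(projections=imgs, views=views,
                      pixel_size=volume.voxel_size, distortion_truth=truth,
                      geometry=geometry)


def _project_aniso(volume, tilt, az, shift, scale_xy, image_shape, step):
    data = volume.data if isinstance(volume, DensityVolume) else volume
    H, W = image_shape
    R = view_matrix(az, tilt, 0.0)
    c_vol = volume_center_xyz(data.shape)
    nz, ny, nx = data.shape
    half = np.array([nx, ny, nz]) / 2.0
    hz = float(np.abs(R[2]) @ half) + 1.0
    K = int(np.ceil(2 * hz / step)) + 3
    ck = (K - 1) / 2.0
    S = np.diag([1.0 / scale_xy[0], 1.0 / scale_xy[1], step])
    M_idx = (R.T @ S)[::-1, ::-1]
    p0 = np.array([(-(W - 1) / 2.0 - shift[0]) / scale_xy[0],
                   (-(H - 1) / 2.0 - shift[1]) / scale_xy[1],
                   -ck * step])
    off_xyz = R.T @ p0 + c_vol
    out = ndimage.affine_transform(data, M_idx, offset=off_xyz[::-1],
                                   output_shape=(K, H, W), order=1,
                                   mode="constant", cval=0.0, prefilter=False)
    return out.sum(axis=0, dtype=np.float64) * step
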