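"""Rotation and view conventions shared pipeline-wide.

A conical view is parameterised by Euler angles (alpha, beta, gamma), in
degrees:

* ``alpha`` -- azimuth, rotation of the specimen about its z axis (the slab
  normal), applied first;
* ``beta`` -- tilt about the laboratory x axis;
* ``gamma`` -- residual in-plane rotation of the detector.

A specimen point ``r`` appears in the laboratory frame at
``Rz(gamma) @ Rx(beta) @ Rz(alpha) @ r``; the beam runs along laboratory z,
and the detector records (x_lab, y_lab).  Axes are right-handed, voxel
indices are 0-based and voxel-centered.
"""

from __future__ import annotations

import numpy as np


def rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def view_matrix(alpha: float, beta: float, gamma: float = 0.0) -> np.ndarray:
    """Specimen-to-laboratory rotation for Euler angles in degrees."""
    return rot_z(gamma) @ rot_x(beta) @ rot_z(alpha)


def project_points(
    points_xyz: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float = 0.0,
    scale: float = 1.0,
    shift: tuple[float, float] = (0.0, 0.0),
    center_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0),
    image_center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Closed-form image coordinates of 3D points for a given view.

    ``scale`` is the in-plane magnification (shrinkage < 1), ``shift`` the
    in-plane image translation in pixels.  Returns an (N, 2) array of
    (u, v) = (x, y) image coordinates.
    """
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float)) - np.asarray(center_xyz, dtype=float)
    lab = pts @ view_matrix(alpha, beta, gamma).T
    u = scale * lab[:, 0] + shift[0] + image_center[0]
    v = scale * lab[:, 1] + shift[1] + image_center[1]
    return np.column_stack([u, v])


def volume_center_xyz(shape_zyx: tuple[int, int, int]) -> np.ndarray:
    """Voxel-centered geometric center (x, y, z) of a (nz, ny, nx) array."""
    nz, ny, nx = shape_zyx
    return np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
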