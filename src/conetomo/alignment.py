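"""Gold-fiducial detection, tracking, and alignment solving.

The alignment model follows the centering-then-alignment procedure of
conical tomography: one gold particle is chosen as the center of every
projection, all detections are expressed relative to it, and per-image
Euler angles (alpha, beta, gamma) plus in-plane shifts are solved jointly
with the shared 3D marker positions by minimizing reprojection error.
Specimen shrinkage from radiation damage is estimated from the gold-pair
distances of the leading and trailing untilted views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .geometry import view_matrix
from .projection import ConicalGeometry, TiltSeries


class UnsolvableError(RuntimeError):
    """Too few complete fiducial tracks to solve the alignment."""


def detect_fiducials(image: np.ndarray, expected_diameter_px: float,
                     threshold_rel: float = 0.35,
                     max_detections: int = 50,
                     ring_reject: float = 0.75) -> np.ndarray:
    """Sub-pixel centroids of gold-sized bright blobs, brightest first.

    A difference-of-Gaussians band-pass matched to the marker diameter
    isolates the gold from slowly varying biological density; local maxima
    above ``threshold_rel`` of the strongest response pass an isotropy
    (ring) test that rejects ridge responses from edge-on membranes, and
    surviving peaks are refined by intensity-weighted centroiding.
    Returns an (n, 2) array of (x, y), strongest first.
    """
    if expected_diameter_px < 2:
        raise ValueError("expected_diameter_px must be >= 2")
    img = np.asarray(image, dtype=np.float64)
    s1 = expected_diameter_px / 3.0
    dog = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, 2.5 * s1)
    if dog.max() <= 0:
        return np.zeros((0, 2))
    peaks = peak_local_max(dog, min_distance=max(2, int(expected_diameter_px)),
                           threshold_abs=threshold_rel * dog.max(),
                           num_peaks=4 * max_detections)
    ring_r = 1.6 * expected_diameter_px
    ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    ring = np.stack([np.sin(ang), np.cos(ang)], axis=1) * ring_r
    out = []
    r = max(2, int(round(expected_diameter_px)))
    for j, i in peaks:
        # isotropy: a gold blob drops off in every direction, a membrane
        # ridge stays high along its axis
        pts = np.array([j, i]) + ring
        vals = ndimage.map_coordinates(dog, [pts[:, 0], pts[:, 1]], order=1,
                                       mode="nearest")
        if vals.max() > ring_reject * dog[j, i]:
            continue
        j0, j1 = max(j - r, 0), min(j + r + 1, img.shape[0])
        i0, i1 = max(i - r, 0), min(i + r + 1, img.shape[1])
        win = dog[j0:j1, i0:i1]
        jj, ii = np.mgrid[j0:j1, i0:i1]
        # local background from the window rim keeps the centroid unbiased
        # when the bead overlaps biological density
        rim = np.hypot(jj - j, ii - i) >= r - 0.5
        w = np.clip(win - np.median(win[rim]), 0.0, None)
        if w.sum() <= 0:
            continue
        out.append(((w * ii).sum() / w.sum(), (w * jj).sum() / w.sum(),
                    dog[j, i]))
    out.sort(key=lambda t: -t[2])
    out = out[:max_detections]
    return np.array([(u, v) for u, v, _ in out]) if out else np.zeros((0, 2))


@dataclass
class FiducialTracks:
    """Per-marker image coordinates across a series.

    ``coords[marker, image]`` is (x, y) relative to nothing in particular
    (raw image coordinates); NaN marks a missing observation.  ``views``
    carries the nominal (tilt, azimuth) per image.
    """

    coords: np.ndarray                     # (n_markers, n_images, 2)
    views: list[tuple[float, float]]
    center_marker: int = 0
    flagged: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must be (n_markers, n_images, 2)")
        if np.any(np.isnan(self.coords[self.center_marker])):
            raise ValueError("center marker must be present in every image")

    @property
    def n_markers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_images(self) -> int:
        return self.coords.shape[1]

    def complete_markers(self) -> np.ndarray:
        return np.where(~np.isnan(self.coords).any(axis=(1, 2)))[0]

    def to_csv(self, path) -> None:
        rows = []
        for m in range(self.n_markers):
            for i in range(self.n_images):
                x, y = self.coords[m, i]
                if np.isfinite(x):
                    rows.append({"image_index": i, "marker_id": m,
                                 "x": x, "y": y})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, views, center_marker=0) -> "FiducialTracks":
        df = pd.read_csv(path)
        n_m = int(df["marker_id"].max()) + 1
        n_i = len(views)
        coords = np.full((n_m, n_i, 2), np.nan)
        for _, r in df.iterrows():
            coords[int(r["marker_id"]), int(r["image_index"])] = (r["x"], r["y"])
        return cls(coords=coords, views=list(views), center_marker=center_marker)


def _triangulate(obs, present, views, image_center):
    """Linear LS 3D position of one marker from its 2D observations."""
    A, b = [], []
    for i, (tilt, az) in enumerate(views):
        if not present[i]:
            continue
        R = view_matrix(az, tilt)[:2]
        A.append(R)
        b.append(obs[i] - image_center)
    A = np.vstack(A)
    b = np.concatenate(b)
    return np.linalg.lstsq(A, b, rcond=None)[0]


def track_fiducials(series: TiltSeries, detections: list[np.ndarray],
                    max_link_dist_px: float = 12.0,
                    max_gap_fraction: float = 0.10,
                    ambiguity_margin_px: float = 1.0) -> FiducialTracks:
    """Link per-image detections into marker tracks.

    Each track keeps a running 3D position estimate (triangulated from the
    nominal view geometry); the predicted position in the next image links
    the nearest detection.  Ambiguous links (margin < 1 px) are flagged,
    markers missing from more than ``max_gap_fraction`` of images are
    dropped, and small gaps are filled from the model prediction.
    """
    n_img = len(detections)
    nonempty = sum(1 for d in detections if len(d))
    if nonempty < 0.9 * n_img:
        raise UnsolvableError("detections missing in more than 10% of images")
    H, W = series.projections.shape[1:]
    ic = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    views = series.views

    # seed tracks in the best-populated frame and track outward both ways;
    # each track keeps a running triangulated 3D position for prediction
    ref = int(np.argmax([len(d) for d in detections]))
    order = sorted(range(n_img), key=lambda i: abs(i - ref))
    tracks = [[None] * n_img for _ in range(len(detections[ref]))]
    for m, q in enumerate(np.asarray(detections[ref])):
        tracks[m][ref] = q
    flagged: list[tuple[int, int]] = []
    for i in order[1:]:
        det = np.asarray(detections[i])
        if len(det) == 0:
            continue
        used = np.zeros(len(det), dtype=bool)
        # strongest-constrained tracks link first
        for m, tr in enumerate(tracks):
            obs = np.array([q if q is not None else (np.nan, np.nan)
                            for q in tr])
            present = np.isfinite(obs[:, 0])
            idx = np.where(present)[0]
            if len(idx) >= 2:
                X = _triangulate(obs[idx], np.ones(len(idx), bool),
                                 [views[k] for k in idx], ic)
                tilt, az = views[i]
                pred = view_matrix(az, tilt)[:2] @ X + ic
            else:
                nearest = idx[np.argmin(np.abs(idx - i))]
                pred = obs[nearest]
            dist = np.linalg.norm(det - pred, axis=1)
            dist[used] = np.inf
            j = int(np.argmin(dist))
            if dist[j] <= max_link_dist_px:
                second = np.partition(dist, 1)[1] if len(dist) > 1 else np.inf
                if second - dist[j] < ambiguity_margin_px:
                    flagged.append((m, i))
                tr[i] = det[j]
                used[j] = True

    # re-linking passes: triangulate each track from everything linked so
    # far, then re-scan every frame; recovers markers lost early on while
    # the 3D estimates were still poor
    for _ in range(2):
        Xs = []
        for tr in tracks:
            obs = np.array([q if q is not None else (np.nan, np.nan)
                            for q in tr])
            present = np.isfinite(obs[:, 0])
            idx = np.where(present)[0]
            Xs.append(_triangulate(obs[idx], np.ones(len(idx), bool),
                                   [views[k] for k in idx], ic)
                      if len(idx) >= 2 else None)
        for i in range(n_img):
            det = np.asarray(detections[i])
            if len(det) == 0:
                continue
            preds = []
            for m, X in enumerate(Xs):
                if X is None:
                    preds.append(None)
                    continue
                tilt, az = views[i]
                preds.append(view_matrix(az, tilt)[:2] @ X + ic)
            used = np.zeros(len(det), dtype=bool)
            # assign greedily by increasing predicted distance
            cand = []
            for m, pred in enumerate(preds):
                if pred is None:
                    continue
                dist = np.linalg.norm(det - pred, axis=1)
                j = int(np.argmin(dist))
                cand.append((dist[j], m, j, pred))
            for m in range(len(tracks)):
                tracks[m][i] = None
            for dmin, m, j, pred in sorted(cand):
                if dmin > max_link_dist_px:
                    continue
                dist = np.linalg.norm(det - pred, axis=1)
                dist[used] = np.inf
                j = int(np.argmin(dist))
                if dist[j] <= max_link_dist_px:
                    tracks[m][i] = det[j]
                    used[j] = True

    coords = np.full((len(tracks), n_img, 2), np.nan)
    for m, tr in enumerate(tracks):
        for i, q in enumerate(tr):
            if q is not None:
                coords[m, i] = q
    # drop gappy tracks, interpolate small gaps from the model
    keep = []
    for m in range(len(tracks)):
        missing = np.isnan(coords[m, :, 0])
        if missing.mean() > max_gap_fraction:
            continue
        if missing.any():
            present = ~missing
            X = _triangulate(coords[m][present], np.ones(present.sum(), bool),
                             [views[k] for k in np.where(present)[0]], ic)
            for i in np.where(missing)[0]:
                tilt, az = views[i]
                coords[m, i] = view_matrix(az, tilt)[:2] @ X + ic
        keep.append(m)
    if len(keep) < 3:
        raise UnsolvableError(
            f"only {len(keep)} complete tracks; >= 3 required")
    coords = coords[keep]
    # center marker: the track whose 3D position is closest to the tilt axis
    Xs = [_triangulate(coords[m], np.ones(n_img, bool), views, ic)
          for m in range(len(keep))]
    center = int(np.argmin([np.hypot(X[0], X[1]) for X in Xs]))
    return FiducialTracks(coords=coords, views=list(views),
                          center_marker=center, flagged=flagged)


@dataclass
class AlignmentSolution:
    """Per-image orientation parameters in the common (center-marker)
    reference frame, with reprojection residuals and global shrinkage."""

    alpha_deg: np.ndarray
    beta_deg: np.ndarray
    gamma_deg: np.ndarray
    shifts_px: np.ndarray           # (n, 2) total in-plane shift per image
    residual_rms_px: np.ndarray
    shrinkage: float = 1.0
    scales: np.ndarray | None = None   # per-image in-plane scale (shrinkage ramp)
    marker_positions: np.ndarray | None = None
    reference_frame: str = "center fiducial at origin; beam along z"

    def __post_init__(self):
        n = len(self.alpha_deg)
        if self.scales is None:
            self.scales = np.ones(n)
        if np.any(self.residual_rms_px < 0):
            raise ValueError("residuals must be non-negative")

    @property
    def n_images(self) -> int:
        return len(self.alpha_deg)

    def to_json_dict(self) -> dict:
        return {"alpha_deg": self.alpha_deg.tolist(),
                "beta_deg": self.beta_deg.tolist(),
                "gamma_deg": self.gamma_deg.tolist(),
                "shifts_px": self.shifts_px.tolist(),
                "residual_rms_px": self.residual_rms_px.tolist(),
                "shrinkage": self.shrinkage,
                "scales": self.scales.tolist(),
                "reference_frame": self.reference_frame}

    @classmethod
    def nominal(cls, views, shrinkage: float = 1.0) -> "AlignmentSolution":
        n = len(views)
        return cls(alpha_deg=np.array([az for _, az in views], float),
                   beta_deg=np.array([t for t, _ in views], float),
                   gamma_deg=np.zeros(n), shifts_px=np.zeros((n, 2)),
                   residual_rms_px=np.zeros(n), shrinkage=shrinkage)


def _rot_all(alpha, beta, gamma):
    """Stacked (n, 2, 3) projection rows of Rz(gamma) Rx(beta) Rz(alpha)."""
    a, b, g = (np.deg2rad(alpha), np.deg2rad(beta), np.deg2rad(gamma))
    ca, sa, cb, sb, cg, sg = np.cos(a), np.sin(a), np.cos(b), np.sin(b), \
        np.cos(g), np.sin(g)
    R = np.empty((len(a), 2, 3))
    # row 0 of Rz(g) Rx(b) Rz(a)
    R[:, 0, 0] = cg * ca - sg * cb * sa
    R[:, 0, 1] = -cg * sa - sg * cb * ca
    R[:, 0, 2] = sg * sb
    # row 1
    R[:, 1, 0] = sg * ca + cg * cb * sa
    R[:, 1, 1] = -sg * sa + cg * cb * ca
    R[:, 1, 2] = -cg * sb
    return R


def solve_alignment(tracks: FiducialTracks,
                    geometry: ConicalGeometry | None = None,
                    refine_tilt: bool = True, max_iter: int = 8,
                    angle_prior_weight: float = 0.05) -> AlignmentSolution:
    """Alternating least squares over marker positions and per-image
    (alpha, beta, gamma, shifts), followed by a joint sparse Levenberg-
    Marquardt polish; the center marker fixes the origin and a weak prior
    pulling angles toward nominal fixes the remaining rotational gauge.

    Shifts are reported as total image shifts: the center-marker position
    plus the residual fitted translation.
    """
    views = tracks.views
    n = tracks.n_images
    complete = tracks.complete_markers()
    if len(complete) < 3:
        raise UnsolvableError("need >= 3 complete tracks")
    obs = tracks.coords[complete]                  # (J, n, 2)
    cidx = int(np.where(complete == tracks.center_marker)[0][0]) \
        if tracks.center_marker in complete else 0
    centered = obs - obs[cidx:cidx + 1]            # center marker -> origin
    J = len(complete)

    alpha = np.array([az for _, az in views], float)
    beta = np.array([t for t, _ in views], float)
    gamma = np.zeros(n)
    t_xy = np.zeros((n, 2))
    a0, b0 = alpha.copy(), beta.copy()
    w = angle_prior_weight

    def solve_markers():
        R = _rot_all(alpha, beta, gamma)
        A = R.reshape(2 * n, 3)
        M = np.zeros((J, 3))
        for j in range(J):
            if j == cidx:
                continue
            b = (centered[j] - t_xy).ravel()
            M[j] = np.linalg.lstsq(A, b, rcond=None)[0]
        return M

    def image_residual(params, i, M):
        a, b_, g, tx, ty = params
        R = _rot_all(np.array([a]), np.array([b_]), np.array([g]))[0]
        pred = M @ R.T + np.array([tx, ty])
        return (pred - centered[:, i]).ravel()

    # --- ALS warm start
    M = solve_markers()
    for _ in range(max_iter):
        for i in range(n):
            x0 = np.array([alpha[i], beta[i], gamma[i], *t_xy[i]])
            if not refine_tilt:
                sol = optimize.least_squares(
                    lambda p: image_residual([p[0], beta[i], p[1], p[2], p[3]],
                                             i, M),
                    np.delete(x0, 1), method="lm")
                alpha[i], gamma[i], t_xy[i, 0], t_xy[i, 1] = sol.x
            else:
                sol = optimize.least_squares(
                    lambda p: np.concatenate([
                        image_residual(p, i, M),
                        [w * (p[0] - a0[i]), w * (p[1] - b0[i]), w * p[2]]]),
                    x0, method="lm")
                alpha[i], beta[i], gamma[i], t_xy[i, 0], t_xy[i, 1] = sol.x
        M = solve_markers()

    # --- joint polish with sparse finite-difference Jacobian
    free_markers = [j for j in range(J) if j != cidx]
    n_ang = 5 if refine_tilt else 4

    def pack():
        per = []
        for i in range(n):
            per += ([alpha[i], beta[i], gamma[i], t_xy[i, 0], t_xy[i, 1]]
                    if refine_tilt else
                    [alpha[i], gamma[i], t_xy[i, 0], t_xy[i, 1]])
        return np.array(per + [c for j in free_markers for c in M[j]])

    def unpack(p):
        per = p[:n_ang * n].reshape(n, n_ang)
        if refine_tilt:
            al, be, ga = per[:, 0], per[:, 1], per[:, 2]
            t = per[:, 3:5]
        else:
            al, ga, t = per[:, 0], per[:, 1], per[:, 2:4]
            be = beta
        Mm = np.zeros((J, 3))
        rest = p[n_ang * n:].reshape(len(free_markers), 3)
        for k, j in enumerate(free_markers):
            Mm[j] = rest[k]
        return al, be, ga, t, Mm

    obs_weight = np.ones((J, n, 1))

    def fun(p):
        al, be, ga, t, Mm = unpack(p)
        R = _rot_all(al, be, ga)                       # (n, 2, 3)
        pred = np.einsum("nab,jb->jna", R, Mm) + t[None]
        r = (obs_weight * (pred - centered)).ravel()
        pri = [w * (al - a0), w * ga]
        if refine_tilt:
            pri.append(w * (be - b0))
        return np.concatenate([r] + pri)

    from scipy.sparse import lil_matrix
    n_res = 2 * n * J
    n_pri = (3 if refine_tilt else 2) * n
    n_par = n_ang * n + 3 * len(free_markers)
    S = lil_matrix((n_res + n_pri, n_par), dtype=np.int8)
    for j in range(J):
        for i in range(n):
            rr = 2 * (j * n + i)
            S[rr:rr + 2, n_ang * i:n_ang * (i + 1)] = 1
            if j != cidx:
                k = free_markers.index(j)
                S[rr:rr + 2, n_ang * n + 3 * k:n_ang * n + 3 * k + 3] = 1
    for q in range(n_pri):
        i = q % n
        col = n_ang * i + (0 if q < n else (2 if refine_tilt else 1)
                           if q < 2 * n else 1)
        S[n_res + q, col] = 1
    sol = optimize.least_squares(fun, pack(), method="trf", jac_sparsity=S,
                                 x_scale="jac", ftol=1e-14, xtol=1e-14,
                                 gtol=1e-14, max_nfev=200)
    # one trimming pass: down-weight gross outlier observations (bad links
    # or detections biased by overlapping structure) and re-solve
    al, be, ga, t, Mm = unpack(sol.x)
    R = _rot_all(al, be, ga)
    err = np.linalg.norm(np.einsum("nab,jb->jna", R, Mm) + t[None]
                         - centered, axis=2)
    cut = max(3.0 * np.median(err), 1.0)
    if (err > cut).any():
        obs_weight[err > cut] = 0.0
        sol = optimize.least_squares(fun, sol.x, method="trf",
                                     jac_sparsity=S, x_scale="jac",
                                     ftol=1e-14, xtol=1e-14, gtol=1e-14,
                                     max_nfev=200)
    alpha, beta_fit, gamma, t_xy, M = unpack(sol.x)
    beta = np.asarray(beta_fit, float)

    R = _rot_all(alpha, beta, gamma)
    pred = np.einsum("nab,jb->jna", R, M) + t_xy[None]
    err = pred - centered
    rms = np.sqrt((err ** 2).sum(axis=2).mean(axis=0))

    shifts = obs[cidx] + t_xy   # total shift: centering translation + residual
    shrink = 1.0
    unt = [i for i, (t, _) in enumerate(views) if t == 0.0]
    if len(unt) >= 2 and J >= 2:
        shrink = estimate_shrinkage(obs[:, unt[0]], obs[:, unt[-1]])
    return AlignmentSolution(alpha_deg=alpha, beta_deg=beta, gamma_deg=gamma,
                             shifts_px=shifts, residual_rms_px=rms,
                             shrinkage=shrink, marker_positions=M)


def gauge_aligned_angle_errors(alpha, beta, gamma,
                               alpha_ref, beta_ref, gamma_ref) -> np.ndarray:
    """Per-image rotation errors (degrees) between two alignment solutions,
    after removing the global reference-frame rotation.

    A fiducial bundle adjustment determines the per-image orientations only
    up to one global rotation of the (markers + views) reference frame; the
    physically meaningful error is the geodesic angle of
    ``R_i @ R0 @ R_ref_i^T`` with ``R0`` the best-fit global rotation
    (polar factor of the cross-covariance).
    """
    from .geometry import view_matrix
    n = len(alpha)
    R = [view_matrix(alpha[i], beta[i], gamma[i]) for i in range(n)]
    Rr = [view_matrix(alpha_ref[i], beta_ref[i], gamma_ref[i]) for i in range(n)]
    C = sum(R[i].T @ Rr[i] for i in range(n))
    U, _, Vt = np.linalg.svd(C)
    R0 = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    errs = np.empty(n)
    for i in range(n):
        D = R[i] @ R0 @ Rr[i].T
        c = np.clip((np.trace(D) - 1.0) / 2.0, -1.0, 1.0)
        errs[i] = np.degrees(np.arccos(c))
    return errs


def estimate_shrinkage(first_points: np.ndarray,
                       last_points: np.ndarray) -> float:
    """Specimen shrinkage as the ratio of mean pairwise gold distances
    between the trailing and leading untilted views (matched points)."""
    a = np.asarray(first_points, float)
    b = np.asarray(last_points, float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need >= 2 matched points in both views")
    da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
    db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
    iu = np.triu_indices(len(a), 1)
    return float(db[iu].mean() / da[iu].mean())


def robust_shrinkage(first_points: np.ndarray, last_points: np.ndarray,
                     max_marker_dev: float = 0.01) -> float:
    """Shrinkage with outlier-marker rejection.

    A single mis-detected or mis-matched bead corrupts every pairwise
    distance it participates in; markers whose median pair ratio deviates
    from the global median by more than ``max_marker_dev`` are dropped
    before the mean-pairwise-distance ratio is taken.
    """
    a = np.asarray(first_points, float)
    b = np.asarray(last_points, float)
    if len(a) < 3:
        return estimate_shrinkage(a, b)
    da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
    db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = db / da
    iu = np.triu_indices(len(a), 1)
    med = float(np.median(r[iu]))
    keep = []
    for k in range(len(a)):
        rk = np.concatenate([r[k, :k], r[k + 1:, k]])
        rk = rk[np.isfinite(rk)]
        if len(rk) and abs(float(np.median(rk)) - med) <= max_marker_dev:
            keep.append(k)
    if len(keep) < 2:
        keep = list(range(len(a)))
    return estimate_shrinkage(a[keep], b[keep])


def match_untilted_points(first: np.ndarray, last: np.ndarray,
                          max_dist_px: float = 15.0):
    """Greedy nearest-neighbor matching of detections between the leading
    and trailing untilted views; returns matched (first, last) arrays."""
    first = np.asarray(first, float)
    last = np.asarray(last, float)
    used = np.zeros(len(last), bool)
    fa, lb = [], []
    for p in first:
        if not len(last):
            break
        d = np.linalg.norm(last - p, axis=1)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= max_dist_px:
            fa.append(p)
            lb.append(last[j])
            used[j] = True
    return np.array(fa), np.array(lb)
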