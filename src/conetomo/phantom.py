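"""Synthetic rod-spherule phantoms with known ground truth.

The phantom emulates the statistical structure a conical-tomography
analysis of a photoreceptor terminal assumes: a ~50 nm section (slab)
containing a triple-layered plasma membrane apposed to a horizontal-cell
ending, a crescent ribbon anchored by an arciform density, 40 nm synaptic
vesicles in cytoplasmic / tethered / docked / omega / coated fusion states,
and 10 nm colloidal gold fiducials deposited on the section surfaces.

Density units are arbitrary but fixed package-wide (see :data:`DENSITY`):
background 0, cytosol low, membranes high, gold maximal, so gold is
separable from any biological density by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .membranes import AXES, MembranePlane, layer_sigma, smooth_step
from .morphometry import (Point3D, VesicleRecord, fraction_inside_slab)
from .volume import DensityVolume

#: Fixed density levels (arbitrary units).
DENSITY = {
    "background": 0.0,
    "cytosol": 0.08,
    "coat": 0.7,
    "ribbon": 0.9,
    "membrane": 1.0,
    "arciform": 1.2,
    # colloidal gold outweighs any stained biological density by an order
    # of magnitude, also in projection (line integrals)
    "gold": 12.0,
}


class PackingError(RuntimeError):
    """Requested vesicle count cannot be placed at the required spacing."""


class GeometryError(ValueError):
    """A fusion state is geometrically inconsistent with the membrane."""


@dataclass
class PhantomParams:
    """Generator parameters; defaults give a small terminal patch.

    ``shape`` is (nx, ny, nz) voxels.  ``spacing_range`` (nm) is the
    center-to-center spacing band of cytoplasmic vesicles;
    ``surface_spacing`` is the minimum spacing of membrane-bound pools
    (docked / omega), which pack denser than the cytoplasmic lattice.
    """

    voxel_size: float = 3.0                      # nm / voxel
    shape: tuple[int, int, int] = (192, 192, 28)  # (nx, ny, nz)
    slab_thickness: float = 50.0                 # nm
    vesicle_diameter: float = 40.0               # nm
    spacing_range: tuple[float, float] = (110.0, 120.0)
    surface_spacing: float = 46.0
    n_cytoplasmic: int = 7
    n_tethered: int = 2
    n_docked: int = 4
    n_omega: int = 2
    n_coated: int = 1
    membrane_normal: str = "x"                   # "x": through-slab, "z": in-plane
    membrane_frac: float = 0.66                  # midplane position / axis extent
    cytoplasm_side: int = -1
    cleft_width: float = 16.0                    # nm to the horizontal-cell membrane
    include_hc_membrane: bool = True
    membrane_layer_spacing: float = 6.0          # nm (resolution proxy: 3 or 6)
    include_ribbon: bool = True
    ribbon_height: float = 420.0                 # nm (clipped to the volume)
    ribbon_width: float = 30.0                   # nm
    arciform_diameter: float = 55.0              # nm
    tether_distance: float = 50.0                # nm from the ribbon surface
    gold_diameter: float = 10.0                  # nm
    n_gold: int = 6
    cytosol_level: float = DENSITY["cytosol"]
    texture: float = 0.01
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_cytoplasmic, self.n_tethered, self.n_docked,
                  self.n_omega, self.n_coated, self.n_gold)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if not self.vesicle_diameter < self.slab_thickness:
            raise ValueError("vesicle_diameter must be < slab_thickness")
        if not self.spacing_range[0] > self.vesicle_diameter:
            raise ValueError("spacing lower bound must exceed vesicle_diameter")
        if self.spacing_range[1] < self.spacing_range[0]:
            raise ValueError("spacing_range must be (lo, hi) with hi >= lo")
        if self.membrane_normal not in AXES:
            raise ValueError("membrane_normal must be 'x', 'y' or 'z'")
        if self.cytoplasm_side not in (-1, 1):
            raise ValueError("cytoplasm_side must be -1 or +1")
        nz = self.shape[2]
        if nz * self.voxel_size < self.slab_thickness:
            raise ValueError("volume z extent must contain the slab")

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size for n in self.shape)

    @property
    def slab_z(self) -> tuple[float, float]:
        lz = self.shape[2] * self.voxel_size
        z0 = (lz - self.slab_thickness) / 2.0
        return (z0, z0 + self.slab_thickness)

    def membrane(self) -> MembranePlane:
        pos = self.membrane_frac * self.extent_nm[AXES[self.membrane_normal]]
        return MembranePlane(self.membrane_normal, pos,
                             self.membrane_layer_spacing,
                             DENSITY["membrane"], self.cytoplasm_side)


@dataclass
class GroundTruth:
    """Everything the generator placed, for recovery tests."""

    vesicles: list[VesicleRecord]
    membranes: list[MembranePlane]
    gold_positions_nm: np.ndarray          # (n, 3) xyz
    ribbon_box_nm: tuple | None            # ((x0,x1),(y0,y1),(z0,z1))
    true_active_zone_area_um2: float
    true_terminal_volume_um3: float
    true_hc_volume_um3: float
    params: PhantomParams | None = None

    def state_counts(self) -> dict[str, int]:
        out = {s: 0 for s in
               ("cytoplasmic", "tethered", "docked", "omega", "coated")}
        for v in self.vesicles:
            out[v.state] += 1
        return out

    def centers_nm(self, state: str | None = None) -> np.ndarray:
        vs = [v for v in self.vesicles if state is None or v.state == state]
        if not vs:
            return np.zeros((0, 3))
        return np.array([[v.center.x, v.center.y, v.center.z] for v in vs]) * 1000.0

    def vesicle_table(self) -> pd.DataFrame:
        rows = [{"x_um": v.center.x, "y_um": v.center.y, "z_um": v.center.z,
                 "diameter_nm": v.diameter, "state": v.state,
                 "fraction_inside": v.fraction_inside,
                 "count_weight": v.count_weight} for v in self.vesicles]
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        obj = {
            "seed": None if self.params is None else self.params.seed,
            "params": None if self.params is None else _params_dict(self.params),
            "vesicles": self.vesicle_table().to_dict(orient="records"),
            "gold_positions_nm": np.asarray(self.gold_positions_nm).tolist(),
            "membranes": [{"axis": m.axis, "position": m.position,
                           "layer_spacing": m.layer_spacing,
                           "cytoplasm_side": m.cytoplasm_side}
                          for m in self.membranes],
            "ribbon_box_nm": self.ribbon_box_nm,
            "true_active_zone_area_um2": self.true_active_zone_area_um2,
            "true_terminal_volume_um3": self.true_terminal_volume_um3,
            "true_hc_volume_um3": self.true_hc_volume_um3,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _params_dict(p: PhantomParams) -> dict:
    d = asdict(p)
    d["shape"] = list(p.shape)
    return d


# ---------------------------------------------------------------- rendering

def _axis_coord(shape_xyz, voxel, axis_idx):
    """1D physical coordinates along one xyz axis, broadcastable to (z,y,x)."""
    n = shape_xyz[axis_idx]
    c = np.arange(n, dtype=np.float32) * voxel
    # array order is (z, y, x): axis x -> last dim, y -> middle, z -> first
    shape = [1, 1, 1]
    shape[2 - axis_idx] = n
    return c.reshape(shape)


def _window(center_nm, half_nm, shape_zyx, voxel):
    """Local (z, y, x) slice window around a physical point, clipped."""
    sl, coords = [], []
    for dim, c in zip(range(3), (center_nm[2], center_nm[1], center_nm[0])):
        n = shape_zyx[dim]
        i0 = max(0, int(np.floor((c - half_nm) / voxel)))
        i1 = min(n, int(np.ceil((c + half_nm) / voxel)) + 1)
        sl.append(slice(i0, i1))
        ax = np.arange(i0, i1, dtype=np.float32) * voxel - c
        shp = [1, 1, 1]
        shp[dim] = i1 - i0
        coords.append(ax.reshape(shp))
    return tuple(sl), coords  # coords are (dz, dy, dx) offsets in nm


def _vesicle_shell(rho, diameter, layer_spacing, voxel, amplitude):
    sig = layer_sigma(layer_spacing, voxel)
    r_out = diameter / 2.0
    r_in = r_out - layer_spacing
    return amplitude * (np.exp(-((rho - r_out) ** 2) / (2 * sig**2))
                        + np.exp(-((rho - r_in) ** 2) / (2 * sig**2)))


def _render_vesicle_patch(add, mem_suppress, state, center_nm, diameter,
                          layer_spacing, voxel, membrane: MembranePlane | None,
                          coat_gap=8.0, coat_amplitude=DENSITY["coat"]):
    """Render one vesicle into ``add`` (additive density) and, for fused
    states, multiply the plasma-membrane suppression field ``mem_suppress``.

    ``add`` and ``mem_suppress`` are full (z, y, x) volumes sharing a grid.
    """
    s = layer_spacing
    half = diameter / 2.0 + coat_gap + s + 4 * layer_sigma(s, voxel) + 2 * voxel
    sl, (dz, dy, dx) = _window(center_nm, half, add.shape, voxel)
    rho = np.sqrt(dx**2 + dy**2 + dz**2)
    shell = _vesicle_shell(rho, diameter, s, voxel, DENSITY["membrane"])

    if state == "coated":
        sig = layer_sigma(s, voxel)
        shell = shell + coat_amplitude * np.exp(
            -((rho - (diameter / 2.0 + coat_gap)) ** 2) / (2 * sig**2))

    if state in ("docked", "omega"):
        if membrane is None:
            raise GeometryError(f"{state} vesicle requires a membrane")
        ax = membrane.axis_index
        d_center = membrane.position - center_nm[ax]
        if abs(d_center) > diameter:
            raise GeometryError(
                f"{state} vesicle center {abs(d_center):.1f} nm from the "
                f"membrane exceeds one diameter ({diameter} nm)")
        to_mem = np.sign(d_center) if d_center != 0 else 1.0
        # axial distance from the center toward the membrane, perpendicular radius
        local = (dx, dy, dz)[ax]
        a = to_mem * local
        others = [c for i, c in enumerate((dx, dy, dz)) if i != ax]
        rho_perp = np.sqrt(others[0] ** 2 + others[1] ** 2)
        h = abs(d_center)
        edge = 1.5 * voxel

        if state == "docked":
            rc = 0.35 * diameter
            disc = smooth_step(rc - rho_perp, edge)
            zone = disc * smooth_step(a - (h - 1.5 * s), edge)
            shell = shell * (1.0 - zone)
            mem_suppress[sl] *= (1.0 - disc * smooth_step(
                (1.2 * s) - np.abs(a - h), edge))
            sig = layer_sigma(s, voxel)
            # single merged leaflet at the cytoplasmic-leaflet plane
            shell = shell + DENSITY["membrane"] * disc * np.exp(
                -((a - (h - s / 2.0)) ** 2) / (2 * sig**2))
        else:  # omega: open pore through the membrane into the cleft
            rp = 0.30 * diameter
            tube = smooth_step(rp - rho_perp, edge) * smooth_step(
                a - 0.15 * diameter, edge)
            shell = shell * (1.0 - tube)
            mem_suppress[sl] *= (1.0 - tube)

    add[sl] += shell.astype(add.dtype)


def docked_center_offset(diameter: float, layer_spacing: float) -> float:
    """Distance from membrane midplane to a docked vesicle center."""
    return diameter / 2.0 + layer_spacing / 2.0


def omega_center_offset(diameter: float, layer_spacing: float) -> float:
    """Distance from membrane midplane to an omega-figure center."""
    return diameter / 2.0 - layer_spacing / 2.0


def render_vesicle(state, center_nm, diameter, membrane: MembranePlane | None,
                   shape_xyz=(32, 32, 32), voxel_size=2.0,
                   layer_spacing=6.0) -> np.ndarray:
    """Render a standalone density patch of one vesicle (plus membrane if
    given); used directly by tests and by illustration code.

    Returns a (z, y, x) array.  Docked / omega states require a membrane
    with the center within one diameter of it.
    """
    if state not in ("cytoplasmic", "tethered", "docked", "omega", "coated"):
        raise ValueError(f"unknown fusion state {state!r}")
    shape_zyx = (shape_xyz[2], shape_xyz[1], shape_xyz[0])
    add = np.zeros(shape_zyx, dtype=np.float32)
    suppress = np.ones(shape_zyx, dtype=np.float32)
    _render_vesicle_patch(add, suppress, state, np.asarray(center_nm, float),
                          diameter, layer_spacing, voxel_size, membrane)
    if membrane is not None:
        coord = _axis_coord(shape_xyz, voxel_size, membrane.axis_index)
        mem = membrane.profile(membrane.signed_distance(coord), voxel_size)
        add += (mem * suppress).astype(np.float32)
    return add


def _render_sphere(vol, center_nm, radius_nm, voxel, level, edge_vox=1.0):
    sl, (dz, dy, dx) = _window(center_nm, radius_nm + 2 * edge_vox * voxel,
                               vol.shape, voxel)
    rho = np.sqrt(dx**2 + dy**2 + dz**2)
    vol[sl] = np.maximum(vol[sl],
                         level * smooth_step(radius_nm - rho, edge_vox * voxel))


def _render_box(vol, box_nm, voxel, level, edge_nm):
    """Soft-edged axis-aligned box; box_nm = ((x0,x1),(y0,y1),(z0,z1))."""
    (x0, x1), (y0, y1), (z0, z1) = box_nm
    cx, cy, cz = (x0 + x1) / 2, (y0 + y1) / 2, (z0 + z1) / 2
    half = max(x1 - x0, y1 - y0, z1 - z0) / 2 + 3 * edge_nm
    sl, (dz, dy, dx) = _window((cx, cy, cz), half, vol.shape, voxel)
    m = (smooth_step((x1 - x0) / 2 - np.abs(dx), edge_nm)
         * smooth_step((y1 - y0) / 2 - np.abs(dy), edge_nm)
         * smooth_step((z1 - z0) / 2 - np.abs(dz), edge_nm))
    vol[sl] = np.maximum(vol[sl], level * m)


# ---------------------------------------------------------------- placement

def _dart_throw(rng, n, sampler, existing, existing_min, intra_min,
                valid=None, max_attempts=600):
    """Reject-sample ``n`` points.

    Each candidate must satisfy ``valid`` (if given), keep at least
    ``existing_min`` nm from all previously placed points of other pools,
    and ``intra_min`` (a constant or a callable drawing a threshold, e.g.
    uniformly from the spacing band) from points of its own pool.  Raises
    PackingError on failure instead of silently truncating.
    """
    placed: list[np.ndarray] = []
    for k in range(n):
        for _ in range(max_attempts):
            p = sampler()
            if valid is not None and not valid(p):
                continue
            if any(np.linalg.norm(p - q) < existing_min for q in existing):
                continue
            ok = True
            for q in placed:
                m = intra_min() if callable(intra_min) else intra_min
                if np.linalg.norm(p - q) < m:
                    ok = False
                    break
            if ok:
                placed.append(p)
                break
        else:
            raise PackingError(
                f"could not place vesicle {k + 1}/{n} after {max_attempts} "
                "attempts; requested count infeasible at this spacing")
    return placed


def generate_phantom(params: PhantomParams) -> tuple[DensityVolume, GroundTruth]:
    """Generate a phantom volume and its ground truth.

    Deterministic for a fixed seed.  Raises :class:`PackingError` if a
    requested pool cannot be placed at the required spacing.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    vox = p.voxel_size
    lx, ly, lz = p.extent_nm
    shape_zyx = (p.shape[2], p.shape[1], p.shape[0])
    z0, z1 = p.slab_z
    mem = p.membrane()
    ax = mem.axis_index
    d = p.vesicle_diameter
    s = p.membrane_layer_spacing
    margin = 24.0  # nm clearance from lateral volume borders

    ext = p.extent_nm
    lo = [margin, margin, z0 + 5.0]
    hi = [ext[0] - margin, ext[1] - margin, z1 - 5.0]

    # --- cytoplasm bounding box along the membrane normal
    if mem.cytoplasm_side < 0:
        cyto_lo, cyto_hi = lo[ax], min(hi[ax], mem.position - d / 2 - s - 8.0)
    else:
        cyto_lo, cyto_hi = max(lo[ax], mem.position + d / 2 + s + 8.0), hi[ax]
    if p.n_cytoplasmic + p.n_tethered + p.n_coated > 0 and cyto_hi <= cyto_lo:
        raise PackingError("no cytoplasmic space on the chosen membrane side")

    # --- ribbon geometry (only rendered for through-slab membranes)
    ribbon_box = None
    if p.include_ribbon and mem.axis == "x" and mem.cytoplasm_side < 0:
        rx1 = mem.position - p.arciform_diameter
        rx0 = max(lo[0], rx1 - min(p.ribbon_height, 0.5 * (cyto_hi - cyto_lo) + 80))
        ry = ly / 2.0
        ribbon_box = ((rx0, rx1), (ry - p.ribbon_width / 2, ry + p.ribbon_width / 2),
                      (z0 + 4, z1 - 4))

    def sample_cyto():
        q = np.array([rng.uniform(lo[i], hi[i]) for i in range(3)])
        q[ax] = rng.uniform(cyto_lo, cyto_hi)
        return q

    arciform_center = None
    if ribbon_box is not None:
        arciform_center = np.array([(ribbon_box[0][1] + mem.position) / 2.0,
                                    ly / 2.0, lz / 2.0])

    def clear_of_ribbon(q):
        if ribbon_box is None:
            return True
        (x0, x1), (y0, y1), (zr0, zr1) = ribbon_box
        pad = d / 2 + 12
        if x0 - pad < q[0] < x1 + pad and y0 - pad < q[1] < y1 + pad:
            return False
        # the arciform density occupies the gap between ribbon base and
        # membrane; vesicles cannot overlap it
        return np.linalg.norm(q - arciform_center) > \
            p.arciform_diameter / 2 + d / 2 + 6

    records: list[tuple[str, np.ndarray]] = []
    placed_all: list[np.ndarray] = []

    h_dock = docked_center_offset(d, s)
    h_omega = omega_center_offset(d, s)
    to_extracellular = -mem.cytoplasm_side

    def sample_surface():
        q = np.array([rng.uniform(lo[i], hi[i]) for i in range(3)])
        q[ax] = mem.position - to_extracellular * h_dock
        if ax != 2:
            q[2] = rng.uniform(z0 + 5.0, z1 - 5.0)
        return q

    # docked and omega figures share the membrane surface: place the pool
    # jointly (one spacing constraint), then assign states, so an unlucky
    # early placement cannot strand the later state
    n_surface = p.n_docked + p.n_omega
    if n_surface > 0:
        pts = _dart_throw(rng, n_surface, sample_surface, placed_all,
                          p.surface_spacing, p.surface_spacing,
                          valid=clear_of_ribbon)
        states = (["docked"] * p.n_docked + ["omega"] * p.n_omega)
        rng.shuffle(states)
        for state, q in zip(states, pts):
            if state == "omega":
                q = q.copy()
                q[ax] = mem.position - to_extracellular * h_omega
            placed_all.append(q)
            records.append((state, q))

    # tethered vesicles hug the ribbon faces
    if p.n_tethered > 0:
        if ribbon_box is not None:
            (x0, x1), (y0, y1), (zr0, zr1) = ribbon_box

            def sample_teth():
                side = rng.choice([-1.0, 1.0])
                yc = (y0 + y1) / 2 + side * (p.ribbon_width / 2 + d / 2 + 4
                                             + rng.uniform(0, p.tether_distance))
                return np.array([rng.uniform(x0, x1), yc,
                                 rng.uniform(z0 + 5.0, z1 - 5.0)])
        else:
            sample_teth = sample_cyto
        pts = _dart_throw(rng, p.n_tethered, sample_teth, placed_all,
                          p.surface_spacing, p.surface_spacing)
        placed_all += pts
        records += [("tethered", q) for q in pts]

    # coated vesicles: cytoplasmic, biased toward the membrane (endocytosis)
    if p.n_coated > 0:
        def sample_coated():
            q = sample_cyto()
            near_lo = (max(cyto_lo, mem.position - 3 * d) if mem.cytoplasm_side < 0
                       else cyto_lo)
            near_hi = (cyto_hi if mem.cytoplasm_side < 0
                       else min(cyto_hi, mem.position + 3 * d))
            q[ax] = rng.uniform(near_lo, near_hi)
            return q
        pts = _dart_throw(rng, p.n_coated, sample_coated, placed_all,
                          p.surface_spacing, p.surface_spacing,
                          valid=clear_of_ribbon)
        placed_all += pts
        records += [("coated", q) for q in pts]

    # cytoplasmic pool at the 110-120 nm lattice spacing (the minimum
    # spacing of each pair is drawn uniformly from the band)
    if p.n_cytoplasmic > 0:
        pts = _dart_throw(rng, p.n_cytoplasmic, sample_cyto, placed_all,
                          p.surface_spacing,
                          lambda: rng.uniform(*p.spacing_range),
                          valid=clear_of_ribbon)
        placed_all += pts
        records += [("cytoplasmic", q) for q in pts]

    # ------------------------------------------------------------- rasterize
    cyto_mask_coord = _axis_coord(p.shape, vox, ax)
    side = mem.cytoplasm_side
    cyto_field = smooth_step(side * (cyto_mask_coord - mem.position) - s, vox)
    bio = np.zeros(shape_zyx, dtype=np.float32)
    bio += (p.cytosol_level * cyto_field).astype(np.float32)

    mem_pm = mem.profile(mem.signed_distance(cyto_mask_coord), vox)
    mem_pm = np.broadcast_to(mem_pm, shape_zyx).copy()

    hc = None
    if p.include_hc_membrane:
        hc_pos = mem.position + to_extracellular * p.cleft_width
        hc = MembranePlane(mem.axis, hc_pos, s, DENSITY["membrane"],
                           cytoplasm_side=int(to_extracellular))
        bio += np.broadcast_to(
            hc.profile(hc.signed_distance(cyto_mask_coord), vox),
            shape_zyx).astype(np.float32)

    suppress = np.ones(shape_zyx, dtype=np.float32)
    add = np.zeros(shape_zyx, dtype=np.float32)
    for state, q in records:
        _render_vesicle_patch(add, suppress, state, q, d, s, vox,
                              mem if state in ("docked", "omega") else None)
    bio += add
    bio += (mem_pm * suppress).astype(np.float32)

    if ribbon_box is not None:
        _render_box(bio, ribbon_box, vox, DENSITY["ribbon"], edge_nm=vox)
        (x0, x1), (yb0, yb1), _ = ribbon_box
        arci = (x1 + mem.position) / 2.0
        _render_sphere(bio, (arci, (yb0 + yb1) / 2, lz / 2),
                       p.arciform_diameter / 2, vox, DENSITY["arciform"])

    if p.texture > 0:
        tex = rng.standard_normal(shape_zyx).astype(np.float32)
        tex = ndimage.gaussian_filter(tex, 1.0)
        bio += p.texture / max(tex.std(), 1e-9) * tex * cyto_field.astype(np.float32)

    # confine biology to the section, with a soft 1-voxel edge
    zc = _axis_coord(p.shape, vox, 2)
    slab_mask = (smooth_step(zc - z0, vox) * smooth_step(z1 - zc, vox))
    vol_data = (bio * slab_mask).astype(np.float32)

    volume = DensityVolume(vol_data, vox, provenance="phantom", slab=(z0, z1))

    gold_pos = np.zeros((0, 3))
    if p.n_gold > 0:
        volume, gold_pos = place_fiducials(volume, p.n_gold,
                                           seed=int(rng.integers(2**31)),
                                           gold_diameter=p.gold_diameter,
                                           margin_nm=margin)

    # ------------------------------------------------------------ truth
    vesicles = []
    for state, q in records:
        frac = fraction_inside_slab(q[2] / 1000.0, d, (z0, z1))
        vesicles.append(VesicleRecord(
            center=Point3D(q[0] / 1000.0, q[1] / 1000.0, q[2] / 1000.0),
            diameter=d, state=state, fraction_inside=frac))

    um = 1e-3
    if ax == 2:
        az_area = (lx * um) * (ly * um)
    else:
        other = [i for i in (0, 1) if i != ax][0]
        az_area = (ext[other] * um) * (p.slab_thickness * um)
    if mem.cytoplasm_side < 0:
        term_len, hc_len = mem.position, ext[ax] - mem.position
    else:
        term_len, hc_len = ext[ax] - mem.position, mem.position
    cross = np.prod([ext[i] * um for i in range(2) if i != ax]) if ax != 2 \
        else (lx * um) * (ly * um)
    if ax == 2:
        slab_frac = 1.0
        term_vol = cross * term_len * um
        hc_vol = cross * hc_len * um
    else:
        other = [i for i in (0, 1) if i != ax][0]
        term_vol = (term_len * um) * (ext[other] * um) * (p.slab_thickness * um)
        hc_vol = (hc_len * um) * (ext[other] * um) * (p.slab_thickness * um)

    truth = GroundTruth(vesicles=vesicles, membranes=[mem] + ([hc] if hc else []),
                        gold_positions_nm=gold_pos, ribbon_box_nm=ribbon_box,
                        true_active_zone_area_um2=az_area,
                        true_terminal_volume_um3=term_vol,
                        true_hc_volume_um3=hc_vol, params=p)
    return volume, truth


def place_fiducials(volume: DensityVolume, n: int, seed: int = 0,
                    gold_diameter: float = 10.0, min_dist_nm: float = 60.0,
                    margin_nm: float = 24.0):
    """Deposit ``n`` gold fiducials on the slab surfaces of ``volume``.

    Gold is rendered at the maximal density level so it is separable from
    any biological structure.  Returns ``(new_volume, positions_nm)``;
    requires n >= 3 (fewer markers leave the alignment underdetermined).
    """
    if n < 3:
        raise ValueError("at least 3 fiducials are required for alignment")
    rng = np.random.default_rng(seed)
    vox = volume.voxel_size
    lx, ly, _ = volume.extent_nm
    z0, z1 = volume.slab
    # clamp the spacing so the requested count stays feasible in small fields
    avail = min(lx, ly) - 2 * margin_nm
    min_dist_nm = min(min_dist_nm, 0.8 * avail / max(np.sqrt(n), 1.0))
    # prefer beads over sparse regions: usable fiducials are the ones not
    # superposed on dense structure in projection
    proj = ndimage.gaussian_filter(
        volume.data.sum(axis=0, dtype=np.float64), 2.0 * gold_diameter / vox)
    clear_level = np.quantile(proj, 0.50)
    out = volume.copy()
    pts: list[np.ndarray] = []
    for k in range(n):
        for attempt in range(1500):
            z = z0 if k % 2 == 0 else z1
            q = np.array([rng.uniform(margin_nm, lx - margin_nm),
                          rng.uniform(margin_nm, ly - margin_nm), z])
            if any(np.linalg.norm(q[:2] - r[:2]) < min_dist_nm for r in pts):
                continue
            iy, ix = int(q[1] / vox), int(q[0] / vox)
            if attempt < 1200 and proj[iy, ix] > clear_level:
                continue  # over dense structure; keep sampling
            pts.append(q)
            break
        else:
            raise PackingError("could not place gold fiducials")
    for q in pts:
        _render_sphere(out.data, q, gold_diameter / 2, vox, DENSITY["gold"])
    return out, np.array(pts)


def add_noise(volume: DensityVolume, snr: float, seed: int = 0,
              reference_level: float = DENSITY["membrane"]) -> DensityVolume:
    """Additive white Gaussian noise at a given SNR.

    SNR is defined against the membrane density level (the structural
    signal): sigma = reference_level / snr.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = np.random.default_rng(seed)
    out = volume.copy()
    out.data = out.data + (reference_level / snr) * rng.standard_normal(
        out.data.shape).astype(np.float32)
    return out
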