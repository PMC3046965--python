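"""Vesicle morphometry: fusion-state bookkeeping, the partial-vesicle
counting rule, and the distance / angle / density / equivalent-sphere
arithmetic used to budget vesicle fusion across adaptation conditions.

Units follow the field's conventions: vesicle diameters in nm, distances
and linear measures in µm, areas in µm², volumes in µm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FUSION_STATES = ("cytoplasmic", "tethered", "docked", "omega", "coated")

#: Condition labels in canonical report order (light first, then time in dark).
CONDITION_ORDER = ("light", "dark 3-5 min", "dark 15 min", "dark 30 min",
                   "dark 60 min", "dark 180 min")


@dataclass(frozen=True)
class Point3D:
    """A point in µm; the unit of all center-to-center measurements."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise ValueError("Point3D coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def count_weight(fraction_inside: float) -> float:
    """Counting weight of a vesicle partially inside the reconstructed slab.

    More than 2/3 of the diameter inside counts as a whole vesicle, one half
    to 2/3 counts as half, less than one half is not counted.  Both interval
    boundaries are closed upward: exactly 2/3 counts 1, exactly 1/2 counts
    0.5.
    """
    if not 0.0 <= fraction_inside <= 1.0:
        raise ValueError(f"fraction_inside must be in [0, 1], got {fraction_inside}")
    if fraction_inside >= 2.0 / 3.0:
        return 1.0
    if fraction_inside >= 0.5:
        return 0.5
    return 0.0


@dataclass
class VesicleRecord:
    """One vesicle: the unit of all morphometry."""

    center: Point3D              # µm
    diameter: float              # nm
    state: str = "cytoplasmic"
    fraction_inside: float = 1.0
    count_weight: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.state not in FUSION_STATES:
            raise ValueError(f"unknown fusion state {self.state!r}")
        if self.count_weight is None:
            self.count_weight = count_weight(self.fraction_inside)


def fraction_inside_slab(center_z_um: float, diameter_nm: float,
                         slab_nm: tuple[float, float]) -> float:
    """Fraction of a vesicle's diameter lying within the slab z range."""
    r = diameter_nm / 2.0
    cz = center_z_um * 1000.0
    lo, hi = cz - r, cz + r
    overlap = max(0.0, min(hi, slab_nm[1]) - max(lo, slab_nm[0]))
    return min(1.0, overlap / diameter_nm)


def weighted_count(records: Iterable[VesicleRecord | float]) -> float:
    """Weighted vesicle count under the 2/3 - 1/2 partial-volume rule.

    Accepts VesicleRecords or raw ``fraction_inside`` values.
    """
    total = 0.0
    for rec in records:
        f = rec.fraction_inside if isinstance(rec, VesicleRecord) else float(rec)
        total += count_weight(f)
    return total


def point_distance(p0: Point3D, p1: Point3D) -> float:
    """Euclidean center-to-center distance in µm."""
    return float(np.linalg.norm(p0.as_array() - p1.as_array()))


def triplet_angle(p0: Point3D, p1: Point3D, p2: Point3D) -> float:
    """Angle (degrees, in [0, 180]) at vertex ``p1`` formed by three
    consecutive vesicle centers."""
    v1 = p0.as_array() - p1.as_array()
    v2 = p2.as_array() - p1.as_array()
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("triplet_angle requires p0 != p1 and p2 != p1")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def density_from_spacing(d_um: float) -> float:
    """Vesicles per µm³ of cytoplasm implied by a center-to-center spacing.

    Uses the simple-cubic packing model 1/d³, which reproduces both ends of
    the 110-120 nm spacing band (≈750 and ≈580 vesicles/µm³).  The packing
    model is an assumption; do not reuse it where a measured density exists.
    """
    if d_um <= 0:
        raise ValueError("spacing must be > 0")
    return 1.0 / d_um**3


def vesicles_per_spherule(density_per_um3: float, terminal_volume_um3: float,
                          populated_fraction: float = 0.75) -> float:
    """Total vesicle budget of a terminal: density × populated cytoplasm.

    ``populated_fraction`` is the fraction of the terminal volume that is
    vesicle-populated cytoplasm (the remainder being mitochondrion, ribbon
    and invaginating processes).
    """
    if not 0 < populated_fraction <= 1:
        raise ValueError("populated_fraction must be in (0, 1]")
    return density_per_um3 * terminal_volume_um3 * populated_fraction


def equivalent_sphere(perimeter_um: float) -> tuple[float, float, float]:
    """(radius, surface area, volume) of the sphere whose great circle has
    the given freehand-traced perimeter: r = P/2π, A = 4πr², V = 4πr³/3."""
    if perimeter_um <= 0:
        raise ValueError("perimeter must be > 0")
    r = perimeter_um / (2.0 * math.pi)
    return r, 4.0 * math.pi * r**2, 4.0 / 3.0 * math.pi * r**3


def surface_area_slab(membrane_length_per_slice_um: Sequence[float],
                      slice_thickness_um: float) -> float:
    """Membrane area from per-slice traced lengths × slice thickness."""
    lengths = np.asarray(list(membrane_length_per_slice_um), dtype=float)
    if lengths.size and lengths.min() < 0:
        raise ValueError("membrane lengths must be >= 0")
    if slice_thickness_um <= 0:
        raise ValueError("slice thickness must be > 0")
    return float(lengths.sum() * slice_thickness_um)


def vesicle_volume_um3(diameter_nm: float) -> float:
    if diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    r_um = diameter_nm / 2000.0
    return 4.0 / 3.0 * math.pi * r_um**3


def vesicles_for_volume(delta_volume_um3: float, diameter_nm: float) -> float:
    """Number of vesicles whose lumen volume accounts for a cytoplasmic
    volume change."""
    if delta_volume_um3 < 0:
        raise ValueError("delta_volume must be >= 0")
    return delta_volume_um3 / vesicle_volume_um3(diameter_nm)


def vesicles_for_area(delta_area_um2: float, diameter_nm: float) -> float:
    """Number of vesicles whose delivered membrane (πd² per fusion) accounts
    for a plasma-membrane area change."""
    if delta_area_um2 < 0:
        raise ValueError("delta_area must be >= 0")
    if diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    d_um = diameter_nm / 1000.0
    return delta_area_um2 / (math.pi * d_um**2)


def percent_of_baseline(value: float, baseline: float) -> float:
    """value as a percentage of baseline (100 × value / baseline)."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return 100.0 * value / baseline


@dataclass
class FusionThresholds:
    """Geometric and density thresholds for fusion-state assignment.

    Densities are in the package's fixed arbitrary units (membrane = 1).
    ``contact_tol_nm`` is the slack allowed on |center-to-membrane| - r for
    a vesicle to count as membrane-contacting; ``pore_density_max`` is the
    maximum density along the lumen-to-extracellular ray for an open pore
    (omega); ``coat_density_min`` is the minimum mean shell density in the
    coat band; ``tether_distance_nm`` bounds the ribbon-tethered pool.
    """

    contact_tol_nm: float = 14.0
    pore_density_max: float = 0.45
    coat_density_min: float = 0.28
    coat_band_nm: tuple[float, float] = (5.0, 11.0)
    tether_distance_nm: float = 60.0
    presmooth_nm: float = 2.0


def classify_fusion_state(center_nm, volume, membrane, diameter_nm: float = 40.0,
                          layer_spacing_nm: float = 6.0,
                          ribbon_box_nm=None,
                          thresholds: FusionThresholds | None = None) -> str:
    """Assign a fusion state to a vesicle found at ``center_nm``.

    Decision rules mirror the morphological definitions: a vesicle whose
    contact zone with the plasma membrane retains dense material is docked
    (hemi-fused, single shared leaflet blocks the lumen); one whose lumen
    opens through the membrane to the extracellular space along the
    membrane normal is an omega figure; an extra dense shell outside the
    vesicle membrane marks a coated vesicle; otherwise the vesicle is
    tethered if near the ribbon, else cytoplasmic.

    ``volume`` is a DensityVolume (tomogram or phantom), ``membrane`` a
    MembranePlane.  The density is lightly pre-smoothed before sampling so
    the tests are robust to tomogram noise.
    """
    import numpy as _np
    from scipy import ndimage as _ndi
    from .membranes import MembranePlane  # noqa: F401  (type of `membrane`)

    th = thresholds or FusionThresholds()
    c = _np.asarray(center_nm, dtype=float)
    vox = volume.voxel_size
    data = volume.data
    sigma = th.presmooth_nm / vox
    key = "_fusion_smoothed"
    cache = getattr(volume, key, None)
    if cache is None or cache[0] != sigma:
        cache = (sigma, _ndi.gaussian_filter(data.astype(_np.float32), sigma))
        setattr(volume, key, cache)
    sm = cache[1]

    def sample(points_nm):
        p = _np.atleast_2d(points_nm) / vox
        return _ndi.map_coordinates(sm, [p[:, 2], p[:, 1], p[:, 0]], order=1)

    ax = membrane.axis_index
    r = diameter_nm / 2.0
    dist = membrane.position - c[ax]         # signed, toward + axis
    to_mem = _np.sign(dist) if dist != 0 else 1.0

    if abs(dist) <= r + layer_spacing_nm + th.contact_tol_nm:
        # membrane contact: docked vs omega by the pore test, sampling the
        # density across the membrane plane on the vesicle's axis
        s2 = layer_spacing_nm
        coords = _np.linspace(membrane.position - s2,
                              membrane.position + s2, 9)
        ray = _np.tile(c, (9, 1))
        ray[:, ax] = coords
        if sample(ray).max() < th.pore_density_max:
            return "omega"
        return "docked"

    # coat test: mean density on a shell band outside the vesicle membrane
    rng = _np.random.default_rng(0)
    dirs = rng.standard_normal((64, 3))
    dirs /= _np.linalg.norm(dirs, axis=1, keepdims=True)
    away = dirs[dirs[:, ax] * to_mem < 0.5]   # avoid the membrane side
    radii = _np.linspace(r + th.coat_band_nm[0], r + th.coat_band_nm[1], 4)
    pts = (c[None, None] + radii[:, None, None] * away[None]).reshape(-1, 3)
    lo = _np.zeros(3)
    hi = (_np.array(data.shape[::-1]) - 1) * vox
    inside = _np.all((pts >= lo) & (pts <= hi), axis=1)
    if inside.any() and sample(pts[inside]).mean() > th.coat_density_min:
        return "coated"

    if ribbon_box_nm is not None:
        (x0, x1), (y0, y1), (z0, z1) = ribbon_box_nm
        gap = _np.array([max(x0 - c[0], 0, c[0] - x1),
                         max(y0 - c[1], 0, c[1] - y1),
                         max(z0 - c[2], 0, c[2] - z1)])
        if _np.linalg.norm(gap) <= th.tether_distance_nm + r:
            return "tethered"
    return "cytoplasmic"


def count_fusion_states(centers_nm, volume, membrane, slab_nm=None,
                        diameter_nm: float = 40.0,
                        layer_spacing_nm: float = 6.0,
                        ribbon_box_nm=None,
                        thresholds: FusionThresholds | None = None) -> dict:
    """Classify every detected vesicle center and apply the counting rule.

    Returns weighted counts per fusion state plus the per-vesicle records.
    ``slab_nm`` defaults to the volume's slab metadata; the counting
    weight of each vesicle follows the 2/3 - 1/2 rule on the fraction of
    its diameter inside the slab.
    """
    slab = slab_nm if slab_nm is not None else volume.slab
    records = []
    for c in np.atleast_2d(np.asarray(centers_nm, dtype=float)):
        state = classify_fusion_state(c, volume, membrane, diameter_nm,
                                      layer_spacing_nm, ribbon_box_nm,
                                      thresholds)
        frac = fraction_inside_slab(c[2] / 1000.0, diameter_nm, slab)
        records.append(VesicleRecord(
            center=Point3D(*(c / 1000.0)), diameter=diameter_nm, state=state,
            fraction_inside=frac))
    counts = {s: 0.0 for s in FUSION_STATES}
    for r in records:
        counts[r.state] += r.count_weight
    counts["records"] = records
    return counts


@dataclass
class SpheruleMorphometry:
    """Per-terminal summary in the schema of the adaptation table."""

    condition: str
    terminal_volume_um3: float = 0.0
    hc_volume_um3: float = 0.0
    hc_area_um2: float = 0.0
    omega_count: float = 0.0
    docked_count: float = 0.0
    coated_count: float = 0.0
    active_zone_area_um2: float = 0.0

    def __post_init__(self):
        for name in ("terminal_volume_um3", "hc_volume_um3", "hc_area_um2",
                     "omega_count", "docked_count", "coated_count",
                     "active_zone_area_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Column order mirroring the adaptation summary table.
SUMMARY_FIELDS = ("terminal_volume_um3", "hc_volume_um3", "hc_area_um2",
                  "omega_count")


def summarize_conditions(per_terminal: Iterable[SpheruleMorphometry],
                         fields: Sequence[str] = SUMMARY_FIELDS) -> pd.DataFrame:
    """Per-condition mean ± sample SD and n for each morphometric field.

    Returns a DataFrame indexed by condition (canonical order first, unknown
    labels after, in order of appearance) with columns
    ``<field>_mean, <field>_sd`` and ``n``.  A single measurement reports
    SD = 0.
    """
    records = list(per_terminal)
    if not records:
        raise ValueError("no records to summarize")
    df = pd.DataFrame([{**{"condition": r.condition},
                        **{f: getattr(r, f) for f in fields}} for r in records])
    order = [c for c in CONDITION_ORDER if c in set(df["condition"])]
    order += [c for c in df["condition"].unique() if c not in order]
    rows = []
    for cond in order:
        sub = df[df["condition"] == cond]
        row: dict[str, float | str] = {"condition": cond, "n": len(sub)}
        for f in fields:
            row[f"{f}_mean"] = float(sub[f].mean())
            row[f"{f}_sd"] = float(sub[f].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows).set_index("condition")
    return out[["n"] + [f"{f}_{s}" for f in fields for s in ("mean", "sd")]]
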