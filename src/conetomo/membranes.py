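"""Triple-layered membrane model.

Membranes are rendered as two parallel Gaussian dense layers (the osmium-
stained leaflets) flanking an electron-lucent core.  The "layer-center
spacing" -- the distance between the centers of the two dense layers -- is
the quantity used throughout as the resolution proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AXES = {"x": 0, "y": 1, "z": 2}


def layer_sigma(layer_spacing: float, voxel_size: float) -> float:
    """Gaussian width of one dense layer; floored to stay resolvable on the
    sampling grid."""
    return max(layer_spacing / 4.0, 0.55 * voxel_size)


@dataclass
class MembranePlane:
    """A planar membrane: midplane normal to one axis at ``position`` (nm).

    ``cytoplasm_side`` is the sign of (coordinate - position) on the
    cytoplasmic side; the extracellular space lies on the opposite side.
    """

    axis: str = "x"
    position: float = 0.0          # nm along the normal axis
    layer_spacing: float = 6.0     # nm between dense-layer centers
    amplitude: float = 1.0
    cytoplasm_side: int = -1

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {tuple(AXES)}")
        if self.layer_spacing <= 0:
            raise ValueError("layer_spacing must be > 0")
        if self.cytoplasm_side not in (-1, 1):
            raise ValueError("cytoplasm_side must be -1 or +1")

    @property
    def axis_index(self) -> int:
        return AXES[self.axis]

    def signed_distance(self, coords_axis_nm: np.ndarray) -> np.ndarray:
        """Signed distance to the midplane (positive on the + axis side)."""
        return np.asarray(coords_axis_nm) - self.position

    def profile(self, d_nm: np.ndarray, voxel_size: float) -> np.ndarray:
        """Bilayer density profile as a function of signed midplane distance."""
        s = self.layer_spacing / 2.0
        sig = layer_sigma(self.layer_spacing, voxel_size)
        d = np.asarray(d_nm, dtype=np.float32)
        return self.amplitude * (
            np.exp(-((d - s) ** 2) / (2 * sig**2))
            + np.exp(-((d + s) ** 2) / (2 * sig**2))
        ).astype(np.float32)


def smooth_step(x: np.ndarray, edge: float) -> np.ndarray:
    """0..1 ramp over ``edge`` nm; 1 where x >= edge."""
    return np.clip(x / max(edge, 1e-9), 0.0, 1.0)
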