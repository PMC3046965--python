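"""The 3D density map container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DensityVolume:
    """A 3D scalar density map with physical metadata.

    ``data`` is indexed ``[z, y, x]`` (the usual image-stack order); all
    physical coordinates elsewhere in the package are (x, y, z) in nm with
    0-based, voxel-centered indexing.  ``slab`` marks the z range (nm) of the
    physical section inside the array, used by the partial-vesicle counting
    rule; it defaults to the full z extent.
    """

    data: np.ndarray
    voxel_size: float  # nm / voxel
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "phantom"  # phantom | wbp | refined
    slab: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("DensityVolume.data must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DensityVolume.data must be finite")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.slab is None:
            self.slab = (0.0, self.data.shape[0] * self.voxel_size)

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.shape_xyz
        return (nx * self.voxel_size, ny * self.voxel_size, nz * self.voxel_size)

    def copy(self) -> "DensityVolume":
        return DensityVolume(
            self.data.copy(), self.voxel_size, self.origin, self.provenance, self.slab
        )
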