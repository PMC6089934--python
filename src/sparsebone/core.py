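"""Shared containers for volumes and masks.

Axis order is (z, y, x) throughout the package; slice-wise TIFF pages map to
the leading axis.  Voxels are isotropic and sized in micrometres.  Attenuation
values are stored in mm^-1 so that line integrals through desk-scale volumes
are of order one (a requirement for realistic Poisson transmission noise).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    """A 3-D (or single-slice 2-D) scalar grid with isotropic voxel size.

    Parameters
    ----------
    data:
        Array of shape (nz, ny, nx) or (ny, nx), attenuation in mm^-1
        (or any scalar field: thickness maps, filtered images, ...).
    voxel_size_um:
        Isotropic voxel edge length in micrometres.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"volume must be 2-D or 3-D, got ndim={self.data.ndim}")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.voxel_size_um)
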