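"""LAC volume container and TIFF I/O.

A tomographic volume stores the per-voxel linear absorption coefficient
(LAC, 1/um) on a regular grid with a physical voxel edge in nm (13 nm for
the imaging conditions this package targets), in z, y, x axis order, with
an optional integer region mask (e.g. heterochromatin / euchromatin /
nucleolus labels).  Volumes and masks are read and written as (multipage)
TIFF stacks via tifffile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["LACVolume", "read_volume", "write_volume"]

VOXEL_NM_DEFAULT = 13.0


@dataclass
class LACVolume:
    """3D LAC grid (z, y, x) with voxel edge in nm and optional mask."""

    data: np.ndarray
    voxel_nm: float = VOXEL_NM_DEFAULT
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("LAC volume must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("LAC values must be finite")
        if self.voxel_nm <= 0:
            raise ValueError("voxel edge must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match the volume")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_nm3(self) -> float:
        return self.voxel_nm**3

    def region_values(self, label: int) -> np.ndarray:
        if self.mask is None:
            raise ValueError("volume has no region mask")
        return self.data[self.mask == label]

    def crop_z_window(self, z_extent_nm: float) -> "LACVolume":
        """Restrict the mask to a central z window (depth-of-field crop)."""
        if self.mask is None:
            raise ValueError("z-window filtering requires a mask")
        nz = self.data.shape[0]
        half = int(round(z_extent_nm / self.voxel_nm / 2))
        zc = nz // 2
        keep = np.zeros(nz, dtype=bool)
        keep[max(0, zc - half): min(nz, zc + half + 1)] = True
        new_mask = self.mask.copy()
        new_mask[~keep] = 0
        return LACVolume(self.data, self.voxel_nm, new_mask)


def read_volume(path: str | Path, voxel_nm: float = VOXEL_NM_DEFAULT,
                mask_path: str | Path | None = None) -> LACVolume:
    data = tifffile.imread(str(path))
    mask = tifffile.imread(str(mask_path)) if mask_path is not None else None
    return LACVolume(np.asarray(data, dtype=float), voxel_nm, mask)


def write_volume(vol: LACVolume, path: str | Path,
                 mask_path: str | Path | None = None) -> None:
    tifffile.imwrite(str(path), vol.data.astype(np.float32))
    if mask_path is not None and vol.mask is not None:
        tifffile.imwrite(str(mask_path), vol.mask.astype(np.int16))
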