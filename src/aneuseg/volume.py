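"""3D volume carrier with physical spacing/origin and NIfTI-1 I/O.

All arrays are indexed ``(i, j, k)`` with 0-based voxel indices; the world
position of voxel ``(i, j, k)`` is ``origin_mm + index * spacing_mm``
(axis-aligned grids only — oblique acquisitions are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "read_nifti", "write_nifti"]


@dataclass
class Volume3D:
    """A 3D scalar grid with physical voxel spacing and origin.

    Parameters
    ----------
    values
        3D array of voxel values. Binary masks use dtype ``uint8`` or
        ``bool``; intensity images use floats.
    spacing_mm
        Per-axis voxel size in millimetres, strictly positive.
    origin_mm
        World position of voxel ``(0, 0, 0)`` in millimetres.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive floats, got {self.spacing_mm}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("values contain non-finite entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        """True when ``other`` shares shape, spacing and origin with self."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def require_same_grid(self, other: "Volume3D", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"{what} are not on a common grid: "
                f"{self.shape}@{self.spacing_mm} vs {other.shape}@{other.spacing_mm}"
            )

    def with_values(self, values: np.ndarray) -> "Volume3D":
        """New volume on the same grid carrying ``values``."""
        return Volume3D(values, self.spacing_mm, self.origin_mm)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


def write_nifti(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz) with a diagonal affine."""
    path = Path(path)
    data = vol.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine())
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> Volume3D:
    """Load a NIfTI file into a :class:`Volume3D` (axis-aligned affines only)."""
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    values = np.asanyarray(img.dataobj)
    return Volume3D(np.ascontiguousarray(values), spacing, origin)
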