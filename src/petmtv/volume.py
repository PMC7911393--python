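"""Core spatial containers: SUV volumes and observer lesion boxes.

A PET volume is stored as a plain 3-D array of body-weight-normalised
standardised uptake values (SUV, unitless) on a regular grid with known
voxel spacing.  Axis order is (x, y, z), 0-based; boxes are half-open
voxel index ranges, low inclusive, high exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["SUVVolume", "LesionBox", "read_nifti", "write_nifti"]


@dataclass
class SUVVolume:
    """A 3-D grid of SUV values with voxel geometry.

    Parameters
    ----------
    values
        3-D float array of SUV, all finite and >= 0.
    spacing
        Voxel spacing (dx, dy, dz) in mm, all > 0.
    origin
        World coordinate of the voxel (0, 0, 0) centre, in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (5.3, 5.3, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"SUV volume must be 3-D, got {self.values.ndim}-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class LesionBox:
    """Axis-aligned half-open voxel box: ``low`` inclusive, ``high`` exclusive."""

    low: tuple[int, int, int]
    high: tuple[int, int, int]
    lesion_id: int = -1
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "low", tuple(int(i) for i in self.low))
        object.__setattr__(self, "high", tuple(int(i) for i in self.high))
        if len(self.low) != 3 or len(self.high) != 3:
            raise ValueError("box corners must be 3-D voxel indices")
        if any(l >= h for l, h in zip(self.low, self.high)):
            raise ValueError(f"degenerate box: low {self.low} must be < high {self.high}")
        if any(l < 0 for l in self.low):
            raise ValueError(f"box extends below the grid: low {self.low}")

    def validate_within(self, shape: tuple[int, int, int]) -> None:
        if any(h > s for h, s in zip(self.high, shape)):
            raise ValueError(f"box high {self.high} exceeds grid shape {shape}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.low, self.high))  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.low, self.high)]))

    def union(self, other: "LesionBox") -> "LesionBox":
        return LesionBox(
            low=tuple(min(a, b) for a, b in zip(self.low, other.low)),
            high=tuple(max(a, b) for a, b in zip(self.high, other.high)),
            lesion_id=min(self.lesion_id, other.lesion_id),
        )

    def contains_point(self, idx: tuple[int, int, int]) -> bool:
        return all(l <= i < h for i, l, h in zip(idx, self.low, self.high))


def write_nifti(volume: SUVVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with the spacing in the header."""
    path = Path(path)
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> SUVVolume:
    """Read a NIfTI-1 volume back into an :class:`SUVVolume`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"malformed NIfTI file {path}: expected 3-D, got {data.ndim}-D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return SUVVolume(values=np.clip(data, 0.0, None), spacing=zooms, origin=origin)
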