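"""Core in-memory containers for volumetric data.

A :class:`VolumeGrid` is a 3D scalar field on a regular axis-aligned grid with
voxel spacing in millimetres and a value semantic (``counts/s``, ``HU``, ``Gy``).
A :class:`StructureSet` holds the aligned binary masks used throughout the
pipeline: tumor, perfused lobe and whole liver, with the normal structures
derived by subtraction (NPL = perfused lobe minus tumor, WNL = whole liver
minus tumor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "StructureSet", "DoseMap", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two volumes/masks that must share a grid do not."""


@dataclass
class VolumeGrid:
    """A 3D scalar field with geometry metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.
    spacing_mm : tuple of float
        Voxel edge lengths along each axis, in mm.
    origin_mm : tuple of float
        World coordinate of the first voxel centre, in mm.
    unit : str
        Value semantic: ``"counts/s"``, ``"HU"``, ``"Gy"`` or ``""``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def require_same_grid(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch with {what}: shapes {self.shape} vs {other.shape}, "
                f"spacing {self.spacing_mm} vs {other.spacing_mm}"
            )

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "VolumeGrid":
        """A copy of this grid carrying new voxel values."""
        return VolumeGrid(
            values=np.asarray(values),
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
            unit=self.unit if unit is None else unit,
        )


def _as_bool_mask(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask {name!r} is not binary (values {uniq[:5]}...)")
        arr = arr.astype(bool)
    return arr


@dataclass
class StructureSet:
    """Aligned binary masks for one case.

    ``npl`` (normal perfused liver) and ``wnl`` (whole normal liver) are
    derived on construction by subtracting the tumor from the perfused lobe
    and the whole liver respectively; the tumor must be contained in the
    perfused lobe, and the perfused lobe in the whole liver.
    """

    tumor: np.ndarray
    perfused_lobe: np.ndarray
    whole_liver: np.ndarray
    npl: np.ndarray = field(init=False)
    wnl: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.tumor = _as_bool_mask(self.tumor, "tumor")
        self.perfused_lobe = _as_bool_mask(self.perfused_lobe, "perfused_lobe")
        self.whole_liver = _as_bool_mask(self.whole_liver, "whole_liver")
        if not (self.tumor.shape == self.perfused_lobe.shape == self.whole_liver.shape):
            raise GridMismatchError(
                "structure masks disagree in shape: "
                f"tumor {self.tumor.shape}, perfused lobe {self.perfused_lobe.shape}, "
                f"whole liver {self.whole_liver.shape}"
            )
        if np.any(self.tumor & ~self.perfused_lobe):
            raise ValueError("tumor mask extends outside the perfused lobe")
        if np.any(self.perfused_lobe & ~self.whole_liver):
            raise ValueError("perfused lobe extends outside the whole liver")
        self.npl = self.perfused_lobe & ~self.tumor
        self.wnl = self.whole_liver & ~self.tumor

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tumor.shape  # type: ignore[return-value]

    def mask(self, structure: str) -> np.ndarray:
        """Mask lookup by canonical structure name (tumor, npl, wnl, ...)."""
        try:
            return {
                "tumor": self.tumor,
                "npl": self.npl,
                "wnl": self.wnl,
                "perfused_lobe": self.perfused_lobe,
                "whole_liver": self.whole_liver,
            }[structure.lower()]
        except KeyError:
            raise KeyError(f"unknown structure {structure!r}") from None


@dataclass
class DoseMap:
    """A dose distribution: a Gy-valued :class:`VolumeGrid` tagged by its
    source channel (``MAA`` pre-therapy surrogate or ``Y90`` post-therapy)
    and dose kind (physical ``Dose`` or biologically effective ``BED``)."""

    grid: VolumeGrid
    nuclide_channel: str  # "MAA" | "Y90"
    dose_kind: str = "Dose"  # "Dose" | "BED"

    def __post_init__(self) -> None:
        if self.nuclide_channel not in ("MAA", "Y90"):
            raise ValueError(f"unknown nuclide channel {self.nuclide_channel!r}")
        if self.dose_kind not in ("Dose", "BED"):
            raise ValueError(f"unknown dose kind {self.dose_kind!r}")
        vals = self.grid.values
        if not np.all(np.isfinite(vals)):
            raise ValueError("dose map contains non-finite voxels")
        if np.any(vals < 0):
            raise ValueError("dose map contains negative voxels")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values
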