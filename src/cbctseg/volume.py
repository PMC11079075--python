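"""Core grid containers shared by every stage of the pipeline.

A :class:`Volume` is a 3-D scalar grid with physical voxel spacing in mm;
a :class:`LabelVolume` is an integer mask on the same grid.  Arrays are
indexed ``(z, y, x)`` — slowest to fastest axis, the convention SimpleITK
uses when converting an image to a NumPy array.

Label semantics used throughout the package:

====== ==========================================
label  structure
====== ==========================================
0      background / soft tissue
1      maxillary bone
2      mandibular bone
3      maxillary sinus
4      mandibular canal
11–48  individual teeth, FDI two-digit notation
====== ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Volume",
    "LabelVolume",
    "CbctError",
    "GridMismatchError",
    "STRUCTURE_NAMES",
    "FDI_TOOTH_CODES",
]

#: Structural (non-tooth) class names, keyed by label.
STRUCTURE_NAMES = {
    1: "maxillary bone",
    2: "mandibular bone",
    3: "maxillary sinus",
    4: "mandibular canal",
}

#: All 32 permanent-tooth FDI codes (quadrant digit 1-4, position digit 1-8).
FDI_TOOTH_CODES = tuple(10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9))


class CbctError(Exception):
    """Base class for all errors raised by this package."""


class GridMismatchError(CbctError):
    """Two volumes that must share a grid (shape + spacing) do not."""


def _as_triple(value) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(value))
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {value!r}")
    return t  # type: ignore[return-value]


@dataclass
class Volume:
    """3-D scalar image with physical geometry.

    Parameters
    ----------
    values
        3-D array, indexed ``(z, y, x)``.
    spacing
        Voxel spacing in mm per axis, same ``(z, y, x)`` order.
    origin
        Physical coordinate (mm) of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise CbctError(f"volume must be 3-D, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise CbctError("volume is empty")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise CbctError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "Volume":
        """Copy of this volume with new voxel data on the same grid."""
        return replace(self, values=values)

    def same_grid(self, other: "Volume | LabelVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing
        )

    def require_same_grid(self, other: "Volume | LabelVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )


@dataclass
class LabelVolume(Volume):
    """Integer label mask on the :class:`Volume` grid contract."""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise CbctError("label volume contains non-integer values")
            arr = np.round(arr).astype(np.int32)
        self.values = arr
        super().__post_init__()

    @property
    def labels(self) -> np.ndarray:
        return self.values

    def present_labels(self) -> np.ndarray:
        """Sorted array of labels present in the mask."""
        return np.unique(self.values)

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one class."""
        return self.values == label
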