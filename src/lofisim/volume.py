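"""Core in-memory containers for 3-D MR volumes and lesion label maps.

Conventions used throughout the package:

* arrays are indexed ``[x, y, z]`` with the axial (slice) axis last;
* ``spacing_mm`` gives the voxel edge lengths along each axis, in mm;
* volumes are skull-stripped: intensities are exactly 0 outside the
  brain mask, and all statistics are computed over in-mask voxels only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["Volume", "LabelMap", "LF_TARGET_SPACING_MM"]

#: Acquisition grid of the portable 64 mT scanner the degradation model
#: targets: 1.6 x 1.6 mm in-plane, 5 mm slice thickness.
LF_TARGET_SPACING_MM: tuple[float, float, float] = (1.6, 1.6, 5.0)


@dataclass
class Volume:
    """A 3-D scalar intensity grid with voxel spacing and optional brain mask.

    Parameters
    ----------
    data
        3-D float array of intensities in arbitrary normalized units.
    spacing_mm
        Voxel edge lengths ``(sx, sy, sz)`` in millimetres.
    mask
        Optional boolean brain mask aligned with ``data``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite everywhere")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing_mm}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane pixel area (mm^2)."""
        return self.spacing_mm[0] * self.spacing_mm[1]

    @property
    def slice_thickness_mm(self) -> float:
        return self.spacing_mm[2]

    def require_mask(self) -> np.ndarray:
        if self.mask is None:
            raise ValueError("operation requires a brain mask but the volume has none")
        return self.mask

    def with_data(self, data: np.ndarray) -> "Volume":
        """Copy of this volume with new intensities on the same grid."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def copy(self) -> "Volume":
        return Volume(
            self.data.copy(),
            self.spacing_mm,
            None if self.mask is None else self.mask.copy(),
        )


@dataclass
class LabelMap:
    """Integer-labeled lesion segmentation aligned to a :class:`Volume`.

    Label 0 is non-lesion; labels 1..K are lesion sub-labels (e.g. tumor
    sub-compartments).
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"label map must be 3-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("label map must contain integer labels")
            arr = np.round(arr).astype(np.int32)
        self.labels = arr.astype(np.int32)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]

    def lesion_mask(self) -> np.ndarray:
        return self.labels > 0

    def sub_labels(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v > 0]
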