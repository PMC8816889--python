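"""NIfTI readers and writers.

Volumes are stored with a diagonal-up-to-permutation affine; voxel
spacing is taken from the header, and the axial (slice) axis is the one
whose direction is closest to the scanner superior axis.  On read, axes
are reordered so the axial axis is last, matching the package's
``[x, y, z]`` convention.
"""

from __future__ import annotations

import json
from pathlib import Path
import nibabel as nib
import numpy as np

from .volume import LabelMap, Volume

__all__ = ["read_volume", "write_volume", "read_labels", "write_labels", "read_mask"]

_ORTHO_TOL = 1e-3


def _spacing_and_axis_order(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column norms (spacing) and the data-axis order putting the
    most-superior-aligned axis last.  Rejects oblique affines."""
    R = affine[:3, :3]
    # the NIfTI-1 affine is float32 on disk; round to 1e-6 mm to recover
    # the intended spacing exactly
    spacing = np.round(np.linalg.norm(R, axis=0), 6)
    if np.any(spacing <= 0):
        raise ValueError("invalid NIfTI affine: zero-length voxel axis")
    dirs = R / spacing
    off_diag = dirs.T @ dirs - np.eye(3)
    if np.max(np.abs(off_diag)) > _ORTHO_TOL:
        raise ValueError(
            "non-orthogonal (oblique) affine beyond tolerance; resample the image "
            "onto an axis-aligned grid first"
        )
    superior_axis = int(np.argmax(np.abs(dirs[2, :])))
    order = [a for a in range(3) if a != superior_axis] + [superior_axis]
    return spacing, np.array(order)


def read_volume(path, mask_path=None) -> Volume:
    """Load a NIfTI volume (and optional mask) as a :class:`Volume`."""
    img = nib.load(str(path))
    affine = img.affine
    if affine is None:
        raise ValueError(f"{path}: NIfTI header missing affine")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing, order = _spacing_and_axis_order(affine)
    data = np.transpose(data, order)
    spacing = tuple(float(spacing[a]) for a in order)
    mask = None
    if mask_path is not None:
        mvol = nib.load(str(mask_path))
        m = np.asanyarray(mvol.dataobj)
        m = np.transpose(m, order)
        if m.shape != data.shape:
            raise ValueError("mask shape does not match volume shape")
        mask = m > 0
    return Volume(data, spacing, mask)


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_volume(volume: Volume, path, mask_path=None) -> None:
    """Write a volume (and optionally its mask) as NIfTI-1."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine(volume.spacing_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    if mask_path is not None:
        m = volume.require_mask().astype(np.uint8)
        mimg = nib.Nifti1Image(m, _affine(volume.spacing_mm))
        mimg.header.set_zooms(volume.spacing_mm)
        nib.save(mimg, str(mask_path))


def read_labels(path) -> LabelMap:
    """Load an integer label map; non-integer data is rejected."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label map, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer) and not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label map contains non-integer values")
    spacing, order = _spacing_and_axis_order(img.affine)
    data = np.transpose(data, order)
    spacing = tuple(float(spacing[a]) for a in order)
    return LabelMap(np.round(data).astype(np.int32), spacing)


def write_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), _affine(labels.spacing_mm))
    img.header.set_zooms(labels.spacing_mm)
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
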