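"""Slice-level classification datasets: labeling, splits, augmentation.

Volumes are decomposed into axial slices; a slice is labeled "lesion
present" if at least one ground-truth lesion pixel lies on it.  Each
slice carries the covariates used by the sensitivity analyses: lesion
area (lesion pixel count x in-plane pixel area, cm^2) and lesion
contrast (mean lesion minus mean non-lesional intensity, divided by the
non-lesional sd).  Train/test splits are patient-exclusive and seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .volume import LabelMap, Volume

__all__ = [
    "SliceRecord",
    "SplitManifest",
    "extract_slices",
    "split_by_patient",
    "augment_flip",
    "records_to_frame",
]


@dataclass
class SliceRecord:
    """One axial slice: the classifier's sample unit."""

    patient_id: str
    slice_index: int  # axial index, 0-based from the inferior end
    pixels: np.ndarray  # 2-D intensity array
    label: int  # 1 if any lesion pixel on the slice
    lesion_area_cm2: float
    lesion_contrast: float  # (mean lesion - mean non-lesional) / sd non-lesional
    arm: str  # "HF" or "simLF"
    split: Optional[str] = None  # "train" / "test", set by the split step

    def __post_init__(self) -> None:
        if (self.label == 1) != (self.lesion_area_cm2 > 0):
            raise ValueError("label must be 1 exactly when lesion area > 0")


@dataclass(frozen=True)
class SplitManifest:
    """Patient-exclusive train/test assignment."""

    train_patients: tuple[str, ...]
    test_patients: tuple[str, ...]
    seed: int
    ratio: float

    def __post_init__(self) -> None:
        overlap = set(self.train_patients) & set(self.test_patients)
        if overlap:
            raise ValueError(f"patients assigned to both splits: {sorted(overlap)}")

    def split_of(self, patient_id: str) -> str:
        if patient_id in self.train_patients:
            return "train"
        if patient_id in self.test_patients:
            return "test"
        raise KeyError(f"patient {patient_id!r} not in manifest")


def extract_slices(
    volume: Volume,
    labels: Optional[LabelMap],
    patient_id: str,
    arm: str = "HF",
) -> list[SliceRecord]:
    """One record per axial slice intersecting the brain mask.

    ``labels=None`` means a control patient (all slices negative).
    Slices with no in-mask pixel are dropped: they carry no brain signal
    and would distort prevalence.
    """
    mask = volume.require_mask()
    if labels is not None and labels.shape != volume.shape:
        raise ValueError(
            f"label map shape {labels.shape} does not match volume shape {volume.shape}"
        )
    pixel_area_cm2 = volume.pixel_area_mm2 / 100.0
    records = []
    for z in range(volume.shape[2]):
        m = mask[:, :, z]
        if not m.any():
            continue
        plane = volume.data[:, :, z]
        if labels is None:
            les = np.zeros_like(m)
        else:
            les = labels.labels[:, :, z] > 0
        n_lesion = int(les.sum())
        area = n_lesion * pixel_area_cm2
        contrast = 0.0
        if n_lesion > 0:
            non_les = m & ~les
            if non_les.any():
                bg = plane[non_les]
                sd = bg.std()
                if sd > 0:
                    contrast = float((plane[les].mean() - bg.mean()) / sd)
        records.append(
            SliceRecord(
                patient_id=patient_id,
                slice_index=z,
                pixels=plane.copy(),
                label=int(n_lesion > 0),
                lesion_area_cm2=float(area),
                lesion_contrast=contrast,
                arm=arm,
            )
        )
    return records


def split_by_patient(cohort_ids: Sequence[str], ratio: float, seed: int) -> SplitManifest:
    """Seeded patient-exclusive split with target train fraction ``ratio``.

    Train size is ``floor(ratio * N)`` clamped so both sets contain at
    least one patient (achieved ratio within one patient of the target).
    """
    ids = list(cohort_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("cohort_ids contains duplicates")
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(ratio * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = tuple(ids[i] for i in sorted(perm[:n_train]))
    test = tuple(ids[i] for i in sorted(perm[n_train:]))
    return SplitManifest(train_patients=train, test_patients=test, seed=seed, ratio=ratio)


def assign_split(records: Sequence[SliceRecord], manifest: SplitManifest) -> None:
    """Stamp each record with its patient's split (in place)."""
    for r in records:
        r.split = manifest.split_of(r.patient_id)


def augment_flip(records: Sequence[SliceRecord], seed: int) -> Iterator[SliceRecord]:
    """On-the-fly training augmentation: each slice is flipped left-right
    with probability 0.5 per pass.  Labels and covariates are unchanged.

    Raises if any record belongs to the test split (leakage guard).
    """
    for r in records:
        if r.split == "test":
            raise ValueError("augmentation must never touch test records")
    rng = np.random.default_rng(seed)
    for r in records:
        if rng.random() < 0.5:
            yield SliceRecord(
                patient_id=r.patient_id,
                slice_index=r.slice_index,
                pixels=r.pixels[:, ::-1].copy(),
                label=r.label,
                lesion_area_cm2=r.lesion_area_cm2,
                lesion_contrast=r.lesion_contrast,
                arm=r.arm,
                split=r.split,
            )
        else:
            yield r


def records_to_frame(records: Sequence[SliceRecord]) -> pd.DataFrame:
    """Tabular index of a dataset (without pixel data)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "slice_index": [r.slice_index for r in records],
            "label": [r.label for r in records],
            "area_cm2": [r.lesion_area_cm2 for r in records],
            "contrast": [r.lesion_contrast for r in records],
            "arm": [r.arm for r in records],
            "split": [r.split for r in records],
        }
    )
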