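"""Lesion-contrast modulation and homogeneity-based cohort selection.

Lesion conspicuity is manipulated by scaling lesion intensities toward
isointensity with surrounding tissue.  Per axial slice and lesion
sub-label, voxel intensities are multiplied by the factor that moves the
sub-label's mean linearly toward the slice's non-lesional in-mask mean
``m``::

    target_mean = m + (scale/100) * (mean_sub - m)
    v' = v * target_mean / mean_sub

so scale 100 is the identity and scale 0 makes the mean intensity of
every lesion sub-label exactly equal to the mean non-lesional intensity
of the same slice (isointense).  Multiplicative scaling preserves
relative within-lesion heterogeneity, so isointense lesions retain
residual texture and structural alterations (mass effect) — the signal
that keeps them partially detectable.

Within-lesion SNR (mean / sd of lesion voxels) measures lesion
homogeneity and drives the top-fraction cohort selection used for the
contrast-sensitivity experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .volume import LabelMap, Volume

__all__ = [
    "ContrastLevel",
    "CONTRAST_LADDER",
    "modulate_contrast",
    "within_lesion_snr",
    "select_homogeneous",
]

#: The standard contrast ladder: 100% (original) down to 0% (isointense).
CONTRAST_LADDER: tuple[int, ...] = (100, 80, 60, 40, 20, 0)


@dataclass(frozen=True)
class ContrastLevel:
    """Relative lesion intensity: 100 = original contrast, 0 = isointense.

    ``per_label`` optionally overrides the scale for individual
    sub-labels, letting tumor sub-compartments be modulated separately.
    """

    scale_percent: float = 100.0
    per_label: Optional[dict[int, float]] = None

    def __post_init__(self) -> None:
        scales = [self.scale_percent] + list((self.per_label or {}).values())
        for s in scales:
            if not 0 <= s <= 100:
                raise ValueError(f"contrast scale must be in [0, 100], got {s}")

    def scale_for(self, sub_label: int) -> float:
        if self.per_label and sub_label in self.per_label:
            return float(self.per_label[sub_label])
        return float(self.scale_percent)


def modulate_contrast(volume: Volume, labels: LabelMap, level: ContrastLevel) -> Volume:
    """Scale lesion intensities toward per-slice isointensity.

    Non-lesion voxels are untouched (bit-identical at every scale); at
    scale 100 the whole volume is returned unchanged.  A slice containing
    lesion but no non-lesional in-mask tissue is skipped with a warning.
    """
    mask = volume.require_mask()
    if labels.shape != volume.shape:
        raise ValueError(f"label map shape {labels.shape} does not match volume {volume.shape}")
    out = volume.data.copy()
    lesion = labels.lesion_mask()
    for z in range(volume.shape[2]):
        les_z = lesion[:, :, z]
        if not les_z.any():
            continue
        non_lesional = mask[:, :, z] & ~les_z
        if not non_lesional.any():
            warnings.warn(f"slice {z}: lesion present but no non-lesional in-mask tissue; skipped")
            continue
        m_slice = volume.data[:, :, z][non_lesional].mean()
        for sub in labels.sub_labels():
            region = labels.labels[:, :, z] == sub
            if not region.any():
                continue
            s = level.scale_for(sub) / 100.0
            if s == 1.0:
                continue
            plane = out[:, :, z]
            mean_sub = plane[region].mean()
            target_mean = m_slice + s * (mean_sub - m_slice)
            if abs(mean_sub) > 1e-12 * max(1.0, abs(m_slice)):
                plane[region] *= target_mean / mean_sub
            else:
                # degenerate near-zero sub-label mean: shift instead of scale
                plane[region] += target_mean - mean_sub
    return volume.with_data(out)


def within_lesion_snr(volume: Volume, labels: LabelMap) -> float:
    """Within-lesion signal-to-noise ratio: mean / population sd of lesion
    voxels.  Higher values indicate more homogeneous lesions; a perfectly
    uniform lesion returns +inf."""
    lesion = labels.lesion_mask()
    vals = volume.data[lesion]
    if vals.size < 2:
        raise ValueError("within-lesion SNR requires at least 2 lesion voxels")
    sd = vals.std()
    if sd == 0:
        return float("inf")
    return float(vals.mean() / sd)


def select_homogeneous(
    cohort: Sequence[tuple[Volume, LabelMap]],
    fraction: float,
    patient_ids: Optional[Sequence[str]] = None,
) -> list[int]:
    """Indices of the top-``fraction`` most homogeneous patients.

    Patients are ranked by within-lesion SNR, descending; the top
    ``ceil(fraction * N)`` are retained.  Ties are broken by cohort order
    (stable sort), which corresponds to patient-ID order when the cohort
    is ID-sorted.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    snrs = np.array([within_lesion_snr(v, l) for v, l in cohort])
    order = np.argsort(-snrs, kind="stable")
    n_keep = int(np.ceil(fraction * len(cohort)))
    kept = sorted(order[:n_keep].tolist())
    return kept
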