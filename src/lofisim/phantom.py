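"""Seeded synthetic brain phantoms with controllable lesions.

The generator produces skull-stripped FLAIR-like volumes at desk scale:
an ellipsoidal "brain" with white-matter / gray-matter / CSF-like
compartments, hyperintense lesions of controllable in-plane area (cm^2),
z-extent, contrast and multi-label substructure, optional radial
mass-effect deformation, and seeded Gaussian acquisition noise inside the
brain mask.  Together with the degradation transform this supplies paired
high-field / low-field cohorts for every downstream experiment.

Intensities are normalized so the within-brain mean is ~1 before noise,
making lesion contrast multipliers and histogram-moment matching
scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .transform import apply_lf_transform, reslice, TransformParams
from .volume import LF_TARGET_SPACING_MM, LabelMap, Volume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "generate_phantom",
    "add_acquisition_noise",
    "generate_paired_lf_target",
]


@dataclass(frozen=True)
class LesionSpec:
    """One lesion: a superellipsoid spanning several adjacent slices.

    ``area_cm2`` is the in-plane area at the lesion's widest (central)
    slice; the generator selects exactly the pixel count matching the
    requested area there (to within one pixel).  Away from the center the
    cross-section tapers like a 3-D lesion cap (``taper_gamma`` controls
    how fast; 0 disables tapering and extrudes a constant cross-section).
    ``contrast`` maps each sub-label (1..n_sublabels) to a mean-intensity
    multiplier applied to the underlying tissue; values > 1 make the
    lesion hyperintense, 1.0 is isointense-by-construction.
    """

    center: tuple[float, float, float]  # voxel coordinates (x, y, z-center)
    area_cm2: float
    z_extent_slices: int = 3
    contrast: float | Sequence[float] = 1.8
    n_sublabels: int = 1
    squareness: float = 2.0  # superellipse exponent; 2 = ellipse
    aspect: float = 1.0  # in-plane axis ratio rx/ry
    taper_gamma: float = 1.0  # cap-shape exponent of the area falloff

    def contrast_per_sublabel(self) -> list[float]:
        if np.isscalar(self.contrast):
            return [float(self.contrast)] * self.n_sublabels
        c = [float(v) for v in self.contrast]  # type: ignore[union-attr]
        if len(c) != self.n_sublabels:
            raise ValueError("contrast list length must equal n_sublabels")
        return c


@dataclass
class PhantomSpec:
    """Full description of one synthetic patient volume."""

    grid_shape: tuple[int, int, int] = (96, 96, 20)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 4.0)
    tissue_means: dict = field(
        default_factory=lambda: {"wm": 1.0, "gm": 1.25, "csf": 0.35}
    )
    lesions: list[LesionSpec] = field(default_factory=list)
    deform_amplitude_mm: float = 0.0
    noise_sd: float = 0.02  # ~SNR 50 relative to unit brain mean, typical 3 T FLAIR
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 voxels per axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        pixel_area_cm2 = self.spacing_mm[0] * self.spacing_mm[1] / 100.0
        for i, les in enumerate(self.lesions):
            if les.area_cm2 < pixel_area_cm2:
                raise ValueError(
                    f"lesion {i}: requested area {les.area_cm2} cm^2 is below one "
                    f"in-plane pixel area ({pixel_area_cm2} cm^2)"
                )
            if les.z_extent_slices < 1:
                raise ValueError(f"lesion {i}: z_extent_slices must be >= 1")


def _brain_geometry(shape, spacing):
    """Ellipsoidal brain mask plus normalized radial coordinate."""
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    # semi-axes leave a small margin so the brain does not touch the edges
    ax, ay, az = 0.42 * nx, 0.44 * ny, 0.47 * nz
    r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return r2 <= 1.0, np.sqrt(r2)


def _tissue_image(shape, spacing, tissue_means, rng):
    """Piecewise tissue intensities: CSF-like ventricles deep inside,
    WM bulk, GM-like cortical band near the brain surface, plus smooth
    low-frequency intensity texture so gradients are non-trivial."""
    mask, r = _brain_geometry(shape, spacing)
    wm = float(tissue_means.get("wm", 1.0))
    gm = float(tissue_means.get("gm", 1.25))
    csf = float(tissue_means.get("csf", 0.35))

    img = np.zeros(shape, dtype=np.float64)
    img[mask] = wm
    img[mask & (r >= 0.82)] = gm  # cortical ribbon

    # two ventricle-like CSF lobes near the center
    nx, ny, nz = shape
    xv, yv, zv = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    for side in (-1, 1):
        cx = (nx - 1) / 2 + side * 0.10 * nx
        cy = (ny - 1) / 2
        cz = (nz - 1) / 2
        d2 = (
            ((xv - cx) / (0.06 * nx)) ** 2
            + ((yv - cy) / (0.22 * ny)) ** 2
            + ((zv - cz) / (0.30 * nz)) ** 2
        )
        img[(d2 <= 1.0) & mask] = csf

    # smooth random texture (~6% modulation) for realistic gradient content
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    t_sd = texture.std()
    if t_sd > 0:
        img[mask] *= 1.0 + 0.06 * texture[mask] / t_sd
    return img, mask


def _radial_deformation(shape, spacing, center, amplitude_mm, rho_mm=25.0):
    """Backward map for an outward radial mass-effect displacement.

    Tissue at sample position x is pulled from x - u(x) where
    u(x) = A * exp(-(|x-c|/rho)^2) * unit(x - c), in mm, converted to
    voxel units per axis.
    """
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    d_mm = [(g - c) * s for g, c, s in zip(grids, center, spacing)]
    r = np.sqrt(sum(d * d for d in d_mm))
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = amplitude_mm * np.exp(-((r / rho_mm) ** 2)) / np.maximum(r, 1e-9)
    coords = [g - scale * d / s for g, d, s in zip(grids, d_mm, spacing)]
    return np.stack(coords)


def _place_lesion(les: LesionSpec, shape, spacing, mask):
    """Rasterize one lesion into sub-label values.

    Returns an int array (0 outside the lesion, sub-label 1..K inside).
    The in-plane footprint is chosen as exactly the n pixels with the
    smallest superellipse distance, where n = round(area / pixel_area),
    so the achieved area is within one pixel area of the request.
    """
    pixel_area_mm2 = spacing[0] * spacing[1]
    n_pixels = int(round(les.area_cm2 * 100.0 / pixel_area_mm2))
    n_pixels = max(n_pixels, 1)

    cx, cy, cz = les.center
    nx, ny, nz = shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    # physical in-plane superellipse distance (mm), anisotropy-aware
    dx = (x - cx) * spacing[0]
    dy = (y - cy) * spacing[1] * les.aspect
    p = les.squareness
    dist = (np.abs(dx) ** p + np.abs(dy) ** p) ** (1.0 / p)
    flat = dist.ravel()
    order = np.argsort(flat, kind="stable")

    z0 = int(round(cz - (les.z_extent_slices - 1) / 2))
    z_slices = [z0 + k for k in range(les.z_extent_slices)]
    if min(z_slices) < 0 or max(z_slices) >= nz:
        raise ValueError(f"lesion at {les.center} extends outside the volume in z")

    lesion = np.zeros(shape, dtype=np.int32)
    z_half = (les.z_extent_slices - 1) / 2 + 0.5
    z_mid = (z_slices[0] + z_slices[-1]) / 2
    for z in z_slices:
        if les.taper_gamma > 0 and les.z_extent_slices > 1:
            # superellipsoid cap: cross-section area falls off toward the ends
            frac = max(0.0, 1.0 - ((z - z_mid) / z_half) ** 2) ** les.taper_gamma
        else:
            frac = 1.0
        n_z = max(1, int(round(n_pixels * frac)))
        chosen_z = order[:n_z]
        foot_z = np.zeros(nx * ny, dtype=bool)
        foot_z[chosen_z] = True
        foot_z = foot_z.reshape(nx, ny)
        # concentric sub-label shells by distance quantile within this slice
        d_in = dist[foot_z]
        if les.n_sublabels > 1 and d_in.size >= les.n_sublabels:
            qs = np.quantile(d_in, np.linspace(0, 1, les.n_sublabels + 1)[1:-1])
            sub = 1 + np.searchsorted(qs, dist, side="right")
        else:
            sub = np.ones_like(dist, dtype=np.int64)
        lesion[:, :, z] = np.where(foot_z, sub, 0).astype(np.int32)

    outside = (lesion > 0) & ~mask
    if outside.any():
        raise ValueError(
            f"lesion at center {les.center} falls outside the brain mask "
            f"({int(outside.sum())} voxels)"
        )
    return lesion


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap, np.ndarray]:
    """Generate one phantom patient.

    Returns ``(volume, label_map, brain_mask)``.  The volume is
    skull-stripped (exactly 0 outside the mask), lesions are hyperintense
    by their contrast multipliers, the label map is nonzero exactly where
    lesions were placed, and output is bit-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    img, mask = _tissue_image(spec.grid_shape, spec.spacing_mm, spec.tissue_means, rng)

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    lesion_fields = []
    for les in spec.lesions:
        lf = _place_lesion(les, spec.grid_shape, spec.spacing_mm, mask)
        lesion_fields.append((les, lf))

    # mass effect: deform the tissue (not the mask) around each lesion centroid
    if spec.deform_amplitude_mm > 0 and lesion_fields:
        for les, lf in lesion_fields:
            coords = _radial_deformation(
                spec.grid_shape, spec.spacing_mm, les.center, spec.deform_amplitude_mm
            )
            img = ndimage.map_coordinates(img, coords, order=1, mode="nearest")

    # paint lesions after deformation so their area stays exact; the
    # contrast multiplier raises each sub-label's mean intensity while the
    # underlying tissue texture keeps its native amplitude (FLAIR lesions
    # are homogeneously bright, not texture-amplified)
    for les, lf in lesion_fields:
        contrasts = les.contrast_per_sublabel()
        for sub in range(1, les.n_sublabels + 1):
            region = lf == sub
            mu = img[region].mean()
            img[region] = img[region] + (contrasts[sub - 1] - 1.0) * mu
        overlap = (labels > 0) & (lf > 0)
        if overlap.any():
            raise ValueError("lesions overlap; adjust lesion centers")
        labels[lf > 0] = lf[lf > 0]

    # normalize within-brain mean to ~1, then add masked acquisition noise
    m = img[mask].mean()
    img[mask] /= m
    img[~mask] = 0.0
    vol = Volume(img, spec.spacing_mm, mask)
    if spec.noise_sd > 0:
        vol = add_acquisition_noise(vol, spec.noise_sd, int(rng.integers(0, 2**31 - 1)))
    return vol, LabelMap(labels, spec.spacing_mm), mask


def add_acquisition_noise(volume: Volume, sd: float, seed: int) -> Volume:
    """Add zero-mean Gaussian acquisition noise inside the brain mask.

    Exposed separately so experiments that alter the clean tissue image
    first (e.g. contrast modulation) can simulate acquisition afterwards,
    keeping lesion and background noise statistics identical.
    """
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    mask = volume.require_mask()
    if sd == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    out = volume.data.copy()
    out[mask] += sd * rng.standard_normal(int(mask.sum()))
    return volume.with_data(out)


def generate_paired_lf_target(
    volume: Volume,
    true_params: TransformParams,
    seed: int,
    target_spacing_mm=LF_TARGET_SPACING_MM,
) -> Volume:
    """Produce a ground-truth low-field target for parameter-recovery tests.

    Reslices the (high-field) phantom onto the LF grid and applies the
    degradation cascade with known parameters, standing in for a real
    paired 64 mT acquisition.
    """
    volume.require_mask()
    lf_grid = reslice(volume, target_spacing_mm)
    return apply_lf_transform(lf_grid, true_params, seed)
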