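"""High-field to low-field domain transformation.

The degradation cascade converts a skull-stripped high-field (HF, ~3 T)
FLAIR volume into a simulated low-field (LF, 64 mT) volume in two stages:

1. re-slicing onto the LF acquisition grid (1.6 x 1.6 x 5 mm by default);
2. a four-parameter smoothing/noise cascade::

       out = G_blur( v + a1 * G_0.5(eps1) ) + a2 * G_s2(eps2)

   where ``eps1, eps2`` are independent unit-variance Gaussian white-noise
   fields, ``G_0.5`` is a fixed 3-D Gaussian smoother with a 0.5-voxel
   standard deviation, ``G_blur`` is the main 3-D Gaussian blur with a
   parameterized standard deviation (mm) and ``G_s2`` the second noise
   filter's parameterized smoother (mm).

The four free parameters (``noise1_amplitude``, ``blur_sigma_mm``,
``noise2_amplitude``, ``noise2_sigma_mm``) are calibrated on paired
HF / LF volumes by matching the first three in-mask histogram moments
(mean, standard deviation, skewness) of the simulated images to the real
LF targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from .volume import LF_TARGET_SPACING_MM, LabelMap, Volume

__all__ = [
    "TransformParams",
    "HistogramMoments",
    "FitConfig",
    "FitResult",
    "reslice",
    "reslice_labels",
    "apply_lf_transform",
    "histogram_moments",
    "fit_transform_params",
]

#: Standard deviation (in voxels of the LF grid) of the fixed pre-smoothing
#: applied to the first noise field before it is scaled and added.
NOISE1_PRESMOOTH_SIGMA_VOX = 0.5


@dataclass(frozen=True)
class TransformParams:
    """The four fitted degradation parameters of the HF->LF transform.

    All parameters are non-negative.  Sigmas are physical (mm) and are
    converted to per-axis voxel units using the volume's spacing.
    """

    noise1_amplitude: float
    blur_sigma_mm: float
    noise2_amplitude: float
    noise2_sigma_mm: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.noise1_amplitude, self.blur_sigma_mm, self.noise2_amplitude, self.noise2_sigma_mm]
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "TransformParams":
        a = [max(0.0, float(v)) for v in arr]
        return cls(*a)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TransformParams":
        return cls(
            noise1_amplitude=d["noise1_amplitude"],
            blur_sigma_mm=d["blur_sigma_mm"],
            noise2_amplitude=d["noise2_amplitude"],
            noise2_sigma_mm=d["noise2_sigma_mm"],
        )


@dataclass(frozen=True)
class HistogramMoments:
    """First three statistical moments of the in-mask intensity histogram."""

    mean: float
    sd: float
    skewness: float
    degenerate: bool = False  # True when sd == 0 (skewness reported as 0)

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.sd, self.skewness])


def _centered_coords(n_out: int, spacing_out: float, n_in: int, spacing_in: float) -> np.ndarray:
    """Voxel-center sample coordinates of the output grid in input voxel units.

    Both grids share the same physical extent origin; the center of output
    voxel ``i`` sits at physical position ``(i + 0.5) * spacing_out``.
    """
    pos = (np.arange(n_out) + 0.5) * spacing_out
    return pos / spacing_in - 0.5


def _output_shape(shape: Sequence[int], spacing: Sequence[float], target: Sequence[float]) -> tuple:
    return tuple(
        int(np.ceil(n * s / t)) for n, s, t in zip(shape, spacing, target)
    )


def reslice(volume: Volume, target_spacing_mm: Sequence[float] = LF_TARGET_SPACING_MM) -> Volume:
    """Resample a volume onto a grid with the given voxel spacing.

    The output grid covers the same physical extent (``ceil(extent /
    target)`` voxels per axis).  Intensities and the brain mask are
    interpolated tri-linearly; the mask is re-binarized at 0.5.  When the
    target spacing equals the input spacing the volume is returned
    unchanged (same grid).
    """
    target = tuple(float(t) for t in target_spacing_mm)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be three positive lengths, got {target}")
    if target == volume.spacing_mm:
        return volume.copy()

    out_shape = _output_shape(volume.shape, volume.spacing_mm, target)
    coords = np.meshgrid(
        *[
            _centered_coords(no, t, ni, s)
            for no, t, ni, s in zip(out_shape, target, volume.shape, volume.spacing_mm)
        ],
        indexing="ij",
    )
    coords = np.stack(coords)
    data = ndimage.map_coordinates(volume.data, coords, order=1, mode="nearest")
    mask = None
    if volume.mask is not None:
        m = ndimage.map_coordinates(volume.mask.astype(np.float64), coords, order=1, mode="nearest")
        mask = m >= 0.5
        data = np.where(mask, data, 0.0)
    return Volume(data, target, mask)


def reslice_labels(labels: LabelMap, target_spacing_mm: Sequence[float] = LF_TARGET_SPACING_MM) -> LabelMap:
    """Nearest-neighbor reslicing for integer label maps."""
    target = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")
    if target == labels.spacing_mm:
        return LabelMap(labels.labels.copy(), target)
    out_shape = _output_shape(labels.shape, labels.spacing_mm, target)
    coords = np.meshgrid(
        *[
            _centered_coords(no, t, ni, s)
            for no, t, ni, s in zip(out_shape, target, labels.shape, labels.spacing_mm)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(labels.labels, np.stack(coords), order=0, mode="nearest")
    return LabelMap(out.astype(np.int32), target)


def _sigma_vox(sigma_mm: float, spacing: Sequence[float]) -> tuple[float, ...]:
    return tuple(sigma_mm / s for s in spacing)


def _smoothed_noise(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    eps = rng.standard_normal(shape)
    if np.any(np.asarray(sigma_vox) > 0):
        return ndimage.gaussian_filter(eps, sigma=sigma_vox)
    return eps


def apply_lf_transform(volume: Volume, params: TransformParams, seed: int) -> Volume:
    """Apply the four-parameter smoothing/noise cascade to an LF-grid volume.

    The volume must be skull-stripped (mask required); noise is added
    within the brain mask only so the background stays exactly 0.
    """
    mask = volume.require_mask()
    rng = np.random.default_rng(seed)
    shape = volume.shape
    spacing = volume.spacing_mm

    n1 = _smoothed_noise(rng, shape, (NOISE1_PRESMOOTH_SIGMA_VOX,) * 3)
    n2_raw = rng.standard_normal(shape)
    return _cascade(volume, params, n1, n2_raw)


def _cascade(volume: Volume, params: TransformParams, n1: np.ndarray, n2_raw: np.ndarray) -> Volume:
    """Deterministic core of the transform given pre-drawn noise fields.

    ``n1`` is already pre-smoothed at the fixed 0.5-voxel sigma; ``n2_raw``
    is white and is smoothed here at the parameterized sigma.  Factoring
    this out lets the fitting objective reuse noise realizations across
    parameter evaluations (common random numbers).
    """
    mask = volume.require_mask()
    spacing = volume.spacing_mm
    img = volume.data + params.noise1_amplitude * np.where(mask, n1, 0.0)
    blur_vox = _sigma_vox(params.blur_sigma_mm, spacing)
    if any(s > 0 for s in blur_vox):
        img = ndimage.gaussian_filter(img, sigma=blur_vox)
    s2_vox = _sigma_vox(params.noise2_sigma_mm, spacing)
    if any(s > 0 for s in s2_vox):
        n2 = ndimage.gaussian_filter(n2_raw, sigma=s2_vox)
    else:
        n2 = n2_raw
    img = img + params.noise2_amplitude * np.where(mask, n2, 0.0)
    img = np.where(mask, img, 0.0)  # skull-stripped output: background exactly 0
    return Volume(img, spacing, mask.copy())


def histogram_moments(volume: Volume) -> HistogramMoments:
    """Mean, population standard deviation, and skewness of in-mask voxels.

    Skewness is the standardized third central moment
    ``E[(x - mu)^3] / sd^3``; for a constant (sd = 0) distribution it is
    reported as 0 with the ``degenerate`` flag set.
    """
    mask = volume.require_mask()
    vals = volume.data[mask]
    if vals.size < 2:
        raise ValueError("histogram moments require at least 2 in-mask voxels")
    mean = float(vals.mean())
    sd = float(vals.std())  # population sd
    if sd == 0.0:
        return HistogramMoments(mean, 0.0, 0.0, degenerate=True)
    skew = float(((vals - mean) ** 3).mean() / sd**3)
    return HistogramMoments(mean, sd, skew)


@dataclass
class FitConfig:
    """Settings for the moment-matching parameter fit.

    ``bounds`` are per-parameter (low, high) boxes in the order
    (noise1_amplitude, blur_sigma_mm, noise2_amplitude, noise2_sigma_mm).
    The objective averages moments over ``n_realizations`` fixed noise
    realizations per evaluation to tame stochasticity; realizations are
    derived from ``seed`` and shared across parameter evaluations.
    """

    bounds: tuple = ((0.0, 1.0), (0.0, 6.0), (0.0, 1.0), (0.0, 6.0))
    seed: int = 0
    n_starts: int = 4
    n_realizations: int = 5
    maxiter: int = 150
    xatol: float = 1e-3
    fatol: float = 1e-6
    #: "per_image": compare moments after dividing every image (target and
    #: simulated alike) by its own in-mask mean, removing arbitrary scanner
    #: scaling; "none": intensities are assumed to share a scale already and
    #: raw moments are compared (appropriate for synthetic pairs).
    normalization: str = "per_image"


@dataclass
class FitResult:
    params: TransformParams
    objective: float
    objective_trace: list[float]
    moment_differences: list[tuple[float, float, float]]
    improved: bool  # False if the optimizer never beat the initial point
    seed: int

    @property
    def warning(self) -> Optional[str]:
        return None if self.improved else "optimizer failed to improve on the initial point"


def _normalize_unit_mean(volume: Volume) -> Volume:
    mask = volume.require_mask()
    m = volume.data[mask].mean()
    if m == 0:
        raise ValueError("cannot normalize a volume with zero in-mask mean")
    out = volume.with_data(volume.data / m)
    return out


def _standardized_moment_sq_diff(sim: HistogramMoments, tgt: HistogramMoments) -> float:
    """Squared moment differences; mean and sd differences are standardized
    by the target sd (making them commensurate and scale-free), skewness is
    already dimensionless."""
    if tgt.sd == 0:
        raise ValueError("target volume has zero in-mask sd; moments cannot be standardized")
    d_mean = (sim.mean - tgt.mean) / tgt.sd
    d_sd = (sim.sd - tgt.sd) / tgt.sd
    d_skew = sim.skewness - tgt.skewness
    return d_mean**2 + d_sd**2 + d_skew**2


def _pair_moment_diffs(sim: HistogramMoments, tgt: HistogramMoments) -> tuple[float, float, float]:
    return (
        abs(sim.mean - tgt.mean) / tgt.sd,
        abs(sim.sd - tgt.sd) / tgt.sd,
        abs(sim.skewness - tgt.skewness),
    )


def fit_transform_params(
    pairs: Sequence[tuple[Volume, Volume]],
    fit_config: Optional[FitConfig] = None,
) -> FitResult:
    """Calibrate the degradation parameters on paired (HF, LF-target) volumes.

    Minimizes the mean over pairs of the squared standardized differences
    of the three in-mask histogram moments between the transformed HF
    volume and the LF target, using a bounded Nelder-Mead simplex from a
    small seeded multi-start.  Each HF volume must already be on the LF
    grid (call :func:`reslice` first).

    Returns a :class:`FitResult`; if no optimizer start improved on its
    initial point the result carries a warning flag rather than failing
    silently.
    """
    cfg = fit_config or FitConfig()
    if len(pairs) == 0:
        raise ValueError("at least one (hf, lf_target) pair is required")
    if cfg.normalization not in ("per_image", "none"):
        raise ValueError(f"unknown normalization mode {cfg.normalization!r}")
    per_image = cfg.normalization == "per_image"
    prepared: list[tuple[Volume, HistogramMoments]] = []
    for hf, lf in pairs:
        if hf.shape != lf.shape:
            raise ValueError(
                f"hf and lf_target must share the LF grid, got {hf.shape} vs {lf.shape}"
            )
        hf.require_mask()
        lf.require_mask()
        if per_image:
            hf = _normalize_unit_mean(hf)
            lf = _normalize_unit_mean(lf)
        prepared.append((hf, histogram_moments(lf)))

    # Fixed noise realizations shared across all objective evaluations
    # (common random numbers -> deterministic, smooth objective).
    rng = np.random.default_rng(cfg.seed)
    realizations = []
    for hf, _ in prepared:
        fields = []
        for _ in range(cfg.n_realizations):
            n1 = _smoothed_noise(rng, hf.shape, (NOISE1_PRESMOOTH_SIGMA_VOX,) * 3)
            n2_raw = rng.standard_normal(hf.shape)
            fields.append((n1, n2_raw))
        realizations.append(fields)

    trace: list[float] = []
    best_so_far = [np.inf]

    def _sim_moments(hf: Volume, params: TransformParams, fields) -> HistogramMoments:
        moments = np.zeros(3)
        for n1, n2_raw in fields:
            sim = _cascade(hf, params, n1, n2_raw)
            m = histogram_moments(sim).as_array()
            if per_image:
                # same per-image scale freedom the target was given
                m = np.array([1.0, m[1] / m[0], m[2]])
            moments += m
        return HistogramMoments(*(moments / len(fields)))

    def objective(x: np.ndarray) -> float:
        params = TransformParams.from_array(x)
        total = 0.0
        for (hf, tgt_moments), fields in zip(prepared, realizations):
            sim_m = _sim_moments(hf, params, fields)
            total += _standardized_moment_sq_diff(sim_m, tgt_moments)
        val = total / len(prepared)
        if val < best_so_far[0]:
            best_so_far[0] = val
            trace.append(val)
        return val

    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    start_rng = np.random.default_rng(cfg.seed + 1)
    starts = [lo + (hi - lo) * start_rng.uniform(0.1, 0.9, size=4) for _ in range(cfg.n_starts)]

    best = None
    initial_vals = []
    for x0 in starts:
        initial_vals.append(objective(x0))
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=cfg.bounds,
            options={
                "maxiter": cfg.maxiter,
                "xatol": cfg.xatol,
                "fatol": cfg.fatol,
            },
        )
        if best is None or res.fun < best.fun:
            best = res

    assert best is not None
    improved = best.fun < min(initial_vals) - 1e-15
    if not improved:
        warnings.warn("transform fit failed to improve beyond its initial point", stacklevel=2)
    params = TransformParams.from_array(best.x)

    # Final per-pair moment differences at the optimum (realization-averaged).
    diffs = []
    for (hf, tgt_moments), fields in zip(prepared, realizations):
        diffs.append(_pair_moment_diffs(_sim_moments(hf, params, fields), tgt_moments))

    return FitResult(
        params=params,
        objective=float(best.fun),
        objective_trace=trace,
        moment_differences=diffs,
        improved=improved,
        seed=cfg.seed,
    )
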