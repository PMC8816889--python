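"""End-to-end simulated-trial orchestration.

Ties the stages together: phantom cohort -> (optional transform fit) ->
HF->LF simulation -> (optional contrast modulation) -> slice datasets ->
two-arm classifier training -> statistical evaluation.  The same
functions back the command-line interface and the reproducibility
script.

Randomness discipline: every experiment takes one top-level seed and
derives per-stage integer seeds from it through a single
``numpy.random.default_rng`` stream, so a run is fully reproducible from
its config.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contrast import ContrastLevel, CONTRAST_LADDER, modulate_contrast, select_homogeneous
from .dataset import (
    SliceRecord,
    SplitManifest,
    assign_split,
    augment_flip,
    extract_slices,
    records_to_frame,
    split_by_patient,
)
from .detect import ClassifierSpec, predict_scores, train
from .evaluate import (
    EvalReport,
    choose_patient_threshold,
    delong_test,
    f1_score,
    null_model_f1,
    patient_classify,
    roc_auc,
    sensitivity_ratio_curve,
    sensitivity_regression,
    youden_threshold,
)
from .phantom import LesionSpec, PhantomSpec, add_acquisition_noise, generate_phantom
from .quality import volume_gradient_entropy
from .transform import (
    FitConfig,
    TransformParams,
    apply_lf_transform,
    fit_transform_params,
    reslice,
    reslice_labels,
)
from .volume import LF_TARGET_SPACING_MM, LabelMap, Volume

log = logging.getLogger("lofisim")

__all__ = [
    "DEFAULT_TRUE_PARAMS",
    "CohortConfig",
    "make_cohort_specs",
    "build_arm_records",
    "TrialResult",
    "run_two_arm_trial",
    "run_contrast_ladder",
    "run_parameter_recovery",
    "run_patient_level_study",
    "quality_comparison",
]

#: Canonical degradation parameters used when no fitted parameters are
#: supplied: blur somewhat above the LF in-plane pixel, plus pre- and
#: post-blur noise whose pooled standard deviation (~0.13 on a unit-mean
#: brain) puts the simulated images at SNR ~ 8, the regime of portable
#: 64 mT FLAIR.
DEFAULT_TRUE_PARAMS = TransformParams(
    noise1_amplitude=0.4, blur_sigma_mm=2.5, noise2_amplitude=0.25, noise2_sigma_mm=1.0
)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclass
class CohortConfig:
    """Study conditions for one phantom cohort.

    Lesion in-plane areas are drawn log-uniformly over ``area_range_cm2``
    (spanning subtle to prominent pathology), contrast multipliers
    uniformly over ``contrast_range`` (hyperintense FLAIR lesions), and
    lesion z-extent uniformly over ``z_extent_range`` slices.  HF
    phantoms use 1 x 1 mm in-plane resolution at the 5 mm slice
    thickness shared with the LF grid, so the two arms sample the same
    axial positions.
    """

    n_lesional: int = 42
    n_control: int = 18
    grid_shape: tuple[int, int, int] = (96, 96, 20)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 5.0)
    area_range_cm2: tuple[float, float] = (1.5, 20.0)
    #: fraction of lesional patients with prominent (tumor-like) lesions,
    #: drawn uniformly above ``prominent_min_cm2``; the rest are subtle
    #: (MS/stroke-like), log-uniform below it.  The default mix mirrors a
    #: pooled cohort dominated by glioma-scale pathology.
    prominent_fraction: float = 0.7
    prominent_min_cm2: float = 5.0
    contrast_range: tuple[float, float] = (1.5, 2.0)
    z_extent_range: tuple[int, int] = (3, 6)
    n_sublabels: int = 3
    deform_amplitude_mm: float = 0.0
    noise_sd: float = 0.02


def _lesion_spec_for(cfg: CohortConfig, rng: np.random.Generator) -> LesionSpec:
    lo, hi = cfg.area_range_cm2
    split = min(max(cfg.prominent_min_cm2, lo), hi)
    if rng.random() < cfg.prominent_fraction:
        area = float(rng.uniform(split, hi))
    else:
        area = float(np.exp(rng.uniform(np.log(lo), np.log(split))))
    contrast = float(rng.uniform(*cfg.contrast_range))
    z_extent = int(rng.integers(cfg.z_extent_range[0], cfg.z_extent_range[1] + 1))

    nx, ny, nz = cfg.grid_shape
    sx, sy, _ = cfg.spacing_mm
    r_mm = np.sqrt(area * 100.0 / np.pi)  # equivalent-circle radius
    # brain ellipsoid semi-axes used by the phantom (voxels)
    ax, ay, az = 0.42 * nx, 0.44 * ny, 0.47 * nz
    cz_mid = (nz - 1) / 2
    z_half = (z_extent - 1) / 2
    # keep the lesion's z-extent well inside the brain
    z_lo = int(np.ceil(cz_mid - 0.55 * az + z_half + 1))
    z_hi = int(np.floor(cz_mid + 0.55 * az - z_half - 1))
    cz = float(rng.integers(z_lo, z_hi + 1)) if z_hi > z_lo else cz_mid
    # in-plane shrink of the brain cross-section at the lesion's extreme slices
    z_far = max(abs(cz - z_half - cz_mid), abs(cz + z_half - cz_mid))
    shrink = np.sqrt(max(0.0, 1.0 - (z_far / az) ** 2))
    r_vox = r_mm / min(sx, sy)
    max_off = min(ax, ay) * shrink - r_vox - 3.0
    if max_off < 0:
        raise ValueError(
            f"lesion of {area:.1f} cm^2 does not fit the brain cross-section; "
            "enlarge the grid or shrink area_range_cm2"
        )
    angle = rng.uniform(0, 2 * np.pi)
    dist = rng.uniform(0, max_off)
    cx = (nx - 1) / 2 + dist * np.cos(angle)
    cy = (ny - 1) / 2 + dist * np.sin(angle)
    return LesionSpec(
        center=(float(cx), float(cy), cz),
        area_cm2=area,
        z_extent_slices=z_extent,
        contrast=contrast,
        n_sublabels=cfg.n_sublabels,
    )


def make_cohort_specs(cfg: CohortConfig, seed: int) -> list[tuple[str, PhantomSpec]]:
    """Seeded phantom specs for a lesional + control cohort."""
    rng = np.random.default_rng(seed)
    specs: list[tuple[str, PhantomSpec]] = []
    for i in range(cfg.n_lesional + cfg.n_control):
        lesional = i < cfg.n_lesional
        pid = f"P{i:03d}"
        lesions = [_lesion_spec_for(cfg, rng)] if lesional else []
        specs.append(
            (
                pid,
                PhantomSpec(
                    grid_shape=cfg.grid_shape,
                    spacing_mm=cfg.spacing_mm,
                    lesions=lesions,
                    deform_amplitude_mm=cfg.deform_amplitude_mm if lesional else 0.0,
                    noise_sd=cfg.noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                ),
            )
        )
    return specs


def build_arm_records(
    pid: str,
    volume: Volume,
    labels: Optional[LabelMap],
    params: TransformParams,
    seed: int,
    contrast_level: Optional[ContrastLevel] = None,
) -> tuple[list[SliceRecord], list[SliceRecord]]:
    """HF and simulated-LF slice records for one patient.

    Contrast modulation (when requested) is applied on the HF volume
    before degradation, mirroring the preparation of reduced-contrast
    simulated LF cohorts.
    """
    from .contrast import modulate_contrast

    hf_vol = volume
    if contrast_level is not None and labels is not None:
        hf_vol = modulate_contrast(volume, labels, contrast_level)
    hf_records = extract_slices(hf_vol, labels, pid, arm="HF")
    lf_grid = reslice(hf_vol, LF_TARGET_SPACING_MM)
    lf_vol = apply_lf_transform(lf_grid, params, seed)
    lf_labels = None if labels is None else reslice_labels(labels, LF_TARGET_SPACING_MM)
    lf_records = extract_slices(lf_vol, lf_labels, pid, arm="simLF")
    return hf_records, lf_records


def _train_score_ensemble(
    train_records: list[SliceRecord],
    eval_records: list[SliceRecord],
    spec: ClassifierSpec,
    seeds: Sequence[int],
    train_scores_out: Optional[list[SliceRecord]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Train one classifier per seed (with fresh flip augmentation each)
    and average scores; returns (train_split_scores, eval_scores)."""
    from dataclasses import replace as _replace

    tr_scores = np.zeros(len(train_records))
    ev_scores = np.zeros(len(eval_records))
    for s in seeds:
        augmented = train_records + list(augment_flip(train_records, seed=s))
        model = train(augmented, _replace(spec, seed=int(s)))
        tr_scores += predict_scores(model, train_records)
        ev_scores += predict_scores(model, eval_records)
    tr_scores /= len(seeds)
    ev_scores /= len(seeds)
    return tr_scores, ev_scores


@dataclass
class ArmResult:
    arm: str
    report: EvalReport
    train_threshold: float
    test_frame: pd.DataFrame  # per-slice: label, score, area, contrast, detected


@dataclass
class TrialResult:
    manifest: SplitManifest
    arms: dict  # arm -> ArmResult
    delong: tuple[float, float, float, float]
    ratio_curve: pd.DataFrame
    auc_large: dict  # arm -> AUC restricted to large-lesion positives
    seed: int
    train_records: dict = field(default_factory=dict)  # arm -> training slices


def run_two_arm_trial(
    cohort: CohortConfig,
    params: TransformParams = DEFAULT_TRUE_PARAMS,
    seed: int = 0,
    split_ratio: float = 0.7,
    classifier: Optional[ClassifierSpec] = None,
    n_models: int = 3,
    size_thresholds: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 100.0),
    large_area_cm2: float = 4.0,
) -> TrialResult:
    """The core simulated clinical trial: train and evaluate matched
    classifiers on the HF arm and the simulated-LF arm of one phantom
    cohort, then compare them statistically."""
    spec = classifier or ClassifierSpec()
    seed_cohort, seed_split, seed_noise, seed_models, seed_null = _child_seeds(seed, 5)
    specs = make_cohort_specs(cohort, seed_cohort)
    noise_seeds = _child_seeds(seed_noise, len(specs))

    records = {"HF": [], "simLF": []}
    t0 = time.time()
    for (pid, pspec), nseed in zip(specs, noise_seeds):
        vol, labels, _ = generate_phantom(pspec)
        lab = labels if labels.labels.any() else None
        hf, lf = build_arm_records(pid, vol, lab, params, nseed)
        records["HF"].extend(hf)
        records["simLF"].extend(lf)
    log.info("cohort of %d patients built in %.1fs", len(specs), time.time() - t0)

    manifest = split_by_patient([pid for pid, _ in specs], split_ratio, seed_split)
    model_seeds = _child_seeds(seed_models, n_models)

    arms: dict[str, ArmResult] = {}
    train_records: dict[str, list[SliceRecord]] = {}
    for arm in ("HF", "simLF"):
        recs = records[arm]
        assign_split(recs, manifest)
        tr = [r for r in recs if r.split == "train"]
        te = [r for r in recs if r.split == "test"]
        train_records[arm] = tr
        tr_scores, te_scores = _train_score_ensemble(tr, te, spec, model_seeds)
        thr = youden_threshold([r.label for r in tr], tr_scores)
        labels_te = np.array([r.label for r in te])
        auc, _ = roc_auc(labels_te, te_scores)
        preds = (te_scores >= thr).astype(int)
        f1 = f1_score(labels_te, preds)
        null_mean, null_sd = null_model_f1(labels_te, trials=1000, seed=seed_null)
        frame = records_to_frame(te)
        frame["score"] = te_scores
        frame["detected"] = preds
        pos = frame[frame.label == 1]
        regression = None
        if len(pos) >= 10 and (pos.area_cm2.std() > 0 or pos.contrast.std() > 0):
            regression = sensitivity_regression(
                pos.detected.to_numpy(), pos.area_cm2.to_numpy(), pos.contrast.to_numpy()
            )
        report = EvalReport(
            per_slice=frame,
            auc=auc,
            f1=f1,
            null_f1_mean=null_mean,
            null_f1_sd=null_sd,
            threshold=thr,
            regression=regression,
        )
        arms[arm] = ArmResult(arm=arm, report=report, train_threshold=thr, test_frame=frame)

    # paired DeLong on the shared axial grid (both arms sample identical
    # z-positions by construction of the cohort's 5 mm HF slices)
    hf_f, lf_f = arms["HF"].test_frame, arms["simLF"].test_frame
    merged = hf_f.merge(
        lf_f, on=["patient_id", "slice_index"], suffixes=("_hf", "_lf"), how="inner"
    )
    delong = delong_test(
        merged.label_hf.to_numpy(), merged.score_hf.to_numpy(), merged.score_lf.to_numpy()
    )

    hf_pos = hf_f[hf_f.label == 1]
    lf_pos = lf_f[lf_f.label == 1]
    ratio = sensitivity_ratio_curve(
        hf_pos.detected.to_numpy(),
        hf_pos.area_cm2.to_numpy(),
        lf_pos.detected.to_numpy(),
        lf_pos.area_cm2.to_numpy(),
        size_thresholds,
    )

    auc_large = {}
    for arm, res in arms.items():
        f = res.test_frame
        keep = (f.label == 0) | (f.area_cm2 >= large_area_cm2)
        sub = f[keep]
        auc_large[arm] = roc_auc(sub.label.to_numpy(), sub.score.to_numpy())[0]

    return TrialResult(
        manifest=manifest,
        arms=arms,
        delong=delong,
        ratio_curve=ratio,
        auc_large=auc_large,
        seed=seed,
        train_records=train_records,
    )


def run_contrast_ladder(
    cohort: Optional[CohortConfig] = None,
    params: TransformParams = DEFAULT_TRUE_PARAMS,
    seed: int = 0,
    scales: Sequence[int] = CONTRAST_LADDER,
    homogeneous_fraction: float = 0.5,
    split_ratio: float = 0.7,
    classifier: Optional[ClassifierSpec] = None,
    n_models: int = 3,
) -> pd.DataFrame:
    """Contrast-sensitivity experiment on the simulated-LF arm.

    Lesional phantoms carry mass-effect deformation and multi-label
    lesions; the cohort is restricted to its most homogeneous half
    (within-lesion SNR ranking) before modulation.  For each contrast
    scale a fresh classifier ensemble is trained on simulated LF images
    whose lesions were scaled toward isointensity on the HF volume
    before degradation; the test AUC traces detectability versus
    contrast.
    """
    cfg = cohort or CohortConfig(
        n_lesional=28,
        n_control=14,
        area_range_cm2=(2.0, 6.0),
        prominent_fraction=1.0,
        contrast_range=(1.5, 1.8),
        z_extent_range=(4, 7),
        deform_amplitude_mm=1.5,
    )
    spec = classifier or ClassifierSpec()
    seed_cohort, seed_split, seed_noise, seed_models = _child_seeds(seed, 4)
    specs = make_cohort_specs(cfg, seed_cohort)
    noise_seeds = _child_seeds(seed_noise, len(specs))
    model_seeds = _child_seeds(seed_models, n_models)

    # generate noise-free tissue; acquisition noise is simulated after
    # modulation so an isointense lesion differs from background only
    # through structure, not through an artificially flat texture
    patients = []
    for (pid, pspec), nseed in zip(specs, noise_seeds):
        clean_spec = PhantomSpec(
            grid_shape=pspec.grid_shape,
            spacing_mm=pspec.spacing_mm,
            tissue_means=pspec.tissue_means,
            lesions=pspec.lesions,
            deform_amplitude_mm=pspec.deform_amplitude_mm,
            noise_sd=0.0,
            seed=pspec.seed,
        )
        vol, labels, _ = generate_phantom(clean_spec)
        lab = labels if labels.labels.any() else None
        patients.append((pid, vol, lab, nseed))

    lesional = [(pid, v, l, s) for pid, v, l, s in patients if l is not None]
    controls = [(pid, v, l, s) for pid, v, l, s in patients if l is None]
    kept_idx = select_homogeneous([(v, l) for _, v, l, _ in lesional], homogeneous_fraction)
    kept = [lesional[i] for i in kept_idx] + controls
    kept.sort(key=lambda t: t[0])

    manifest = split_by_patient([pid for pid, *_ in kept], split_ratio, seed_split)
    rows = []
    for scale in scales:
        level = ContrastLevel(scale_percent=float(scale))
        recs = []
        for pid, vol, lab, nseed in kept:
            hf_vol = vol
            if lab is not None:
                hf_vol = modulate_contrast(vol, lab, level)
            hf_vol = add_acquisition_noise(hf_vol, cfg.noise_sd, nseed + 1)
            _, lf = build_arm_records(pid, hf_vol, lab, params, nseed)
            recs.extend(lf)
        assign_split(recs, manifest)
        tr = [r for r in recs if r.split == "train"]
        te = [r for r in recs if r.split == "test"]
        _, te_scores = _train_score_ensemble(tr, te, spec, model_seeds)
        labels_te = np.array([r.label for r in te])
        auc, _ = roc_auc(labels_te, te_scores)
        rows.append({"scale_percent": int(scale), "auc": auc, "n_test_slices": len(te)})
        log.info("contrast ladder scale %d%%: AUC %.3f", scale, auc)
    return pd.DataFrame(rows)


def run_parameter_recovery(
    true_params: TransformParams = DEFAULT_TRUE_PARAMS,
    seed: int = 0,
    n_pairs: int = 3,
    n_fit_seeds: int = 5,
    grid_shape: tuple[int, int, int] = (128, 128, 24),
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 4.0),
    fit_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Calibration self-test: fit the transform on synthetic pairs with
    known generating parameters, across several fitting seeds.

    Returns one row per fitting seed with recovered parameters, relative
    errors, and the largest standardized moment difference.
    """
    seed_phantoms, seed_targets, seed_fits = _child_seeds(seed, 3)
    target_seeds = _child_seeds(seed_targets, n_pairs)
    pairs = []
    for i in range(n_pairs):
        pspec = PhantomSpec(
            grid_shape=grid_shape, spacing_mm=spacing_mm, seed=seed_phantoms + i
        )
        vol, _, _ = generate_phantom(pspec)
        hf = reslice(vol, LF_TARGET_SPACING_MM)
        lf = apply_lf_transform(hf, true_params, target_seeds[i])
        pairs.append((hf, lf))

    fit_seeds = _child_seeds(seed_fits, n_fit_seeds)
    kwargs = dict(normalization="none", n_starts=2, maxiter=120)
    kwargs.update(fit_kwargs or {})
    rows = []
    truth = true_params.as_array()
    for fs in fit_seeds:
        res = fit_transform_params(pairs, FitConfig(seed=fs, **kwargs))
        est = res.params.as_array()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(est - truth) / np.where(truth > 0, truth, np.nan)
        rows.append(
            {
                "fit_seed": fs,
                "noise1_amplitude": est[0],
                "blur_sigma_mm": est[1],
                "noise2_amplitude": est[2],
                "noise2_sigma_mm": est[3],
                "rel_err_noise1": rel[0],
                "rel_err_blur": rel[1],
                "rel_err_noise2": rel[2],
                "rel_err_noise2_sigma": rel[3],
                "objective": res.objective,
                "max_moment_diff": max(max(d) for d in res.moment_differences),
                "improved": res.improved,
            }
        )
    return pd.DataFrame(rows)


def run_patient_level_study(
    train_cohort: Optional[CohortConfig] = None,
    test_cohort: Optional[CohortConfig] = None,
    params: TransformParams = DEFAULT_TRUE_PARAMS,
    seed: int = 1,
    classifier: Optional[ClassifierSpec] = None,
    n_models: int = 3,
    window_mm: float = 15.0,
) -> pd.DataFrame:
    """Patient-level sliding-window classification on a clean held-out
    phantom cohort (half lesional with prominent lesions, half control).

    Mirroring the per-cohort design of the full-scale study (one model
    per pathology cohort), the classifier ensemble is trained on a
    cohort whose composition matches the test cohort; the decision
    threshold maximizes patient-level accuracy over the training
    patients and is then applied unchanged to the fresh test patients.
    """
    prominent = dict(
        area_range_cm2=(8.0, 16.0),
        prominent_fraction=1.0,
        contrast_range=(1.7, 2.0),
        z_extent_range=(4, 7),
    )
    train_cfg = train_cohort or CohortConfig(n_lesional=16, n_control=10, **prominent)
    test_cfg = test_cohort or CohortConfig(n_lesional=6, n_control=6, **prominent)
    spec = classifier or ClassifierSpec()
    seed_train, seed_test, seed_noise, seed_models = _child_seeds(seed + 7919, 4)
    model_seeds = _child_seeds(seed_models, n_models)

    def build(cfg, cohort_seed, tag):
        specs = make_cohort_specs(cfg, cohort_seed)
        noise_seeds = _child_seeds(cohort_seed + 1, len(specs))
        per_arm = {"HF": {}, "simLF": {}}
        truth = {}
        for (pid, pspec), nseed in zip(specs, noise_seeds):
            pid = f"{tag}{pid}"
            vol, labels, _ = generate_phantom(pspec)
            lab = labels if labels.labels.any() else None
            truth[pid] = int(lab is not None)
            hf, lf = build_arm_records(pid, vol, lab, params, nseed)
            per_arm["HF"][pid] = hf
            per_arm["simLF"][pid] = lf
        return per_arm, truth

    train_recs, train_truth = build(train_cfg, seed_train, "TR")
    test_recs, test_truth = build(test_cfg, seed_test, "TE")

    thickness = 5.0  # both arms share the 5 mm axial grid
    rows = []
    for arm in ("HF", "simLF"):
        tr = _flatten(train_recs[arm].values())
        for r in tr:
            r.split = "train"
        eval_records = _flatten(test_recs[arm].values())
        tr_scores, ev_scores = _train_score_ensemble(tr, eval_records, spec, model_seeds)

        tr_frame = records_to_frame(tr)
        tr_frame["score"] = tr_scores
        max_scores, labels = [], []
        for pid, g in tr_frame.sort_values("slice_index").groupby("patient_id"):
            trace, _ = patient_classify(
                g.score.to_numpy(), thickness, threshold=0.5, window_mm=window_mm
            )
            max_scores.append(trace.max())
            labels.append(train_truth[pid])
        thr, degenerate = choose_patient_threshold(max_scores, labels)

        ev_frame = records_to_frame(eval_records)
        ev_frame["score"] = ev_scores
        for pid, g in ev_frame.sort_values("slice_index").groupby("patient_id"):
            trace, decision = patient_classify(
                g.score.to_numpy(), thickness, threshold=thr, window_mm=window_mm
            )
            rows.append(
                {
                    "arm": arm,
                    "patient_id": pid,
                    "max_windowed_score": float(trace.max()),
                    "decision": int(decision),
                    "truth": test_truth[pid],
                    "threshold": thr,
                    "threshold_degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def _flatten(groups):
    out = []
    for g in groups:
        out.extend(g)
    return out


def quality_comparison(
    n_phantoms: int = 10,
    params: TransformParams = DEFAULT_TRUE_PARAMS,
    seed: int = 0,
    cohort: Optional[CohortConfig] = None,
) -> pd.DataFrame:
    """Gradient entropy of HF phantoms (on the LF grid) vs their
    simulated-LF counterparts; one row per phantom.

    Both members are evaluated on the shared LF grid so the per-slice
    pixel count — which sets the entropy's ceiling — is identical and
    the comparison isolates the degradation itself.
    """
    cfg = cohort or CohortConfig(n_lesional=0, n_control=n_phantoms)
    specs = make_cohort_specs(cfg, _child_seeds(seed, 1)[0])[:n_phantoms]
    noise_seeds = _child_seeds(seed + 13, n_phantoms)
    rows = []
    for (pid, pspec), nseed in zip(specs, noise_seeds):
        vol, _, _ = generate_phantom(pspec)
        hf_lf_grid = reslice(vol, LF_TARGET_SPACING_MM)
        sim = apply_lf_transform(hf_lf_grid, params, nseed)
        rows.append(
            {
                "patient_id": pid,
                "F_hf": volume_gradient_entropy(hf_lf_grid).F,
                "F_simLF": volume_gradient_entropy(sim).F,
            }
        )
    return pd.DataFrame(rows)
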