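"""Statistical harness for two-arm detectability comparisons.

Implements the per-slice and per-patient evaluation battery: ROC/AUC
(Mann-Whitney convention for ties), F1, a random-chance null model,
DeLong's test for correlated AUCs (structural-components covariance
estimator), logistic regression of detection sensitivity on lesion size
and intensity with Wald tests, the sensitivity-ratio-versus-size curve,
and sliding-window patient-level classification with an empirically
maximized threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "EvalReport",
    "roc_auc",
    "f1_score",
    "null_model_f1",
    "delong_test",
    "youden_threshold",
    "sensitivity_regression",
    "sensitivity_ratio_curve",
    "patient_classify",
    "choose_patient_threshold",
]


# ---------------------------------------------------------------------------
# per-slice metrics


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return labels


def roc_auc(labels, scores) -> tuple[float, pd.DataFrame]:
    """Trapezoidal AUC and ROC points.

    Ties are handled by rank-averaging, so the AUC equals the
    Mann-Whitney probability P(score+ > score-) + 0.5 P(score+ = score-);
    identical scores everywhere give 0.5.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("ROC requires both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def f1_score(labels, predictions) -> float:
    """Harmonic mean of precision and recall; 0 when precision + recall = 0."""
    labels = _check_binary(labels)
    predictions = _check_binary(predictions)
    return float(_sk_f1(labels, predictions, zero_division=0))


def null_model_f1(labels, trials: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Random-chance benchmark: F1 of uniform coin-flip predictions.

    Each trial predicts positive with probability 0.5 per slice; the mean
    and sd of F1 over ``trials`` trials benchmark chance performance.
    For prevalence ``q`` the expected F1 approaches ``2*(q*0.5)/(q+0.5)``.
    """
    labels = _check_binary(labels)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    n = labels.size
    pos = labels.astype(bool)
    n_pos = int(pos.sum())
    preds = rng.random((trials, n)) < 0.5
    tp = preds[:, pos].sum(axis=1)
    pred_pos = preds.sum(axis=1)
    denom = pred_pos + n_pos  # P+R denominator: 2TP/(pred_pos + n_pos)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * tp / denom, 0.0)
    return float(f1.mean()), float(f1.std(ddof=1)) if trials > 1 else 0.0


# ---------------------------------------------------------------------------
# DeLong's test for paired ROC curves


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")

def _delong_components(labels: np.ndarray, scores: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return auc, v10, v01


def delong_test(labels, scores_a, scores_b) -> tuple[float, float, float, float]:
    """DeLong's test for the difference of two correlated AUCs.

    Both score vectors must be computed on the same slices.  Returns
    ``(auc_a, auc_b, z, p)`` with a two-sided p-value.  Identical scores
    give z = 0, p = 1.
    """
    labels = _check_binary(labels)
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if not (labels.shape == scores_a.shape == scores_b.shape):
        raise ValueError("labels, scores_a and scores_b must be paired (equal length)")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("DeLong test requires both classes present")

    auc_a, v10_a, v01_a = _delong_components(labels, scores_a)
    auc_b, v10_b, v01_b = _delong_components(labels, scores_b)
    m, n = v10_a.size, v01_a.size

    v10 = np.stack([v10_a, v10_b])
    v01 = np.stack([v01_a, v01_b])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        if np.isclose(diff, 0):
            return float(auc_a), float(auc_b), 0.0, 1.0
        return float(auc_a), float(auc_b), float(np.sign(diff) * np.inf), 0.0
    z = diff / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


# ---------------------------------------------------------------------------
# sensitivity analyses


def youden_threshold(labels, scores) -> float:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    t = float(thr[best])
    if not np.isfinite(t):  # roc_curve's sentinel first threshold
        t = float(scores.max())
    return t


@dataclass
class RegressionResult:
    coef_size: float
    coef_intensity: float
    z_size: float
    z_intensity: float
    p_size: float
    p_intensity: float
    separation_flag: bool = False


def sensitivity_regression(detected, area_cm2, contrast) -> RegressionResult:
    """Logistic regression of per-slice detection on lesion size and
    intensity, with Wald z and two-sided p per covariate.

    ``detected`` is the binary outcome on positive slices (score above
    the chosen operating point).  Perfect separation is caught and
    refitted with a small L2 penalty, flagged in the result.
    """
    detected = _check_binary(detected)
    area = np.asarray(area_cm2, dtype=np.float64)
    contr = np.asarray(contrast, dtype=np.float64)
    if detected.size < 10:
        raise ValueError("need >= 10 positive slices for the sensitivity regression")
    if area.std() == 0 and contr.std() == 0:
        raise ValueError("both covariates are constant; regression undefined")
    X = sm.add_constant(np.column_stack([area, contr]), has_constant="add")
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(detected, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e4):
            raise np.linalg.LinAlgError("unstable standard errors")
    except Exception:
        separation = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(detected, X).fit_regularized(
                alpha=1.0, L1_wt=0.0, disp=0, maxiter=500
            )
            # refit unpenalized covariance at the penalized solution
            fit = sm.GLM(detected, X, family=sm.families.Binomial()).fit(
                start_params=np.asarray(fit.params), maxiter=0
            )
    params = np.asarray(fit.params)
    bse = np.asarray(fit.bse)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = params / bse
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    return RegressionResult(
        coef_size=float(params[1]),
        coef_intensity=float(params[2]),
        z_size=float(zvals[1]),
        z_intensity=float(zvals[2]),
        p_size=float(pvals[1]),
        p_intensity=float(pvals[2]),
        separation_flag=separation,
    )


def sensitivity_ratio_curve(
    hf_detected,
    hf_area_cm2,
    lf_detected,
    lf_area_cm2,
    size_thresholds: Sequence[float],
    min_slices: int = 5,
) -> pd.DataFrame:
    """LF/HF sensitivity ratio over lesions smaller than each size threshold.

    For threshold t, sensitivity is computed over positive slices with
    area < t in each arm; the ratio is sens_LF / sens_HF.  Thresholds
    with fewer than ``min_slices`` qualifying slices in either arm are
    flagged unstable; zero HF sensitivity leaves the ratio NaN, flagged.
    """
    hf_det = _check_binary(hf_detected)
    lf_det = _check_binary(lf_detected)
    hf_area = np.asarray(hf_area_cm2, dtype=np.float64)
    lf_area = np.asarray(lf_area_cm2, dtype=np.float64)
    rows = []
    for t in size_thresholds:
        hf_q = hf_area < t
        lf_q = lf_area < t
        n_hf, n_lf = int(hf_q.sum()), int(lf_q.sum())
        unstable = min(n_hf, n_lf) < min_slices
        sens_hf = hf_det[hf_q].mean() if n_hf else np.nan
        sens_lf = lf_det[lf_q].mean() if n_lf else np.nan
        if sens_hf and np.isfinite(sens_hf) and sens_hf > 0:
            ratio = float(sens_lf / sens_hf)
            undefined = False
        else:
            ratio = float("nan")
            undefined = True
        rows.append(
            {
                "threshold_cm2": float(t),
                "sens_hf": float(sens_hf) if np.isfinite(sens_hf) else np.nan,
                "sens_lf": float(sens_lf) if np.isfinite(sens_lf) else np.nan,
                "ratio": ratio,
                "n_hf": n_hf,
                "n_lf": n_lf,
                "unstable": bool(unstable or undefined),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patient-level classification


def moving_mean(scores: np.ndarray, window: int) -> np.ndarray:
    """Truncated moving mean: windows are shortened at the edges rather
    than padded, so no scores are fabricated."""
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.size
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        out[i] = scores[lo:hi].mean()
    return out


def patient_classify(
    per_slice_scores: Sequence[float],
    slice_thickness_mm: float,
    threshold: float,
    window_mm: float = 15.0,
) -> tuple[np.ndarray, bool]:
    """Sliding-window patient-level decision.

    Slice scores (ordered along z) are averaged with a moving window
    spanning approximately ``window_mm`` in z (``max(1,
    round(window_mm / thickness))`` slices); the patient is called
    positive iff the maximum windowed score reaches the threshold.
    """
    scores = np.asarray(per_slice_scores, dtype=np.float64)
    if scores.size < 1:
        raise ValueError("need at least one slice score")
    if slice_thickness_mm <= 0:
        raise ValueError("slice thickness must be positive")
    w = max(1, int(round(window_mm / slice_thickness_mm)))
    trace = moving_mean(scores, w)
    decision = bool(trace.max() >= threshold)
    return trace, decision


def choose_patient_threshold(
    training_max_scores: Sequence[float], training_labels: Sequence[int]
) -> tuple[float, bool]:
    """Threshold maximizing patient-level training accuracy.

    Candidates are the observed max-windowed scores; ties are broken
    toward the higher threshold (favoring specificity).  Returns
    ``(threshold, degenerate_flag)``; the flag is set when all traces are
    identical and the midpoint fallback is used.
    """
    scores = np.asarray(training_max_scores, dtype=np.float64)
    labels = _check_binary(training_labels)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("need at least one positive and one negative training patient")
    if np.allclose(scores, scores[0]):
        return float(scores[0]), True
    candidates = np.unique(scores)
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = ((scores >= t).astype(int) == labels).mean()
        if acc >= best_acc:  # >= breaks ties toward the higher threshold
            best_acc, best_t = acc, t
    return float(best_t), False


# ---------------------------------------------------------------------------
# report container


@dataclass
class EvalReport:
    """Evaluation results for one arm (optionally compared to another)."""

    per_slice: pd.DataFrame  # label, score, area_cm2, contrast
    auc: float
    f1: float
    null_f1_mean: float
    null_f1_sd: float
    threshold: float
    delong: Optional[tuple[float, float, float, float]] = None
    regression: Optional[RegressionResult] = None
    patient_level: Optional[pd.DataFrame] = None  # patient_id, max_windowed_score, decision

    def __post_init__(self) -> None:
        for name, v in (("auc", self.auc), ("f1", self.f1)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "f1": self.f1,
            "null_f1_mean": self.null_f1_mean,
            "null_f1_sd": self.null_f1_sd,
            "threshold": self.threshold,
        }
        if self.delong is not None:
            d["delong"] = dict(zip(("auc_a", "auc_b", "z", "p"), self.delong))
        if self.regression is not None:
            r = self.regression
            d["regression"] = {
                "coef_size": r.coef_size,
                "coef_intensity": r.coef_intensity,
                "z_size": r.z_size,
                "z_intensity": r.z_intensity,
                "p_size": r.p_size,
                "p_intensity": r.p_intensity,
            }
        return d
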