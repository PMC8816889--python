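"""Pluggable slice classifiers with a desk-scale seeded baseline.

The scientific payload of the framework is the two-arm comparison
harness, not any particular backbone, so the classifier is an interface:
any model mapping preprocessed axial slices to lesion-presence scores in
[0, 1] plugs in.

The default ``baseline_small_cnn`` backbone is a compact convolutional
model that trains in seconds on one CPU: a fixed multi-scale band-pass
(Laplacian-of-Gaussian) filter bank over the resized,
per-slice-standardized image, reduced by signed max pooling on a coarse
spatial grid, feeding a small learned multilayer-perceptron head.  Like
the full-scale CNN it is translation tolerant and responds to both
bright blobs (hyperintense lesions) and dark structure (displaced
CSF spaces), so detectability differences between arms reflect image
quality rather than model idiosyncrasies.

A ``densenet121`` configuration mirroring a transfer-learning setup
(ImageNet-pretrained DenseNet-121, Nadam, lr 0.002, batch size 32, 100
epochs) is declared for completeness; it requires an external
deep-learning backend and is not bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier

from .dataset import SliceRecord

__all__ = ["ClassifierSpec", "SliceClassifier", "train", "predict_scores"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Serializable training configuration.

    ``backbone='baseline_mlp'`` is the bundled default; ``'densenet121'``
    records the full-scale configuration (epochs=100, lr=0.002, batch 32)
    but needs an external deep-learning backend.
    """

    name: str = "baseline"
    backbone: str = "baseline_small_cnn"
    input_size: int = 64
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 2e-3
    hidden_layers: tuple[int, ...] = (64, 32)
    alpha: float = 1e-3  # L2 penalty of the MLP head
    log_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)  # blob scales, pixels
    pool_grid: int = 4  # spatial max-pool grid per scale
    seed: int = 0

    @classmethod
    def densenet121(cls, seed: int = 0) -> "ClassifierSpec":
        return cls(
            name="densenet121",
            backbone="densenet121",
            input_size=224,
            epochs=100,
            batch_size=32,
            learning_rate=2e-3,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_layers"] = list(self.hidden_layers)
        return d


def _standardized_slice(r: SliceRecord, input_size: int) -> np.ndarray:
    img = np.asarray(r.pixels, dtype=np.float64)
    zoom = (input_size / img.shape[0], input_size / img.shape[1])
    small = ndimage.zoom(img, zoom, order=1, grid_mode=True, mode="nearest")
    sd = small.std()
    small = small - small.mean()
    if sd > 0:
        small /= sd
    return small


def _grid_pool(resp: np.ndarray, grid: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed max pooling (max and min) over a grid x grid partition."""
    n = resp.shape[0]
    edges = np.linspace(0, n, grid + 1).astype(int)
    mx = np.empty((grid, grid))
    mn = np.empty((grid, grid))
    for a in range(grid):
        for b in range(grid):
            block = resp[edges[a] : edges[a + 1], edges[b] : edges[b + 1]]
            mx[a, b] = block.max()
            mn[a, b] = block.min()
    return mx, mn


def _features(records: Sequence[SliceRecord], spec: "ClassifierSpec") -> np.ndarray:
    """Fixed convolutional front end.

    Per slice: a coarse 8x8 mean-pooled copy of the standardized image
    (global structure) plus, per blob scale, grid-pooled signed extrema
    and global statistics of the scale-normalized
    Laplacian-of-Gaussian response.
    """
    feats = []
    for r in records:
        img = _standardized_slice(r, spec.input_size)
        n = spec.input_size
        block = n // 8
        coarse = img[: 8 * block, : 8 * block].reshape(8, block, 8, block).mean(axis=(1, 3))
        row = [coarse.ravel()]
        for s in spec.log_sigmas:
            resp = -(s**2) * ndimage.gaussian_laplace(img, sigma=s)
            mx, mn = _grid_pool(resp, spec.pool_grid)
            row.extend([mx.ravel(), mn.ravel()])
            row.append(np.array([resp.max(), resp.min(), resp.std()]))
        feats.append(np.concatenate(row))
    return np.asarray(feats)


@dataclass
class SliceClassifier:
    """A trained slice classifier: spec + fitted estimator + training log."""

    spec: ClassifierSpec
    model: MLPClassifier
    loss_curve: list[float]

    def predict_scores(self, records: Sequence[SliceRecord]) -> np.ndarray:
        return predict_scores(self, records)


def train(records_train: Sequence[SliceRecord], spec: Optional[ClassifierSpec] = None) -> SliceClassifier:
    """Train a classifier on training-split slices.

    Both classes must be present.  Training is fully seeded; identical
    spec, seed and data give identical models.
    """
    spec = spec or ClassifierSpec()
    if spec.backbone == "densenet121":
        raise NotImplementedError(
            "the densenet121 backbone requires an external deep-learning backend; "
            "use the bundled 'baseline_small_cnn' backbone"
        )
    if spec.backbone != "baseline_small_cnn":
        raise ValueError(f"unknown backbone {spec.backbone!r}")
    records_train = list(records_train)
    if any(r.split == "test" for r in records_train):
        raise ValueError("training received records stamped as test split (leakage)")
    y = np.array([r.label for r in records_train])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = _features(records_train, spec)
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        solver="adam",
        alpha=spec.alpha,
        batch_size=min(spec.batch_size, len(records_train)),
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        shuffle=True,
        random_state=spec.seed,
        early_stopping=False,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        # reaching the epoch budget without convergence is expected usage
        from sklearn.exceptions import ConvergenceWarning

        _warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return SliceClassifier(spec=spec, model=clf, loss_curve=list(clf.loss_curve_))


def predict_scores(classifier: SliceClassifier, records: Sequence[SliceRecord]) -> np.ndarray:
    """Lesion-presence scores in [0, 1], one per record, order-preserving."""
    records = list(records)
    if not records:
        return np.empty(0)
    X = _features(records, classifier.spec)
    scores = classifier.model.predict_proba(X)[:, 1]
    return np.clip(scores, 0.0, 1.0)
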