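"""Image-based quality scoring on amplified labels.

The scorer follows the transfer-learning recipe: a frozen convolutional
backbone turns each slice into a feature vector, and only a small head —
dense layer of 256 ReLU units, 50% dropout, single sigmoid output — is
trained, as a regression on the continuous amplified labels under mean
squared error. Training runs a fixed number of epochs and keeps the
checkpoint with the lowest validation loss. Splits are grouped by
subject so no subject's slices straddle train/validation/test, and the
whole procedure is repeated across seeds to measure AUC variability
against binarized gold labels.

The default backbone is a deliberately small, seeded random filter bank
(zero-mean convolution kernels + rectified responses pooled over a
spatial grid): it is fixed, deterministic, needs no weight download, and
is sensitive to the background ghost energy that motion artifacts
produce. A VGG16 backbone can be plugged in where a deep-learning
framework with pretrained weights is installed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.measure import block_reduce
from skimage.transform import resize

from .metrics import auc_mann_whitney

__all__ = [
    "prepare_input",
    "split_grouped",
    "SplitAssignment",
    "RandomConvBackbone",
    "VGG16Backbone",
    "extract_features",
    "train_scorer",
    "TrainedScorer",
    "evaluate_multi_seed",
    "MultiSeedResult",
]


def prepare_input(image: np.ndarray) -> np.ndarray:
    """Resize a 2D slice to 256x256, scale to [0, 1], triplicate channels."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("prepare_input expects a non-empty 2D image")
    if img.shape != (256, 256):
        img = resize(img, (256, 256), order=1, preserve_range=True, anti_aliasing=True)
    peak = img.max()
    if peak > 0:
        img = img / peak
    return np.repeat(img[:, :, None], 3, axis=2)


@dataclass
class SplitAssignment:
    assignment: pd.Series  # slice_id -> "train" | "validation" | "test"
    subjects: dict[str, list[str]]

    def ids(self, part: str) -> list[str]:
        return list(self.assignment.index[self.assignment == part])

    def mask(self, index: pd.Index, part: str) -> np.ndarray:
        return self.assignment.reindex(index).eq(part).to_numpy()


def split_grouped(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Partition slices into train/validation/test at subject granularity.

    Subjects are shuffled, then assigned in order until the cumulative
    slice count reaches each fraction boundary; all slices of a subject
    land in the same partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    subjects = manifest.groupby("subject_id")["slice_id"].apply(list)
    if len(subjects) < 3:
        raise ValueError("grouped split needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.array(sorted(subjects.index)))
    total = len(manifest)
    t1 = fractions[0] * total
    t2 = (fractions[0] + fractions[1]) * total

    parts: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
    assignment = {}
    cum = 0
    for subj in order:
        part = "train" if cum < t1 else ("validation" if cum < t2 else "test")
        parts[part].append(subj)
        for sid in subjects[subj]:
            assignment[sid] = part
        cum += len(subjects[subj])
    for part in ("train", "validation", "test"):
        if not parts[part]:
            raise ValueError(f"split produced an empty {part} partition")
    return SplitAssignment(
        assignment=pd.Series(assignment, name="split"), subjects=parts
    )


class RandomConvBackbone:
    """Fixed, seeded random convolutional feature extractor.

    The prepared image is collapsed to grayscale, mean-pooled down by
    ``downsample``, convolved with ``n_filters`` zero-mean random
    kernels, and the positive and negative rectified responses are
    average-pooled over a ``pool_grid`` x ``pool_grid`` spatial grid.
    Raw grid means of the image itself are appended, so background ghost
    energy is directly visible to the head.
    """

    def __init__(
        self,
        n_filters: int = 12,
        filter_size: int = 5,
        pool_grid: int = 6,
        downsample: int = 4,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        filt = rng.normal(0.0, 1.0, size=(n_filters, filter_size, filter_size))
        self.filters = filt - filt.mean(axis=(1, 2), keepdims=True)
        self.pool_grid = pool_grid
        self.downsample = downsample
        self.identifier = (
            f"randomconv(n={n_filters},k={filter_size},pool={pool_grid},"
            f"ds={downsample},seed={seed})"
        )

    @property
    def n_features(self) -> int:
        g = self.pool_grid
        return self.filters.shape[0] * 2 * g * g + g * g

    def _pool(self, img: np.ndarray) -> np.ndarray:
        g = self.pool_grid
        h = img.shape[0] // g
        return block_reduce(img[: h * g, : h * g], (h, h), np.mean).ravel()

    def transform_one(self, prepared: np.ndarray) -> np.ndarray:
        gray = np.asarray(prepared, dtype=float)
        if gray.ndim == 3:
            gray = gray.mean(axis=2)
        small = block_reduce(gray, (self.downsample, self.downsample), np.mean)
        feats = [self._pool(small)]
        for f in self.filters:
            resp = fftconvolve(small, f, mode="same")
            feats.append(self._pool(np.maximum(resp, 0.0)))
            feats.append(self._pool(np.maximum(-resp, 0.0)))
        return np.concatenate(feats)

    def transform(self, prepared_images) -> np.ndarray:
        return np.stack([self.transform_one(im) for im in prepared_images])


class VGG16Backbone:
    """Pretrained 16-layer ImageNet backbone (requires keras/tensorflow)."""

    def __init__(self) -> None:
        try:
            from keras.applications.vgg16 import VGG16, preprocess_input
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "VGG16Backbone requires keras/tensorflow with ImageNet weights; "
                "use RandomConvBackbone for a framework-free extractor"
            ) from exc
        self._preprocess = preprocess_input  # pragma: no cover
        self._model = VGG16(weights="imagenet", include_top=False, pooling="avg")  # pragma: no cover
        self.identifier = "vgg16-imagenet"  # pragma: no cover

    def transform(self, prepared_images) -> np.ndarray:  # pragma: no cover
        x = np.stack([np.asarray(im, dtype=float) * 255.0 for im in prepared_images])
        return self._model.predict(self._preprocess(x), verbose=0)


def extract_features(
    images: dict[str, np.ndarray] | pd.Series,
    backbone: RandomConvBackbone | None = None,
) -> pd.DataFrame:
    """Run the frozen backbone on prepared images keyed by slice_id."""
    backbone = backbone or RandomConvBackbone()
    items = images.items() if hasattr(images, "items") else images
    ids, mats = zip(*items)
    feats = backbone.transform([prepare_input(m) if m.ndim == 2 else m for m in mats])
    return pd.DataFrame(feats, index=pd.Index(ids, name="slice_id"))


# ---------------------------------------------------------------------------
# dense head: 256 ReLU -> dropout 0.5 -> 1 sigmoid, MSE loss, Adam


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _Head:
    def __init__(self, d: int, hidden: int, rng: np.random.Generator) -> None:
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, hidden))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, 1))
        self.b2 = np.zeros(1)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def set_params(self, params):
        self.w1, self.b1, self.w2, self.b2 = [p.copy() for p in params]

    def forward(self, x, dropout=0.0, rng=None):
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        mask = None
        if dropout > 0:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
        y = _sigmoid(h @ self.w2 + self.b2).ravel()
        return y, h, mask

    def grads(self, x, t, dropout, rng):
        y, h, mask = self.forward(x, dropout=dropout, rng=rng)
        n = x.shape[0]
        dz2 = (2.0 / n) * (y - t) * y * (1.0 - y)  # MSE through sigmoid
        gw2 = h.T @ dz2[:, None]
        gb2 = np.array([dz2.sum()])
        dh = dz2[:, None] @ self.w2.T
        if mask is not None:
            dh = dh * mask
        dh[h <= 0] = 0.0
        gw1 = x.T @ dh
        gb1 = dh.sum(axis=0)
        return [gw1, gb1, gw2, gb2]


@dataclass
class TrainedScorer:
    backbone_id: str
    head: _Head
    feat_mean: np.ndarray
    feat_std: np.ndarray
    best_epoch: int
    history: dict[str, list[float]]
    seed: int
    config: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
        x = np.asarray(features, dtype=float)
        x = (x - self.feat_mean) / self.feat_std
        y, _, _ = self.head.forward(x)
        if isinstance(features, pd.DataFrame):
            return pd.Series(y, index=features.index, name="score")
        return y


def train_scorer(
    features: pd.DataFrame,
    targets: pd.Series,
    split: SplitAssignment,
    epochs: int = 50,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 32,
    hidden: int = 256,
    dropout: float = 0.5,
    backbone_id: str = "randomconv",
) -> TrainedScorer:
    """Train the regression head on amplified labels.

    Only the head is trained (the backbone is frozen and already applied
    to produce ``features``). Minimises MSE with Adam; after each epoch
    the validation loss (without dropout) is recorded, and the weights
    from the best epoch are restored at the end.
    """
    targets = targets.reindex(features.index)
    t = targets.to_numpy(dtype=float)
    if np.isnan(t).any():
        raise ValueError("every feature row needs a target")
    if (t < 0).any() or (t > 1).any():
        raise ValueError("targets must lie in [0, 1]")
    train_mask = split.mask(features.index, "train")
    val_mask = split.mask(features.index, "validation")
    if not train_mask.any() or not val_mask.any():
        raise ValueError("train and validation partitions must be non-empty")

    x = features.to_numpy(dtype=float)
    mean = x[train_mask].mean(axis=0)
    std = x[train_mask].std(axis=0)
    std[std == 0] = 1.0
    xs = (x - mean) / std
    x_tr, t_tr = xs[train_mask], t[train_mask]
    x_va, t_va = xs[val_mask], t[val_mask]

    rng = np.random.default_rng(seed)
    head = _Head(x.shape[1], hidden, rng)
    m = [np.zeros_like(p) for p in head.params()]
    v = [np.zeros_like(p) for p in head.params()]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, -1, [p.copy() for p in head.params()])
    n_tr = x_tr.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, batch_size):
            idx = order[start : start + batch_size]
            grads = head.grads(x_tr[idx], t_tr[idx], dropout, rng)
            step += 1
            params = head.params()
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1**step)
                vhat = v[i] / (1 - beta2**step)
                params[i] -= lr * mhat / (np.sqrt(vhat) + eps)
        y_tr, _, _ = head.forward(x_tr)
        y_va, _, _ = head.forward(x_va)
        tr_loss = float(np.mean((y_tr - t_tr) ** 2))
        va_loss = float(np.mean((y_va - t_va) ** 2))
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(va_loss)
        if va_loss < best[0]:
            best = (va_loss, epoch, [p.copy() for p in head.params()])

    head.set_params(best[2])
    return TrainedScorer(
        backbone_id=backbone_id,
        head=head,
        feat_mean=mean,
        feat_std=std,
        best_epoch=best[1],
        history=history,
        seed=seed,
        config={
            "epochs": epochs,
            "lr": lr,
            "batch_size": batch_size,
            "hidden": hidden,
            "dropout": dropout,
        },
    )


@dataclass
class MultiSeedResult:
    per_seed_auc: list[float]
    seeds: list[int]
    mean_auc: float
    sd_auc: float

    def summary(self) -> str:
        lines = ["Multi-seed scorer evaluation (test split vs binarized gold)"]
        lines += [
            f"  seed {s}: AUC = {a:.4f}" for s, a in zip(self.seeds, self.per_seed_auc)
        ]
        lines.append(f"  mean AUC = {self.mean_auc:.4f}  (SD = {self.sd_auc:.4f})")
        return "\n".join(lines)


def evaluate_multi_seed(
    features: pd.DataFrame,
    targets: pd.Series,
    split: SplitAssignment,
    gold_labels: pd.Series,
    n_seeds: int = 10,
    base_seed: int = 0,
    **train_kwargs,
) -> MultiSeedResult:
    """Train the head ``n_seeds`` times and report test AUC mean and SD.

    Each run differs only in head initialisation and shuffling. The AUC
    is computed on test-split slices that carry a binary gold label.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    test_ids = [s for s in split.ids("test") if s in gold_labels.index and s in features.index]
    y_true = gold_labels.loc[test_ids].astype(int)
    if y_true.nunique() < 2:
        from .metrics import UndefinedMetricError

        raise UndefinedMetricError("test split gold labels contain a single class")

    seeds = [base_seed + k for k in range(n_seeds)]
    aucs = []
    for s in seeds:
        scorer = train_scorer(features, targets, split, seed=s, **train_kwargs)
        pred = scorer.predict(features.loc[test_ids])
        aucs.append(auc_mann_whitney(pred, y_true))
    return MultiSeedResult(
        per_seed_auc=aucs,
        seeds=seeds,
        mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs)) if n_seeds > 1 else 0.0,
    )
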