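"""Binary in-focus / out-of-focus frame classifier.

A single small convolutional network (conv blocks + global average pooling +
linear head) trained with Adam on cross-entropy, with random rotation /
contrast / brightness augmentation and per-dataset z-score normalization.

Note on ``n_iterations``: the protocol this follows states "100 iterations"
without disambiguating optimizer steps from passes over the data; here the
field means *full passes* (epochs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from sklearn.model_selection import StratifiedKFold

from . import _nn
from ._nets import ClassifierNet
from ._util import as_rng, resize_image, subseed, save_checkpoint, load_checkpoint

__all__ = [
    "ClassifierConfig",
    "ClassifierState",
    "FocusPrediction",
    "CVReport",
    "augment",
    "rotate_image",
    "train_classifier",
    "predict_frame",
    "predict_batch",
    "cross_validate",
    "save_classifier",
    "load_classifier",
]


@dataclass(frozen=True)
class ClassifierConfig:
    input_size_px: int = 64
    conv_widths: Tuple[int, ...] = (8, 16, 32, 32)
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 50
    n_iterations: int = 100          # full passes over the training set
    rotation_degrees_max: float = 15.0
    contrast_jitter: float = 0.1
    brightness_jitter: float = 0.1
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


@dataclass
class ClassifierState:
    params: dict
    config: ClassifierConfig
    norm_mean: float
    norm_std: float
    history: List[float]

    def make_net(self) -> ClassifierNet:
        net = ClassifierNet(conv_widths=self.config.conv_widths)
        net.params = self.params
        return net


@dataclass(frozen=True)
class FocusPrediction:
    label: str       # "in_focus" | "oof"
    score: float     # probability of "oof"

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class CVReport:
    fold_accuracies: List[float]
    mean_accuracy: float
    std_accuracy: float
    fold_assignments: np.ndarray     # fold index per CV-pool item
    pool_indices: np.ndarray         # indices (into the input) of the CV pool


# ---------------------------------------------------------------------------
# augmentation


def rotate_image(image: np.ndarray, angle_degrees: float) -> np.ndarray:
    """Rotate about the image centre with bilinear interpolation.

    Multiples of 90 degrees map grid points to grid points and are exact.
    """
    if angle_degrees == 0.0:
        return np.asarray(image, dtype=np.float64).copy()
    out = ndi.rotate(np.asarray(image, dtype=np.float64), angle_degrees,
                     reshape=False, order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def augment(image: np.ndarray, config: ClassifierConfig, seed) -> np.ndarray:
    """Random rotation plus multiplicative contrast and additive brightness jitter.

    All jitter magnitudes zero -> identity (the input is returned unchanged).
    """
    rng = as_rng(seed)
    img = np.asarray(image, dtype=np.float64)
    if (config.rotation_degrees_max == 0 and config.contrast_jitter == 0
            and config.brightness_jitter == 0):
        return img
    if config.rotation_degrees_max > 0:
        angle = rng.uniform(-config.rotation_degrees_max,
                            config.rotation_degrees_max)
        img = rotate_image(img, angle)
    if config.contrast_jitter > 0:
        factor = 1.0 + rng.uniform(-config.contrast_jitter, config.contrast_jitter)
        m = img.mean()
        img = m + (img - m) * factor
    if config.brightness_jitter > 0:
        img = img + rng.uniform(-config.brightness_jitter, config.brightness_jitter)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# training / inference


def _prepare(images: Sequence[np.ndarray], size: int) -> np.ndarray:
    return np.stack([resize_image(np.asarray(im, dtype=np.float64), size)
                     for im in images])


def train_classifier(frames: Sequence[np.ndarray], labels: Sequence[int],
                     config: ClassifierConfig = ClassifierConfig(),
                     seed: int = 0) -> ClassifierState:
    """Train the focus classifier; deterministic given (inputs, config, seed).

    ``labels``: 1 = OOF, 0 = in-focus.  Raises ``ValueError`` when only one
    class is present.  With ``n_iterations == 0`` the returned parameters are
    the (seeded) initialization and the history is empty.
    """
    y = np.asarray(labels, dtype=np.int64)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    x = _prepare(frames, config.input_size_px)
    mean = float(x.mean())
    std = float(x.std()) or 1.0

    net = ClassifierNet(conv_widths=config.conv_widths, seed=subseed(seed, 0))
    opt = _nn.Adam(net.params, lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    rng = as_rng(subseed(seed, 1))
    history: List[float] = []
    n = len(y)
    for _epoch in range(config.n_iterations):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = np.stack([augment(x[i], config, rng) for i in idx])
            batch = (batch - mean) / std
            logits, cache = net.forward(batch[..., None].astype(np.float32),
                                        train=True)
            loss, dlogits = _nn.softmax_xent(logits, y[idx])
            grads = net.backward(dlogits, cache)
            opt.step(grads)
            history.append(loss)
    return ClassifierState(params=net.params, config=config,
                           norm_mean=mean, norm_std=std, history=history)


def predict_batch(state: ClassifierState, frames: Sequence[np.ndarray]) -> np.ndarray:
    """OOF probability for each frame (deterministic inference)."""
    x = _prepare(frames, state.config.input_size_px)
    x = (x - state.norm_mean) / state.norm_std
    net = state.make_net()
    scores = []
    for start in range(0, len(x), 256):
        logits = net.forward(x[start:start + 256][..., None].astype(np.float32))
        scores.append(_nn.softmax(logits)[:, 1])
    return np.concatenate(scores)


def predict_frame(state: ClassifierState, image: np.ndarray) -> FocusPrediction:
    score = float(predict_batch(state, [image])[0])
    label = "oof" if score >= state.config.threshold else "in_focus"
    return FocusPrediction(label=label, score=score)


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(frames: Sequence[np.ndarray], labels: Sequence[int],
                   config: ClassifierConfig = ClassifierConfig(),
                   k: int = 5, cv_fraction: float = 0.75,
                   seed: int = 0) -> CVReport:
    """Label-stratified k-fold cross-validation on a seeded subset.

    ``round(cv_fraction * n)`` items form the CV pool; folds are disjoint and
    stratified, with sizes differing by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(labels, dtype=np.int64)
    n = len(y)
    n_pool = int(round(cv_fraction * n))
    if n_pool < k:
        raise ValueError("fewer CV items than folds")
    if len(set(y.tolist())) < 2:
        raise ValueError("cross-validation requires both classes")
    rng = as_rng(subseed(seed, 100))
    pool = rng.permutation(n)[:n_pool]
    y_pool = y[pool]
    if len(set(y_pool.tolist())) < 2:
        raise ValueError("CV pool contains a single class")
    frames = list(frames)

    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(subseed(seed, 101) % (2 ** 32)))
    assignments = np.full(n_pool, -1, dtype=np.int64)
    accuracies = []
    for fold, (train_idx, val_idx) in enumerate(skf.split(np.zeros(n_pool), y_pool)):
        assignments[val_idx] = fold
        tr = pool[train_idx]
        va = pool[val_idx]
        state = train_classifier([frames[i] for i in tr], y[tr], config,
                                 seed=subseed(seed, 200 + fold))
        scores = predict_batch(state, [frames[i] for i in va])
        pred = (scores >= config.threshold).astype(np.int64)
        accuracies.append(float((pred == y[va]).mean()))
    return CVReport(fold_accuracies=accuracies,
                    mean_accuracy=float(np.mean(accuracies)),
                    std_accuracy=float(np.std(accuracies)),
                    fold_assignments=assignments,
                    pool_indices=pool)


# ---------------------------------------------------------------------------
# checkpoint io


def save_classifier(state: ClassifierState, path) -> None:
    meta = {
        "kind": "focus_classifier",
        "config": asdict(state.config),
        "norm_mean": state.norm_mean,
        "norm_std": state.norm_std,
        "history": state.history,
    }
    save_checkpoint(path, state.params, meta)


def load_classifier(path) -> ClassifierState:
    params, meta = load_checkpoint(path)
    if meta.get("kind") != "focus_classifier":
        raise ValueError("not a focus-classifier checkpoint")
    cfg = meta["config"]
    cfg["conv_widths"] = tuple(cfg["conv_widths"])
    return ClassifierState(params=params, config=ClassifierConfig(**cfg),
                           norm_mean=meta["norm_mean"], norm_std=meta["norm_std"],
                           history=list(meta["history"]))
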