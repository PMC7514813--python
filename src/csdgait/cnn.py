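"""Toe-off frame classifier: a small fixed-architecture CNN.

The network has three convolutional layers (64, 128, 256 kernels of
size 5x5, 3x3, 3x3, each followed by ReLU and 2x2/stride-2 max
pooling) and three fully connected layers (1024, 512, 2 neurons).  The
two output neurons score "toe-off frame" vs "non-toe-off frame"; a
softmax turns them into a probability.

Training uses plain SGD with momentum 0.9, learning rate 1e-3 and
weight decay 5e-4.  Weights start by default from fan-in-scaled ("He")
Gaussians, which give unit forward gain under ReLU so the loss moves
from the first iterations; a fixed Gaussian std (e.g. the historical
1e-4 of :class:`SolverConfig`) can be requested instead, but needs a
far larger iteration budget to leave the symmetric initialization
region.  Because toe-off anchors are a small minority of frames (one
frame per step), batches are class-balanced by oversampling positives
1:1 by default — without this the all-negative classifier is a strong
local minimum.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._net import (
    Conv2DSame,
    Dense,
    Flatten,
    MaxPool2x2,
    ReLU,
    SGDMomentum,
    Sequential,
    softmax,
)
from .csd import NormalizedCSDMap
from .evaluate import DetectionResult

__all__ = [
    "ModelSpec",
    "SolverConfig",
    "ToeOffCNN",
    "build_model",
    "train",
    "predict_scores",
    "detect_events",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """The fixed classifier architecture for a given input size."""

    input_h: int
    input_w: int
    conv_channels: tuple[int, int, int] = (64, 128, 256)
    conv_kernels: tuple[int, int, int] = (5, 3, 3)
    pool_size: int = 2
    pool_stride: int = 2
    fc_sizes: tuple[int, int, int] = (1024, 512, 2)

    def stage_shapes(self) -> list[tuple[int, int]]:
        """Spatial (h, w) after each conv+pool stage."""
        h, w = self.input_h, self.input_w
        shapes = []
        for _ in self.conv_channels:
            h, w = h // self.pool_stride, w // self.pool_stride
            shapes.append((h, w))
        return shapes

    def flat_dim(self) -> int:
        h, w = self.stage_shapes()[-1]
        return h * w * self.conv_channels[-1]

    def param_count(self) -> int:
        count = 0
        in_ch = 1
        for ch, k in zip(self.conv_channels, self.conv_kernels):
            count += ch * in_ch * k * k + ch
            in_ch = ch
        in_dim = self.flat_dim()
        for fc in self.fc_sizes:
            count += in_dim * fc + fc
            in_dim = fc
        return count


@dataclass
class SolverConfig:
    """SGD solver settings (defaults follow the published configuration)."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    max_iterations: int = 20_000
    weight_init_std: float = 0.0001
    bias_init: float = 1.0
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("solver rates must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def build_model(input_h: int, input_w: int) -> ModelSpec:
    """Validate an input size and return the architecture spec for it.

    Three stride-2 poolings must leave at least a 1x1 spatial extent, so
    both input dimensions must be >= 8.
    """
    spec = ModelSpec(input_h=input_h, input_w=input_w)
    if input_h < 8 or input_w < 8:
        raise ValueError(
            f"input {input_h}x{input_w} too small: three 2x2/stride-2 poolings "
            "require both dimensions >= 8"
        )
    return spec


def _build_net(spec: ModelSpec) -> Sequential:
    layers: list = []
    in_ch = 1
    for li, (ch, k) in enumerate(zip(spec.conv_channels, spec.conv_kernels)):
        layers += [Conv2DSame(in_ch, ch, k, need_input_grad=li > 0), ReLU(), MaxPool2x2()]
        in_ch = ch
    layers.append(Flatten())
    in_dim = spec.flat_dim()
    for i, fc in enumerate(spec.fc_sizes):
        layers.append(Dense(in_dim, fc))
        if i < len(spec.fc_sizes) - 1:
            layers.append(ReLU())
        in_dim = fc
    return Sequential(layers)


class ToeOffCNN(ClassifierMixin, BaseEstimator):
    """Scikit-learn style binary classifier over normalized CSD-maps.

    Parameters mirror :class:`SolverConfig`; the architecture itself is
    fixed (see :class:`ModelSpec`) and only the input size varies.

    ``fit`` accepts ``X`` of shape ``(n, h, w)`` or ``(n, h*w)`` with
    values in [0, 1] and binary labels ``y``; fitted attributes are
    ``spec_`` (architecture), ``net_`` (parameters), ``loss_curve_`` and
    ``training_log_``.

    Examples
    --------
    >>> clf = ToeOffCNN(input_h=16, input_w=16, max_iter=50, random_state=0)
    >>> _ = clf.fit(X_train, y_train)          # doctest: +SKIP
    >>> scores = clf.predict_proba(X_test)[:, 1]   # doctest: +SKIP
    """

    def __init__(
        self,
        input_h: int = 48,
        input_w: int = 32,
        learning_rate: float = 0.001,
        momentum: float = 0.9,
        weight_decay: float = 0.0005,
        max_iter: int = 2000,
        batch_size: int = 32,
        weight_init_std: "float | str" = "he",
        bias_init: float = 1.0,
        balance_classes: bool = True,
        log_every: int = 50,
        random_state: int | None = None,
    ):
        self.input_h = input_h
        self.input_w = input_w
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.max_iter = max_iter
        self.batch_size = batch_size
        self.weight_init_std = weight_init_std
        self.bias_init = bias_init
        self.balance_classes = balance_classes
        self.log_every = log_every
        self.random_state = random_state

    # -- internals ----------------------------------------------------
    def _validate_X(self, X, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        h = self.input_h if not fitted else self.spec_.input_h
        w = self.input_w if not fitted else self.spec_.input_w
        if X.ndim == 2 and X.shape[1] == h * w:
            X = X.reshape(-1, h, w)
        if X.ndim != 3 or X.shape[1:] != (h, w):
            raise ValueError(
                f"X must have shape (n, {h}, {w}) or (n, {h * w}), got {X.shape}"
            )
        return X[:, None, :, :]  # add channel axis

    def fit(self, X, y) -> "ToeOffCNN":
        from ._net import softmax_cross_entropy

        X = self._validate_X(X)
        y = np.asarray(y).astype(np.int64).ravel()
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                "training requires both classes (labels {0,1}); got "
                f"classes {classes.tolist()}"
            )
        self.spec_ = build_model(self.input_h, self.input_w)
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC5D]))
        net = _build_net(self.spec_)
        for layer in net.layers:
            if hasattr(layer, "init_params"):
                layer.init_params(rng, self.weight_init_std, self.bias_init)
        opt = SGDMomentum(net, self.learning_rate, self.momentum, self.weight_decay)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        half = self.batch_size // 2
        log: list[tuple[int, float, float]] = []
        losses: list[float] = []
        for it in range(1, self.max_iter + 1):
            if self.balance_classes:
                idx = np.concatenate(
                    [
                        rng.choice(pos, size=half, replace=True),
                        rng.choice(neg, size=self.batch_size - half, replace=True),
                    ]
                )
            else:
                idx = rng.choice(len(y), size=self.batch_size, replace=True)
            xb, yb = X[idx], y[idx]
            logits = net.forward(xb)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at iteration {it}: loss={loss}"
                )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
            if it % self.log_every == 0 or it == self.max_iter:
                acc = float((logits.argmax(axis=1) == yb).mean())
                log.append((it, loss, acc))
        self.net_ = net
        self.classes_ = np.array([0, 1])
        self.n_iter_ = self.max_iter
        self.loss_curve_ = np.array(losses)
        self.training_log_ = log
        self.n_features_in_ = self.input_h * self.input_w
        return self

    def decision_scores(self, X, batch: int = 256) -> np.ndarray:
        """Toe-off probability per example (softmax of the two logits)."""
        check_is_fitted(self, "net_")
        X = self._validate_X(X, fitted=True)
        out = np.empty(len(X), dtype=np.float64)
        for i in range(0, len(X), batch):
            logits = self.net_.forward(X[i : i + batch])
            out[i : i + batch] = softmax(logits)[:, 1]
        return out

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.decision_scores(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(np.int64)


# -- functional wrappers ---------------------------------------------------


def _dataset_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        return np.asarray(dataset[0]), np.asarray(dataset[1])
    return np.asarray(dataset.X), np.asarray(dataset.y)


def train(dataset, solver: SolverConfig | None = None, **kwargs) -> ToeOffCNN:
    """Train the classifier on a labeled example set.

    ``dataset`` is either a ``(X, y)`` tuple or an object with ``X`` and
    ``y`` attributes (see :func:`csdgait.simulate.make_dataset`).
    """
    solver = solver or SolverConfig(max_iterations=2000)
    X, y = _dataset_arrays(dataset)
    clf = ToeOffCNN(
        input_h=X.shape[1],
        input_w=X.shape[2],
        learning_rate=solver.learning_rate,
        momentum=solver.momentum,
        weight_decay=solver.weight_decay,
        max_iter=solver.max_iterations,
        batch_size=solver.batch_size,
        weight_init_std=solver.weight_init_std,
        bias_init=solver.bias_init,
        random_state=solver.seed,
        **kwargs,
    )
    return clf.fit(X, y)


def predict_scores(
    model: ToeOffCNN, maps: Sequence[NormalizedCSDMap]
) -> tuple[np.ndarray, np.ndarray]:
    """Score an ordered list of normalized CSD-maps.

    Returns ``(anchor_indices, scores)`` with one toe-off probability in
    [0, 1] per map, aligned to each map's anchor frame index.
    """
    if len(maps) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    X = np.stack([m.values for m in maps])
    anchors = np.array([m.anchor_frame_index for m in maps], dtype=np.int64)
    return anchors, model.decision_scores(X)


def detect_events(
    scores: np.ndarray,
    threshold: float = 0.5,
    min_separation: int = 6,
    anchor_indices: np.ndarray | None = None,
) -> DetectionResult:
    """Turn per-frame toe-off scores into discrete event frame indices.

    Candidate events are local maxima of the score sequence that exceed
    ``threshold``; they are kept greedily in descending score order with
    non-maximum suppression: a candidate within ``min_separation`` frames
    of an already kept event is discarded.  With a 25 fps camera and
    ~1 s gait cycles, successive toe-offs are ~12 frames apart, so the
    default separation of 6 (a quarter cycle) suppresses double peaks
    without merging genuine events.

    ``anchor_indices`` maps score positions to frame indices (defaults
    to 0..len-1); it must be consecutive.
    """
    scores = np.asarray(scores, dtype=float)
    if anchor_indices is None:
        anchor_indices = np.arange(len(scores), dtype=np.int64)
    else:
        anchor_indices = np.asarray(anchor_indices, dtype=np.int64)
        if len(anchor_indices) != len(scores):
            raise ValueError("anchor_indices and scores length mismatch")
        if len(anchor_indices) > 1 and not np.all(np.diff(anchor_indices) == 1):
            raise ValueError("anchor_indices must be consecutive")
    n = len(scores)
    cand = [
        i
        for i in range(n)
        if scores[i] > threshold
        and (i == 0 or scores[i] >= scores[i - 1])
        and (i == n - 1 or scores[i] >= scores[i + 1])
    ]
    # descending score, earliest-first on ties, then greedy suppression
    cand.sort(key=lambda i: (-scores[i], i))
    kept: list[int] = []
    for i in cand:
        if all(abs(i - j) >= min_separation for j in kept):
            kept.append(i)
    kept.sort()
    return DetectionResult(
        predicted_indices=anchor_indices[kept],
        per_frame_scores=scores,
        anchor_indices=anchor_indices,
    )


# -- checkpointing ---------------------------------------------------------


def save_model(model: ToeOffCNN, path: str | Path) -> None:
    """Save weights as .npz with a JSON sidecar (architecture + solver)."""
    check_is_fitted(model, "net_")
    path = Path(path)
    weights = model.net_.get_weights()
    np.savez(path.with_suffix(".npz"), *weights)
    sidecar = {
        "model_spec": asdict(model.spec_),
        "params": model.get_params(),
        "n_iter": int(model.n_iter_),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> ToeOffCNN:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    clf = ToeOffCNN(**sidecar["params"])
    clf.spec_ = ModelSpec(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in sidecar["model_spec"].items()
        }
    )
    net = _build_net(clf.spec_)
    with np.load(path.with_suffix(".npz")) as data:
        net.set_weights([data[k] for k in data.files])
    clf.net_ = net
    clf.classes_ = np.array([0, 1])
    clf.n_iter_ = sidecar["n_iter"]
    clf.n_features_in_ = clf.spec_.input_h * clf.spec_.input_w
    return clf
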