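"""CPU tile classifiers: frozen convolutional feature stem + trainable MLP head.

The transfer-learning structure mirrors fine-tuning practice: a fixed
("pretrained") feature stem — a deterministic bank of zero-mean 3x3
convolution filters plus pooled color/gradient statistics — feeds a small
fully connected softmax head, and only the last ``layers_to_retrain`` dense
blocks are updated during fitting.  The stem is identical for every fit
(bit-identical parameters before and after), which is what makes the frozen
/retrained split meaningful and testable.

Backbones are registered by name and expose one interface, so the
purification loop runs unchanged with any of them.  ``inception_small`` is
the 299-native member used for cross-input-size transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .datatypes import Tile, tile_stack
from .errors import ConfigError, DataError


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    n_filters: int = 8
    hidden_sizes: tuple[int, ...] = (32, 16)
    native_input_size: int = 224
    feature_seed: int = 90021  # fixes the frozen stem


BACKBONES: dict[str, BackboneSpec] = {
    "small_cnn": BackboneSpec("small_cnn"),
    "wide_cnn": BackboneSpec("wide_cnn", n_filters=16, hidden_sizes=(64, 32)),
    "inception_small": BackboneSpec("inception_small", native_input_size=299),
}


def get_backbone(name: str | BackboneSpec) -> BackboneSpec:
    if isinstance(name, BackboneSpec):
        return name
    try:
        return BACKBONES[name]
    except KeyError:
        raise ConfigError(
            f"unknown backbone {name!r}; available: {sorted(BACKBONES)}"
        ) from None


def filter_bank(spec: BackboneSpec) -> np.ndarray:
    """The frozen stem's 3x3 convolution filters (zero-mean, unit-norm),
    a pure function of the backbone spec."""
    rng = np.random.default_rng(spec.feature_seed)
    f = rng.standard_normal((spec.n_filters, 3, 3))
    f -= f.mean(axis=(1, 2), keepdims=True)
    f /= np.sqrt((f**2).sum(axis=(1, 2), keepdims=True))
    return f


def extract_features(stack: np.ndarray, spec: BackboneSpec) -> np.ndarray:
    """Pooled features of an (N, S, S, 3) uint8 stack.

    Per tile: per-channel mean/sd, gradient-magnitude mean/sd, bright and
    dark pixel fractions, and mean |response| + sd of each frozen filter.
    Global pooling makes the stem input-size agnostic.
    """
    x = stack.astype(np.float64) / 255.0
    gray = x @ np.array([0.299, 0.587, 0.114])
    cols = [
        x.mean(axis=(1, 2)),
        x.std(axis=(1, 2)),
    ]
    gy = np.gradient(gray, axis=1)
    gx = np.gradient(gray, axis=2)
    gm = np.hypot(gx, gy)
    cols.append(gm.mean(axis=(1, 2))[:, None])
    cols.append(gm.std(axis=(1, 2))[:, None])
    cols.append((gray > 0.9).mean(axis=(1, 2))[:, None])
    cols.append((gray < 0.47).mean(axis=(1, 2))[:, None])
    for k in filter_bank(spec):
        resp = ndimage.correlate(gray, k[None, :, :], mode="reflect")
        cols.append(np.abs(resp).mean(axis=(1, 2))[:, None])
        cols.append(resp.std(axis=(1, 2))[:, None])
    return np.concatenate(cols, axis=1)


def n_features(spec: BackboneSpec) -> int:
    return 10 + 2 * spec.n_filters


def init_head(
    spec: BackboneSpec, n_classes: int, seed: int
) -> dict[str, np.ndarray]:
    """He-initialized dense parameters; block i is (W{i}, b{i})."""
    rng = np.random.default_rng(seed)
    sizes = (n_features(spec), *spec.hidden_sizes, n_classes)
    params = {}
    for i in range(len(sizes) - 1):
        fan_in = sizes[i]
        params[f"W{i}"] = rng.standard_normal((sizes[i], sizes[i + 1])) * np.sqrt(
            2.0 / fan_in
        )
        params[f"b{i}"] = np.zeros(sizes[i + 1])
    return params


def head_forward(
    params: dict[str, np.ndarray], x: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass; returns (logits, per-block activations incl. input)."""
    acts = [x]
    h = x
    for i in range(n_blocks):
        h = h @ params[f"W{i}"] + params[f"b{i}"]
        if i < n_blocks - 1:
            h = np.maximum(h, 0.0)
        acts.append(h)
    return h, acts


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TileClassifier:
    """A trained tile classifier handle.

    ``classes`` fixes the softmax column order; argmax ties resolve to the
    lowest class index.  ``input_size`` is the tile side seen at fit time;
    predicting differently sized tiles is an error naming the expected size.
    """

    backbone: BackboneSpec
    classes: tuple[str, ...]
    params: dict[str, np.ndarray]
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    input_size: int
    seed: int = 0
    tie_count: int = field(default=0, repr=False)

    @property
    def n_blocks(self) -> int:
        return len(self.backbone.hidden_sizes) + 1

    def _features(self, stack: np.ndarray) -> np.ndarray:
        f = extract_features(stack, self.backbone)
        return (f - self.feat_mean) / self.feat_sd

    def predict_proba(self, tiles: list[Tile]) -> np.ndarray:
        stack = tile_stack(tiles)
        if stack.shape[1] != self.input_size:
            raise DataError(
                f"tile size {stack.shape[1]} does not match model input size "
                f"{self.input_size}"
            )
        logits, _ = head_forward(self.params, self._features(stack), self.n_blocks)
        return softmax(logits)

    def predict(self, tiles: list[Tile]) -> tuple[np.ndarray, list[str]]:
        """Per-tile softmax rows (summing to 1) and argmax labels."""
        probs = self.predict_proba(tiles)
        idx = probs.argmax(axis=1)  # first maximum -> lowest class index
        row_max = probs.max(axis=1)
        self.tie_count += int(((probs == row_max[:, None]).sum(axis=1) > 1).sum())
        return probs, [self.classes[i] for i in idx]


class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params, grads, trainable):
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, lr, momentum=0.9):
        super().__init__(lr)
        self.momentum = momentum
        self.v = {}

    def step(self, params, grads, trainable):
        for k in trainable:
            v = self.v.get(k, 0.0) * self.momentum - self.lr * grads[k]
            self.v[k] = v
            params[k] = params[k] + v


class Adam(_Optimizer):
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params, grads, trainable):
        self.t += 1
        for k in trainable:
            g = grads[k]
            self.m[k] = self.b1 * self.m.get(k, 0.0) + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v.get(k, 0.0) + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, lr, rho=0.9, eps=1e-8):
        super().__init__(lr)
        self.rho, self.eps = rho, eps
        self.s = {}

    def step(self, params, grads, trainable):
        for k in trainable:
            g = grads[k]
            self.s[k] = self.rho * self.s.get(k, 0.0) + (1 - self.rho) * g * g
            params[k] = params[k] - self.lr * g / (np.sqrt(self.s[k]) + self.eps)


OPTIMIZERS = {"sgd": SGD, "adam": Adam, "rmsprop": RMSprop}


def make_optimizer(name: str, lr: float) -> _Optimizer:
    try:
        return OPTIMIZERS[name](lr)
    except KeyError:
        raise ConfigError(
            f"unknown optimizer {name!r}; available: {sorted(OPTIMIZERS)}"
        ) from None
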