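"""Transfer-learning harness: subject-level splits, class balancing,
minibatch fitting with LR decay and early stopping, and a hyperparameter
grid runner ranked by the four-score.

The protocol follows fine-tuning practice for tile classifiers: only the
last ``layers_to_retrain`` dense blocks of the backbone are updated,
cross-entropy is minimized with Adam/SGD/RMSprop, the learning rate decays
by 5% every five epochs, training stops when the validation loss fails to
improve for ``early_stop_patience`` epochs, and the best-validation-loss
checkpoint is returned.  Optional Gaussian-blur augmentation and
random-doubling class balancing are applied to the training set only.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import CLASSES, Tile, TileDataset, tile_stack
from .errors import ConfigError, DataError
from .evaluation import (
    classification_score_vector,
    confusion_and_metrics,
    four_score,
)
from .models import (
    BackboneSpec,
    TileClassifier,
    extract_features,
    get_backbone,
    head_forward,
    init_head,
    make_optimizer,
    softmax,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``input_size`` optionally declares the canonical deployment tile side
    (224 or 299); the harness otherwise adopts the tile size of the training
    data.  ``lr_decay`` is the fractional decrease applied every
    ``lr_decay_every`` epochs.  ``balance`` is "to_majority" (upsample with
    replacement until every class matches the majority count),
    "strict_double" (duplicate each minority class once), or "off".
    """

    backbone: str = "small_cnn"
    input_size: Optional[int] = None
    layers_to_retrain: int = 3
    optimizer: str = "adam"
    lr: float = 1e-4
    lr_decay: float = 0.05
    lr_decay_every: int = 5
    batch_size: int = 150
    max_epochs: int = 100
    early_stop_patience: int = 5
    gaussian_blur: bool = True
    balance: str = "to_majority"
    seed: int = 0

    def __post_init__(self):
        if self.input_size not in (None, 224, 299):
            raise ConfigError("input_size must be 224, 299 or None")
        spec = get_backbone(self.backbone)
        if self.input_size is not None and self.input_size != spec.native_input_size:
            raise ConfigError(
                f"backbone {self.backbone!r} is native to input size "
                f"{spec.native_input_size}, got {self.input_size}"
            )
        if self.lr <= 0:
            raise ConfigError("lr must be positive")
        if not 0 <= self.lr_decay < 1:
            raise ConfigError("lr_decay must lie in [0, 1)")
        if self.balance not in ("to_majority", "strict_double", "off"):
            raise ConfigError(f"unknown balance mode {self.balance!r}")


def learning_rate_at(config: TrainConfig, epoch: int) -> float:
    """LR of a 1-indexed epoch: lr * (1 - decay)^(epoch // every)."""
    return config.lr * (1.0 - config.lr_decay) ** (epoch // config.lr_decay_every)


@dataclass
class SplitPlan:
    """Subject-level train/val/test assignment."""

    assignment: dict[str, str]
    proportions: tuple[float, float, float]
    seed: int

    def counts(self) -> dict[str, int]:
        out = {"train": 0, "val": 0, "test": 0}
        for v in self.assignment.values():
            out[v] += 1
        return out


def make_splits(
    dataset: TileDataset,
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitPlan:
    """Random subject-disjoint split at the given proportions, stratified by
    class (each class's subjects are assigned independently).

    A class with a single subject cannot satisfy disjointness across splits
    and is placed entirely in train with a warning; classes with fewer than
    3 subjects also trigger a warning.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ConfigError("split proportions must sum to 1")
    subj_class: dict[str, str] = {}
    for t in dataset.tiles:
        subj_class.setdefault(t.subject_id, t.label)
    by_class: dict[str, list[str]] = {}
    for s, c in subj_class.items():
        by_class.setdefault(c, []).append(s)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in sorted(by_class):
        subs = sorted(by_class[cls])
        rng.shuffle(subs)
        n = len(subs)
        if n < 3:
            warnings.warn(
                f"class {cls} has only {n} subject(s); split disjointness is degenerate"
            )
        if n == 1:
            assignment[subs[0]] = "train"
            continue
        if n == 2:
            assignment[subs[0]] = "train"
            assignment[subs[1]] = "test"
            continue
        n_test = max(1, int(round(proportions[2] * n)))
        n_val = max(1, int(round(proportions[1] * n)))
        for s in subs[:n_test]:
            assignment[s] = "test"
        for s in subs[n_test : n_test + n_val]:
            assignment[s] = "val"
        for s in subs[n_test + n_val :]:
            assignment[s] = "train"
    return SplitPlan(assignment=assignment, proportions=proportions, seed=seed)


def apply_split(dataset: TileDataset, plan: SplitPlan) -> None:
    dataset.split = dict(plan.assignment)


def balance_by_doubling(
    tiles: list[Tile], seed: int = 0, mode: str = "to_majority"
) -> list[Tile]:
    """Upsample underrepresented classes by random duplication.

    ``to_majority`` draws with replacement until every class count equals
    the majority count; ``strict_double`` appends one full copy of each
    minority class.  Duplicates reference the same underlying Tile objects
    (no pixel copies); the majority class is unchanged.
    """
    by_label: dict[str, list[Tile]] = {}
    for t in tiles:
        by_label.setdefault(t.label, []).append(t)
    if not by_label:
        return []
    n_max = max(len(v) for v in by_label.values())
    rng = np.random.default_rng(seed)
    out = list(tiles)
    for label in sorted(by_label):
        group = by_label[label]
        if len(group) == n_max:
            continue
        if mode == "to_majority":
            idx = rng.integers(0, len(group), size=n_max - len(group))
            out.extend(group[i] for i in idx)
        elif mode == "strict_double":
            out.extend(group)
        else:
            raise ConfigError(f"unknown balance mode {mode!r}")
    return out


def _class_order(labels: set[str]) -> tuple[str, ...]:
    known = [c for c in CLASSES if c in labels]
    extra = sorted(labels - set(CLASSES))
    return tuple(known + extra)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


def _blur_stack(stack: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaussian blur each tile with its own sigma in [0.1, 2]."""
    out = np.empty_like(stack)
    sigmas = rng.uniform(0.1, 2.0, size=len(stack))
    for i, s in enumerate(sigmas):
        out[i] = ndimage.gaussian_filter(
            stack[i].astype(np.float64), sigma=(s, s, 0)
        ).round().clip(0, 255)
    return out


def fit(
    train_tiles: list[Tile],
    val_tiles: list[Tile],
    config: TrainConfig,
) -> tuple[TileClassifier, pd.DataFrame]:
    """Fit a backbone head on training tiles with validation-based early
    stopping; returns the best-validation-loss checkpoint and a per-epoch
    log (epoch, lr, train_loss, val_loss).

    Only the last ``layers_to_retrain`` dense blocks are trainable; earlier
    blocks and the convolutional stem keep their initialization.  The run is
    fully deterministic given ``config.seed``.
    """
    if not train_tiles or not val_tiles:
        raise DataError("empty train or val set")
    spec = get_backbone(config.backbone)
    classes = _class_order({t.label for t in train_tiles})
    if len(classes) < 2:
        raise DataError("training set must contain at least two classes")

    rng = np.random.default_rng(config.seed)
    init_seed = int(rng.integers(0, 2**31 - 1))
    blur_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    shuffle_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))

    if config.balance != "off":
        train_tiles = balance_by_doubling(
            train_tiles, seed=int(rng.integers(0, 2**31 - 1)), mode=config.balance
        )

    stack = tile_stack(train_tiles)
    tile_size = int(stack.shape[1])
    if config.input_size is not None and tile_size != config.input_size:
        raise DataError(
            f"training tiles are {tile_size} px but config declares input size "
            f"{config.input_size}"
        )
    cls_index = {c: i for i, c in enumerate(classes)}
    y = np.array([cls_index[t.label] for t in train_tiles])

    feats = extract_features(stack, spec)
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd < 1e-8] = 1.0
    x_train = (feats - mu) / sd
    if config.gaussian_blur:
        x_blur = (extract_features(_blur_stack(stack, blur_rng), spec) - mu) / sd
    else:
        x_blur = x_train

    val_stack = tile_stack(val_tiles)
    if val_stack.shape[1] != tile_size:
        raise DataError("validation tile size differs from training tile size")
    x_val = (extract_features(val_stack, spec) - mu) / sd
    y_val = np.array([cls_index.get(t.label, -1) for t in val_tiles])
    if (y_val < 0).any():
        raise DataError("validation set contains classes absent from training")

    n_blocks = len(spec.hidden_sizes) + 1
    params = init_head(spec, len(classes), init_seed)
    retrain = min(max(config.layers_to_retrain, 1), n_blocks)
    trainable = [
        f"{p}{i}" for i in range(n_blocks - retrain, n_blocks) for p in ("W", "b")
    ]
    opt = make_optimizer(config.optimizer, config.lr)

    best_loss = np.inf
    best_params = copy.deepcopy(params)
    stale = 0
    records = []
    n = len(x_train)
    for epoch in range(1, config.max_epochs + 1):
        opt.lr = learning_rate_at(config, epoch)
        order = shuffle_rng.permutation(n)
        use_blur = shuffle_rng.random(n) < 0.5
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = np.where(use_blur[idx, None], x_blur[idx], x_train[idx])
            yb = y[idx]
            logits, acts = head_forward(params, xb, n_blocks)
            probs = softmax(logits)
            epoch_losses.append(_cross_entropy(probs, yb))
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad /= len(yb)
            grads = {}
            for i in range(n_blocks - 1, -1, -1):
                grads[f"W{i}"] = acts[i].T @ grad
                grads[f"b{i}"] = grad.sum(axis=0)
                if i > 0:
                    grad = (grad @ params[f"W{i}"].T) * (acts[i] > 0)
            opt.step(params, grads, trainable)
        val_logits, _ = head_forward(params, x_val, n_blocks)
        val_loss = _cross_entropy(softmax(val_logits), y_val)
        records.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_params = copy.deepcopy(params)
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break

    model = TileClassifier(
        backbone=spec,
        classes=classes,
        params=best_params,
        feat_mean=mu,
        feat_sd=sd,
        input_size=tile_size,
        seed=config.seed,
    )
    return model, pd.DataFrame(records)


def predict(model: TileClassifier, tiles: list[Tile]) -> tuple[np.ndarray, list[str]]:
    """Per-tile softmax and argmax labels (ties -> lowest class index)."""
    return model.predict(tiles)


#: default harness settings for the small MLP heads used on CPU; the
#: classic fine-tuning default (lr 1e-4, batch 150) remains TrainConfig's
DESK_CONFIG = TrainConfig(
    backbone="small_cnn", lr=3e-3, batch_size=64, max_epochs=40, early_stop_patience=5
)


def run_grid(
    configs: list[TrainConfig],
    train_tiles: list[Tile],
    val_tiles: list[Tile],
    test_tiles: list[Tile],
    validation_images: dict[str, tuple[str, list[Tile]]],
    expert: pd.DataFrame,
    classes: tuple[str, ...] = CLASSES,
) -> pd.DataFrame:
    """Train every config, evaluate accuracy/F1/Jaccard on the test tiles
    and the four-score on grouped validation images, and rank by four-score.

    ``validation_images`` maps image_id -> (group, tiles); ``expert`` is the
    per-image class-fraction table.  Individual config failures are logged
    and ranked last rather than aborting the sweep.
    """
    if not configs:
        raise ConfigError("empty config grid")
    expert_vec = {
        r["image_id"]: np.array([r[c] for c in classes])
        for _, r in expert.iterrows()
    }
    rows = []
    for j, cfg in enumerate(configs):
        row: dict = {"config_index": j, **asdict(cfg)}
        try:
            model, _ = fit(train_tiles, val_tiles, cfg)
            y_true = [t.true_class or t.label for t in test_tiles]
            _, y_pred = model.predict(test_tiles)
            rep = confusion_and_metrics(y_true, y_pred, model.classes)
            groups = {i: g for i, (g, _) in validation_images.items()}
            fractions = {}
            for image_id, (_, tiles) in validation_images.items():
                _, labels = model.predict(tiles)
                fractions[image_id] = classification_score_vector(labels, classes)
            fs = four_score(groups, fractions, expert_vec, classes)
            row.update(
                accuracy=rep.accuracy,
                weighted_f1=rep.weighted["f1"],
                weighted_jaccard=rep.weighted["jaccard"],
                four_score=fs.fourscore,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - sweep must survive one bad config
            log.warning("grid config %d failed: %s", j, exc)
            row.update(
                accuracy=np.nan,
                weighted_f1=np.nan,
                weighted_jaccard=np.nan,
                four_score=np.nan,
                error=str(exc),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        "four_score", ascending=False, na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
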