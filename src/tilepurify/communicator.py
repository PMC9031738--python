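"""Iterative dataset purification by two cross-trained classifiers.

A noisily labeled "new" class (e.g. HP tiles cut from whole pancreas spots,
some of which actually show fat or glass) is purified against a reference
dataset of known contaminant classes (ADI, BG).  Per cycle i:

1. Communicator 1 is trained on reference tiles plus the current Data A_i
   tiles labeled as the target class, then filters all tiles of a disjoint
   B-image subset: tiles not classified as the target class are removed,
   yielding Data B_i.
2. Communicator 2 is trained on reference plus Data B_i and filters Data
   A_i, yielding Data A_{i+1}.

Filtering never adds tiles, so |A_{i+1}| <= |A_i|.  After the requested
cycles, the final communicators sweep every tile of every image: tiles
whose top softmax falls below a threshold (default 0.55) are discarded as
unclassifiable, tiles classified as ADI/BG are moved into those classes,
and the rest keep their parenchymal label.  Per-cycle filtering itself uses
plain argmax; the threshold applies only to the final sweep.

Each communicator is retrained from its initialization every cycle (no
warm start), and one master seed drives subset selection, initialization
and data order, so a run is bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import (
    CLASSES,
    CONTAMINANT_CLASSES,
    PARENCHYMAL_CLASSES,
    STATUS_DISCARDED,
    STATUS_KEPT,
    STATUS_MOVED_ADI,
    STATUS_MOVED_BG,
    ImageRecord,
    Tile,
    TileDataset,
)
from .errors import ConfigError, DataError
from .models import TileClassifier
from .training import TrainConfig, fit

log = logging.getLogger(__name__)


@dataclass
class ReferenceDataset:
    """Labeled tiles of the reference contaminant classes (ADI required,
    BG supported); class names must be disjoint from the class being
    purified, and each class needs at least 2 tiles."""

    tiles: list[Tile]
    source: str = "synthetic"

    def class_names(self) -> tuple[str, ...]:
        present = {t.label for t in self.tiles}
        return tuple(c for c in CLASSES if c in present) + tuple(
            sorted(present - set(CLASSES))
        )

    def validate(self, target_class: str) -> None:
        counts: dict[str, int] = {}
        for t in self.tiles:
            counts[t.label] = counts.get(t.label, 0) + 1
        if "ADI" not in counts:
            raise DataError("reference dataset must contain an ADI class")
        if target_class in counts:
            raise DataError(
                f"reference classes overlap the purified class {target_class!r}"
            )
        thin = [c for c, n in counts.items() if n < 2]
        if thin:
            raise DataError(f"reference classes with < 2 tiles: {thin}")


def select_image_subsets(
    images: list[str] | list[ImageRecord],
    k: int = 20,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Draw two disjoint image subsets of size k without replacement.

    With fewer than 2k images available, k falls back to floor(n/2) with a
    warning; fewer than 2 images is an error.
    """
    ids = [im if isinstance(im, str) else im.image_id for im in images]
    n = len(ids)
    if n < 2:
        raise DataError("need at least 2 images to form disjoint subsets")
    if n < 2 * k:
        k = n // 2
        warnings.warn(f"fewer than 2k images available; using k={k}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(n, size=2 * k, replace=False)
    return [ids[i] for i in pick[:k]], [ids[i] for i in pick[k:]]


@dataclass
class CommunicatorState:
    """Per-cycle state of the purification loop for one target class."""

    target_class: str
    cycle_index: int = 0
    a_images: list[str] = field(default_factory=list)
    a_set: list[Tile] = field(default_factory=list)  # Data A_i
    b_set: list[Tile] = field(default_factory=list)  # Data B_i of last cycle
    model_1: Optional[TileClassifier] = None
    model_2: Optional[TileClassifier] = None
    discard_log: list[dict] = field(default_factory=list)


def _as_target(tiles: list[Tile], target_class: str) -> list[Tile]:
    """Shallow-copied tiles relabeled as the target class for training."""
    return [
        Tile(
            image_id=t.image_id,
            grid_row=t.grid_row,
            grid_col=t.grid_col,
            pixels=t.pixels,
            label=target_class,
            subject_id=t.subject_id,
            normalized=t.normalized,
            true_class=t.true_class,
        )
        for t in tiles
    ]


def train_communicator(
    reference: ReferenceDataset,
    candidate_tiles: list[Tile],
    target_class: str,
    config: TrainConfig,
    val_fraction: float = 0.15,
) -> TileClassifier:
    """Train one communicator on reference classes plus the candidate tiles
    labeled as the target class.

    The class set is reference classes ∪ {target_class}; an internal
    stratified split provides the validation set for early stopping.
    """
    if not reference.tiles or not candidate_tiles:
        raise DataError("reference and candidate tile sets must be non-empty")
    reference.validate(target_class)
    pool = list(reference.tiles) + _as_target(candidate_tiles, target_class)
    if len({t.label for t in pool}) < 2:
        raise DataError("single-class training set")
    rng = np.random.default_rng([config.seed, 104729])
    train, val = [], []
    by_label: dict[str, list[Tile]] = {}
    for t in pool:
        by_label.setdefault(t.label, []).append(t)
    for label in sorted(by_label):
        group = by_label[label]
        order = rng.permutation(len(group))
        n_val = max(1, int(round(val_fraction * len(group))))
        for j, i in enumerate(order):
            (val if j < n_val else train).append(group[i])
    model, _ = fit(train, val, config)
    return model


def filter_tiles(
    model: TileClassifier, tiles: list[Tile], target_class: str
) -> tuple[list[Tile], list[tuple[Tile, str]]]:
    """Keep tiles whose argmax class is the target; removed tiles are
    returned with their predicted class."""
    if target_class not in model.classes:
        raise DataError(
            f"model classes {model.classes} do not include {target_class!r}"
        )
    if not tiles:
        return [], []
    probs, labels = model.predict(tiles)
    kept, removed = [], []
    for t, p, lab in zip(tiles, probs, labels):
        t.softmax = p
        if lab == target_class:
            kept.append(t)
        else:
            removed.append((t, lab))
    return kept, removed


def _contaminant_fraction(tiles: list[Tile]) -> float:
    """Truth-table audit: fraction of tiles whose hidden class is ADI/BG
    (NaN when truth is unavailable)."""
    known = [t for t in tiles if t.true_class is not None]
    if not known:
        return float("nan")
    return sum(t.true_class in CONTAMINANT_CLASSES for t in known) / len(known)


def cleanup_cycle(
    state: CommunicatorState,
    reference: ReferenceDataset,
    config: TrainConfig,
    b_tiles: list[Tile],
) -> CommunicatorState:
    """Run one purification cycle in place and append to the discard log.

    ``b_tiles`` are all tiles of this cycle's B-image subset.  Trains
    Communicator 1 on reference ∪ A_i, filters B -> Data B_i, trains
    Communicator 2 on reference ∪ B_i, filters A_i -> A_{i+1}.
    """
    if not state.a_set:
        raise DataError("Data A is empty; review threshold or backbone")
    i = state.cycle_index
    seed_base = np.random.default_rng([config.seed, 31 + i]).integers(0, 2**31 - 1, 2)
    cfg1 = TrainConfig(**{**_cfg_dict(config), "seed": int(seed_base[0])})
    cfg2 = TrainConfig(**{**_cfg_dict(config), "seed": int(seed_base[1])})

    state.model_1 = train_communicator(
        reference, state.a_set, state.target_class, cfg1
    )
    b_kept, b_removed = filter_tiles(state.model_1, b_tiles, state.target_class)
    state.model_2 = train_communicator(
        reference, b_kept, state.target_class, cfg2
    ) if b_kept else state.model_1
    a_kept, a_removed = filter_tiles(state.model_2, state.a_set, state.target_class)
    if not a_kept:
        raise DataError(
            "purification removed every Data A tile; review threshold or backbone"
        )
    state.discard_log.append(
        {
            "cycle": i,
            "a_in": len(state.a_set),
            "a_kept": len(a_kept),
            "a_removed": len(a_removed),
            "b_in": len(b_tiles),
            "b_kept": len(b_kept),
            "b_removed": len(b_removed),
            "a_contaminant_fraction": _contaminant_fraction(a_kept),
            "b_contaminant_fraction": _contaminant_fraction(b_kept),
        }
    )
    state.a_set = a_kept
    state.b_set = b_kept
    state.cycle_index = i + 1
    return state


def _cfg_dict(config: TrainConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)


@dataclass
class CleanupResult:
    states: dict[str, CommunicatorState]
    models: dict[str, TileClassifier]  # final communicator per class

    def purified(self, cls: str) -> list[Tile]:
        return self.states[cls].a_set


def run_cleanup(
    dataset: TileDataset,
    reference: ReferenceDataset,
    n_cycles: int,
    config: TrainConfig,
    target_classes: tuple[str, ...] = PARENCHYMAL_CLASSES,
    k: int = 20,
    subset_mode: str = "resample",
    seed: int = 0,
) -> CleanupResult:
    """Purify each target class independently against the reference.

    The A-image subset is fixed at initialization (its tile set shrinks
    monotonically); the B-image subset is redrawn each cycle from the
    class's remaining images (``subset_mode="resample"``, default) or fixed
    (``"fixed"``).  Returns per-class states and the final communicator of
    each class (Communicator 2 of the last cycle).
    """
    if n_cycles < 1:
        raise ConfigError("n_cycles must be >= 1")
    if subset_mode not in ("resample", "fixed"):
        raise ConfigError(f"unknown subset_mode {subset_mode!r}")
    by_image = dataset.by_image()
    states: dict[str, CommunicatorState] = {}
    models: dict[str, TileClassifier] = {}
    master = np.random.default_rng(seed)
    for cls in target_classes:
        cls_images = sorted(
            {t.image_id for t in dataset.tiles if t.label == cls}
        )
        sub_seed = int(master.integers(0, 2**31 - 1))
        a_imgs, b_imgs = select_image_subsets(cls_images, k=k, seed=sub_seed)
        state = CommunicatorState(
            target_class=cls,
            a_images=a_imgs,
            a_set=[t for im in a_imgs for t in by_image[im]],
        )
        non_a = [im for im in cls_images if im not in set(a_imgs)]
        for cyc in range(n_cycles):
            if subset_mode == "resample" and cyc > 0:
                b_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
                b_imgs = list(
                    b_rng.choice(non_a, size=min(len(b_imgs), len(non_a)), replace=False)
                )
            b_tiles = [t for im in b_imgs for t in by_image[im]]
            cleanup_cycle(state, reference, _with_seed(config, master), b_tiles)
        states[cls] = state
        models[cls] = state.model_2
        log.info(
            "class %s purified: %d -> %d tiles over %d cycles",
            cls,
            state.discard_log[0]["a_in"],
            len(state.a_set),
            n_cycles,
        )
    return CleanupResult(states=states, models=models)


def _with_seed(config: TrainConfig, rng: np.random.Generator) -> TrainConfig:
    d = _cfg_dict(config)
    d["seed"] = int(rng.integers(0, 2**31 - 1))
    return TrainConfig(**d)


def final_sweep(
    models: dict[str, TileClassifier],
    dataset: TileDataset,
    threshold: float = 0.55,
) -> TileDataset:
    """Relabel every tile of every image with the final communicators.

    For a tile of parenchymal class L: if the top softmax of class-L's
    communicator is below ``threshold`` the tile is discarded as
    unclassifiable; if the predicted class is ADI or BG the tile is moved
    into that class; otherwise it keeps its label.  Non-parenchymal tiles
    pass through unchanged.  Tile counts are conserved per image
    (kept + moved + discarded = input).
    """
    if not 0 < threshold < 1:
        raise ConfigError("threshold must lie strictly between 0 and 1")
    out_tiles: list[Tile] = []
    by_label: dict[str, list[Tile]] = {}
    for t in dataset.tiles:
        by_label.setdefault(t.label, []).append(t)
    for label in sorted(by_label):
        tiles = by_label[label]
        if label not in models:
            out_tiles.extend(tiles)
            continue
        model = models[label]
        probs, pred = model.predict(tiles)
        for t, p, lab in zip(tiles, probs, pred):
            new = Tile(
                image_id=t.image_id,
                grid_row=t.grid_row,
                grid_col=t.grid_col,
                pixels=t.pixels,
                label=t.label,
                subject_id=t.subject_id,
                normalized=t.normalized,
                softmax=p,
                status=STATUS_KEPT,
                true_class=t.true_class,
            )
            if float(p.max()) < threshold:
                new.status = STATUS_DISCARDED
            elif lab == "ADI":
                new.status = STATUS_MOVED_ADI
                new.label = "ADI"
            elif lab == "BG":
                new.status = STATUS_MOVED_BG
                new.label = "BG"
            out_tiles.append(new)
    return TileDataset(tiles=out_tiles, classes=dataset.classes, split=dict(dataset.split))


def conservation_check(before: TileDataset, after: TileDataset) -> dict[str, bool]:
    """Per-image audit that kept + moved + discarded counts equal the input
    tile count; returns image_id -> ok."""
    b = {k: len(v) for k, v in before.by_image().items()}
    a = {k: len(v) for k, v in after.by_image().items()}
    return {im: a.get(im, 0) == n for im, n in b.items()}


def sweep_summary(after: TileDataset) -> dict[str, int]:
    out: dict[str, int] = {}
    for t in after.tiles:
        out[t.status] = out.get(t.status, 0) + 1
    return out
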