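"""End-to-end synthetic study harness.

These routines wire the generator, preprocessing, communicator loop,
training harness and scores into the experiments the package is built
around: planted-contamination recovery, cleaned-vs-raw retraining, score
validation against synthetic expert annotations, and cross-input-size
label transfer.  They are the substance behind the worked examples and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .communicator import (
    CleanupResult,
    ReferenceDataset,
    conservation_check,
    final_sweep,
    run_cleanup,
)
from .datatypes import (
    CLASSES,
    CONTAMINANT_CLASSES,
    PARENCHYMAL_CLASSES,
    STATUS_DISCARDED,
    STATUS_KEPT,
    ImageRecord,
    Tile,
    TileDataset,
)
from .evaluation import (
    classification_score_vector,
    confusion_and_metrics,
    four_score,
    three_score,
)
from .models import TileClassifier
from .preprocessing import center_crop, map_tiles, tile_image, transfer_crop_labels
from .stain import normalize_stain, normalize_tiles
from .synthetic import (
    DEFAULT_SPECS,
    SyntheticCohortConfig,
    ValidationCohortConfig,
    cohort_to_dataset,
    generate_cohort,
    generate_validation_cohort,
    render_tile,
)
from .training import DESK_CONFIG, TrainConfig, apply_split, fit, make_splits


def _normalized_views(
    images: list[ImageRecord], truth, tile_size: int
) -> tuple[TileDataset, TileDataset]:
    """Per-tile-normalized and in-toto-normalized tilings of one cohort."""
    raw = cohort_to_dataset(images, truth, tile_size)
    per_tile = TileDataset(
        tiles=normalize_tiles(raw.tiles), classes=raw.classes, split=dict(raw.split)
    )
    in_toto_images = [
        ImageRecord(
            im.image_id,
            im.subject_id,
            im.class_label,
            normalize_stain(im.pixels),
            im.magnification,
            im.provenance,
        )
        for im in images
    ]
    in_toto = cohort_to_dataset(in_toto_images, truth, tile_size)
    return per_tile, in_toto


@dataclass
class PurificationOutcome:
    contaminant_removal: float  # fraction of planted ADI/BG tiles removed
    false_removal: float  # fraction of true parenchymal tiles removed
    per_cycle_contaminant: dict[str, list[float]]  # A-set audit per class
    conservation_ok: bool
    swept: TileDataset  # per-tile view after the final sweep
    in_toto: TileDataset  # in-toto view with transferred statuses
    cleanup: CleanupResult


def purification_experiment(
    seed: int,
    cohort: Optional[SyntheticCohortConfig] = None,
    n_cycles: int = 3,
    config: TrainConfig = DESK_CONFIG,
    threshold: float = 0.55,
    k: int = 20,
) -> PurificationOutcome:
    """Full purification run on one synthetic cohort, audited against the
    hidden truth table.

    Generates a contaminated cohort, stain-normalizes tiles (both per-tile
    and in-toto views, mapped one-to-one), purifies each parenchymal class
    with the communicator loop, applies the final threshold sweep, and
    transfers statuses to the in-toto view.
    """
    cohort = cohort or SyntheticCohortConfig(seed=seed)
    if cohort.seed != seed:
        cohort = replace(cohort, seed=seed)
    images, truth = generate_cohort(cohort)
    per_tile, in_toto = _normalized_views(images, truth, cohort.tile_size)

    reference = ReferenceDataset(
        tiles=[t for t in per_tile.tiles if t.label in CONTAMINANT_CLASSES]
    )
    parenchymal = TileDataset(
        tiles=[t for t in per_tile.tiles if t.label in PARENCHYMAL_CLASSES],
        classes=per_tile.classes,
    )
    cleanup = run_cleanup(
        parenchymal, reference, n_cycles=n_cycles, config=config, k=k, seed=seed
    )
    swept = final_sweep(cleanup.models, per_tile, threshold=threshold)
    conservation = all(conservation_check(per_tile, swept).values())

    corr = map_tiles(swept, in_toto)
    corr.transfer_status(source="a")

    planted = [
        t
        for t in swept.tiles
        if t.true_class in CONTAMINANT_CLASSES
        and t.image_id.split("_")[0] in PARENCHYMAL_CLASSES
    ]
    true_parenchymal = [
        t
        for t in swept.tiles
        if t.true_class in PARENCHYMAL_CLASSES and t.true_class == t.image_id.split("_")[0]
    ]
    removal = (
        sum(t.status != STATUS_KEPT for t in planted) / len(planted)
        if planted
        else float("nan")
    )
    false_removal = sum(t.status != STATUS_KEPT for t in true_parenchymal) / len(
        true_parenchymal
    )
    per_cycle = {
        cls: [rec["a_contaminant_fraction"] for rec in st.discard_log]
        for cls, st in cleanup.states.items()
    }
    return PurificationOutcome(
        contaminant_removal=removal,
        false_removal=false_removal,
        per_cycle_contaminant=per_cycle,
        conservation_ok=conservation,
        swept=swept,
        in_toto=in_toto,
        cleanup=cleanup,
    )


@dataclass
class RetrainOutcome:
    baseline_weighted_f1: float
    cleaned_weighted_f1: float
    cleaned_accuracy: float
    baseline_accuracy: float


def cleaned_vs_baseline_experiment(
    seed: int,
    cohort: Optional[SyntheticCohortConfig] = None,
    n_cycles: int = 3,
    config: TrainConfig = DESK_CONFIG,
    threshold: float = 0.55,
) -> RetrainOutcome:
    """Retrain on communicator-cleaned vs raw contaminated labels.

    Subjects are split 80/10/10; purification sees only non-test subjects.
    The baseline mirrors the pre-clean-up setting: a three-class model
    trained on the raw parenchymal labels, which has no ADI/BG vocabulary
    and therefore must assign planted fat/background tiles a tissue label.
    The cleaned model trains on the swept five-class dataset (moved tiles
    relabeled, unclassifiable tiles dropped).  Both are scored against the
    hidden truth on the same held-out test tiles from parenchymal images.
    """
    cohort = cohort or SyntheticCohortConfig(seed=seed)
    if cohort.seed != seed:
        cohort = replace(cohort, seed=seed)
    images, truth = generate_cohort(cohort)
    raw = cohort_to_dataset(images, truth, cohort.tile_size)
    dataset = TileDataset(
        tiles=normalize_tiles(raw.tiles), classes=raw.classes
    )
    plan = make_splits(dataset, seed=seed)
    apply_split(dataset, plan)

    non_test = TileDataset(
        tiles=[
            t
            for t in dataset.tiles
            if dataset.split.get(t.subject_id) != "test"
            and t.label in PARENCHYMAL_CLASSES
        ],
        classes=dataset.classes,
    )
    reference = ReferenceDataset(
        tiles=[
            t
            for t in dataset.tiles
            if dataset.split.get(t.subject_id) != "test"
            and t.label in CONTAMINANT_CLASSES
        ]
    )
    cleanup = run_cleanup(
        non_test, reference, n_cycles=n_cycles, config=config, seed=seed
    )
    swept = final_sweep(cleanup.models, dataset, threshold=threshold)
    swept.split = dict(dataset.split)

    test_tiles = [
        t for t in dataset.of_split("test") if t.label in PARENCHYMAL_CLASSES
    ]
    y_true = [t.true_class for t in test_tiles]

    cfg = replace(config, seed=seed)
    base_train = [
        t for t in dataset.of_split("train") if t.label in PARENCHYMAL_CLASSES
    ]
    base_val = [t for t in dataset.of_split("val") if t.label in PARENCHYMAL_CLASSES]
    base_model, _ = fit(base_train, base_val, cfg)
    _, base_pred = base_model.predict(test_tiles)
    base_rep = confusion_and_metrics(y_true, base_pred, CLASSES)

    cleaned_train = [
        t for t in swept.of_split("train") if t.status != STATUS_DISCARDED
    ]
    cleaned_val = [t for t in swept.of_split("val") if t.status != STATUS_DISCARDED]
    clean_model, _ = fit(cleaned_train, cleaned_val, cfg)
    _, clean_pred = clean_model.predict(test_tiles)
    clean_rep = confusion_and_metrics(y_true, clean_pred, CLASSES)

    return RetrainOutcome(
        baseline_weighted_f1=base_rep.weighted["f1"],
        cleaned_weighted_f1=clean_rep.weighted["f1"],
        cleaned_accuracy=clean_rep.accuracy,
        baseline_accuracy=base_rep.accuracy,
    )


@dataclass
class ValidationScores:
    three_components: dict[str, float]
    three: float
    four: float
    m: dict[str, float]


def validation_scores(
    model: TileClassifier,
    seed: int,
    config: Optional[ValidationCohortConfig] = None,
) -> ValidationScores:
    """Score a trained five-class model on a grouped synthetic validation
    cohort: three-score over its parenchymal images and four-score against
    the exact expert fractions."""
    config = config or ValidationCohortConfig(seed=seed)
    images, truth, expert = generate_validation_cohort(config)
    groups: dict[str, str] = {}
    vectors: dict[str, np.ndarray] = {}
    for im in images:
        tiles = normalize_tiles(tile_image(im, config.tile_size))
        _, labels = model.predict(tiles)
        vectors[im.image_id] = classification_score_vector(labels, CLASSES)
        groups[im.image_id] = im.class_label
    expert_vec = {
        r["image_id"]: np.array([r[c] for c in CLASSES])
        for _, r in expert.iterrows()
    }
    parenchymal = {i: g for i, g in groups.items() if g in PARENCHYMAL_CLASSES}
    comps, agg = three_score(parenchymal, vectors, CLASSES)
    fs = four_score(groups, vectors, expert_vec, CLASSES)
    return ValidationScores(
        three_components=comps, three=agg, four=fs.fourscore, m=fs.m
    )


@dataclass
class CrossSizeOutcome:
    n_parents: int
    n_labeled: int  # parents that received a crop label
    transfer_loss: int  # parents left unlabeled (should be 0)
    inception_val_accuracy: float


def cross_size_transfer_experiment(
    seed: int,
    n_per_class: int = 8,
    parent_size: int = 299,
    crop_size: int = 224,
) -> CrossSizeOutcome:
    """Label 299-tile parents through their 224 center crops and train a
    299-native backbone on the transferred labels.

    Crops are classified by a small model trained on crop-sized renders;
    labels propagate to parents by grid coordinates; an ``inception_small``
    head then trains on the labeled parents (smoke-level epochs).
    """
    rng = np.random.default_rng([seed, 299])
    parents: list[Tile] = []
    for cls in CLASSES:
        for i in range(n_per_class):
            t = render_tile(
                DEFAULT_SPECS[cls], seed=int(rng.integers(0, 2**31 - 1)), size=parent_size
            )
            t.image_id = f"X_{cls}_{i:02d}"
            t.subject_id = f"SX_{cls}_{i:02d}"
            parents.append(t)

    # trainer for the crop-sized communicating classifier
    crop_train, crop_val = [], []
    for cls in CLASSES:
        for i in range(20):
            t = render_tile(
                DEFAULT_SPECS[cls], seed=int(rng.integers(0, 2**31 - 1)), size=crop_size
            )
            (crop_val if i < 4 else crop_train).append(t)
    cfg = replace(DESK_CONFIG, seed=seed)
    crop_model, _ = fit(crop_train, crop_val, cfg)

    crops = [center_crop(t, crop_size) for t in parents]
    _, labels = crop_model.predict(crops)
    for c, lab in zip(crops, labels):
        c.label = lab
    for p in parents:
        p.label = ""  # labels must arrive via the transfer, not the render
    transfer_crop_labels(crops, parents)
    unlabeled = sum(1 for p in parents if not p.label)

    # stratified by transferred label so validation never sees a class
    # absent from training
    by_label: dict[str, list[Tile]] = {}
    for p in parents:
        by_label.setdefault(p.label, []).append(p)
    train_p, val_p = [], []
    for lab in sorted(by_label):
        group = by_label[lab]
        order = rng.permutation(len(group))
        n_val = len(group) // 5 if len(group) >= 5 else 0
        for j, i in enumerate(order):
            (val_p if j < n_val else train_p).append(group[i])
    if not val_p:
        val_p = train_p[:5]
    cfg299 = replace(cfg, backbone="inception_small")
    model299, _ = fit(train_p, val_p, cfg299)
    _, pred = model299.predict(val_p)
    acc = float(np.mean([p == t.true_class for p, t in zip(pred, val_p)]))
    return CrossSizeOutcome(
        n_parents=len(parents),
        n_labeled=len(parents) - unlabeled,
        transfer_loss=unlabeled,
        inception_val_accuracy=acc,
    )
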