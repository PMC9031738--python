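"""Procedural H&E-like textures, contaminated cohorts, and expert annotations.

The generator emulates the structure of a tissue-microarray tile study
without any real slides: each of the five classes gets a parametric texture
(noise plus geometric primitives) whose mean color and spatial statistics
make the classes controllably separable on CPU.  Parenchymal images (HLN,
HP, PDAC) are mosaics in which a known fraction of tile positions is
replaced by adipose or background texture — the planted label noise that
the communicator loop is meant to remove.  Every tile carries a hidden true
class, emitted as a sidecar manifest, never embedded in pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from .datatypes import (
    CLASSES,
    CONTAMINANT_CLASSES,
    PARENCHYMAL_CLASSES,
    ImageRecord,
    Tile,
    TileDataset,
)
from .errors import ConfigError
from .preprocessing import tile_image

log = logging.getLogger(__name__)

STRUCTURES = (
    "dense_dots",
    "acinar_blobs",
    "irregular_ducts",
    "white_circles",
    "near_white_noise",
)


@dataclass(frozen=True)
class TextureSpec:
    """Parametric texture for one tissue class.

    ``base_color`` is the background RGB; ``structure`` selects the geometric
    primitive; ``noise_sd`` is additive Gaussian pixel noise in 8-bit
    intensity units; ``seed`` individualizes the class texture stream.
    """

    class_name: str
    base_color: tuple[int, int, int]
    structure: str
    noise_sd: float = 6.0
    seed: int = 0
    #: BG only: post-noise clip floor keeping every channel mean above it
    white_floor: int = 235

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ConfigError(
                f"unknown structure {self.structure!r}; expected one of {STRUCTURES}"
            )


#: Default texture for each class.  HLN: densely packed dark nuclei on a
#: purple field; HP: acinar blobs on pink; PDAC: irregular duct-like rings
#: on pale stroma; ADI: near-white fat vacuoles with thin darker rims;
#: BG: near-white glass with faint noise.
DEFAULT_SPECS: dict[str, TextureSpec] = {
    "HLN": TextureSpec("HLN", (168, 136, 192), "dense_dots", seed=11),
    "HP": TextureSpec("HP", (214, 150, 178), "acinar_blobs", seed=22),
    "PDAC": TextureSpec("PDAC", (206, 170, 196), "irregular_ducts", seed=33),
    "ADI": TextureSpec("ADI", (244, 241, 244), "white_circles", seed=44),
    "BG": TextureSpec("BG", (248, 248, 246), "near_white_noise", noise_sd=3.0, seed=55),
}


def _disk_mask(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _ring_mask(size: int, cy: float, cx: float, r: float, w: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return (d2 <= (r + w) ** 2) & (d2 >= max(r - w, 0.5) ** 2)


def _paint(canvas: np.ndarray, mask: np.ndarray, color: np.ndarray) -> None:
    canvas[mask] = color


def render_tile(spec: TextureSpec, seed: int, size: int = 224) -> Tile:
    """Render one deterministic RGB tile for ``spec``.

    Identical (spec, seed, size) triples render bit-identical pixel arrays.
    The hidden true class of the returned tile is ``spec.class_name``.
    """
    rng = np.random.default_rng([abs(spec.seed), abs(seed), size])
    canvas = np.ones((size, size, 3), dtype=np.float64) * np.array(
        spec.base_color, dtype=np.float64
    )
    area = size * size

    if spec.structure == "dense_dots":
        n = max(8, area // 110)  # dense nuclear field
        dark = np.array(spec.base_color, dtype=np.float64) * 0.45
        for _ in range(n):
            cy, cx = rng.uniform(0, size, 2)
            r = rng.uniform(size / 55 + 0.6, size / 28 + 1.2)
            _paint(canvas, _disk_mask(size, cy, cx, r), dark)
    elif spec.structure == "acinar_blobs":
        n = max(4, area // 700)
        blob = np.array([166, 104, 148], dtype=np.float64)
        for _ in range(n):
            cy, cx = rng.uniform(0, size, 2)
            r0 = rng.uniform(size / 16, size / 8)
            for _ in range(rng.integers(4, 8)):  # cluster of acinar cells
                ang = rng.uniform(0, 2 * np.pi)
                _paint(
                    canvas,
                    _disk_mask(
                        size,
                        cy + r0 * np.sin(ang),
                        cx + r0 * np.cos(ang),
                        rng.uniform(size / 26 + 0.8, size / 14 + 1.0),
                    ),
                    blob * rng.uniform(0.92, 1.08),
                )
    elif spec.structure == "irregular_ducts":
        n = max(3, area // 1500)
        rim = np.array([122, 82, 142], dtype=np.float64)
        lumen = np.array([236, 228, 236], dtype=np.float64)
        for _ in range(n):
            cy, cx = rng.uniform(0, size, 2)
            r = rng.uniform(size / 12, size / 5)
            w = rng.uniform(size / 40 + 0.8, size / 18 + 1.0)
            _paint(canvas, _disk_mask(size, cy, cx, max(r - w, 1.0)), lumen)
            _paint(canvas, _ring_mask(size, cy, cx, r, w), rim * rng.uniform(0.9, 1.1))
    elif spec.structure == "white_circles":
        n = max(4, area // 900)
        fill = np.array([251, 249, 251], dtype=np.float64)
        rim = np.array([205, 198, 208], dtype=np.float64)
        for _ in range(n):  # fat vacuoles: white disks, thin darker rims
            cy, cx = rng.uniform(0, size, 2)
            r = rng.uniform(size / 14, size / 6)
            _paint(canvas, _disk_mask(size, cy, cx, r), fill)
            _paint(canvas, _ring_mask(size, cy, cx, r, max(size / 110, 1.0)), rim)
    elif spec.structure == "near_white_noise":
        pass  # noise-only glass background

    canvas += rng.normal(0.0, spec.noise_sd, canvas.shape)
    if spec.structure == "near_white_noise":
        canvas = np.clip(canvas, spec.white_floor, 255.0)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return Tile(
        image_id="",
        grid_row=0,
        grid_col=0,
        pixels=pixels,
        label=spec.class_name,
        true_class=spec.class_name,
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for a synthetic tile cohort.

    Defaults are the desk-scale conditions used throughout the test suite:
    32 px tiles on 128 px mosaics (16 tile positions per image), 16 images
    per class, one subject per image, and a planted ADI/BG contamination
    rate of 0.25 inside parenchymal images.
    """

    n_images_per_class: int = 16
    image_size: int = 128
    tile_size: int = 32
    contamination_rate: float = 0.25
    n_subjects: Optional[int] = None  # None -> one subject per image
    seed: int = 0
    specs: dict[str, TextureSpec] = field(default_factory=lambda: dict(DEFAULT_SPECS))
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        if not 0 <= self.contamination_rate < 1:
            raise ConfigError("contamination_rate must lie in [0, 1)")
        if self.image_size % self.tile_size != 0:
            raise ConfigError("image_size must be a multiple of tile_size")
        if self.n_images_per_class < 1:
            raise ConfigError("n_images_per_class must be >= 1")


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[ImageRecord], pd.DataFrame]:
    """Generate mosaic images and their hidden tile-level truth table.

    Returns ``(images, truth)`` where ``truth`` has one row per tile
    position with columns (image_id, subject_id, grid_row, grid_col,
    image_class, true_class).  In each parenchymal image, exactly
    ``round(contamination_rate * n_positions)`` positions hold a texture
    drawn uniformly from {ADI, BG}; pure-class images are untouched.
    """
    rng = np.random.default_rng(config.seed)
    g = config.image_size // config.tile_size
    images: list[ImageRecord] = []
    rows: list[dict] = []
    image_index = 0
    for cls in config.classes:
        for i in range(config.n_images_per_class):
            image_id = f"{cls}_{i:03d}"
            if config.n_subjects is None:
                subject_id = f"S_{cls}_{i:03d}"
            else:
                subject_id = f"S_{image_index % config.n_subjects:03d}"
            truth_grid = np.full((g, g), cls, dtype=object)
            if cls in PARENCHYMAL_CLASSES and config.contamination_rate > 0:
                n_contam = int(round(config.contamination_rate * g * g))
                pos = rng.choice(g * g, size=n_contam, replace=False)
                for p in pos:
                    truth_grid[p // g, p % g] = rng.choice(CONTAMINANT_CLASSES)
            canvas = np.empty(
                (config.image_size, config.image_size, 3), dtype=np.uint8
            )
            for r in range(g):
                for c in range(g):
                    true_cls = truth_grid[r, c]
                    t = render_tile(
                        config.specs[true_cls],
                        seed=int(rng.integers(0, 2**31 - 1)),
                        size=config.tile_size,
                    )
                    s = config.tile_size
                    canvas[r * s : (r + 1) * s, c * s : (c + 1) * s] = t.pixels
                    rows.append(
                        {
                            "image_id": image_id,
                            "subject_id": subject_id,
                            "grid_row": r,
                            "grid_col": c,
                            "image_class": cls,
                            "true_class": true_cls,
                        }
                    )
            images.append(
                ImageRecord(
                    image_id=image_id,
                    subject_id=subject_id,
                    class_label=cls,
                    pixels=canvas,
                    magnification="20x",
                    provenance="synthetic",
                )
            )
            image_index += 1
    return images, pd.DataFrame(rows)


def generate_expert_annotation(
    images: list[ImageRecord], truth: pd.DataFrame
) -> pd.DataFrame:
    """Per-image class-fraction vectors, the stand-in for regional expert
    annotation: for every image the exact fraction of its tile positions
    whose true class is each of the five classes (rows sum to 1)."""
    recs = []
    for img in images:
        sub = truth[truth["image_id"] == img.image_id]
        if len(sub) == 0:
            raise ConfigError(f"image {img.image_id} missing from truth table")
        frac = sub["true_class"].value_counts(normalize=True)
        row = {"image_id": img.image_id, "group": img.class_label}
        for c in CLASSES:
            row[c] = float(frac.get(c, 0.0))
        recs.append(row)
    return pd.DataFrame(recs)


@dataclass(frozen=True)
class ValidationCohortConfig:
    """Validation images scored by the four-score.

    Group sizes default to the small whole-slide validation cohort layout
    of the TMA study setting (HP 3, PDAC 15, HLN 5, LNPM 6).  LNPM images
    are lymph-node mosaics in which a fraction ``metastasis_range`` of tile
    positions carries PDAC texture.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HP": 3, "PDAC": 15, "HLN": 5, "LNPM": 6}
    )
    image_size: int = 128
    tile_size: int = 32
    contamination_rate: float = 0.1
    metastasis_range: tuple[float, float] = (0.25, 0.6)
    seed: int = 0
    specs: dict[str, TextureSpec] = field(default_factory=lambda: dict(DEFAULT_SPECS))


def generate_validation_cohort(
    config: ValidationCohortConfig,
) -> tuple[list[ImageRecord], pd.DataFrame, pd.DataFrame]:
    """Generate grouped validation images plus truth and expert annotation.

    Returns ``(images, truth, expert)``; ``expert`` is the exact per-image
    class-fraction table (``generate_expert_annotation`` of the truth).
    """
    rng = np.random.default_rng([config.seed, 7919])
    g = config.image_size // config.tile_size
    images: list[ImageRecord] = []
    rows: list[dict] = []
    for group, n in config.n_per_group.items():
        base_cls = "HLN" if group == "LNPM" else group
        for i in range(n):
            image_id = f"VAL_{group}_{i:03d}"
            subject_id = f"SV_{group}_{i:03d}"
            truth_grid = np.full((g, g), base_cls, dtype=object)
            if group == "LNPM":
                met = rng.uniform(*config.metastasis_range)
                n_met = max(1, int(round(met * g * g)))
                for p in rng.choice(g * g, size=n_met, replace=False):
                    truth_grid[p // g, p % g] = "PDAC"
            if base_cls in PARENCHYMAL_CLASSES and config.contamination_rate > 0:
                free = [
                    (r, c)
                    for r in range(g)
                    for c in range(g)
                    if truth_grid[r, c] == base_cls
                ]
                n_contam = int(round(config.contamination_rate * g * g))
                idx = rng.choice(len(free), size=min(n_contam, len(free)), replace=False)
                for j in idx:
                    truth_grid[free[j]] = rng.choice(CONTAMINANT_CLASSES)
            canvas = np.empty(
                (config.image_size, config.image_size, 3), dtype=np.uint8
            )
            s = config.tile_size
            for r in range(g):
                for c in range(g):
                    t = render_tile(
                        config.specs[truth_grid[r, c]],
                        seed=int(rng.integers(0, 2**31 - 1)),
                        size=s,
                    )
                    canvas[r * s : (r + 1) * s, c * s : (c + 1) * s] = t.pixels
                    rows.append(
                        {
                            "image_id": image_id,
                            "subject_id": subject_id,
                            "grid_row": r,
                            "grid_col": c,
                            "image_class": group,
                            "true_class": truth_grid[r, c],
                        }
                    )
            images.append(
                ImageRecord(image_id, subject_id, group, canvas, "20x", "synthetic")
            )
    truth = pd.DataFrame(rows)
    expert = generate_expert_annotation(images, truth)
    return images, truth, expert


def cohort_to_dataset(
    images: list[ImageRecord],
    truth: pd.DataFrame,
    tile_size: int,
    classes: tuple[str, ...] = CLASSES,
) -> TileDataset:
    """Tile every image and attach hidden truth, yielding a TileDataset whose
    working labels are the (possibly wrong) image-level labels."""
    lookup = {
        (r.image_id, r.grid_row, r.grid_col): r.true_class
        for r in truth.itertuples()
    }
    tiles: list[Tile] = []
    for img in images:
        for t in tile_image(img, tile_size):
            t.true_class = lookup.get(t.key)
            tiles.append(t)
    return TileDataset(tiles=tiles, classes=classes)


def write_cohort(
    directory: str | Path,
    images: list[ImageRecord],
    truth: pd.DataFrame,
    expert: Optional[pd.DataFrame] = None,
) -> None:
    """Write images as PNG plus truth/annotation CSV sidecar manifests."""
    directory = Path(directory)
    img_dir = directory / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    meta = []
    for img in images:
        Image.fromarray(img.pixels).save(img_dir / f"{img.image_id}.png")
        meta.append(
            {
                "image_id": img.image_id,
                "subject_id": img.subject_id,
                "class_label": img.class_label,
                "magnification": img.magnification,
                "provenance": img.provenance,
            }
        )
    pd.DataFrame(meta).to_csv(directory / "images.csv", index=False)
    truth.to_csv(directory / "truth.csv", index=False)
    if expert is not None:
        expert.to_csv(directory / "expert.csv", index=False)


def read_cohort(directory: str | Path) -> tuple[list[ImageRecord], pd.DataFrame]:
    """Load a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "images.csv")
    truth = pd.read_csv(directory / "truth.csv")
    images = []
    for r in meta.itertuples():
        pixels = np.asarray(Image.open(directory / "images" / f"{r.image_id}.png"))
        images.append(
            ImageRecord(
                r.image_id, r.subject_id, r.class_label, pixels,
                r.magnification, r.provenance,
            )
        )
    return images, truth
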