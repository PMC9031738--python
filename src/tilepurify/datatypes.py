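"""Core containers for tile-based histopathology workflows.

The class vocabulary follows the pancreatic TMA setting: three parenchymal
tissue classes (HLN healthy lymph node, HP healthy pancreas, PDAC pancreatic
ductal adenocarcinoma) plus two contaminant classes commonly present on
slides (ADI adipose tissue, BG background/glass).  ``CLASSES`` fixes the
canonical class order used by every score vector and confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CLASSES: tuple[str, ...] = ("HLN", "HP", "PDAC", "ADI", "BG")
PARENCHYMAL_CLASSES: tuple[str, ...] = ("HLN", "HP", "PDAC")
CONTAMINANT_CLASSES: tuple[str, ...] = ("ADI", "BG")
#: validation image groups scored by the four-score (LNPM = lymph node with
#: PDAC metastasis; scored on its PDAC fraction)
VALIDATION_GROUPS: tuple[str, ...] = ("HLN", "HP", "PDAC", "LNPM")

STATUS_KEPT = "kept"
STATUS_DISCARDED = "discarded_unclassifiable"
STATUS_MOVED_ADI = "moved_to_ADI"
STATUS_MOVED_BG = "moved_to_BG"
STATUS_REMOVED_CUTOFF = "removed_pixel_cutoff"
STATUSES = (
    STATUS_KEPT,
    STATUS_DISCARDED,
    STATUS_MOVED_ADI,
    STATUS_MOVED_BG,
    STATUS_REMOVED_CUTOFF,
)


@dataclass(eq=False)
class ImageRecord:
    """One source image: a TMA spot, a whole-slide crop, or a synthetic mosaic."""

    image_id: str
    subject_id: str
    class_label: str
    pixels: np.ndarray  # H x W x 3 uint8
    magnification: str = "20x"  # "20x" | "40x"
    provenance: str = "synthetic"  # "tma_spot" | "wsi" | "synthetic"

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(eq=False)
class Tile:
    """One square patch cut from an image on a non-overlapping grid.

    ``label`` is the working label (initially inherited from the image);
    ``true_class`` is the hidden oracle label available only for synthetic
    data; ``status`` records the purification outcome.
    """

    image_id: str
    grid_row: int
    grid_col: int
    pixels: np.ndarray  # S x S x 3 uint8
    label: str
    subject_id: str = ""
    normalized: bool = False
    softmax: Optional[np.ndarray] = None
    status: str = STATUS_KEPT
    true_class: Optional[str] = None

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def origin_xy(self) -> tuple[int, int]:
        """(x, y) of the tile's top-left corner in the resized image frame."""
        s = self.size
        return (self.grid_col * s, self.grid_row * s)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.image_id, self.grid_row, self.grid_col)

    @property
    def tile_id(self) -> str:
        return f"{self.image_id}:{self.grid_row}:{self.grid_col}"


@dataclass(eq=False)
class TileDataset:
    """A labeled tile collection with a subject-level split assignment.

    ``classes`` is the ordered class list: index i of every score vector and
    confusion-matrix axis refers to ``classes[i]``.  ``split`` maps
    subject_id -> "train" | "val" | "test"; a subject never appears in more
    than one split.
    """

    tiles: list[Tile]
    classes: tuple[str, ...] = CLASSES
    split: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tiles)

    def labels(self) -> list[str]:
        return [t.label for t in self.tiles]

    def by_image(self) -> dict[str, list[Tile]]:
        out: dict[str, list[Tile]] = {}
        for t in self.tiles:
            out.setdefault(t.image_id, []).append(t)
        return out

    def of_split(self, name: str) -> list[Tile]:
        return [t for t in self.tiles if self.split.get(t.subject_id) == name]

    def of_label(self, label: str) -> list[Tile]:
        return [t for t in self.tiles if t.label == label]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for t in self.tiles:
            counts[t.label] = counts.get(t.label, 0) + 1
        return counts


def tile_stack(tiles: list[Tile]) -> np.ndarray:
    """Stack tile pixels into an (N, S, S, 3) uint8 array; sizes must agree."""
    if not tiles:
        raise ValueError("empty tile list")
    sizes = {t.size for t in tiles}
    if len(sizes) != 1:
        raise ValueError(f"mixed tile sizes: {sorted(sizes)}")
    return np.stack([t.pixels for t in tiles])
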