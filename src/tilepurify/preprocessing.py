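"""Image-to-tile conversion conventions.

Covers the resize-at-40x rule, non-overlapping grid tiling with discarded
edge remainders, the bright-tile pixel cutoff, center cropping between the
224 and 299 input-size families, and the bijective mapping between per-tile
and in-toto normalized representations of the same grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .datatypes import ImageRecord, Tile, TileDataset, STATUS_REMOVED_CUTOFF
from .errors import DataError

log = logging.getLogger(__name__)


def resize_half(image: ImageRecord) -> ImageRecord:
    """Downscale a 40x image to 50% linear size (floor dimensions, bilinear);
    20x images pass through unchanged."""
    if image.magnification != "40x":
        return image
    h, w = image.height // 2, image.width // 2
    out = _sk_resize(
        image.pixels, (h, w), order=1, anti_aliasing=False, preserve_range=True
    )
    return ImageRecord(
        image_id=image.image_id,
        subject_id=image.subject_id,
        class_label=image.class_label,
        pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        magnification="20x",
        provenance=image.provenance,
    )


def tile_image(image: ImageRecord, size: int) -> list[Tile]:
    """Cut a non-overlapping grid of full ``size`` x ``size`` tiles.

    Partial edge remainders are discarded.  Tiles inherit the image's class
    label.  An image smaller than ``size`` yields an empty list (logged).
    """
    if size <= 0:
        raise DataError("tile size must be positive")
    n_rows, n_cols = image.height // size, image.width // size
    if n_rows == 0 or n_cols == 0:
        log.info("image %s smaller than tile size %d: 0 tiles", image.image_id, size)
        return []
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            tiles.append(
                Tile(
                    image_id=image.image_id,
                    grid_row=r,
                    grid_col=c,
                    pixels=image.pixels[
                        r * size : (r + 1) * size, c * size : (c + 1) * size
                    ].copy(),
                    label=image.class_label,
                    subject_id=image.subject_id,
                )
            )
    return tiles


def pixel_cutoff_filter(
    tiles: list[Tile], cutoff: float = 239.0, statistic: str = "mean"
) -> tuple[list[Tile], list[Tile]]:
    """Partition tiles into (kept, removed) by brightness.

    With the default ``statistic="mean"`` a tile is removed iff its mean
    intensity over all pixels and channels exceeds ``cutoff``.  The
    alternative ``"bright_fraction"`` removes tiles in which more than half
    of the pixels have mean channel intensity above the cutoff.  Removed
    tiles get status ``removed_pixel_cutoff``.
    """
    kept, removed = [], []
    for t in tiles:
        if statistic == "mean":
            bright = float(t.pixels.mean()) > cutoff
        elif statistic == "bright_fraction":
            bright = float((t.pixels.mean(axis=2) > cutoff).mean()) > 0.5
        else:
            raise DataError(f"unknown cutoff statistic {statistic!r}")
        if bright:
            t.status = STATUS_REMOVED_CUTOFF
            removed.append(t)
        else:
            kept.append(t)
    return kept, removed


def center_crop(tile: Tile, size: int = 224) -> Tile:
    """Center-crop a tile to ``size`` (299 -> 224 uses offset 37 on both axes).

    The crop keeps the parent's grid coordinates so that labels/statuses
    decided on the crop can be transferred back to the parent.
    """
    s = tile.size
    if s < size:
        raise DataError(f"tile of size {s} cannot be cropped to {size}")
    if s == size:
        return tile
    off = (s - size) // 2
    return Tile(
        image_id=tile.image_id,
        grid_row=tile.grid_row,
        grid_col=tile.grid_col,
        pixels=tile.pixels[off : off + size, off : off + size].copy(),
        label=tile.label,
        subject_id=tile.subject_id,
        normalized=tile.normalized,
        status=tile.status,
        true_class=tile.true_class,
    )


def transfer_crop_labels(crops: list[Tile], parents: list[Tile]) -> None:
    """Propagate label/status decided on center crops to their parent tiles,
    matched by (image_id, grid_row, grid_col)."""
    by_key = {t.key: t for t in parents}
    for c in crops:
        p = by_key.get(c.key)
        if p is None:
            raise DataError(f"crop {c.tile_id} has no parent tile")
        p.label = c.label
        p.status = c.status
        p.softmax = c.softmax


@dataclass
class TileCorrespondence:
    """Bijection between two tilings of the same grid, keyed by
    (image_id, grid_row, grid_col)."""

    pairs: dict[tuple[str, int, int], tuple[Tile, Tile]]

    def __len__(self) -> int:
        return len(self.pairs)

    def transfer_status(self, source: str = "a") -> None:
        """Copy label/status/softmax from one side to the other
        (``source`` = "a" or "b")."""
        for ta, tb in self.pairs.values():
            src, dst = (ta, tb) if source == "a" else (tb, ta)
            dst.label = src.label
            dst.status = src.status
            dst.softmax = src.softmax


def map_tiles(a: TileDataset, b: TileDataset) -> TileCorrespondence:
    """One-to-one correspondence between two datasets tiled on identical
    grids (e.g. per-tile-normalized vs in-toto-normalized pixels).

    Raises :class:`DataError` naming the offending image on any mismatch.
    """
    ka = {t.key: t for t in a.tiles}
    kb = {t.key: t for t in b.tiles}
    if set(ka) != set(kb):
        diff = set(ka).symmetric_difference(kb)
        image = sorted({k[0] for k in diff})[0]
        raise DataError(f"tile grids differ for image {image!r}")
    return TileCorrespondence({k: (ka[k], kb[k]) for k in ka})
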