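"""CSV tile manifests and tile-pixel bundles.

Manifests record bookkeeping only (coordinates are 0-based, half-open,
(row, col) grid order); pixels travel separately as PNG class directories
or a single NPZ bundle keyed by tile id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .datatypes import Tile, TileDataset
from .errors import DataError

MANIFEST_COLUMNS = [
    "image_id",
    "subject_id",
    "grid_row",
    "grid_col",
    "label",
    "status",
    "split",
    "true_class",
]


def dataset_to_manifest(dataset: TileDataset) -> pd.DataFrame:
    rows = []
    for t in dataset.tiles:
        rows.append(
            {
                "image_id": t.image_id,
                "subject_id": t.subject_id,
                "grid_row": t.grid_row,
                "grid_col": t.grid_col,
                "label": t.label,
                "status": t.status,
                "split": dataset.split.get(t.subject_id, ""),
                "true_class": t.true_class if t.true_class is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_manifest(dataset: TileDataset, path: str | Path) -> None:
    dataset_to_manifest(dataset).to_csv(path, index=False)


def write_tile_bundle(dataset: TileDataset, path: str | Path) -> None:
    """Single-file NPZ bundle of tile pixels keyed by tile id."""
    arrays = {t.tile_id: t.pixels for t in dataset.tiles}
    np.savez_compressed(path, **arrays)


def read_dataset(
    manifest_path: str | Path, bundle_path: str | Path, classes: tuple[str, ...]
) -> TileDataset:
    df = pd.read_csv(manifest_path, keep_default_na=False)
    bundle = np.load(bundle_path)
    tiles = []
    split: dict[str, str] = {}
    for r in df.itertuples():
        tid = f"{r.image_id}:{r.grid_row}:{r.grid_col}"
        if tid not in bundle:
            raise DataError(f"tile {tid} missing from pixel bundle")
        tiles.append(
            Tile(
                image_id=r.image_id,
                grid_row=int(r.grid_row),
                grid_col=int(r.grid_col),
                pixels=bundle[tid],
                label=r.label,
                subject_id=r.subject_id,
                status=r.status or "kept",
                true_class=r.true_class or None,
            )
        )
        if r.split:
            split[r.subject_id] = r.split
    return TileDataset(tiles=tiles, classes=classes, split=split)


def write_tile_pngs(tiles: list[Tile], directory: str | Path) -> None:
    """Tile pixels as PNG files in class-named directories (the layout of
    common public tile collections)."""
    directory = Path(directory)
    for t in tiles:
        d = directory / t.label
        d.mkdir(parents=True, exist_ok=True)
        Image.fromarray(t.pixels).save(
            d / f"{t.image_id}_{t.grid_row}_{t.grid_col}.png"
        )
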