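"""Patch-label overlays and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .datatypes import STATUS_DISCARDED, STATUS_REMOVED_CUTOFF, ImageRecord, Tile
from .errors import DataError

#: fixed class palette: HLN yellow, HP red, PDAC blue, BG grey, ADI cyan
PALETTE: dict[str, tuple[int, int, int]] = {
    "HLN": (255, 255, 0),
    "HP": (255, 0, 0),
    "PDAC": (0, 0, 255),
    "BG": (128, 128, 128),
    "ADI": (0, 255, 255),
}

_UNCOLORED = (STATUS_DISCARDED, STATUS_REMOVED_CUTOFF)


def render_overlay(
    image: ImageRecord,
    tiles: list[Tile],
    palette: dict[str, tuple[int, int, int]] = PALETTE,
    opacity: float = 0.45,
) -> np.ndarray:
    """Blend per-tile class colors over the source image.

    Each kept/moved tile is tinted with its label's palette color at the
    given opacity; discarded and cutoff-removed tiles stay uncolored.
    Output dimensions equal the source dimensions.
    """
    out = image.pixels.astype(np.float64).copy()
    for t in tiles:
        if t.image_id != image.image_id or t.status in _UNCOLORED:
            continue
        if t.label not in palette:
            raise DataError(f"no palette color for label {t.label!r}")
        color = np.array(palette[t.label], dtype=np.float64)
        s = t.size
        r0, c0 = t.grid_row * s, t.grid_col * s
        region = out[r0 : r0 + s, c0 : c0 + s]
        out[r0 : r0 + s, c0 : c0 + s] = (1.0 - opacity) * region + opacity * color
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def save_overlay(overlay: np.ndarray, path: str | Path) -> None:
    Image.fromarray(overlay).save(path)


def write_run_manifest(path: str | Path, entries: dict) -> None:
    """Machine-readable run log: seeds, configs, versions, artifact paths."""
    from . import __version__

    payload = {"tilepurify_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
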