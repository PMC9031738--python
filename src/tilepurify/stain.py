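"""Macenko-style H&E stain normalization.

Stain vectors are estimated per image by SVD on the optical density of
non-background pixels; stain concentrations are rescaled so that their 99th
percentiles match a fixed reference profile, and the image is re-rendered
with the reference stain matrix.  Mapping every slide to one profile removes
batch-to-batch staining variation before tiles are fed to classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import Tile

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StainProfile:
    """Reference H&E stain matrix (columns = hematoxylin, eosin unit vectors
    in OD space) and reference 99th-percentile concentrations."""

    stain_matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.5626, 0.2159], [0.7201, 0.8012], [0.4062, 0.5581]]
        )
    )
    max_concentration: np.ndarray = field(
        default_factory=lambda: np.array([1.9705, 1.0308])
    )


DEFAULT_PROFILE = StainProfile()

_IO = 255.0  # transmitted light intensity


def _optical_density(pixels: np.ndarray) -> np.ndarray:
    return -np.log((pixels.astype(np.float64) + 1.0) / (_IO + 1.0))


def estimate_stain_matrix(
    pixels: np.ndarray, beta: float = 0.15, alpha: float = 1.0
) -> np.ndarray | None:
    """Estimate the 3x2 H&E stain matrix of one image, or None when too few
    tissue pixels (all-white input) are available."""
    od = _optical_density(pixels).reshape(-1, 3)
    norms = np.linalg.norm(od, axis=1)
    # adaptive L2 mask: threshold tracks the stained-pixel distribution so
    # the same tissue pixels are selected under global intensity scaling
    thr = max(beta, 0.2 * float(np.percentile(norms, 90)))
    tissue = od[norms > thr]
    if tissue.shape[0] < 30:
        return None
    # plane spanned by the two dominant eigenvectors of the OD scatter
    _, eigvec = np.linalg.eigh(np.cov(tissue.T))
    v = eigvec[:, 1:3]
    proj = tissue @ v
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, alpha), np.percentile(phi, 100 - alpha)
    v1 = v @ np.array([np.cos(lo), np.sin(lo)])
    v2 = v @ np.array([np.cos(hi), np.sin(hi)])
    v1 *= np.sign(v1.sum()) or 1.0
    v2 *= np.sign(v2.sum()) or 1.0
    # hematoxylin first: larger red-channel OD component
    he = np.array([v1, v2]).T if v1[0] > v2[0] else np.array([v2, v1]).T
    return he


def normalize_stain(
    pixels: np.ndarray,
    reference: StainProfile = DEFAULT_PROFILE,
    beta: float = 0.15,
) -> np.ndarray:
    """Normalize one RGB image/tile to the reference stain profile.

    Near-empty (all-white) inputs with no estimable stain vectors are
    returned unchanged with a logged warning.
    """
    he = estimate_stain_matrix(pixels, beta=beta)
    if he is None:
        log.warning("no tissue pixels for stain estimation; returning input unchanged")
        return pixels
    od = _optical_density(pixels).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(he, od.T, rcond=None)
    conc = np.maximum(conc, 0.0)  # physical stains cannot have negative amounts
    max_c = np.percentile(conc, 99, axis=1)
    max_c[max_c <= 1e-8] = 1e-8
    conc *= (reference.max_concentration / max_c)[:, None]
    out = (_IO + 1.0) * np.exp(-reference.stain_matrix @ conc) - 1.0
    out = np.clip(np.rint(out.T.reshape(pixels.shape)), 0, 255).astype(np.uint8)
    return out


def normalize_tiles(
    tiles: list[Tile], reference: StainProfile = DEFAULT_PROFILE
) -> list[Tile]:
    """Per-tile stain normalization; returns new Tile objects flagged
    ``normalized`` with otherwise identical bookkeeping."""
    out = []
    for t in tiles:
        out.append(
            Tile(
                image_id=t.image_id,
                grid_row=t.grid_row,
                grid_col=t.grid_col,
                pixels=normalize_stain(t.pixels, reference),
                label=t.label,
                subject_id=t.subject_id,
                normalized=True,
                status=t.status,
                true_class=t.true_class,
            )
        )
    return out
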