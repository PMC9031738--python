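"""Tile- and image-level evaluation scores.

One-vs-rest confusion metrics
    For class i, TP/FP/TN/FN are counted with i as positive and all other
    classes pooled as negative.  Precision = TP/(TP+FP), recall =
    TP/(TP+FN), F1 = 2TP/(2TP+FP+FN), Jaccard = TP/(TP+FP+FN), accuracy =
    trace/total.  Macro averages are unweighted means; weighted averages
    are support-weighted.  Zero-denominator cases score 0 and are flagged.

Classification score vector
    For one image with M patches, c_i = (#patches predicted class i)/M, so
    the entries are the predicted per-class tile fractions and sum to 1.
    The image label is argmax(c) with ties resolved to the lowest class
    index.

Three-score
    Mean, over the test images of each parenchymal class, of the correct
    class's score-vector entry; aggregated as the mean of the three class
    components.

Four-score
    Validation images are grouped (HLN, HP, PDAC, LNPM; LNPM images are
    scored on their PDAC fraction).  For group i, m_i is the absolute gap
    between the model's average scored-class fraction over the group's N_i
    images and the expert-annotated average p_i; fourscore = 1 - (1/4) Σ
    m_i.  The per-image gap terms are averaged over the N_i images so that
    m_i is a fraction comparable with p_i regardless of group size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix as _sk_confusion,
    jaccard_score,
    precision_recall_fscore_support,
)

from .datatypes import PARENCHYMAL_CLASSES, VALIDATION_GROUPS
from .errors import DataError

log = logging.getLogger(__name__)

#: model class whose fraction is scored within each validation group;
#: metastatic lymph nodes are scored on detected PDAC
GROUP_SCORED_CLASS = {"HLN": "HLN", "HP": "HP", "PDAC": "PDAC", "LNPM": "PDAC"}


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def jaccard_from_precision_recall(precision: float, recall: float) -> float:
    """J = PR/(P+R-PR), the intersection-over-union implied by (P, R)."""
    denom = precision + recall - precision * recall
    if denom == 0:
        return 0.0
    return precision * recall / denom


def jaccard_from_f1(f1: float) -> float:
    """J = F1/(2-F1); exact identity on count data."""
    return f1 / (2.0 - f1) if f1 < 2.0 else 1.0


@dataclass
class MetricsReport:
    confusion: np.ndarray  # rows = true, cols = predicted
    per_class: pd.DataFrame  # precision, recall, f1, jaccard, support
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]
    zero_division_classes: list[str]
    classes: tuple[str, ...]


def confusion_and_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str],
) -> MetricsReport:
    """Confusion matrix plus per-class one-vs-rest metrics and averages."""
    if len(y_true) == 0:
        raise DataError("empty evaluation input")
    if len(y_true) != len(y_pred):
        raise DataError("label lists differ in length")
    classes = tuple(classes)
    cm = _sk_confusion(y_true, y_pred, labels=list(classes))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(classes), zero_division=0
    )
    jac = jaccard_score(
        y_true, y_pred, labels=list(classes), average=None, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "jaccard": jac,
            "support": support,
        },
        index=list(classes),
    )
    zero_div = [
        classes[i]
        for i in range(len(classes))
        if cm[:, i].sum() == 0 or cm[i, :].sum() == 0
    ]
    total = support.sum()
    weights = support / total if total else np.zeros_like(support, dtype=float)
    macro = {
        k: float(per_class[k].mean()) for k in ("precision", "recall", "f1", "jaccard")
    }
    weighted = {
        k: float((per_class[k].to_numpy() * weights).sum())
        for k in ("precision", "recall", "f1", "jaccard")
    }
    return MetricsReport(
        confusion=cm,
        per_class=per_class,
        accuracy=float(accuracy_score(y_true, y_pred)),
        macro=macro,
        weighted=weighted,
        zero_division_classes=zero_div,
        classes=classes,
    )


def classification_score_vector(
    patch_labels: Sequence[str], classes: Sequence[str]
) -> np.ndarray:
    """Per-class predicted tile fractions of one image (sums to 1)."""
    if len(patch_labels) == 0:
        raise DataError("image yielded no tiles; score vector undefined")
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    c = np.zeros(len(classes))
    for p in patch_labels:
        try:
            c[idx[p]] += 1
        except KeyError:
            raise DataError(f"patch label {p!r} not in class list") from None
    return c / len(patch_labels)


def image_label(c: np.ndarray, classes: Sequence[str]) -> str:
    """Argmax image label; ties resolve to the lowest class index (logged)."""
    c = np.asarray(c, dtype=float)
    top = c.max()
    if int((c == top).sum()) > 1:
        log.info("image-label tie at score %.4f; lowest class index wins", top)
    return tuple(classes)[int(c.argmax())]


def three_score(
    image_classes: Mapping[str, str],
    score_vectors: Mapping[str, np.ndarray],
    classes: Sequence[str],
) -> tuple[dict[str, float], float]:
    """Per-class mean correct-label fraction over parenchymal test images.

    Returns ``(components, aggregate)`` where ``components[k]`` is the mean
    over class-k images of the score vector's k entry and the aggregate is
    the mean of the available components.  A class with zero images is
    excluded with a warning.
    """
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    components: dict[str, float] = {}
    for cls in PARENCHYMAL_CLASSES:
        ids = [i for i, c in image_classes.items() if c == cls]
        if not ids:
            log.warning("three-score: no images of class %s; component excluded", cls)
            continue
        components[cls] = float(
            np.mean([score_vectors[i][idx[cls]] for i in ids])
        )
    if not components:
        raise DataError("three-score undefined: no parenchymal images")
    return components, float(np.mean(list(components.values())))


@dataclass
class FourScoreReport:
    """Per-group gaps m_i between model and expert average fractions, the
    averages themselves, group sizes, and fourscore = 1 - mean(m_i)."""

    m: dict[str, float]
    model_avg: dict[str, float]
    expert_avg: dict[str, float]
    n_images: dict[str, int]
    fourscore: float


def four_score(
    image_groups: Mapping[str, str],
    score_vectors: Mapping[str, np.ndarray],
    expert_fractions: Mapping[str, np.ndarray],
    classes: Sequence[str],
    scored_class: Mapping[str, str] = GROUP_SCORED_CLASS,
    exclude: Iterable[str] = (),
) -> FourScoreReport:
    """Four-score of model predictions against expert per-image fractions.

    ``image_groups`` maps image_id -> group in {HLN, HP, PDAC, LNPM};
    ``score_vectors`` and ``expert_fractions`` map image_id -> vectors over
    ``classes``.  Images in ``exclude`` (insufficient labeling) are dropped
    before averaging.  Raises :class:`DataError` listing any empty group.
    """
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    excluded = set(exclude)
    m: dict[str, float] = {}
    model_avg: dict[str, float] = {}
    expert_avg: dict[str, float] = {}
    n_images: dict[str, int] = {}
    missing = []
    for group in VALIDATION_GROUPS:
        ids = [
            i for i, g in image_groups.items() if g == group and i not in excluded
        ]
        if not ids:
            missing.append(group)
            continue
        k = idx[scored_class[group]]
        mod = float(np.mean([score_vectors[i][k] for i in ids]))
        exp = float(np.mean([expert_fractions[i][k] for i in ids]))
        m[group] = abs(mod - exp)
        model_avg[group] = mod
        expert_avg[group] = exp
        n_images[group] = len(ids)
    if missing:
        raise DataError(f"four-score groups without images: {missing}")
    fourscore = 1.0 - float(np.mean([m[g] for g in VALIDATION_GROUPS]))
    return FourScoreReport(
        m=m,
        model_avg=model_avg,
        expert_avg=expert_avg,
        n_images=n_images,
        fourscore=fourscore,
    )
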