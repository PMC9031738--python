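"""Independent brute-force tallies used as oracles against the evaluation
module.  Deliberately written with plain loops and no shared code."""

import numpy as np


def brute_confusion(y_true, y_pred, classes):
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def brute_class_metrics(y_true, y_pred, cls):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    jaccard = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    support = tp + fn
    return precision, recall, f1, jaccard, support


def brute_accuracy(y_true, y_pred):
    return sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)


def brute_score_vector(labels, classes):
    return np.array([sum(1 for p in labels if p == c) for c in classes]) / len(labels)


def brute_three_score(image_classes, vectors, classes):
    comps = {}
    for cls in ("HLN", "HP", "PDAC"):
        vals = [
            vectors[i][classes.index(cls)]
            for i, c in image_classes.items()
            if c == cls
        ]
        if vals:
            comps[cls] = sum(vals) / len(vals)
    return comps, sum(comps.values()) / len(comps)


def brute_four_score(groups, vectors, expert, classes, scored):
    ms = []
    for g in ("HLN", "HP", "PDAC", "LNPM"):
        ids = [i for i, gg in groups.items() if gg == g]
        k = classes.index(scored[g])
        mod = sum(vectors[i][k] for i in ids) / len(ids)
        exp = sum(expert[i][k] for i in ids) / len(ids)
        ms.append(abs(mod - exp))
    return 1.0 - sum(ms) / 4.0
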