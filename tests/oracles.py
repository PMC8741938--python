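"""Independent reference implementations (oracles) used by the tests.

Each function recomputes a quantity by brute force or enumeration,
deliberately avoiding the package's own code paths.
"""

import numpy as np
import pandas as pd


def brute_force_youden(scores, labels):
    """Exhaustive threshold search for the Youden-optimal cutoff."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    distinct = np.sort(np.unique(scores))
    candidates = [distinct[0]] + [
        (lo + hi) / 2.0 for lo, hi in zip(distinct[:-1], distinct[1:])
    ]
    best = None
    for c in candidates:
        tp = sum(1 for s, l in zip(scores, labels) if s >= c and l == 1)
        fn = sum(1 for s, l in zip(scores, labels) if s < c and l == 1)
        tn = sum(1 for s, l in zip(scores, labels) if s < c and l == 0)
        fp = sum(1 for s, l in zip(scores, labels) if s >= c and l == 0)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if best is None or j > best[1] + 1e-12:
            best = (c, j)
    return best


def oracle_match(gt, det: pd.DataFrame) -> pd.DataFrame:
    """Greedy claiming matcher, written independently of the package."""
    order = det.sort_values(
        ["confidence", "row", "col"], ascending=[False, True, True], kind="mergesort"
    )
    claimed, labels = set(), []
    for _, d in order.iterrows():
        lab = int(gt[int(d.row), int(d.col)]) if gt is not None else 0
        if lab > 0 and lab not in claimed:
            claimed.add(lab)
            labels.append(True)
        else:
            labels.append(False)
    return order.assign(is_tp=labels)


def oracle_froc(images, fp_targets=(1, 2, 4, 8, 16, 32)):
    """Exhaustive confidence sweep, re-matching from scratch per threshold."""
    confs = sorted(
        {c for im in images for c in im.detections["confidence"].tolist()}, reverse=True
    )
    n_benign = sum(im.is_benign for im in images)
    n_gt = sum(im.n_gt for im in images)
    points = []
    for t in confs:
        tp = fp_benign = 0
        for im in images:
            sub = im.detections[im.detections["confidence"] >= t]
            m = oracle_match(im.gt_labels, sub)
            tp += int(m.is_tp.sum())
            if im.is_benign:
                fp_benign += int((~m.is_tp).sum())
        points.append((t, tp / n_gt, fp_benign / n_benign))
    recalls = []
    for f in fp_targets:
        ok = [(t, r) for t, r, m in points if m <= f]
        recalls.append(max((r for _, r in ok), default=0.0))
    return float(np.mean(recalls)), points
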