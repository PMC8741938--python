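"""FROC evaluation of point detections against instance masks.

The detector emits cell-centre points with confidences.  A detection is a
true positive when its point falls inside a ground-truth instance that no
higher-confidence detection has already claimed (greedy claiming in
descending confidence order; each instance is claimed at most once).
False positives on *benign* images — tumour-free fields — define the
false-positive axis: at a confidence threshold t, "Nor FPs" is the mean
number of retained false positives per benign image.

The FROC score is the mean instance-level recall at the thresholds where
Nor FPs first reaches each operating point in {1, 2, 4, 8, 16, 32}: for
each target the operating point with the largest recall among those with
mean benign FPs <= target is used (recall 0 when even the strictest
threshold overshoots; the all-detections recall when the target is never
reached).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvalImage",
    "FrocResult",
    "DEFAULT_FP_TARGETS",
    "match_detections",
    "froc_curve",
]

DEFAULT_FP_TARGETS = (1, 2, 4, 8, 16, 32)


@dataclass
class EvalImage:
    """One evaluation field: GT instance labels, benign flag, detections.

    ``detections`` has columns ``row``, ``col``, ``confidence``.
    Benign images must carry zero GT instances.
    """

    image_id: str
    gt_labels: Optional[np.ndarray]
    detections: pd.DataFrame
    is_benign: bool = False

    def __post_init__(self) -> None:
        n_gt = self.n_gt
        if self.is_benign and n_gt > 0:
            raise ValueError(f"{self.image_id}: benign image has {n_gt} GT instances")
        conf = self.detections["confidence"].to_numpy(float) if len(self.detections) else np.empty(0)
        if conf.size and ((conf < 0) | (conf > 1)).any():
            raise ValueError(f"{self.image_id}: confidences outside [0, 1]")

    @property
    def n_gt(self) -> int:
        if self.gt_labels is None:
            return 0
        labs = np.unique(self.gt_labels)
        return int((labs > 0).sum())


def match_detections(
    gt_labels: Optional[np.ndarray],
    detections: pd.DataFrame,
    criterion: str = "center-in-mask",
) -> pd.DataFrame:
    """Label each detection TP/FP by greedy claiming in confidence order.

    Returns the detections sorted by descending confidence with added
    columns ``is_tp`` and ``gt_id`` (claimed instance, 0 for FPs).
    Greediness makes the labels threshold-stable: the labels of the
    detections above any confidence threshold equal the labels obtained
    by matching only those detections.
    """
    if criterion != "center-in-mask":
        raise ValueError(f"unknown matching criterion {criterion!r}")
    det = detections.sort_values(
        ["confidence", "row", "col"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    is_tp = np.zeros(len(det), dtype=bool)
    gt_id = np.zeros(len(det), dtype=int)
    if gt_labels is not None and len(det):
        claimed: set[int] = set()
        rows = det["row"].to_numpy(float)
        cols = det["col"].to_numpy(float)
        shape = gt_labels.shape
        for i in range(len(det)):
            r, c = int(rows[i]), int(cols[i])
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                continue
            lab = int(gt_labels[r, c])
            if lab > 0 and lab not in claimed:
                claimed.add(lab)
                is_tp[i] = True
                gt_id[i] = lab
    det["is_tp"] = is_tp
    det["gt_id"] = gt_id
    return det


@dataclass
class FrocResult:
    """Operating points and their average recall (the FROC score)."""

    points: pd.DataFrame  # fp_target, threshold, recall, mean_fps
    froc: float
    n_gt: int = 0
    n_benign: int = 0

    def to_dict(self) -> dict:
        return {
            "froc": self.froc,
            "n_gt": self.n_gt,
            "n_benign": self.n_benign,
            "points": self.points.to_dict(orient="records"),
        }


def froc_curve(
    dataset: Sequence[EvalImage],
    fp_targets: Sequence[float] = DEFAULT_FP_TARGETS,
) -> FrocResult:
    """Sweep all distinct confidences and average recall at the FP targets."""
    n_benign = sum(im.is_benign for im in dataset)
    total_gt = sum(im.n_gt for im in dataset)
    if n_benign == 0:
        raise ValueError("FROC needs >= 1 benign image to define Nor FPs")
    if total_gt == 0:
        raise ValueError("FROC needs >= 1 ground-truth instance overall")

    conf_list, tp_list, benign_fp_list = [], [], []
    for im in dataset:
        matched = match_detections(im.gt_labels, im.detections)
        if len(matched) == 0:
            continue
        conf_list.append(matched["confidence"].to_numpy(float))
        tp_list.append(matched["is_tp"].to_numpy(bool))
        benign_fp_list.append(
            (~matched["is_tp"].to_numpy(bool)) & im.is_benign
        )

    if conf_list:
        conf = np.concatenate(conf_list)
        tp = np.concatenate(tp_list)
        benign_fp = np.concatenate(benign_fp_list)
        order = np.argsort(-conf, kind="mergesort")
        conf, tp, benign_fp = conf[order], tp[order], benign_fp[order]
        cum_tp = np.cumsum(tp)
        cum_bfp = np.cumsum(benign_fp)
        # operating point at each distinct confidence = last index with that conf
        last = np.flatnonzero(np.diff(conf, append=-np.inf) != 0)
        thresholds = conf[last]
        recalls = cum_tp[last] / total_gt
        mean_fps = cum_bfp[last] / n_benign
    else:
        thresholds = np.empty(0)
        recalls = np.empty(0)
        mean_fps = np.empty(0)

    rows = []
    chosen = []
    for f in fp_targets:
        ok = np.flatnonzero(mean_fps <= f)
        if ok.size:
            i = int(ok[-1])  # lowest admissible threshold -> largest recall
            rows.append(
                {
                    "fp_target": float(f),
                    "threshold": float(thresholds[i]),
                    "recall": float(recalls[i]),
                    "mean_fps": float(mean_fps[i]),
                }
            )
            chosen.append(float(recalls[i]))
        else:
            # even the strictest threshold yields too many benign FPs
            rows.append(
                {"fp_target": float(f), "threshold": np.inf, "recall": 0.0, "mean_fps": 0.0}
            )
            chosen.append(0.0)
    points = pd.DataFrame(rows)
    froc = float(np.mean(chosen)) if chosen else 0.0
    return FrocResult(points=points, froc=froc, n_gt=total_gt, n_benign=n_benign)
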