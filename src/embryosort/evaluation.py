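"""Object-detection scoring: greedy IoU matching, precision/recall, AP, mAP.

Matching follows the standard single-class convention: within each frame,
detections are processed in descending confidence; a detection is a true
positive if its best-IoU not-yet-matched ground-truth box reaches the IoU
threshold (that box is then consumed), otherwise a false positive;
leftover ground-truth boxes are false negatives. Average precision is the
exact area under the precision envelope of the confidence-ranked PR curve
(all-point interpolation, no sampling grid). mAP@0.5:0.95 averages AP over
the ten thresholds 0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detector import BoundingBox, FrameDetections, iou, read_detections

__all__ = [
    "GroundTruthSet",
    "EvalReport",
    "match_detections",
    "average_precision",
    "map_range",
    "load_ground_truth_dir",
    "load_detections_dir",
]

MAP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))

GroundTruthSet = dict[int, list[BoundingBox]]


@dataclass
class EvalReport:
    """Detection metrics; precision/recall are at IoU 0.5, no conf cutoff."""

    precision: float
    recall: float
    ap_by_threshold: dict[float, float]
    map50: float
    map5095: float
    n_ground_truth: int = 0
    n_detections: int = 0

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "precision": self.precision,
                "recall": self.recall,
                "map50": self.map50,
                "map5095": self.map5095,
                "ap_by_threshold": {f"{k:.2f}": v for k, v in self.ap_by_threshold.items()},
                "n_ground_truth": self.n_ground_truth,
                "n_detections": self.n_detections,
            },
            **{"indent": 2, **kwargs},
        )


@dataclass
class MatchResult:
    """Per-detection TP/FP flags (confidence-sorted) and FN counts."""

    confidences: np.ndarray  # descending, across all frames
    tp_flags: np.ndarray  # bool, aligned with confidences
    n_false_negatives: int
    fn_per_frame: dict[int, int] = field(default_factory=dict)


def match_detections(
    preds: list[FrameDetections], gts: GroundTruthSet, iou_thr: float
) -> MatchResult:
    """Greedily match detections to ground truth at one IoU threshold."""
    if not 0.0 < iou_thr < 1.0:
        raise ValueError(f"iou_thr must be in (0,1), got {iou_thr}")
    records: list[tuple[float, bool]] = []
    fn_per_frame: dict[int, int] = {}
    pred_frames = {fd.frame_index for fd in preds}
    for fd in preds:
        gt_boxes = list(gts.get(fd.frame_index, []))
        consumed = [False] * len(gt_boxes)
        for det in sorted(fd.detections, key=lambda d: -d.confidence):
            best_iou, best_j = 0.0, -1
            for j, gt in enumerate(gt_boxes):
                if consumed[j]:
                    continue
                v = iou(det.box, gt)
                if v > best_iou:
                    best_iou, best_j = v, j
            if best_j >= 0 and best_iou >= iou_thr:
                consumed[best_j] = True
                records.append((det.confidence, True))
            else:
                records.append((det.confidence, False))
        fn_per_frame[fd.frame_index] = consumed.count(False)
    # ground-truth frames with no prediction entry contribute pure FNs
    for fidx, boxes in gts.items():
        if fidx not in pred_frames:
            fn_per_frame[fidx] = len(boxes)
    records.sort(key=lambda r: -r[0])
    conf = np.array([r[0] for r in records], dtype=float)
    tp = np.array([r[1] for r in records], dtype=bool)
    return MatchResult(
        confidences=conf,
        tp_flags=tp,
        n_false_negatives=sum(fn_per_frame.values()),
        fn_per_frame=fn_per_frame,
    )


def average_precision(
    preds: list[FrameDetections], gts: GroundTruthSet, iou_thr: float
) -> float:
    """Exact-envelope AP at one IoU threshold.

    All detections are ranked by descending confidence across frames; the
    PR curve's precision envelope is integrated over recall exactly. The
    recall denominator is the total ground-truth box count, which must be
    positive.
    """
    n_gt = sum(len(b) for b in gts.values())
    if n_gt == 0:
        raise ValueError("average_precision undefined with zero ground-truth boxes")
    result = match_detections(preds, gts, iou_thr)
    tp = result.tp_flags.astype(float)
    if tp.size == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope: max precision at any recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def map_range(preds: list[FrameDetections], gts: GroundTruthSet) -> EvalReport:
    """Full report: AP at each threshold in 0.50:0.95, mAP, precision, recall."""
    ap_by_thr = {
        float(thr): average_precision(preds, gts, float(thr)) for thr in MAP_THRESHOLDS
    }
    map50 = ap_by_thr[0.5]
    map5095 = float(np.mean(list(ap_by_thr.values())))
    m = match_detections(preds, gts, 0.5)
    n_det = int(m.tp_flags.size)
    n_tp = int(m.tp_flags.sum())
    n_gt = sum(len(b) for b in gts.values())
    precision = n_tp / n_det if n_det else 0.0
    recall = n_tp / n_gt if n_gt else 0.0
    return EvalReport(
        precision=precision,
        recall=recall,
        ap_by_threshold=ap_by_thr,
        map50=map50,
        map5095=map5095,
        n_ground_truth=n_gt,
        n_detections=n_det,
    )


def _load_dir(path: Path, image_w: int, image_h: int) -> list[FrameDetections]:
    files = sorted(path.glob("frame_*.txt"))
    out = []
    for f in files:
        idx = int(f.stem.split("_")[-1])
        out.append(read_detections(f, image_w, image_h, frame_index=idx))
    return out


def load_detections_dir(
    path: str | Path, image_w: int, image_h: int
) -> list[FrameDetections]:
    """Load a directory of frame_%06d.txt detection files."""
    return _load_dir(Path(path), image_w, image_h)


def load_ground_truth_dir(
    path: str | Path, image_w: int, image_h: int
) -> GroundTruthSet:
    """Load ground truth from the same text dialect (confidence ignored)."""
    return {
        fd.frame_index: [d.box for d in fd.detections]
        for fd in _load_dir(Path(path), image_w, image_h)
    }
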