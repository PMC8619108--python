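"""Detection and tracking evaluation.

Two separate protocols, matching how keypoint detectors and
multi-object trackers are scored in the livestock-monitoring
literature:

* **Detection**: around every annotated shoulder point a circular
  detection region is drawn whose radius is the frame's mean
  shoulder-to-ear distance.  Exactly one predicted point inside a
  region is a true positive; extra points inside a region and points
  inside no region are false positives; an empty region is a false
  negative.  From the counts: sensitivity = TP/(TP+FN),
  precision = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN).

* **Tracking**: Multiple Object Tracking Accuracy,
  ``MOTA = 1 - (FP_T + FN_T + IDSW) / N``, where FP_T are tracker
  points matching no animal (including points placed too far from
  their animal), FN_T are animals with no tracker point, IDSW counts
  identity-switch events, and N is the number of points evaluated.
  IDSW is counted CLEAR-MOT style: once per change of the
  truth-to-track identity mapping, not per frame of the wrong mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .pose import PigPose


# ---------------------------------------------------------------------------
# detection protocol

@dataclass
class DetectionEvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def n_annotated(self) -> int:
        """Number of annotated shoulder points (TP + FN)."""
        return self.tp + self.fn

    @property
    def sensitivity(self) -> float:
        return detection_metrics(self.tp, self.fp, self.fn)[0]

    @property
    def precision(self) -> float:
        return detection_metrics(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return detection_metrics(self.tp, self.fp, self.fn)[2]


def detection_region_radius(truth_frame: Sequence[PigPose]) -> float:
    """Mean shoulder-to-ear distance over all pigs and both ears."""
    dists = []
    for p in truth_frame:
        s = np.asarray(p.shoulder, float)
        for ear in (p.left_ear, p.right_ear):
            if ear is not None:
                dists.append(float(np.linalg.norm(s - np.asarray(ear, float))))
    if not dists:
        raise ValueError("detection region radius undefined: "
                         "no ear annotations in frame")
    return float(np.mean(dists))


def classify_detections(truth_frame: Sequence[PigPose],
                        predicted_shoulders: Sequence,
                        radius: Optional[float] = None
                        ) -> Tuple[int, int, int]:
    """Per-frame (TP, FP, FN) under the circular detection region rule.

    Each prediction is assigned to at most one region: the nearest
    region containing it, ties broken by lower truth index.  Per
    region, one assigned point is a TP, each extra one an FP, none an
    FN; predictions inside no region are FPs.
    """
    if radius is None:
        radius = detection_region_radius(truth_frame)
    truth = np.array([p.shoulder for p in truth_frame],
                     float).reshape(len(truth_frame), 2)
    hits = np.zeros(len(truth_frame), dtype=int)
    fp = 0
    for q in predicted_shoulders:
        q = np.asarray(q, float)
        if len(truth) == 0:
            fp += 1
            continue
        d = np.linalg.norm(truth - q[None, :], axis=1)
        inside = np.nonzero(d <= radius)[0]
        if len(inside) == 0:
            fp += 1
            continue
        k = inside[np.lexsort((inside, d[inside]))[0]]
        hits[k] += 1
    tp = int(np.count_nonzero(hits))
    fp += int(hits.sum()) - tp
    fn = len(truth_frame) - tp
    return tp, fp, fn


def evaluate_detections(truth_frames: Sequence[Sequence[PigPose]],
                        predicted_frames: Sequence[Sequence]
                        ) -> DetectionEvalResult:
    """Aggregate TP/FP/FN over a test set of frames."""
    tp = fp = fn = 0
    for truth, preds in zip(truth_frames, predicted_frames):
        t, f, n = classify_detections(truth, preds)
        tp, fp, fn = tp + t, fp + f, fn + n
    return DetectionEvalResult(tp=tp, fp=fp, fn=fn)


def detection_metrics(tp: int, fp: int, fn: int
                      ) -> Tuple[float, float, float]:
    """(sensitivity, precision, F1) from the detection counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("no annotated positives: sensitivity undefined")
    sens = tp / (tp + fn)
    prec = tp / (tp + fp) if tp + fp > 0 else 1.0
    f1 = 2 * tp / (2 * tp + fp + fn)
    return float(sens), float(prec), float(f1)


# ---------------------------------------------------------------------------
# tracking protocol

@dataclass
class TrackingEvalResult:
    fp: int
    fn: int
    idsw: int
    n_points: int
    # identity-switch events as (frame, truth_id, old_track_id, new_track_id)
    idsw_events: List[Tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def n_failures(self) -> int:
        return self.fp + self.fn + self.idsw

    @property
    def mota(self) -> float:
        return mota(self.fp, self.fn, self.idsw, self.n_points)


def mota(fp: int, fn: int, idsw: int, n: int) -> float:
    """Multiple Object Tracking Accuracy: 1 - (FP + FN + IDSW) / N."""
    if n <= 0:
        raise ValueError("MOTA undefined for a non-positive denominator")
    if min(fp, fn, idsw) < 0:
        raise ValueError("counts must be non-negative")
    return 1.0 - (fp + fn + idsw) / n


PointFrame = List[Tuple[int, float, float]]  # (id, x, y) per animal


def poses_to_point_frames(per_frame_poses: Sequence[Sequence[PigPose]]
                          ) -> List[PointFrame]:
    return [[(int(p.id), p.shoulder[0], p.shoulder[1]) for p in frame]
            for frame in per_frame_poses]


def tracks_to_point_frames(tracks, n_frames: int,
                           first_frame: int = 0) -> List[PointFrame]:
    out: List[PointFrame] = []
    for f in range(first_frame, n_frames):
        row: PointFrame = []
        for t in tracks:
            if t.has_frame(f):
                xy, _, _ = t.at(f)
                row.append((t.id, xy[0], xy[1]))
        out.append(row)
    return out


def classify_tracking(truth_frames: Sequence[PointFrame],
                      predicted_frames: Sequence[PointFrame],
                      loc_threshold: Optional[float] = None,
                      loc_thresholds: Optional[Sequence[float]] = None
                      ) -> TrackingEvalResult:
    """Automated FP/FN/IDSW counting over aligned frame sequences.

    Per frame, truth and tracker points are matched one-to-one by
    minimum total distance among pairs within the localisation
    threshold; unmatched truth points are FNs, unmatched tracker points
    (including matched-too-far ones, which the gating already excludes)
    are FPs.  An IDSW is counted whenever a truth identity's matched
    track id differs from the one it was last matched with.  The MOTA
    denominator is the number of truth points presented.

    ``loc_threshold`` is a scalar; ``loc_thresholds`` optionally gives a
    per-frame radius (e.g. the frame's detection-region radius).
    """
    if len(truth_frames) != len(predicted_frames):
        raise ValueError("truth and prediction must cover the same frames")
    if loc_threshold is None and loc_thresholds is None:
        raise ValueError("a localisation threshold is required")
    fp = fn = idsw = n_points = 0
    events: List[Tuple[int, int, int, int]] = []
    mapping: Dict[int, int] = {}
    for f, (truth, preds) in enumerate(zip(truth_frames, predicted_frames)):
        thr = loc_thresholds[f] if loc_thresholds is not None else loc_threshold
        n_points += len(truth)
        if not truth or not preds:
            fn += len(truth)
            fp += len(preds)
            continue
        T = np.array([(x, y) for (_, x, y) in truth], float)
        P = np.array([(x, y) for (_, x, y) in preds], float)
        cost = np.linalg.norm(T[:, None, :] - P[None, :, :], axis=2)
        gated = np.where(cost <= thr, cost, 1e9)
        rows, cols = linear_sum_assignment(gated)
        matched_t, matched_p = set(), set()
        changes: List[Tuple[int, int, int]] = []
        for r, c in zip(rows, cols):
            if cost[r, c] > thr:
                continue
            matched_t.add(r)
            matched_p.add(c)
            tid, pid = truth[r][0], preds[c][0]
            if tid in mapping and mapping[tid] != pid:
                changes.append((tid, mapping[tid], pid))
                events.append((f, tid, mapping[tid], pid))
            mapping[tid] = pid
        # a simultaneous pairwise identity exchange is one switch case,
        # not two: coalesce complementary changes within the frame
        used = [False] * len(changes)
        for i in range(len(changes)):
            if used[i]:
                continue
            used[i] = True
            for j in range(i + 1, len(changes)):
                if (not used[j] and changes[i][1] == changes[j][2]
                        and changes[i][2] == changes[j][1]):
                    used[j] = True
                    break
            idsw += 1
        fn += len(truth) - len(matched_t)
        fp += len(preds) - len(matched_p)
    return TrackingEvalResult(fp=fp, fn=fn, idsw=idsw, n_points=n_points,
                              idsw_events=events)
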