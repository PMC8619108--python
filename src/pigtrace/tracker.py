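"""Identity-stable multi-animal tracking of shoulder keypoints.

One constant-velocity Kalman filter per animal tracks the shoulder
point; per-frame detections are assigned to filter predictions by
minimum total Euclidean distance (Hungarian algorithm by default,
greedy nearest-first as an alternative).  The animal count is known and
fixed, so there is no track birth/death: tracking starts at the first
frame whose detection count equals the expected count.

Frames whose detection count differs from the expected count are
flagged *corrupted* and excluded from measurement: each filter is then
updated with its own previous estimate as a surrogate measurement under
strongly inflated measurement noise, which keeps the covariance
bookkeeping honest while effectively coasting on the motion model.
This mirrors how a filter should down-weight an unreliable detector —
when the input is suspect, the variance of the input signal is raised
so the prediction dominates the estimate.

State: ``(x, y, vx, vy)`` in pixels and pixels/frame.  At 10 fps pig
motion moves keypoints only a few pixels per frame, so the
constant-velocity model with modest process noise is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .pose import PigPose

# constant-velocity model matrices (dt = 1 frame)
F = np.array([[1., 0., 1., 0.],
              [0., 1., 0., 1.],
              [0., 0., 1., 0.],
              [0., 0., 0., 1.]])
H = np.array([[1., 0., 0., 0.],
              [0., 1., 0., 0.]])
# discrete white-noise acceleration covariance, unit intensity, dt = 1
_Q_UNIT = np.array([[0.25, 0.00, 0.50, 0.00],
                    [0.00, 0.25, 0.00, 0.50],
                    [0.50, 0.00, 1.00, 0.00],
                    [0.00, 0.50, 0.00, 1.00]])


@dataclass
class KalmanState:
    """Gaussian state belief of one animal's shoulder point."""

    x: np.ndarray                 # (4,) state mean
    P: np.ndarray                 # (4, 4) covariance
    last_update_frame: int = -1

    @property
    def position(self) -> np.ndarray:
        return self.x[:2].copy()

    @property
    def velocity(self) -> np.ndarray:
        return self.x[2:].copy()


def kf_init(position, frame: int = 0, pos_var: float = 10.0,
            vel_var: float = 25.0) -> KalmanState:
    """Initial belief: measured position, unknown (zero-mean) velocity."""
    x = np.array([position[0], position[1], 0.0, 0.0], float)
    P = np.diag([pos_var, pos_var, vel_var, vel_var]).astype(float)
    return KalmanState(x=x, P=P, last_update_frame=frame)


def kf_predict(s: KalmanState, process_noise: float = 1.0) -> KalmanState:
    """Propagate one frame ahead under the constant-velocity model."""
    x = F @ s.x
    P = F @ s.P @ F.T + process_noise * _Q_UNIT
    return KalmanState(x=x, P=P, last_update_frame=s.last_update_frame)


def kf_update(s: KalmanState, z, base_measurement_noise: float = 4.0,
              noise_scale: float = 1.0, frame: Optional[int] = None
              ) -> KalmanState:
    """Fuse a shoulder measurement ``z = (x, y)``.

    ``noise_scale`` multiplies the measurement covariance; a large scale
    makes the filter nearly ignore the measurement (the inflation used
    on corrupted frames), a tiny scale makes the posterior follow it.
    Non-finite measurements are treated as missing (no update).
    """
    z = np.asarray(z, float)
    if not np.all(np.isfinite(z)):
        return s
    R = base_measurement_noise * noise_scale * np.eye(2)
    y = z - H @ s.x
    S = H @ s.P @ H.T + R
    K = s.P @ H.T @ np.linalg.inv(S)
    x = s.x + K @ y
    P = (np.eye(4) - K @ H) @ s.P
    P = (P + P.T) / 2.0  # keep symmetric under round-off
    return KalmanState(x=x, P=P,
                       last_update_frame=s.last_update_frame
                       if frame is None else frame)


# ---------------------------------------------------------------------------
# association

def associate(predicted: Sequence, detections: Sequence,
              gate_radius: float = np.inf,
              method: Literal["hungarian", "greedy"] = "hungarian"
              ) -> Tuple[List[Tuple[int, int]], List[int], List[int]]:
    """One-to-one matching of predicted points to detected points.

    ``predicted`` and ``detections`` are sequences of ``(x, y)``.
    Pairs farther apart than ``gate_radius`` are never matched.  Returns
    ``(matches, unmatched_predicted, unmatched_detections)`` with
    matches as ``(pred_idx, det_idx)``; the Hungarian method minimises
    the total Euclidean distance over admissible pairs.
    """
    np_, nd = len(predicted), len(detections)
    if np_ == 0 or nd == 0:
        return [], list(range(np_)), list(range(nd))
    P = np.asarray(predicted, float).reshape(np_, 2)
    D = np.asarray(detections, float).reshape(nd, 2)
    cost = np.linalg.norm(P[:, None, :] - D[None, :, :], axis=2)
    matches: List[Tuple[int, int]] = []
    if method == "hungarian":
        gated = np.where(cost <= gate_radius, cost, 1e9)
        rows, cols = linear_sum_assignment(gated)
        for r, c in zip(rows, cols):
            if cost[r, c] <= gate_radius:
                matches.append((int(r), int(c)))
    elif method == "greedy":
        c = cost.copy()
        while True:
            r, col = np.unravel_index(np.argmin(c), c.shape)
            if not np.isfinite(c[r, col]) or c[r, col] > gate_radius:
                break
            matches.append((int(r), int(col)))
            c[r, :] = np.inf
            c[:, col] = np.inf
            if len(matches) == min(np_, nd):
                break
    else:
        raise ValueError(f"unknown assignment method {method!r}")
    mp = {r for r, _ in matches}
    md = {c for _, c in matches}
    return (matches, [i for i in range(np_) if i not in mp],
            [j for j in range(nd) if j not in md])


# ---------------------------------------------------------------------------
# sequence tracking

STATUS_MEASURED = "measured"
STATUS_PREDICTED = "predicted-only"


@dataclass
class TrackerConfig:
    n_pigs: int = 4
    process_noise: float = 1.0
    base_measurement_noise: float = 4.0
    inflation_factor: float = 10.0
    gate_radius: Optional[float] = None   # None: median body length at init
    assignment: Literal["hungarian", "greedy"] = "hungarian"

    def __post_init__(self) -> None:
        if self.process_noise <= 0 or self.base_measurement_noise <= 0:
            raise ValueError("noise scalars must be > 0")
        if self.inflation_factor <= 0:
            raise ValueError("inflation_factor must be > 0")
        if self.gate_radius is not None and self.gate_radius <= 0:
            raise ValueError("gate_radius must be > 0")


@dataclass
class Track:
    """One animal's per-frame shoulder estimates and carried tail."""

    id: int
    frames: List[int] = field(default_factory=list)
    xy: List[Tuple[float, float]] = field(default_factory=list)
    tail: List[Tuple[float, float]] = field(default_factory=list)
    status: List[str] = field(default_factory=list)
    _index: Dict[int, int] = field(default_factory=dict, repr=False)

    def append(self, frame: int, xy, tail, status: str) -> None:
        self._index[frame] = len(self.frames)
        self.frames.append(frame)
        self.xy.append((float(xy[0]), float(xy[1])))
        self.tail.append((float(tail[0]), float(tail[1])))
        self.status.append(status)

    def has_frame(self, frame: int) -> bool:
        return frame in self._index

    def at(self, frame: int) -> Tuple[Tuple[float, float], Tuple[float, float], str]:
        k = self._index[frame]
        return self.xy[k], self.tail[k], self.status[k]

    def pose_at(self, frame: int) -> PigPose:
        xy, tail, _ = self.at(frame)
        if xy == tail:  # degenerate; nudge is not meaningful, keep raw
            tail = (tail[0], tail[1] + 1e-9)
        return PigPose(shoulder=xy, tail=tail, frame=frame, id=self.id)


def _shoulders(dets: Sequence[PigPose]) -> np.ndarray:
    return np.array([d.shoulder for d in dets], float).reshape(len(dets), 2)


def track_sequence(detections: Sequence[Sequence[PigPose]],
                   cfg: TrackerConfig) -> List[Track]:
    """Link per-frame detections into ``cfg.n_pigs`` identity-stable tracks.

    Initialization uses the first frame with exactly ``n_pigs``
    detections (IDs 1..n in that frame's detection order).  Thereafter,
    frames with any other detection count are corrupted: every filter
    is fed its own previous estimate with measurement noise inflated by
    ``inflation_factor``, and the frame is logged predicted-only.
    """
    n = cfg.n_pigs
    first = next((f for f, d in enumerate(detections) if len(d) == n), None)
    if first is None:
        raise RuntimeError(
            f"initialization failed: no frame contains exactly {n} detections")

    init_dets = list(detections[first])
    gate = cfg.gate_radius
    if gate is None:
        gate = float(np.median([d.body_length for d in init_dets]))

    tracks = [Track(id=i + 1) for i in range(n)]
    states: List[KalmanState] = []
    for i, det in enumerate(init_dets):
        states.append(kf_init(det.shoulder, frame=first))
        tracks[i].append(first, det.shoulder, det.tail, STATUS_MEASURED)

    for f in range(first + 1, len(detections)):
        states = [kf_predict(s, cfg.process_noise) for s in states]
        dets = list(detections[f])
        if len(dets) != n:
            # corrupted frame: self-feed previous estimates, inflated noise
            for i, tr in enumerate(tracks):
                prev_xy, prev_tail, _ = tr.at(f - 1)
                states[i] = kf_update(states[i], prev_xy,
                                      cfg.base_measurement_noise,
                                      noise_scale=cfg.inflation_factor,
                                      frame=f)
                tracks[i].append(f, states[i].position, prev_tail,
                                 STATUS_PREDICTED)
            continue
        preds = [s.position for s in states]
        matches, unmatched_tracks, _ = associate(
            preds, _shoulders(dets), gate_radius=gate, method=cfg.assignment)
        for (ti, di) in matches:
            z = dets[di].shoulder
            innovation = float(np.linalg.norm(states[ti].position
                                              - np.asarray(z)))
            scale = cfg.inflation_factor if innovation > 3.0 * gate else 1.0
            states[ti] = kf_update(states[ti], z, cfg.base_measurement_noise,
                                   noise_scale=scale, frame=f)
            tracks[ti].append(f, states[ti].position, dets[di].tail,
                              STATUS_MEASURED)
        for ti in unmatched_tracks:
            _, prev_tail, _ = tracks[ti].at(f - 1)
            tracks[ti].append(f, states[ti].position, prev_tail,
                              STATUS_PREDICTED)
    return tracks
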