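"""Synthetic pen simulator: trajectories, ground-truth contacts, detector noise.

The simulator emulates the study conditions every downstream stage is
built for: a fixed, known number of pigs moving in a rectangular pen
viewed from above (default 640x400 px at 10 fps), with the body of each
animal reduced to its shoulder and tail keypoints plus two ears.  Pigs
wander with a waypoint-following correlated random walk whose per-frame
step is bounded by ``body_length / 10`` and whose heading change is
bounded by 15 deg/frame — at 10 fps even brisk motion moves a keypoint
only a few pixels between frames, which is the regime the tracker's
constant-velocity model assumes.

Scripted *approach events* steer a pair of pigs into a guaranteed
head-head or head-tail contact inside a stated frame window, giving
every contact-detection test a known answer.  Ground-truth contacts are
produced by brute-force pairwise region intersection over the generated
poses, so the truth table is exactly what a perfect pipeline should
recover.

Detector corruption reproduces the failure modes a keypoint CNN shows on
real footage: coordinate jitter, missed detections (including scripted
occlusion episodes), spurious full poses, and shoulder-tail swaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import contacts as _contacts
from .pose import PigPose, rotate, unit

HEAD_HEAD = _contacts.HEAD_HEAD
HEAD_TAIL = _contacts.HEAD_TAIL

# ear placement: forward of the shoulder, +-50 deg off the body axis
_EAR_ANGLE = math.radians(50.0)


@dataclass
class PenConfig:
    """Geometry and timing of the simulated pen."""

    width: int = 640
    height: int = 400
    n_pigs: int = 4
    body_length: float = 90.0
    ear_offset: float = 18.0
    fps: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pigs < 1:
            raise ValueError("n_pigs must be >= 1")
        if self.body_length <= 0:
            raise ValueError("body_length must be > 0")

    @property
    def step_max(self) -> float:
        """Maximum per-frame shoulder displacement (body_length / 10)."""
        return self.body_length / 10.0

    @property
    def turn_max(self) -> float:
        """Maximum per-frame heading change, radians (15 deg)."""
        return math.radians(15.0)


@dataclass
class ApproachEvent:
    """A scripted contact between two pigs inside a frame window.

    ``kind`` is ``"head-head"`` or ``"head-tail"``; for head-tail the
    approaching pig ``pig_a`` puts its head at ``pig_b``'s tail.
    """

    kind: str
    pig_a: int
    pig_b: int
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.kind not in (HEAD_HEAD, HEAD_TAIL):
            raise ValueError(f"unknown approach kind {self.kind!r}")
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame before start_frame")
        if self.pig_a == self.pig_b:
            raise ValueError("an approach needs two distinct pigs")


@dataclass
class NoiseConfig:
    """Detector-failure model applied to ground-truth poses."""

    jitter_sigma: float = 0.0
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    swap_rate: float = 0.0
    occlusion_episodes: List[Tuple[int, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fn_rate", "swap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.jitter_sigma < 0 or self.fp_rate < 0:
            raise ValueError("jitter_sigma and fp_rate must be >= 0")


@dataclass
class GroundTruth:
    """Per-frame poses with persistent true IDs plus implied contacts."""

    cfg: PenConfig
    poses: List[List[PigPose]]
    contacts: "_contacts.ContactTable"
    alpha: float = _contacts.DEFAULT_ALPHA

    @property
    def n_frames(self) -> int:
        return len(self.poses)


# ---------------------------------------------------------------------------
# trajectory generation

def _margin(cfg: PenConfig) -> float:
    # keep the shoulder far enough from the walls that tail and ears fit
    return cfg.body_length + 2.0


def _clamp(p: np.ndarray, cfg: PenConfig) -> np.ndarray:
    m = _margin(cfg)
    return np.array([np.clip(p[0], m, cfg.width - 1 - m),
                     np.clip(p[1], m, cfg.height - 1 - m)])


def _pose_from_state(pig_id: int, frame: int, s: np.ndarray, heading: float,
                     cfg: PenConfig) -> PigPose:
    u = np.array([math.cos(heading), math.sin(heading)])
    tail = s - cfg.body_length * u
    le = s + cfg.ear_offset * rotate(u, -_EAR_ANGLE)
    re = s + cfg.ear_offset * rotate(u, +_EAR_ANGLE)
    return PigPose(shoulder=tuple(s), tail=tuple(tail),
                   left_ear=tuple(le), right_ear=tuple(re),
                   frame=frame, id=pig_id)


def _turn_toward(heading: float, target_dir: float, turn_max: float) -> float:
    d = (target_dir - heading + math.pi) % (2 * math.pi) - math.pi
    return heading + np.clip(d, -turn_max, turn_max)


class _Walker:
    """Waypoint-following pig with bounded step and turn rate."""

    def __init__(self, pig_id: int, s: np.ndarray, heading: float,
                 cfg: PenConfig, rng: np.random.Generator,
                 loiter_center: Optional[np.ndarray] = None,
                 loiter_radius: float = 0.0):
        self.id = pig_id
        self.s = s.astype(float)
        self.heading = float(heading)
        self.cfg = cfg
        self.rng = rng
        self.loiter_center = loiter_center
        self.loiter_radius = loiter_radius
        self.waypoint = self._new_waypoint()
        self.halted = False
        self.target: Optional[np.ndarray] = None  # scripted approach target

    def _new_waypoint(self) -> np.ndarray:
        cfg = self.cfg
        if self.loiter_center is not None:
            ang = self.rng.uniform(0, 2 * math.pi)
            rad = self.loiter_radius * math.sqrt(self.rng.uniform())
            w = self.loiter_center + rad * np.array([math.cos(ang), math.sin(ang)])
        else:
            m = _margin(cfg)
            w = np.array([self.rng.uniform(m, cfg.width - 1 - m),
                          self.rng.uniform(m, cfg.height - 1 - m)])
        return _clamp(w, cfg)

    def step(self, repulsion: np.ndarray) -> None:
        cfg = self.cfg
        if self.halted:
            return
        tgt = self.target if self.target is not None else self.waypoint
        to_tgt = tgt - self.s
        dist = np.linalg.norm(to_tgt)
        if self.target is None and dist < cfg.step_max:
            self.waypoint = self._new_waypoint()
            to_tgt = self.waypoint - self.s
            dist = np.linalg.norm(to_tgt)
        desired = to_tgt / dist if dist > 1e-9 else np.array([1.0, 0.0])
        if self.target is None and np.linalg.norm(repulsion) > 0:
            desired = unit(desired + repulsion)
        target_dir = math.atan2(desired[1], desired[0])
        new_heading = _turn_toward(self.heading, target_dir, cfg.turn_max)
        # slow down while badly misaligned: turn (almost) in place instead
        # of orbiting the target
        misalign = abs((target_dir - new_heading + math.pi) % (2 * math.pi) - math.pi)
        step = min(cfg.step_max, dist)
        if misalign > math.radians(45):
            step *= 0.15
        self.heading = float(new_heading)
        self.s = _clamp(self.s + step * np.array([math.cos(self.heading),
                                                  math.sin(self.heading)]), cfg)


# ---------------------------------------------------------------------------
# scripted approach choreography

class _EventController:
    """Steers the two pigs of one ApproachEvent into contact.

    Before the window the approacher walks toward its partner (the lead
    starts as soon as the remaining frames barely cover the remaining
    distance).  Inside the window the partner halts and the approacher
    homes onto the contact point; once the contact geometry is reached
    both pigs hold still until the window closes.
    """

    def __init__(self, event: ApproachEvent, cfg: PenConfig, alpha: float):
        self.ev = event
        self.cfg = cfg
        self.alpha = alpha
        self.done = False
        self.engaged = False  # pair currently steered toward contact

    def active(self, frame: int) -> bool:
        return not self.done and frame <= self.ev.end_frame

    def _contact_target(self, wa: _Walker, wb: _Walker) -> np.ndarray:
        cfg = self.cfg
        r = cfg.body_length / self.alpha
        ub = np.array([math.cos(wb.heading), math.sin(wb.heading)])
        if self.ev.kind == HEAD_HEAD:
            # in front of b's shoulder, comfortably inside the 2r band
            return _clamp(wb.s + min(1.2 * r, 2 * r - 5) * ub, cfg)
        tail_b = wb.s - cfg.body_length * ub
        return _clamp(tail_b - min(1.2 * r, 2 * r - 5) * ub, cfg)

    def _in_contact(self, wa: _Walker, wb: _Walker) -> bool:
        r = self.cfg.body_length / self.alpha
        ub = np.array([math.cos(wb.heading), math.sin(wb.heading)])
        if self.ev.kind == HEAD_HEAD:
            return float(np.linalg.norm(wa.s - wb.s)) <= 2 * r - 2
        tail_b = wb.s - self.cfg.body_length * ub
        return float(np.linalg.norm(wa.s - tail_b)) <= 2 * r - 2

    def apply(self, frame: int, walkers: Dict[int, _Walker]) -> None:
        ev = self.ev
        wa, wb = walkers[ev.pig_a], walkers[ev.pig_b]
        if frame > ev.end_frame or self.done:
            wa.target = None
            wb.target = None
            wa.halted = False
            wb.halted = False
            self.engaged = False
            return
        dist = float(np.linalg.norm(wa.s - wb.s))
        frames_left = ev.start_frame - frame
        # both pigs close in during the lead, so effective closing speed is
        # nearly twice the walking speed
        lead_needed = dist / (1.0 * self.cfg.step_max) + 14
        in_window = frame >= ev.start_frame
        if in_window or frames_left < lead_needed:
            self.engaged = True
            wa.target = self._contact_target(wa, wb)
            if in_window:
                wb.target = None
                wb.halted = True
                if self._in_contact(wa, wb):
                    wa.halted = True
            else:
                wb.target = wa.s.copy()
        if frame == ev.end_frame:
            # release both pigs after the window
            wa.target = None
            wb.target = None
            wa.halted = False
            wb.halted = False
            self.done = True


def _validate_script(script: Sequence[ApproachEvent], cfg: PenConfig,
                     n_frames: int) -> None:
    spans: Dict[int, List[Tuple[int, int]]] = {}
    for ev in script:
        for pid in (ev.pig_a, ev.pig_b):
            if not 0 <= pid < cfg.n_pigs:
                raise ValueError(f"approach event references unknown pig {pid}")
        if ev.start_frame < 0 or ev.end_frame >= n_frames:
            raise ValueError(
                f"event window {ev.start_frame}-{ev.end_frame} outside the "
                f"simulated range 0-{n_frames - 1}")
        for pid in (ev.pig_a, ev.pig_b):
            for (s, e) in spans.get(pid, []):
                if ev.start_frame <= e and s <= ev.end_frame:
                    raise ValueError(
                        f"pig {pid} has overlapping staged events "
                        f"({s}-{e} and {ev.start_frame}-{ev.end_frame})")
            spans.setdefault(pid, []).append((ev.start_frame, ev.end_frame))


def simulate_pen(cfg: PenConfig, n_frames: int,
                 script: Sequence[ApproachEvent] = (),
                 alpha: float = _contacts.DEFAULT_ALPHA) -> GroundTruth:
    """Generate a seeded pen run with ground-truth poses and contacts.

    Pigs involved in scripted events loiter near the pen centre before
    their window so the bounded-speed approach always reaches contact in
    time; unscripted pigs wander the whole pen with soft mutual
    repulsion (pigs are solid — shoulders rarely come closer than about
    1.2 body lengths unless scripted to).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    script = list(script)
    _validate_script(script, cfg, n_frames)
    rng = np.random.default_rng(cfg.seed)

    scripted_ids = sorted({pid for ev in script for pid in (ev.pig_a, ev.pig_b)})
    center = np.array([cfg.width / 2.0, cfg.height / 2.0])
    loiter_radius = min(cfg.width, cfg.height) / 4.0

    walkers: Dict[int, _Walker] = {}
    min_sep = 1.2 * cfg.body_length
    for pid in range(cfg.n_pigs):
        for _ in range(200):  # rejection-sample a spread-out start
            if pid in scripted_ids:
                ang = rng.uniform(0, 2 * math.pi)
                rad = loiter_radius * math.sqrt(rng.uniform())
                s = _clamp(center + rad * np.array([math.cos(ang),
                                                    math.sin(ang)]), cfg)
            else:
                m = _margin(cfg)
                s = np.array([rng.uniform(m, cfg.width - 1 - m),
                              rng.uniform(m, cfg.height - 1 - m)])
            if all(np.linalg.norm(s - w.s) > 0.8 * min_sep
                   for w in walkers.values()):
                break
        heading = rng.uniform(0, 2 * math.pi)
        walkers[pid] = _Walker(
            pid, s, heading, cfg, rng,
            loiter_center=center if pid in scripted_ids else None,
            loiter_radius=loiter_radius)

    controllers = [_EventController(ev, cfg, alpha) for ev in script]

    frames: List[List[PigPose]] = []
    for f in range(n_frames):
        for ctl in controllers:
            ctl.apply(f, walkers)
        # soft repulsion between unscripted close pairs
        rep: Dict[int, np.ndarray] = {pid: np.zeros(2) for pid in walkers}
        ids = list(walkers)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = walkers[ids[i]], walkers[ids[j]]
                d = a.s - b.s
                dist = np.linalg.norm(d)
                if 0 < dist < min_sep:
                    push = (min_sep - dist) / min_sep * (d / dist)
                    rep[a.id] += push
                    rep[b.id] -= push
        for pid in range(cfg.n_pigs):
            walkers[pid].step(rep[pid])
        # rigid-body separation: pigs cannot interpenetrate, so shoulders of
        # unengaged pairs are projected apart to at least half a body length
        engaged = {frozenset((ctl.ev.pig_a, ctl.ev.pig_b))
                   for ctl in controllers if ctl.engaged}
        hard_min = 0.5 * cfg.body_length
        for _ in range(3):
            moved = False
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if frozenset((ids[i], ids[j])) in engaged:
                        continue
                    a, b = walkers[ids[i]], walkers[ids[j]]
                    d = a.s - b.s
                    dist = float(np.linalg.norm(d))
                    if dist >= hard_min:
                        continue
                    axis = d / dist if dist > 1e-9 else np.array([1.0, 0.0])
                    push = (hard_min - dist) / 2.0
                    a.s = _clamp(a.s + push * axis, cfg)
                    b.s = _clamp(b.s - push * axis, cfg)
                    moved = True
            if not moved:
                break
        frames.append([_pose_from_state(pid, f, walkers[pid].s,
                                        walkers[pid].heading, cfg)
                       for pid in range(cfg.n_pigs)])

    table = _contacts.poses_contact_table(frames, alpha=alpha)
    return GroundTruth(cfg=cfg, poses=frames, contacts=table, alpha=alpha)


# ---------------------------------------------------------------------------
# detector corruption

def corrupt_detections(truth: GroundTruth,
                       noise: NoiseConfig) -> List[List[PigPose]]:
    """Turn ground-truth poses into noisy, unordered, id-less detections.

    Per pig-frame: drop with probability ``fn_rate`` (plus scripted
    occlusion episodes), swap shoulder/tail with probability
    ``swap_rate``, then jitter every keypoint coordinate with
    N(0, jitter_sigma^2).  Per frame, ``Poisson(fp_rate)`` spurious full
    poses (random position/heading, true body length) are added so they
    exercise the tracker, not just the detection scorer.
    """
    if truth.n_frames == 0:
        raise ValueError("empty ground truth")
    rng = np.random.default_rng(noise.seed)
    cfg = truth.cfg
    occluded = {(pid, f)
                for (pid, s, e) in noise.occlusion_episodes
                for f in range(s, e + 1)}
    out: List[List[PigPose]] = []
    for f, poses in enumerate(truth.poses):
        dets: List[PigPose] = []
        for p in poses:
            if (p.id, f) in occluded or rng.uniform() < noise.fn_rate:
                continue
            q = p.copy(id=None)
            if noise.swap_rate > 0 and rng.uniform() < noise.swap_rate:
                q = q.copy(shoulder=q.tail, tail=q.shoulder)
            if noise.jitter_sigma > 0:
                def jit(pt):
                    if pt is None:
                        return None
                    d = rng.normal(0.0, noise.jitter_sigma, size=2)
                    return (float(np.clip(pt[0] + d[0], 0, cfg.width - 1)),
                            float(np.clip(pt[1] + d[1], 0, cfg.height - 1)))
                q = q.copy(shoulder=jit(q.shoulder), tail=jit(q.tail),
                           left_ear=jit(q.left_ear), right_ear=jit(q.right_ear))
            dets.append(q)
        n_fp = rng.poisson(noise.fp_rate) if noise.fp_rate > 0 else 0
        for _ in range(n_fp):
            m = _margin(cfg)
            s = np.array([rng.uniform(m, cfg.width - 1 - m),
                          rng.uniform(m, cfg.height - 1 - m)])
            heading = rng.uniform(0, 2 * math.pi)
            dets.append(_pose_from_state(None, f, s, heading, cfg))
        out.append(dets)
    return out
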