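"""Proximity-based social-contact detection from tracked poses.

Each animal gets two circular regions of interest per frame: one at the
head (anchored at the shoulder keypoint, optionally pushed forward along
the body orientation) and one at the tail keypoint.  The shared radius is
recomputed every frame as the mean shoulder-tail body length of the
animals present divided by a scaling factor ``alpha``; this makes the
regions track animal growth.  With the default ``alpha = 3`` the region
covers the head/rear of a typical pig without flagging animals that
merely walk past each other.

Two equal circles of radius ``r`` intersect iff their centres are at most
``2 r`` apart (boundary-inclusive for determinism), so contact detection
reduces to pairwise centre-distance thresholding:

* head-head contact:  ``||head_a - head_b|| <= 2 r``
* head-tail contact:  ``||head_a - tail_b|| <= 2 r`` (role-tagged; the
  symmetric test with the roles swapped is evaluated independently).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .pose import PigPose, unit

DEFAULT_ALPHA = 3.0
HEAD_HEAD = "head-head"
HEAD_TAIL = "head-tail"


def region_radius(poses: Sequence[PigPose], alpha: float = DEFAULT_ALPHA) -> float:
    """Region radius for one frame: mean shoulder-tail length / alpha.

    r = (1 / (alpha * N)) * sum_i ||s_i - t_i||
    """
    if len(poses) == 0:
        raise ValueError("region radius undefined for an empty frame")
    lengths = [p.body_length for p in poses]
    return float(np.mean(lengths) / alpha)


@dataclass
class RegionSet:
    """Head/tail circles for every (non-degenerate) pig of one frame."""

    frame: int
    ids: List[int]
    head_centers: np.ndarray  # (n, 2) x,y
    tail_centers: np.ndarray  # (n, 2) x,y
    radius: float

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class ContactEvent:
    """One per-frame contact observation.

    ``id_a < id_b`` always; for head-tail contacts ``head_id``/``tail_id``
    record whose head touched whose tail.
    """

    frame: int
    id_a: int
    id_b: int
    type: str
    head_id: Optional[int] = None
    tail_id: Optional[int] = None

    def sort_key(self):
        return (self.frame, self.id_a, self.id_b, self.type,
                -1 if self.head_id is None else self.head_id)


def make_regions(poses: Sequence[PigPose], alpha: float = DEFAULT_ALPHA,
                 head_offset_frac: float = 0.0,
                 radius: Optional[float] = None) -> RegionSet:
    """Build the per-frame region set from oriented poses.

    The head circle sits at ``shoulder + head_offset_frac * r * u`` where
    ``u`` is the unit body orientation; with the default offset of 0 it is
    centred on the shoulder keypoint itself.  Degenerate poses (shoulder
    coincides with tail, so no orientation) are excluded.
    """
    poses = [p for p in poses if p.id is not None]
    valid = [p for p in poses if p.body_length > 0]
    frame = poses[0].frame if poses else 0
    if not valid:
        return RegionSet(frame=frame, ids=[], head_centers=np.empty((0, 2)),
                         tail_centers=np.empty((0, 2)), radius=0.0)
    r = region_radius(valid, alpha) if radius is None else float(radius)
    heads, tails, ids = [], [], []
    for p in valid:
        u = unit(np.asarray(p.shoulder, float) - np.asarray(p.tail, float))
        heads.append(np.asarray(p.shoulder, float) + head_offset_frac * r * u)
        tails.append(np.asarray(p.tail, float))
        ids.append(int(p.id))
    return RegionSet(frame=valid[0].frame, ids=ids,
                     head_centers=np.asarray(heads),
                     tail_centers=np.asarray(tails), radius=r)


def detect_contacts(regions: RegionSet) -> List[ContactEvent]:
    """All head-head and head-tail events for one frame.

    A pair may yield several simultaneous events of different types (e.g.
    two pigs side by side can touch head-head and head-tail at once).
    """
    events: List[ContactEvent] = []
    n = len(regions)
    thr = 2.0 * regions.radius
    for i, j in itertools.combinations(range(n), 2):
        a, b = regions.ids[i], regions.ids[j]
        lo, hi = min(a, b), max(a, b)
        hh = np.linalg.norm(regions.head_centers[i] - regions.head_centers[j])
        if hh <= thr:
            events.append(ContactEvent(regions.frame, lo, hi, HEAD_HEAD))
        # head of i at tail of j, and the mirrored roles
        if np.linalg.norm(regions.head_centers[i] - regions.tail_centers[j]) <= thr:
            events.append(ContactEvent(regions.frame, lo, hi, HEAD_TAIL,
                                       head_id=a, tail_id=b))
        if np.linalg.norm(regions.head_centers[j] - regions.tail_centers[i]) <= thr:
            events.append(ContactEvent(regions.frame, lo, hi, HEAD_TAIL,
                                       head_id=b, tail_id=a))
    events.sort(key=ContactEvent.sort_key)
    return events


@dataclass
class Episode:
    """A run of consecutive (up to ``gap_tolerance``) same-type contacts."""

    id_a: int
    id_b: int
    type: str
    head_id: Optional[int]
    tail_id: Optional[int]
    start_frame: int
    end_frame: int
    n_frames: int  # number of per-frame events merged into this episode


@dataclass
class ContactTable:
    """Ordered per-frame contact events plus an episode view."""

    events: List[ContactEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"frame": e.frame, "id_a": e.id_a, "id_b": e.id_b,
                 "type": e.type,
                 "head_id": e.head_id, "tail_id": e.tail_id}
                for e in self.events]
        return pd.DataFrame(rows, columns=["frame", "id_a", "id_b", "type",
                                           "head_id", "tail_id"])

    def episodes(self, gap_tolerance: int = 5) -> List[Episode]:
        """Merge same-(pair, type, roles) events whose successive frame
        gaps are at most ``gap_tolerance`` frames."""
        groups: dict = {}
        for e in self.events:
            groups.setdefault((e.id_a, e.id_b, e.type, e.head_id, e.tail_id),
                              []).append(e.frame)
        episodes: List[Episode] = []
        for (a, b, typ, hid, tid), frames in groups.items():
            frames = sorted(frames)
            start = prev = frames[0]
            count = 1
            for f in frames[1:]:
                if f - prev <= gap_tolerance + 1 and f - prev >= 1:
                    prev = f
                    count += 1
                elif f == prev:  # duplicates cannot occur, defensive
                    continue
                else:
                    episodes.append(Episode(a, b, typ, hid, tid, start, prev, count))
                    start = prev = f
                    count = 1
            episodes.append(Episode(a, b, typ, hid, tid, start, prev, count))
        episodes.sort(key=lambda ep: (ep.start_frame, ep.id_a, ep.id_b, ep.type))
        return episodes

    def episodes_frame(self, gap_tolerance: int = 5) -> pd.DataFrame:
        rows = [vars(ep) for ep in self.episodes(gap_tolerance)]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "type", "head_id",
                                           "tail_id", "start_frame",
                                           "end_frame", "n_frames"])


def frame_contacts(poses: Sequence[PigPose], alpha: float = DEFAULT_ALPHA,
                   head_offset_frac: float = 0.0) -> List[ContactEvent]:
    """Regions + detection for one frame of id-carrying poses."""
    if not poses:
        return []
    return detect_contacts(make_regions(poses, alpha=alpha,
                                        head_offset_frac=head_offset_frac))


def build_contact_table(tracks, alpha: float = DEFAULT_ALPHA,
                        head_offset_frac: float = 0.0) -> ContactTable:
    """Frame-wise contact detection over a full tracking run.

    ``tracks`` is a list of :class:`pigtrace.tracker.Track` (anything with
    ``id``, ``frames`` and ``pose_at(frame)``).  The region radius is
    recomputed each frame from the tracked shoulder/tail estimates.
    """
    if not tracks:
        return ContactTable([])
    frames = sorted(set().union(*[set(t.frames) for t in tracks]))
    events: List[ContactEvent] = []
    for f in frames:
        poses = [t.pose_at(f) for t in tracks if t.has_frame(f)]
        events.extend(frame_contacts(poses, alpha=alpha,
                                     head_offset_frac=head_offset_frac))
    events.sort(key=ContactEvent.sort_key)
    return ContactTable(events)


def poses_contact_table(per_frame_poses, alpha: float = DEFAULT_ALPHA,
                        head_offset_frac: float = 0.0) -> ContactTable:
    """Contact table straight from per-frame pose lists (e.g. ground truth)."""
    events: List[ContactEvent] = []
    for poses in per_frame_poses:
        events.extend(frame_contacts(poses, alpha=alpha,
                                     head_offset_frac=head_offset_frac))
    events.sort(key=ContactEvent.sort_key)
    return ContactTable(events)
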