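"""CSV dialects shared by the CLI and the library.

All coordinates are 0-based pixels, x = column, y = row.  One row per
animal per frame; frames with no detections simply have no rows, so a
reader that must know the sequence length can be given ``n_frames``.

* detection CSV: ``frame,x_shoulder,y_shoulder,x_tail,y_tail,
  x_lear,y_lear,x_rear,y_rear`` (ear fields may be empty); ground-truth
  pose files carry an extra leading ``pig_id`` column.
* track CSV: ``frame,pig_id,x,y,x_tail,y_tail,status``.
* contact CSV / episode CSV: see the contacts module.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactEvent, ContactTable
from .pose import PigPose
from .tracker import Track

DET_COLUMNS = ["frame", "x_shoulder", "y_shoulder", "x_tail", "y_tail",
               "x_lear", "y_lear", "x_rear", "y_rear"]


def _pose_row(p: PigPose) -> dict:
    row = {"frame": p.frame,
           "x_shoulder": p.shoulder[0], "y_shoulder": p.shoulder[1],
           "x_tail": p.tail[0], "y_tail": p.tail[1],
           "x_lear": np.nan, "y_lear": np.nan,
           "x_rear": np.nan, "y_rear": np.nan}
    if p.left_ear is not None:
        row["x_lear"], row["y_lear"] = p.left_ear
    if p.right_ear is not None:
        row["x_rear"], row["y_rear"] = p.right_ear
    return row


def write_detections(per_frame: Sequence[Sequence[PigPose]], path,
                     with_ids: bool = False) -> Path:
    rows = []
    for frame_poses in per_frame:
        for p in frame_poses:
            row = _pose_row(p)
            if with_ids:
                row = {"pig_id": p.id, **row}
            rows.append(row)
    cols = (["pig_id"] if with_ids else []) + DET_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False,
                                            float_format="%.17g")
    return Path(path)


def read_detections(path, n_frames: Optional[int] = None
                    ) -> List[List[PigPose]]:
    """Read a detection (or ground-truth pose) CSV into per-frame lists."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing detection columns {missing}")
    if len(df) and not df["frame"].is_monotonic_increasing:
        warnings.warn(f"{path}: frames out of order; reordering")
        df = df.sort_values("frame", kind="stable")
    last = int(df["frame"].max()) + 1 if len(df) else 0
    n = max(n_frames or 0, last)
    out: List[List[PigPose]] = [[] for _ in range(n)]
    has_id = "pig_id" in df.columns
    for row in df.itertuples(index=False):
        def opt(x, y):
            return None if (pd.isna(x) or pd.isna(y)) else (float(x), float(y))
        p = PigPose(shoulder=(row.x_shoulder, row.y_shoulder),
                    tail=(row.x_tail, row.y_tail),
                    left_ear=opt(row.x_lear, row.y_lear),
                    right_ear=opt(row.x_rear, row.y_rear),
                    frame=int(row.frame),
                    id=None if not has_id or pd.isna(row.pig_id)
                    else int(row.pig_id))
        out[p.frame].append(p)
    return out


def write_tracks(tracks: Sequence[Track], path) -> Path:
    rows = []
    for t in tracks:
        for k, f in enumerate(t.frames):
            rows.append({"frame": f, "pig_id": t.id,
                         "x": t.xy[k][0], "y": t.xy[k][1],
                         "x_tail": t.tail[k][0], "y_tail": t.tail[k][1],
                         "status": t.status[k]})
    df = pd.DataFrame(rows, columns=["frame", "pig_id", "x", "y",
                                     "x_tail", "y_tail", "status"])
    df = df.sort_values(["frame", "pig_id"], kind="stable")
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_tracks(path) -> List[Track]:
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) and not df["frame"].is_monotonic_increasing:
        warnings.warn(f"{path}: frames out of order; reordering")
        df = df.sort_values("frame", kind="stable")
    tracks = {}
    for row in df.itertuples(index=False):
        t = tracks.setdefault(int(row.pig_id), Track(id=int(row.pig_id)))
        t.append(int(row.frame), (row.x, row.y), (row.x_tail, row.y_tail),
                 str(row.status))
    return [tracks[k] for k in sorted(tracks)]


def write_contacts(table: ContactTable, path) -> Path:
    table.to_frame().to_csv(path, index=False)
    return Path(path)


def read_contacts(path) -> ContactTable:
    df = pd.read_csv(path)
    events = []
    for row in df.itertuples(index=False):
        events.append(ContactEvent(
            frame=int(row.frame), id_a=int(row.id_a), id_b=int(row.id_b),
            type=str(row.type),
            head_id=None if pd.isna(row.head_id) else int(row.head_id),
            tail_id=None if pd.isna(row.tail_id) else int(row.tail_id)))
    return ContactTable(events)


def write_episodes(table: ContactTable, path, gap_tolerance: int = 5) -> Path:
    table.episodes_frame(gap_tolerance).to_csv(path, index=False)
    return Path(path)
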