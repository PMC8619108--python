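"""Per-animal pose primitives shared by every pipeline stage.

A pig is represented by four keypoints in image coordinates: shoulder,
tail, and the two ears.  The body orientation is the unit vector pointing
from tail to shoulder (the direction the animal faces); it is derivable
from the keypoints and never stored separately.

Coordinate convention (used package-wide): 0-based pixel indices,
``x`` = column (rightward), ``y`` = row (downward).  Arrays are indexed
``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

Point = Tuple[float, float]


@dataclass
class PigPose:
    """One animal's keypoints in one frame.

    Parameters
    ----------
    shoulder, tail
        ``(x, y)`` pixel coordinates.  Must differ for the orientation to
        be defined.
    left_ear, right_ear
        ``(x, y)`` or ``None`` when the ear was not annotated/detected.
    frame
        Frame index the pose belongs to.
    id
        Persistent animal identity, or ``None`` for unassigned detections.
    ambiguous
        Set by the decoder when shoulder/tail could not be told apart; the
        keypoint pair is then an unordered line-endpoint pair.
    """

    shoulder: Point
    tail: Point
    left_ear: Optional[Point] = None
    right_ear: Optional[Point] = None
    frame: int = 0
    id: Optional[int] = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        self.shoulder = (float(self.shoulder[0]), float(self.shoulder[1]))
        self.tail = (float(self.tail[0]), float(self.tail[1]))
        for attr in ("left_ear", "right_ear"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, (float(v[0]), float(v[1])))

    # -- derived geometry -------------------------------------------------
    @property
    def body_length(self) -> float:
        """Euclidean shoulder-tail distance in pixels."""
        return float(np.hypot(self.shoulder[0] - self.tail[0],
                              self.shoulder[1] - self.tail[1]))

    @property
    def orientation(self) -> Optional[np.ndarray]:
        """Unit vector from tail to shoulder, or ``None`` if degenerate
        or the shoulder/tail labelling is ambiguous."""
        if self.ambiguous:
            return None
        d = np.asarray(self.shoulder, float) - np.asarray(self.tail, float)
        n = np.linalg.norm(d)
        if n == 0:
            return None
        return d / n

    def keypoints(self) -> dict:
        """Mapping of keypoint name to coordinate (ears may be None)."""
        return {"shoulder": self.shoulder, "tail": self.tail,
                "left_ear": self.left_ear, "right_ear": self.right_ear}

    def in_bounds(self, width: int, height: int) -> bool:
        """True when every present keypoint lies in [0,width) x [0,height)."""
        for p in (self.shoulder, self.tail, self.left_ear, self.right_ear):
            if p is None:
                continue
            if not (0 <= p[0] < width and 0 <= p[1] < height):
                return False
        return True

    def copy(self, **changes) -> "PigPose":
        return replace(self, **changes)


def unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def rotate(v, angle_rad: float) -> np.ndarray:
    """Rotate a 2-vector by ``angle_rad`` (image convention: y down, so a
    positive angle turns clockwise on screen)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    v = np.asarray(v, float)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])
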