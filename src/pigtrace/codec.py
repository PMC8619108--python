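"""Seven-channel keypoint image encoding and its inverse.

Pose annotations (and, at inference time, the detector's real-valued
output maps) are represented as a stack of seven binary images of the
frame's size, one semantic item per channel:

====  ==========================
 ch   content
====  ==========================
  0   left-ear keypoints (discs)
  1   right-ear keypoints (discs)
  2   shoulder keypoints (discs)
  3   tail keypoints (discs)
  4   shoulder-tail connection lines
  5   shoulder-left-ear connection lines
  6   shoulder-right-ear connection lines
====  ==========================

Decoding inverts the encoding: the shoulder-tail line channel (ch4)
carries each animal's location — every 8-connected component yields one
endpoint pair (the component's maximal-diameter pixel pair) — and the
keypoint/ear channels disambiguate which endpoint is the shoulder,
giving the body orientation.  Components of touching animals can merge;
such components are decoded as a single pose and flagged ambiguous when
orientation evidence conflicts — splitting merged animals is out of
scope, mirroring the occlusion failures any per-frame detector shows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import disk, line as draw_line, polygon

from .pose import PigPose

N_CHANNELS = 7
CH_LEFT_EAR, CH_RIGHT_EAR, CH_SHOULDER, CH_TAIL = 0, 1, 2, 3
CH_BODY_LINE, CH_LEFT_EAR_LINE, CH_RIGHT_EAR_LINE = 4, 5, 6

DEFAULT_MARKER_RADIUS = 4
DEFAULT_LINE_WIDTH = 3
DEFAULT_MIN_COMPONENT_PIXELS = 10
DEFAULT_EAR_SEARCH_RADIUS = 30.0
DEFAULT_THRESHOLD = 0.5


@dataclass
class ChannelStack:
    """Seven H x W images holding one frame's pose annotations.

    ``channels`` is a ``(7, H, W)`` array; binary stacks use {0, 1},
    detector outputs may be real-valued in [0, 1].
    """

    channels: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] != N_CHANNELS:
            raise ValueError("ChannelStack needs a (7, H, W) array")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.channels.shape[1], self.channels.shape[2]  # (H, W)

    def __getitem__(self, k: int) -> np.ndarray:
        return self.channels[k]


# ---------------------------------------------------------------------------
# encoding

def _draw_disc(img: np.ndarray, p, radius: int) -> None:
    rr, cc = disk((p[1], p[0]), radius, shape=img.shape)
    img[rr, cc] = 1


def _draw_thick_line(img: np.ndarray, p0, p1, width: int) -> None:
    # 1-px Bresenham line guarantees 8-connectivity; a butt-ended
    # quadrilateral adds the width without lengthening the segment
    r0, c0 = int(round(p0[1])), int(round(p0[0]))
    r1, c1 = int(round(p1[1])), int(round(p1[0]))
    rr, cc = draw_line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
    img[rr[keep], cc[keep]] = 1
    if width > 1:
        d = np.array([p1[0] - p0[0], p1[1] - p0[1]], float)
        n = np.linalg.norm(d)
        if n > 0:
            perp = np.array([-d[1], d[0]]) / n * (width / 2.0)
            xs = [p0[0] + perp[0], p0[0] - perp[0],
                  p1[0] - perp[0], p1[0] + perp[0]]
            ys = [p0[1] + perp[1], p0[1] - perp[1],
                  p1[1] - perp[1], p1[1] + perp[1]]
            rr, cc = polygon(ys, xs, shape=img.shape)
            img[rr, cc] = 1


def encode(poses: Sequence[PigPose], H: int, W: int,
           marker_radius: int = DEFAULT_MARKER_RADIUS,
           line_width: int = DEFAULT_LINE_WIDTH) -> ChannelStack:
    """Render poses into the seven-channel binary representation.

    Keypoints become filled discs of ``marker_radius``; connections
    become rasterized segments of ``line_width``.  Absent ears render
    nothing.  A pose with any keypoint outside ``[0, W) x [0, H)`` is
    rejected.
    """
    stack = np.zeros((N_CHANNELS, H, W), dtype=np.uint8)
    for k, p in enumerate(poses):
        if not p.in_bounds(W, H):
            raise ValueError(f"pose {k} (id={p.id}, frame={p.frame}) has a "
                             f"keypoint outside the {W}x{H} image")
        _draw_disc(stack[CH_SHOULDER], p.shoulder, marker_radius)
        _draw_disc(stack[CH_TAIL], p.tail, marker_radius)
        _draw_thick_line(stack[CH_BODY_LINE], p.shoulder, p.tail, line_width)
        if p.left_ear is not None:
            _draw_disc(stack[CH_LEFT_EAR], p.left_ear, marker_radius)
            _draw_thick_line(stack[CH_LEFT_EAR_LINE], p.shoulder, p.left_ear,
                             line_width)
        if p.right_ear is not None:
            _draw_disc(stack[CH_RIGHT_EAR], p.right_ear, marker_radius)
            _draw_thick_line(stack[CH_RIGHT_EAR_LINE], p.shoulder, p.right_ear,
                             line_width)
    return ChannelStack(stack)


# ---------------------------------------------------------------------------
# line extraction

def _diameter_pair(coords: np.ndarray) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Maximal-distance pixel pair of a component, deterministic tie-break.

    ``coords`` is (n, 2) in (y, x) order.  Distances are compared as
    exact squared integers; ties resolve to the lexicographically
    smallest ordered pair in (y, x).  The diameter of a point set is
    attained at convex-hull vertices, so large components are reduced to
    their hull first.
    """
    pts = coords.astype(np.int64)
    if len(pts) > 80:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (collinear) component: brute-force below
    n = len(pts)
    if n == 1:
        p = (int(pts[0, 0]), int(pts[0, 1]))
        return p, p
    d = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    iu, ju = np.triu_indices(n, k=1)
    vals = d[iu, ju]
    best = vals.max()
    candidates = []
    for idx in np.nonzero(vals == best)[0]:
        a = (int(pts[iu[idx], 0]), int(pts[iu[idx], 1]))
        b = (int(pts[ju[idx], 0]), int(pts[ju[idx], 1]))
        candidates.append((a, b) if a <= b else (b, a))
    return min(candidates)


def extract_lines(line_channel: np.ndarray,
                  min_component_pixels: int = DEFAULT_MIN_COMPONENT_PIXELS
                  ) -> List[Tuple[Tuple[float, float], Tuple[float, float]]]:
    """Endpoint pairs of the 8-connected components of a binary image.

    Components with fewer than ``min_component_pixels`` set pixels are
    discarded as noise.  Returns ``[( (x0, y0), (x1, y1) ), ...]`` with
    each pair being the component's maximal-diameter pixel pair.
    """
    img = np.asarray(line_channel) > 0
    labels, n = ndimage.label(img, structure=np.ones((3, 3), dtype=int))
    pairs = []
    for comp in range(1, n + 1):
        coords = np.argwhere(labels == comp)
        if len(coords) < min_component_pixels:
            continue
        (y0, x0), (y1, x1) = _diameter_pair(coords)
        pairs.append(((float(x0), float(y0)), (float(x1), float(y1))))
    return pairs


# ---------------------------------------------------------------------------
# orientation

def _dist_to_set(channel: np.ndarray) -> Optional[np.ndarray]:
    """Per-pixel Euclidean distance to the nearest set pixel, or None if
    the channel is empty."""
    mask = np.asarray(channel) > 0
    if not mask.any():
        return None
    return ndimage.distance_transform_edt(~mask)

def _ear_evidence(stack: ChannelStack, p, radius: float) -> float:
    """Count of set ear/ear-line pixels within ``radius`` of point p."""
    H, W = stack.shape
    x, y = p
    r = int(np.ceil(radius))
    y0, y1 = max(0, int(y) - r), min(H, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(W, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return 0.0
    sub = (stack[CH_LEFT_EAR][y0:y1, x0:x1] > 0) \
        | (stack[CH_RIGHT_EAR][y0:y1, x0:x1] > 0) \
        | (stack[CH_LEFT_EAR_LINE][y0:y1, x0:x1] > 0) \
        | (stack[CH_RIGHT_EAR_LINE][y0:y1, x0:x1] > 0)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    within = (yy - y) ** 2 + (xx - x) ** 2 <= radius ** 2
    return float((sub & within).sum())


def _blob_centroids(channel: np.ndarray) -> np.ndarray:
    """(n, 2) array of (x, y) centroids of the channel's 8-connected blobs."""
    mask = np.asarray(channel) > 0
    if not mask.any():
        return np.empty((0, 2))
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    cents = ndimage.center_of_mass(mask, labels, range(1, n + 1))
    return np.array([(cx, cy) for (cy, cx) in cents])


def _nearest_centroid(centroids: np.ndarray, p,
                      radius: float) -> Optional[Tuple[float, float]]:
    if len(centroids) == 0:
        return None
    d = np.hypot(centroids[:, 0] - p[0], centroids[:, 1] - p[1])
    k = int(np.argmin(d))
    if d[k] <= radius:
        return float(centroids[k, 0]), float(centroids[k, 1])
    return None


def orient_lines(pairs, stack: ChannelStack,
                 ear_search_radius: float = DEFAULT_EAR_SEARCH_RADIUS,
                 tie_eps: float = 1.5, frame: int = 0) -> List[PigPose]:
    """Label each endpoint pair's shoulder/tail end and attach ears.

    The endpoint closer to a shoulder-channel blob is the shoulder; when
    the shoulder channel is empty or the two distances tie, ear evidence
    (ear discs and shoulder-ear lines cluster at the head end) breaks
    the tie.  Pairs with no decisive evidence are kept but flagged
    ambiguous.  Ears are filled from the nearest ear-channel blob within
    ``ear_search_radius`` of the shoulder endpoint.
    """
    sh_dist = _dist_to_set(stack[CH_SHOULDER])
    le_centroids = _blob_centroids(stack[CH_LEFT_EAR])
    re_centroids = _blob_centroids(stack[CH_RIGHT_EAR])
    poses: List[PigPose] = []
    H, W = stack.shape
    for (p0, p1) in pairs:
        shoulder, tail, ambiguous = p0, p1, False
        decided = False
        if sh_dist is not None:
            d0 = sh_dist[min(int(round(p0[1])), H - 1), min(int(round(p0[0])), W - 1)]
            d1 = sh_dist[min(int(round(p1[1])), H - 1), min(int(round(p1[0])), W - 1)]
            if abs(d0 - d1) > tie_eps:
                shoulder, tail = (p0, p1) if d0 < d1 else (p1, p0)
                decided = True
        if not decided:
            e0 = _ear_evidence(stack, p0, ear_search_radius)
            e1 = _ear_evidence(stack, p1, ear_search_radius)
            if e0 != e1:
                shoulder, tail = (p0, p1) if e0 > e1 else (p1, p0)
                decided = True
        if not decided:
            ambiguous = True
        le = _nearest_centroid(le_centroids, shoulder, ear_search_radius)
        re = _nearest_centroid(re_centroids, shoulder, ear_search_radius)
        if shoulder == tail:
            continue  # degenerate single-pixel pair: nothing to report
        poses.append(PigPose(shoulder=shoulder, tail=tail, left_ear=le,
                             right_ear=re, frame=frame, ambiguous=ambiguous))
    return poses


def decode(stack: ChannelStack, threshold: float = DEFAULT_THRESHOLD,
           min_component_pixels: int = DEFAULT_MIN_COMPONENT_PIXELS,
           ear_search_radius: float = DEFAULT_EAR_SEARCH_RADIUS,
           frame: int = 0) -> List[PigPose]:
    """Binarize a (possibly real-valued) stack, then extract and orient.

    Returns unordered, id-less poses — the tracker assigns identities.
    """
    binary = ChannelStack((stack.channels >= threshold).astype(np.uint8))
    pairs = extract_lines(binary[CH_BODY_LINE],
                          min_component_pixels=min_component_pixels)
    return orient_lines(pairs, binary, ear_search_radius=ear_search_radius,
                        frame=frame)
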