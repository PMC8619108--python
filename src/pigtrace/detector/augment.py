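"""Joint geometric augmentation of frames and their annotation stacks.

Four operations: vertical shift, horizontal shift, shrink, and rotation
about the image centre.  The same transform is applied to the grayscale
frame (bilinear) and to all seven annotation channels (nearest
neighbour, then re-binarized), so decoded poses of an augmented stack
match the transformed ground-truth poses.  Default magnitudes: shifts
up to +-10% of the image size, shrink to 0.9x, rotation up to +-15 deg;
the realised values are drawn from the given seed and can be recovered
with ``return_params=True``.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from ..codec import ChannelStack

ALL_OPS = ("vshift", "hshift", "shrink", "rotate")
MAX_SHIFT_FRAC = 0.1
SHRINK_FACTOR = 0.9
MAX_ROTATE_DEG = 15.0


def _matrix_offset(op: str, param: float, shape) -> Tuple[np.ndarray, np.ndarray]:
    """Affine map (in (y, x) coordinates) s.t. output[o] = input[M o + off]."""
    h, w = shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    if op == "vshift":
        return np.eye(2), np.array([-param, 0.0])
    if op == "hshift":
        return np.eye(2), np.array([0.0, -param])
    if op == "shrink":
        M = np.eye(2) / param
        return M, c - M @ c
    if op == "rotate":
        th = math.radians(param)
        M = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        return M, c - M @ c
    raise ValueError(f"unknown augmentation op {op!r}")


def apply_transform(image: np.ndarray, stack: ChannelStack, op: str,
                    param: float) -> Tuple[np.ndarray, ChannelStack]:
    """Apply one op with an explicit parameter to an (image, stack) pair."""
    M, off = _matrix_offset(op, param, image.shape)
    img = ndimage.affine_transform(np.asarray(image, float), M, offset=off,
                                   order=1, mode="constant", cval=0.0)
    chans = [ndimage.affine_transform(ch.astype(np.uint8), M, offset=off,
                                      order=0, mode="constant", cval=0)
             for ch in stack.channels]
    return img, ChannelStack(np.stack(chans))


def transform_point(p, op: str, param: float, shape):
    """Where an input-image point lands in the transformed image.

    ``p`` is (x, y); returns (x, y).
    """
    M, off = _matrix_offset(op, param, shape)
    v = np.array([p[1], p[0]], float)           # to (y, x)
    o = np.linalg.solve(M, v - off)
    return float(o[1]), float(o[0])


def draw_params(ops: Sequence[str], shape, seed: int = 0) -> Dict[str, float]:
    rng = np.random.default_rng(seed)
    h, w = shape
    params: Dict[str, float] = {}
    for op in ops:
        if op == "vshift":
            params[op] = float(rng.uniform(-MAX_SHIFT_FRAC, MAX_SHIFT_FRAC) * h)
        elif op == "hshift":
            params[op] = float(rng.uniform(-MAX_SHIFT_FRAC, MAX_SHIFT_FRAC) * w)
        elif op == "shrink":
            params[op] = SHRINK_FACTOR
        elif op == "rotate":
            params[op] = float(rng.uniform(-MAX_ROTATE_DEG, MAX_ROTATE_DEG))
        else:
            raise ValueError(f"unknown augmentation op {op!r}")
    return params


def augment(image: np.ndarray, stack: ChannelStack,
            ops: Sequence[str] = ALL_OPS, seed: int = 0,
            return_params: bool = False) -> List:
    """Original plus one transformed copy per op: ``1 + len(ops)`` pairs."""
    params = draw_params(ops, np.asarray(image).shape, seed)
    out = [(np.asarray(image, float), stack)]
    recs = [("original", 0.0)]
    for op in ops:
        out.append(apply_transform(image, stack, op, params[op]))
        recs.append((op, params[op]))
    if return_params:
        return [(img, st, rec) for (img, st), rec in zip(out, recs)]
    return out
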