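"""Easy synthetic training data for desk-scale smoke training.

One large animal per crop, drawn as a bright filled capsule on a noisy
dark background, with the pose drawn from a small fixed family of
headings.  The detector only has to learn "bright blob ends ->
keypoints", which a few epochs of the full architecture can do on a
single CPU.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np
from skimage.draw import disk, ellipse

from ..codec import ChannelStack, encode
from ..pose import PigPose, rotate

# fixed pose family: four canonical headings
_HEADINGS = (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)
_EAR_ANGLE = math.radians(50.0)


def make_toy_pair(size: int, rng: np.random.Generator,
                  marker_radius: int = 3, line_width: int = 3
                  ) -> Tuple[np.ndarray, np.ndarray, PigPose]:
    """One (image, target-stack, pose) triple on a ``size x size`` crop."""
    L = 0.5 * size                       # body length
    ear = 0.1 * size
    margin = L / 2 + ear + 2
    heading = _HEADINGS[rng.integers(len(_HEADINGS))]
    u = np.array([math.cos(heading), math.sin(heading)])
    center = np.array([rng.uniform(margin, size - 1 - margin),
                       rng.uniform(margin, size - 1 - margin)])
    shoulder = center + (L / 2) * u
    tail = center - (L / 2) * u
    le = shoulder + ear * rotate(u, -_EAR_ANGLE)
    re = shoulder + ear * rotate(u, +_EAR_ANGLE)
    pose = PigPose(shoulder=tuple(shoulder), tail=tuple(tail),
                   left_ear=tuple(le), right_ear=tuple(re))

    img = rng.normal(0.08, 0.03, size=(size, size))
    rr, cc = ellipse(center[1], center[0], 0.18 * size, L / 2 + 2,
                     rotation=-heading, shape=(size, size))
    img[rr, cc] = 0.85
    # brighter head end so orientation is learnable
    rr, cc = disk((shoulder[1], shoulder[0]), 0.1 * size, shape=(size, size))
    img[rr, cc] = 1.0
    img = np.clip(img, 0.0, 1.0)

    stack = encode([pose], size, size, marker_radius=marker_radius,
                   line_width=line_width)
    return img.astype(np.float32), stack.channels.astype(np.float32), pose


def make_toy_pairs(n: int, size: int = 64, seed: int = 0
                   ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """``n`` (image, 7-channel target) pairs for :func:`train_toy`."""
    rng = np.random.default_rng(seed)
    return [make_toy_pair(size, rng)[:2] for _ in range(n)]
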