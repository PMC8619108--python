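"""Frame normalisation: any RGB/gray frame -> 640x400 grayscale in [0, 1]."""

from __future__ import annotations

from typing import Tuple

import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize

TARGET_SHAPE: Tuple[int, int] = (400, 640)  # (H, W)


def preprocess_frame(frame, out_shape: Tuple[int, int] = TARGET_SHAPE
                     ) -> np.ndarray:
    """Grayscale, resize (bilinear) and scale a raw frame to [0, 1].

    Accepts ``(H, W)``, ``(H, W, 3)`` or ``(H, W, 4)`` arrays of integer
    or float dtype.  A frame already at the target shape is only
    dtype-scaled, never resampled.
    """
    arr = np.asarray(frame)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        arr = rgb2gray(arr[..., :3])  # returns float64 in [0, 1]
    elif arr.ndim == 2:
        arr = arr.astype(np.float64)
        if np.issubdtype(np.asarray(frame).dtype, np.integer):
            arr = arr / np.iinfo(np.asarray(frame).dtype).max
    else:
        raise ValueError(f"cannot interpret frame of shape {arr.shape} "
                         "as an image")
    if arr.shape != out_shape:
        arr = resize(arr, out_shape, order=1, anti_aliasing=True,
                     preserve_range=True)
    return np.clip(arr, 0.0, 1.0)
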