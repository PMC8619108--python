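"""Encoder-decoder CNN mapping a grayscale frame to the 7-channel stack.

Structure (25 convolutions in total):

* encoder — five pairs of 3x3 ReLU convolutions, with a 2x2 max pool
  after each of the first four pairs (10 convolutions, spatial size
  /16, e.g. 640x400 -> 40x25);
* bottleneck — six stacked 3x3 ReLU convolutions at the latent size;
* decoder — four blocks of [2x upsample, skip concatenation from the
  matching encoder level, two 3x3 ReLU convolutions] (8 convolutions),
  then a final 3x3 convolution with sigmoid activation producing the
  seven output channels.

Filter widths follow a doubling schedule from ``base_filters`` (default
16 -> 256 at the bottleneck); widths are configurable because only the
layer/pool structure is fixed by design.  Training uses binary
cross-entropy and Adam.  Everything is plain numpy, so runs are exactly
reproducible for a fixed seed; training at full 640x400 scale is
supported but intended use is desk-scale crops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .layers import Adam, Conv3x3, MaxPool2, Upsample2, bce_loss, sigmoid


@dataclass
class NetSpec:
    input_shape: Tuple[int, int, int] = (400, 640, 1)   # H, W, C
    n_channels_out: int = 7
    base_filters: int = 16
    seed: int = 0

    @property
    def latent_shape(self) -> Tuple[int, int]:
        return self.input_shape[0] // 16, self.input_shape[1] // 16


class PoseNet:
    """The trainable model handle returned by :func:`build_network`."""

    def __init__(self, spec: NetSpec):
        h, w, _ = spec.input_shape
        if h % 16 or w % 16:
            raise ValueError(
                f"input dims must be divisible by 16 (four 2x2 poolings); "
                f"got {h}x{w}")
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        b = spec.base_filters
        widths = [b, 2 * b, 4 * b, 8 * b, 16 * b]
        self.ops: List[Tuple[str, object]] = []
        c = spec.input_shape[2]
        # encoder
        for lvl in range(4):
            for _ in range(2):
                conv = Conv3x3(c, widths[lvl], rng)
                self.ops.append(("conv", conv))
                c = widths[lvl]
            self.ops.append(("save", lvl))
            self.ops.append(("pool", MaxPool2()))
        for _ in range(2):
            self.ops.append(("conv", Conv3x3(c, widths[4], rng)))
            c = widths[4]
        # bottleneck
        for _ in range(6):
            self.ops.append(("conv", Conv3x3(c, widths[4], rng)))
        # decoder
        for lvl in range(3, -1, -1):
            self.ops.append(("up", Upsample2()))
            self.ops.append(("cat", lvl))
            c = c + widths[lvl]
            for _ in range(2):
                self.ops.append(("conv", Conv3x3(c, widths[lvl], rng)))
                c = widths[lvl]
        self.ops.append(("conv", Conv3x3(c, spec.n_channels_out, rng,
                                         relu=False)))
        self._skip_channels: Dict[int, int] = {}

    # -- inference / training ------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Map ``(N, H, W, 1)`` inputs to ``(N, H, W, 7)`` sigmoid maps."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        skips: Dict[int, np.ndarray] = {}
        for kind, op in self.ops:
            if kind == "conv":
                x = op.forward(x, train=train)
            elif kind == "pool" or kind == "up":
                x = op.forward(x, train=train)
            elif kind == "save":
                skips[op] = x
            elif kind == "cat":
                skip = skips[op]
                self._skip_channels[op] = skip.shape[-1]
                x = np.concatenate([skip, x], axis=-1)
        self._last_z = x if train else None
        return sigmoid(x)

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate the gradient w.r.t. the pre-sigmoid output."""
        skip_grads: Dict[int, np.ndarray] = {}
        g = dz
        for kind, op in reversed(self.ops):
            if kind == "conv":
                g = op.backward(g)
            elif kind in ("pool", "up"):
                g = op.backward(g)
            elif kind == "cat":
                nskip = self._skip_channels[op]
                skip_grads[op] = g[..., :nskip]
                g = g[..., nskip:]
            elif kind == "save":
                g = g + skip_grads.pop(op)

    def layers(self):
        return [op for kind, op in self.ops if kind == "conv"]

    def audit(self) -> Dict[str, object]:
        """Structural accounting of the built network."""
        kinds = [k for k, _ in self.ops]
        convs = self.layers()
        h, w, _ = self.spec.input_shape
        return {
            "n_conv_layers": kinds.count("conv"),
            "n_pool_layers": kinds.count("pool"),
            "n_upsample_layers": kinds.count("up"),
            "n_concat_layers": kinds.count("cat"),
            "n_bottleneck_convs": 6,
            "latent_shape": (h // 16, w // 16),
            "latent_spatial_scale": 1 / 16,
            "out_channels": convs[-1].c_out,
            "out_activation": "sigmoid",
            "n_parameters": int(sum(c.W.size + c.b.size for c in convs)),
        }


def build_network(spec: Optional[NetSpec] = None) -> PoseNet:
    """Construct the encoder-decoder network for a given spec."""
    return PoseNet(spec or NetSpec())


def train_toy(model: PoseNet, pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
              epochs: int, split: float = 0.9, seed: int = 0,
              lr: float = 1e-3, batch_size: int = 8
              ) -> Dict[str, List[float]]:
    """Desk-scale training loop.

    ``pairs`` is a sequence of ``(image, target)`` with image ``(H, W)``
    in [0, 1] and target ``(7, H, W)`` binary (a ChannelStack's array).
    90% of the pairs train, 10% validate after each epoch.  Returns
    ``{"train_loss": [...], "val_loss": [...]}``; raises on divergence.
    """
    if len(pairs) < 32:
        raise ValueError("need at least 32 training pairs")
    rng = np.random.default_rng(seed)
    x = np.stack([np.asarray(img, np.float32) for img, _ in pairs])[..., None]
    t = np.stack([np.moveaxis(np.asarray(tgt, np.float32), 0, -1)
                  for _, tgt in pairs])
    order = rng.permutation(len(pairs))
    n_train = max(1, int(round(split * len(pairs))))
    tr, va = order[:n_train], order[n_train:]
    opt = Adam(lr=lr)
    history: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}
    for epoch in range(epochs):
        perm = rng.permutation(len(tr))
        losses = []
        for start in range(0, len(tr), batch_size):
            idx = tr[perm[start:start + batch_size]]
            xb, tb = x[idx], t[idx]
            p = model.forward(xb, train=True)
            loss = bce_loss(p, tb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    f"try a smaller learning rate")
            losses.append(loss)
            dz = ((p - tb) / p[0].size / len(xb)).astype(np.float32)
            model.backward(dz)
            opt.step(model.layers())
        history["train_loss"].append(float(np.mean(losses)))
        if len(va):
            pv = model.forward(x[va], train=False)
            history["val_loss"].append(bce_loss(pv, t[va]))
        else:
            history["val_loss"].append(float("nan"))
    return history
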