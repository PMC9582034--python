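"""Encoder–decoder restoration network for unsupervised lesion detection.

The model learns to map a hemisphere cross-section with a *simulated*
lesion back to the original healthy image.  At inference time, feeding a
genuinely lesioned cross-section yields an approximation of its healthy
counterpart; the difference between restoration and input is a lesion
probability map (see :mod:`strokect.lesion_pipeline`).

Architecture (U-shaped): per encoder level a 3x3 convolution (ReLU)
followed by a 3x3 stride-2 convolution (ReLU) that doubles the channel
count; per decoder level a 3x3 stride-2 transposed convolution (ReLU)
halving channels, concatenation with the matching encoder feature map,
and a 3x3 convolution (ReLU); a final linear 3x3 convolution produces
the single-channel output.  With the full-scale profile (base 64,
depth 5) the deepest feature width is 1024 and the input is 192x128;
training uses mean-squared error and Adam at learning rate 0.001 with
batch size 32 for 100 epochs.  A scaled-down profile (base 16, depth 3,
96x64, 20 epochs) is provided for CPU-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._nn import Adam, Conv2d, ConvTranspose2d, DTYPE, mse_loss
from .lesion_sim import LesionSimParams, simulate_lesion

__all__ = [
    "NetConfig",
    "RestorationNet",
    "build_network",
    "train",
    "restore",
    "normalize_stack",
]


@dataclass
class NetConfig:
    """Hyper-parameters of the restoration network."""

    input_shape: tuple[int, int] = (192, 128)
    base_kernels: int = 64
    depth: int = 5
    kernel_size: int = 3
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_kernels < 1:
            raise ValueError("base_kernels must be >= 1")
        div = 2 ** (self.depth - 1)
        rows, cols = self.input_shape
        if rows % div or cols % div:
            raise ValueError(
                f"input_shape {self.input_shape} must be divisible by 2^(depth-1)={div}"
            )

    @property
    def deepest_width(self) -> int:
        return self.base_kernels * 2 ** (self.depth - 1)

    @classmethod
    def scaled_down(cls, **overrides) -> "NetConfig":
        """CPU-scale profile: 96x64 input, depth 3, base 16, 20 epochs.

        Uses batch size 4 rather than the full-scale 32: with only a
        few hundred training slices, smaller batches give the optimizer
        ~1000 steps within the same 20-epoch compute budget, which the
        restoration quality needs.
        """
        cfg = cls(
            input_shape=(96, 64), base_kernels=16, depth=3, epochs=20, batch_size=4
        )
        return replace(cfg, **overrides)


class RestorationNet:
    """U-shaped restoration model built from the NumPy engine."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = [cfg.base_kernels * 2**i for i in range(cfg.depth)]
        self.enc_pre: list[Conv2d] = []
        self.enc_down: list[Conv2d] = []
        c_in = 1
        for i in range(cfg.depth - 1):
            self.enc_pre.append(Conv2d(c_in, widths[i], rng))
            self.enc_down.append(Conv2d(widths[i], widths[i + 1], rng, stride=2))
            c_in = widths[i + 1]
        self.bottom = Conv2d(widths[-1], widths[-1], rng)
        self.dec_up: list[ConvTranspose2d] = []
        self.dec_conv: list[Conv2d] = []
        c = widths[-1]
        for i in reversed(range(cfg.depth - 1)):
            self.dec_up.append(ConvTranspose2d(c, widths[i], rng))
            self.dec_conv.append(Conv2d(2 * widths[i], widths[i], rng))
            c = widths[i]
        self.final = Conv2d(widths[0], 1, rng, relu=False)
        from ._nn import _BufferPool

        self._pool = _BufferPool()

    @property
    def layers(self):
        return (
            self.enc_pre
            + self.enc_down
            + [self.bottom]
            + self.dec_up
            + self.dec_conv
            + [self.final]
        )

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def release_buffers(self) -> None:
        """Free all scratch buffers (training working memory)."""
        self._pool.clear()
        for layer in self.layers:
            layer._pool.clear()
            inner = getattr(layer, "conv", None)
            if inner is not None:
                inner._pool.clear()
            for attr in ("_mask", "_cache", "dW", "db"):
                if hasattr(layer, attr):
                    try:
                        delattr(layer, attr)
                    except AttributeError:
                        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Forward pass over a batch shaped ``(N, rows, cols, 1)``."""
        skips = []
        for pre, down in zip(self.enc_pre, self.enc_down):
            x = pre.forward(x)
            skips.append(x)
            x = down.forward(x)
        x = self.bottom.forward(x)
        self._skip_channels = []
        for i, (up, conv, skip) in enumerate(
            zip(self.dec_up, self.dec_conv, reversed(skips))
        ):
            x = up.forward(x)
            c_skip = skip.shape[-1]
            cat = self._pool.get(
                f"cat{i}", x.shape[:-1] + (c_skip + x.shape[-1],)
            )
            cat[..., :c_skip] = skip
            cat[..., c_skip:] = x
            self._skip_channels.append(c_skip)
            x = conv.forward(cat)
        return self.final.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.final.backward(dy)
        dskips = []
        for conv, up, c_skip in zip(
            reversed(self.dec_conv), reversed(self.dec_up), reversed(self._skip_channels)
        ):
            dy = conv.backward(dy)
            dskip, dy = dy[..., :c_skip], dy[..., c_skip:]
            dskips.append(dskip)
            dy = up.backward(dy)
        dy = self.bottom.backward(dy)
        # dskips were collected shallow-to-deep; encoder unwinds deep-to-shallow
        for i, (pre, down, dskip) in enumerate(
            zip(reversed(self.enc_pre), reversed(self.enc_down), reversed(dskips))
        ):
            dy = down.backward(dy)
            dy = pre.backward(
                np.add(dy, dskip, out=self._pool.get(f"dsum{i}", dy.shape))
            )


def build_network(cfg: NetConfig) -> RestorationNet:
    """Instantiate the restoration network for a validated config."""
    return RestorationNet(cfg)


def normalize_stack(slices: np.ndarray, low_pct: float = 1, high_pct: float = 99) -> np.ndarray:
    """Min–max scale a slice stack to [0, 1] robustly.

    The low anchor is a low percentile of *all* voxels (the air floor)
    and the high anchor a high percentile of brain voxels (those above
    10% of the stack's bright percentile), so the scale is robust to
    stain-intensity variation while keeping normalized values
    proportional to raw attenuation.  Proportionality matters: lesions
    darken tissue multiplicatively, and anchoring the low end inside
    the brain-intensity range would clip real lesions to zero — outside
    anything the lesion simulator produces during training.
    """
    slices = np.asarray(slices, dtype=np.float64)
    hi_all = np.percentile(slices, high_pct)
    brain = slices[slices > 0.1 * hi_all] if hi_all > 0 else slices.ravel()
    if brain.size == 0:
        brain = slices.ravel()
    lo = np.percentile(slices, low_pct)
    hi = np.percentile(brain, high_pct)
    if hi <= lo:
        raise ValueError("degenerate intensity range; cannot normalize")
    return np.clip((slices - lo) / (hi - lo), 0.0, 1.0)


def train(
    model: RestorationNet,
    healthy_slices: np.ndarray,
    sim: LesionSimParams,
    cfg: NetConfig | None = None,
    *,
    online: bool = True,
    swa_fraction: float = 0.0,
) -> list[float]:
    """Train the model to undo simulated lesions on healthy slices.

    ``healthy_slices`` is a stack ``(n, rows, cols)`` of normalized
    ([0, 1]) healthy hemisphere cross-sections matching the model's
    input shape.  Each step draws a batch of slices, applies a fresh
    lesion simulation (``online=True``; with ``online=False`` one fixed
    simulated set is built up-front and reused every epoch), and takes
    an Adam step on the mean-squared restoration error.  Returns the
    per-epoch mean loss.

    ``swa_fraction > 0`` averages the weights over the last such
    fraction of epochs (stochastic weight averaging), damping the
    end-of-training fluctuation of the restoration floor.
    """
    cfg = cfg or model.cfg
    healthy = np.asarray(healthy_slices, dtype=DTYPE)
    if healthy.ndim != 3 or healthy.shape[0] == 0:
        raise ValueError("healthy_slices must be a non-empty (n, rows, cols) stack")
    if healthy.shape[1:] != tuple(cfg.input_shape):
        raise ValueError(
            f"slices {healthy.shape[1:]} do not match input_shape {cfg.input_shape}"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = Adam(model.layers, lr=cfg.learning_rate)

    fixed_inputs = None
    if not online:
        fixed_inputs = np.stack(
            [simulate_lesion(s, sim, rng)[0] for s in healthy]
        ).astype(DTYPE)

    n = healthy.shape[0]
    history: list[float] = []
    swa_start = cfg.epochs - max(1, int(round(cfg.epochs * swa_fraction))) if swa_fraction else cfg.epochs
    swa_sums = None
    swa_count = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            targets = healthy[idx]
            if online:
                inputs = np.stack(
                    [simulate_lesion(s, sim, rng)[0] for s in targets]
                ).astype(DTYPE)
            else:
                inputs = fixed_inputs[idx]
            pred = model.forward(inputs[..., None])
            loss, dpred = mse_loss(pred, targets[..., None])
            model.backward(dpred.astype(DTYPE))
            optimizer.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if epoch >= swa_start:
            # accumulate weights for tail averaging
            if swa_sums is None:
                swa_sums = [
                    (layer.W.astype(np.float64), layer.b.astype(np.float64))
                    for layer in model.layers
                ]
            else:
                for (sw, sb), layer in zip(swa_sums, model.layers):
                    sw += layer.W
                    sb += layer.b
            swa_count += 1
    if swa_sums is not None and swa_count > 1:
        for (sw, sb), layer in zip(swa_sums, model.layers):
            layer.W[:] = (sw / swa_count).astype(layer.W.dtype)
            layer.b[:] = (sb / swa_count).astype(layer.b.dtype)
    model.release_buffers()
    return history


def restore(model: RestorationNet, slice_2d: np.ndarray) -> np.ndarray:
    """Run one normalized cross-section through the model; clip to [0, 1]."""
    slice_2d = np.asarray(slice_2d, dtype=DTYPE)
    if slice_2d.shape != tuple(model.cfg.input_shape):
        raise ValueError(
            f"slice shape {slice_2d.shape} does not match input_shape "
            f"{model.cfg.input_shape}"
        )
    out = model.forward(slice_2d[None, ..., None])[0, ..., 0]
    return np.clip(out.astype(np.float64), 0.0, 1.0)
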