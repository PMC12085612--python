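"""MUNet: a feature-pyramid encoder-decoder with two heads.

Encoder: five convolution blocks Conv1-Conv5, each a stride-2 CBL
(convolution - batch norm - leaky ReLU) that halves the spatial size and
doubles the channel count, followed by a stride-1 CBL.  Downsampling is
done by the stride-2 convolution itself; there is no pooling.  For an
S x S x 3 input the pyramid level C_k has spatial size S / 2^k and
64 * 2^(k-1) channels at the reference width (base_channels=64), so a
256 x 256 x 3 input yields C1..C5 of 128x128x64, 64x64x128, 32x32x256,
16x16x512 and 8x8x1024.

Decoder: starting from C5, each stage upsamples x2, concatenates the
matching encoder map C_k, compresses channels with a 1x1
convolution + batch norm + leaky ReLU, and refines with a 3x3 DBL
block, producing decoder maps X4..X1; a final x2 upsampling and 1x1
convolution give a full-resolution map with per-pixel softmax over the
six labels (background + five subtypes).

Classification head: C5 is globally average-pooled and passed through
fully connected layers with a softmax over the five subtypes.

The downsampling convolutions use padding 1: a stride-2 3x3 convolution
with zero padding would give 127 from 256 and contradict the halving
rule and the printed pyramid sizes, so the sizes win.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    LeakyReLU,
    Linear,
    Param,
    Upsample2x,
    softmax,
)


@dataclass(frozen=True)
class MUNetConfig:
    """Architecture settings.

    ``base_channels`` scales the whole pyramid (64 reproduces the
    reference widths; desk-scale tests use 8); the channel-doubling rule
    is preserved at any width.  ``input_size`` must be divisible by 32
    so that five halvings are integral.
    """

    input_size: int = 256
    base_channels: int = 64
    num_seg_classes: int = 6
    num_cls_classes: int = 5
    leaky_slope: float = 0.001
    upsample_mode: str = "bilinear"
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0 or self.input_size < 32:
            raise ValueError(
                f"input_size must be a positive multiple of 32, got {self.input_size}"
            )
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    def level_channels(self, k: int) -> int:
        return self.base_channels * 2 ** (k - 1)


@dataclass
class FeaturePyramid:
    """Encoder maps C1..C5 and decoder maps X1..X5 with their shapes.

    ``c[k]`` is the level-k encoder map; ``x[k]`` the decoder map at the
    same spatial size (``x[5]`` is the decoder's starting map, i.e. C5).
    Arrays are NCHW.
    """

    c: dict[int, np.ndarray]
    x: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def shapes(self) -> dict[str, tuple[int, int, int]]:
        """Per-level (height, width, channels), encoder and decoder."""
        out = {}
        for k, arr in sorted(self.c.items()):
            out[f"C{k}"] = (arr.shape[2], arr.shape[3], arr.shape[1])
        for k, arr in sorted(self.x.items()):
            out[f"X{k}"] = (arr.shape[2], arr.shape[3], arr.shape[1])
        return out


class _CBL(Layer):
    """Convolution -> batch normalization -> leaky ReLU."""

    def __init__(self, cin, cout, kernel, stride, slope, eps, momentum, rng):
        self.conv = Conv2d(cin, cout, kernel=kernel, stride=stride, pad=kernel // 2, rng=rng)
        self.bn = BatchNorm2d(cout, eps=eps, momentum=momentum)
        self.act = LeakyReLU(slope)

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=False):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))


class MUNet:
    """The segmentation-and-classification network.

    ``forward`` returns per-pixel segmentation probabilities, per-slice
    class probabilities and the feature pyramid; ``backward`` takes
    gradients with respect to the two heads' pre-softmax logits (the
    softmax Jacobian is folded into the loss gradients).
    """

    def __init__(self, cfg: MUNetConfig = MUNetConfig()):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        a = dict(slope=cfg.leaky_slope, eps=cfg.bn_eps, momentum=cfg.bn_momentum, rng=rng)

        # encoder: five blocks of [stride-2 CBL, stride-1 CBL]
        self.enc: list[tuple[_CBL, _CBL]] = []
        cin = 3
        for k in range(1, 6):
            cout = cfg.level_channels(k)
            self.enc.append(
                (
                    _CBL(cin, cout, kernel=3, stride=2, **a),
                    _CBL(cout, cout, kernel=3, stride=1, **a),
                )
            )
            cin = cout

        # decoder stages for levels 4..1: up, concat C_k, 1x1 CBL, 3x3 DBL
        self.dec: list[dict] = []
        for k in (4, 3, 2, 1):
            ch_prev = cfg.level_channels(k + 1)
            ch_k = cfg.level_channels(k)
            self.dec.append(
                {
                    "level": k,
                    "up": Upsample2x(cfg.upsample_mode),
                    "compress": _CBL(ch_prev + ch_k, ch_k, kernel=1, stride=1, **a),
                    "dbl": _CBL(ch_k, ch_k, kernel=3, stride=1, **a),
                }
            )
        self.final_up = Upsample2x(cfg.upsample_mode)
        self.seg_head = Conv2d(
            cfg.base_channels, cfg.num_seg_classes, kernel=1, stride=1, pad=0, rng=rng
        )

        # classification head on globally pooled C5
        ch5 = cfg.level_channels(5)
        hidden = max(8, ch5 // 4)
        self.gap = GlobalAvgPool()
        self.fc1 = Linear(ch5, hidden, rng=rng)
        self.fc_act = LeakyReLU(cfg.leaky_slope)
        self.fc2 = Linear(hidden, cfg.num_cls_classes, rng=rng)

        self._concat_channels: dict[int, tuple[int, int]] = {}

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for down, keep in self.enc:
            out += down.params() + keep.params()
        for stage in self.dec:
            out += stage["compress"].params() + stage["dbl"].params()
        out += self.seg_head.params()
        out += self.fc1.params() + self.fc2.params()
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        bn_layers = self._bn_layers()
        for i, bn in enumerate(bn_layers):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.array(state[f"param_{i}"], dtype=np.float32)
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = np.array(state[f"bn_{i}_mean"], dtype=np.float32)
            bn.running_var = np.array(state[f"bn_{i}_var"], dtype=np.float32)

    def _bn_layers(self) -> list[BatchNorm2d]:
        out = []
        for down, keep in self.enc:
            out += [down.bn, keep.bn]
        for stage in self.dec:
            out += [stage["compress"].bn, stage["dbl"].bn]
        return out

    # -- forward ------------------------------------------------------------

    def encoder_forward(self, x: np.ndarray, train: bool = False) -> FeaturePyramid:
        """Run the backbone; returns the pyramid with C1..C5 filled in."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[2] % 32 or x.shape[2] != x.shape[3]:
            raise ValueError(
                f"input spatial size must be square and divisible by 32, got {x.shape[2:]}"
            )
        if x.shape[1] != 3:
            raise ValueError(f"expected 3 input channels, got {x.shape[1]}")
        c: dict[int, np.ndarray] = {}
        h = x
        for k, (down, keep) in enumerate(self.enc, start=1):
            h = keep.forward(down.forward(h, train), train)
            c[k] = h
        return FeaturePyramid(c=c)

    def decoder_forward(self, pyr: FeaturePyramid, train: bool = False) -> np.ndarray:
        """Fuse the pyramid and return per-pixel class probabilities."""
        h = pyr.c[5]
        pyr.x[5] = h
        for stage in self.dec:
            k = stage["level"]
            h = stage["up"].forward(h, train)
            skip = pyr.c[k]
            if h.shape[2:] != skip.shape[2:]:
                raise ValueError(
                    f"shape mismatch at level {k}: {h.shape} vs {skip.shape}"
                )
            self._concat_channels[k] = (h.shape[1], skip.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = stage["dbl"].forward(stage["compress"].forward(h, train), train)
            pyr.x[k] = h
        h = self.final_up.forward(h, train)
        logits = self.seg_head.forward(h, train)
        return softmax(logits, axis=1)

    def classifier_forward(self, pyr: FeaturePyramid, train: bool = False) -> np.ndarray:
        """Class probabilities (length num_cls_classes, summing to 1)."""
        h = self.gap.forward(pyr.c[5], train)
        h = self.fc_act.forward(self.fc1.forward(h, train), train)
        logits = self.fc2.forward(h, train)
        return softmax(logits, axis=1)

    def forward(
        self, x: np.ndarray, train: bool = False
    ) -> tuple[np.ndarray, np.ndarray, FeaturePyramid]:
        pyr = self.encoder_forward(x, train)
        seg = self.decoder_forward(pyr, train)
        cls = self.classifier_forward(pyr, train)
        return seg, cls, pyr

    # -- backward -----------------------------------------------------------

    def backward(self, d_seg_logits: np.ndarray, d_cls_logits: np.ndarray) -> None:
        """Accumulate parameter gradients from both heads' logit gradients."""
        # classification branch back to C5
        d = self.fc2.backward(d_cls_logits.astype(np.float32))
        d = self.fc1.backward(self.fc_act.backward(d))
        d_c5_cls = self.gap.backward(d)

        # segmentation branch back through the decoder
        d = self.seg_head.backward(d_seg_logits.astype(np.float32))
        d = self.final_up.backward(d)
        d_skip: dict[int, np.ndarray] = {}
        for stage in reversed(self.dec):
            k = stage["level"]
            d = stage["compress"].backward(stage["dbl"].backward(d))
            n_main, n_skip = self._concat_channels[k]
            d_skip[k] = d[:, n_main:]
            d = stage["up"].backward(np.ascontiguousarray(d[:, :n_main]))
        d = d + d_c5_cls  # both heads share the encoder through C5

        # encoder, injecting each skip gradient at its level
        for k in range(5, 0, -1):
            down, keep = self.enc[k - 1]
            if k in d_skip:
                d = d + d_skip[k]
            d = down.backward(keep.backward(d))

    def make_optimizer(self, lr: float = 1e-4) -> Adam:
        return Adam(self.params(), lr=lr)
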