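"""Attention-guided generator and patch discriminator.

The generator is a shared encoder (7x7 stem, two stride-2 downsampling
convolutions, residual blocks at the encoder output width) feeding two
independent decoder branches.  The content branch produces n-1
candidate images squashed to [-1, 1]; the attention branch produces n
per-pixel weights normalized to the channel simplex by a softmax.  The
output composes the n-1 content channels with their foreground
attention weights and lets the background channel (the last one) pass
the input through unchanged:

    out = sum_f content_f * attention_f + input * attention_bg

Because the attention weights are a convex combination and every term
is bounded by 1 in magnitude, the output cannot leave [-1, 1].

The discriminator is the fully-convolutional 70x70-receptive-field
patch design (four stride-2/1 4x4 convolutions, leaky ReLU 0.2, no
normalization on the first layer); its score map is reduced by
``patch_mean`` so a whole image is judged by the mean patch score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    ResidualBlock,
    Sequential,
    Tanh,
    Tensor,
)
from .nn.tensor import channel_softmax as _tensor_channel_softmax

__all__ = [
    "GeneratorConfig",
    "MaskStack",
    "AttentionGenerator",
    "PatchDiscriminator",
    "channel_softmax",
    "compose_output",
    "generator_forward",
    "discriminator_forward",
    "patch_mean",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture hyperparameters.

    ``n_masks`` is the attention channel count n (content channels are
    n-1); defaults mirror the reference architecture (n=10, encoder
    64/128/256, 9 residual blocks).  ``use_attention=False`` turns the
    generator into a plain single-output translator (the cycle-GAN
    baseline), isolating the attention mechanism as the only
    difference between the two modes.
    """

    n_masks: int = 10
    base_channels: int = 64
    n_residual: int = 9
    use_attention: bool = True
    background_bias: float = 3.0

    def __post_init__(self):
        if self.n_masks < 2:
            raise ValueError("n_masks must be >= 2")
        if self.base_channels < 1 or self.n_residual < 0:
            raise ValueError("invalid channel/block counts")

    @property
    def content_channels(self) -> int:
        return self.n_masks - 1 if self.use_attention else 1

    @property
    def background_index(self) -> int:
        return self.n_masks - 1

    def to_dict(self) -> dict:
        return {
            "n_masks": self.n_masks,
            "base_channels": self.base_channels,
            "n_residual": self.n_residual,
            "use_attention": self.use_attention,
            "background_bias": self.background_bias,
        }


@dataclass(frozen=True)
class MaskStack:
    """Generator mask output: content channels and attention weights.

    ``content`` is (n-1, H, W) in [-1, 1]; ``attention`` is (n, H, W),
    non-negative with channels summing to one per pixel; the designated
    background channel is ``background_index`` (last by convention).
    """

    content: np.ndarray
    attention: np.ndarray
    background_index: int = -1

    def __post_init__(self):
        c = np.asarray(self.content)
        a = np.asarray(self.attention)
        if c.ndim != 3 or a.ndim != 3:
            raise ValueError("content and attention must be (C, H, W)")
        if a.shape[0] != c.shape[0] + 1:
            raise ValueError("attention must have one more channel than content")
        if c.shape[1:] != a.shape[1:]:
            raise ValueError("content/attention spatial shapes differ")
        if c.size and (c.min() < -1 - 1e-5 or c.max() > 1 + 1e-5):
            raise ValueError("content channels must lie in [-1, 1]")
        if a.size and a.min() < -1e-6:
            raise ValueError("attention weights must be non-negative")
        sums = a.sum(axis=0)
        if a.size and not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("attention channels must sum to 1 per pixel")
        bg = self.background_index % a.shape[0]
        object.__setattr__(self, "background_index", bg)
        object.__setattr__(self, "content", c)
        object.__setattr__(self, "attention", a)


def channel_softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically-stabilized softmax over the leading (channel) axis."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def compose_output(masks: MaskStack, image: np.ndarray) -> np.ndarray:
    """Attention-weighted composition of content channels and the input.

    ``image`` is (H, W) in [-1, 1] and must match the mask spatial
    shape; the result is again (H, W) in [-1, 1].
    """
    image = np.asarray(image)
    if image.shape != masks.attention.shape[1:]:
        raise ValueError(
            f"image shape {image.shape} does not match masks {masks.attention.shape[1:]}"
        )
    bg = masks.background_index
    fg = [i for i in range(masks.attention.shape[0]) if i != bg]
    out = masks.attention[bg] * image
    for ci, ai in enumerate(fg):
        out = out + masks.content[ci] * masks.attention[ai]
    return out


class _DecoderBranch(Module):
    """Two stride-2 transposed convolutions followed by an output head."""

    def __init__(self, c4: int, c2: int, c1: int, head: Module, *, rng):
        self.up1 = ConvTranspose2d(c4, c2, rng=rng)
        self.n1 = InstanceNorm2d(c2)
        self.up2 = ConvTranspose2d(c2, c1, rng=rng)
        self.n2 = InstanceNorm2d(c1)
        self.head = head

    def forward(self, x):
        x = self.n1(self.up1(x)).relu()
        x = self.n2(self.up2(x)).relu()
        return self.head(x)


class AttentionGenerator(Module):
    """Shared encoder, content branch, attention branch, composition."""

    def __init__(self, config: GeneratorConfig = GeneratorConfig(), *,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        c = config.base_channels
        self.stem = Conv2d(1, c, 7, padding=3, pad_mode="reflect", rng=rng)
        self.stem_norm = InstanceNorm2d(c)
        self.down1 = Conv2d(c, 2 * c, 3, stride=2, padding=1, rng=rng)
        self.down1_norm = InstanceNorm2d(2 * c)
        self.down2 = Conv2d(2 * c, 4 * c, 3, stride=2, padding=1, rng=rng)
        self.down2_norm = InstanceNorm2d(4 * c)
        self.res = [ResidualBlock(4 * c, rng=rng) for _ in range(config.n_residual)]
        content_head = Sequential(
            Conv2d(c, config.content_channels, 7, padding=3, pad_mode="reflect", rng=rng),
            Tanh(),
        )
        self.content_branch = _DecoderBranch(4 * c, 2 * c, c, content_head, rng=rng)
        if config.use_attention:
            attn_head = Conv2d(c, config.n_masks, 1, rng=rng)
            # warm start at the identity composition: favouring the
            # background channel at initialization lets the attention
            # branch learn where to admit generated content instead of
            # first having to recover the input from near-uniform masks
            attn_head.bias.data[config.background_index] = config.background_bias
            self.attention_branch = _DecoderBranch(4 * c, 2 * c, c, attn_head, rng=rng)
        else:
            self.attention_branch = None

    def encode(self, x: Tensor) -> Tensor:
        h = self.stem_norm(self.stem(x)).relu()
        h = self.down1_norm(self.down1(h)).relu()
        h = self.down2_norm(self.down2(h)).relu()
        for block in self.res:
            h = block(h)
        return h

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor | None, Tensor | None]:
        """Returns (output, content, attention); output is (1, H, W).

        In non-attention mode content/attention are None and the output
        is the single squashed content channel.
        """
        if x.shape[0] != 1:
            raise ValueError("generator expects a single-channel (1, H, W) input")
        h = self.encode(x)
        content = self.content_branch(h)
        if self.attention_branch is None:
            return content, None, None
        attn = _tensor_channel_softmax(self.attention_branch(h))
        n = self.config.n_masks
        fg = attn.channels(0, n - 1)
        bg = attn.channels(n - 1, n)
        out = (content * fg).sum(axis=0, keepdims=True) + x * bg
        return out, content, attn

    def synthesize(self, image: np.ndarray) -> tuple[np.ndarray, MaskStack | None]:
        """Numpy-in / numpy-out forward pass (no gradient tape)."""
        x = Tensor(np.asarray(image, dtype=np.float32)[None])
        out, content, attn = self.forward(x)
        if attn is None:
            return out.data[0], None
        masks = MaskStack(
            content=content.data,
            attention=attn.data,
            background_index=self.config.n_masks - 1,
        )
        return out.data[0], masks


class PatchDiscriminator(Module):
    """70x70-receptive-field patch classifier (fully convolutional)."""

    def __init__(self, base_channels: int = 64, *, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        d = base_channels
        self.base_channels = d
        self.net = Sequential(
            Conv2d(1, d, 4, stride=2, padding=1, rng=rng),
            LeakyReLU(0.2),
            Conv2d(d, 2 * d, 4, stride=2, padding=1, rng=rng),
            InstanceNorm2d(2 * d),
            LeakyReLU(0.2),
            Conv2d(2 * d, 4 * d, 4, stride=2, padding=1, rng=rng),
            InstanceNorm2d(4 * d),
            LeakyReLU(0.2),
            Conv2d(4 * d, 8 * d, 4, stride=1, padding=1, rng=rng),
            InstanceNorm2d(8 * d),
            LeakyReLU(0.2),
            Conv2d(8 * d, 1, 4, stride=1, padding=1, rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        """Patch score map, shape (1, H', W'); no global pooling inside."""
        return self.net(x)

    @staticmethod
    def output_shape(input_hw: tuple[int, int]) -> tuple[int, int]:
        """Analytic score-map size for a given input size."""
        h, w = input_hw
        for stride in (2, 2, 2, 1, 1):
            h = (h + 2 * 1 - 4) // stride + 1
            w = (w + 2 * 1 - 4) // stride + 1
        return h, w


def generator_forward(image: np.ndarray, generator: AttentionGenerator):
    """Functional wrapper: (H, W) image -> (synthetic image, MaskStack)."""
    return generator.synthesize(image)


def discriminator_forward(image: np.ndarray, discriminator: PatchDiscriminator) -> np.ndarray:
    """Functional wrapper: (H, W) image -> 2-D patch score map."""
    x = Tensor(np.asarray(image, dtype=np.float32)[None])
    return discriminator.forward(x).data[0]


def patch_mean(scores) -> float | Tensor:
    """Mean over all patch scores; judges the whole image at once."""
    if isinstance(scores, Tensor):
        if scores.data.size == 0:
            raise ValueError("empty score map")
        return scores.mean()
    arr = np.asarray(scores)
    if arr.size == 0:
        raise ValueError("empty score map")
    return float(arr.mean())
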