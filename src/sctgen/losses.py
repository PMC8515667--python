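"""Adversarial, cycle-consistency and identity objectives.

Least-squares adversarial losses (real label 1, fake label 0):

    L_D = 1/(2m) sum_i [(D(real_i) - 1)^2 + D(fake_i)^2]
    L_G = 1/(2m) sum_i (D(fake_i) - 1)^2

where D(.) reduces a patch score map to a scalar.  By default the
reduction is the mean over all patches taken *before* the squared
penalty (one verdict per image); the per-patch alternative (penalty per
patch, then mean), used by the classic cycle-GAN implementations, is
available via ``reduction="patch"``.

Cycle and identity terms are mean absolute differences, averaged per
image so they are resolution independent:

    L_cycle = 1/m sum_i |G_BA(G_AB(a_i)) - a_i|,  similarly for b
    L_idt   = 1/m sum_i |G_AB(b_i) - b_i|,        similarly for a

and the total generator objective is

    L = L_GAN + lambda_cycle * L_cycle + lambda_idt * L_idt

with lambda_cycle = 10 and lambda_idt = 5 by default.  The paired
conditional baseline replaces cycle/identity with an L1 term against
the registered target, weighted by lambda_l1 = 100.

All functions accept either autodiff tensors (returning a tensor on
the tape) or plain arrays/floats (returning a float), so the same code
path serves training and direct numerical checks.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .nn import Tensor

__all__ = [
    "LossWeights",
    "LossReport",
    "lsgan_d_loss",
    "lsgan_g_loss",
    "l1_cycle_loss",
    "l1_identity_loss",
    "total_loss",
    "paired_cgan_loss",
]


@dataclass(frozen=True)
class LossWeights:
    lambda_cycle: float = 10.0
    lambda_idt: float = 5.0
    lambda_l1_paired: float = 100.0

    def __post_init__(self):
        if min(self.lambda_cycle, self.lambda_idt, self.lambda_l1_paired) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossReport:
    """Per-iteration scalar record of every loss term."""

    gan_d_ct: float = 0.0
    gan_g_cbct_ct: float = 0.0
    gan_d_cbct: float = 0.0
    gan_g_ct_cbct: float = 0.0
    cycle_cbct: float = 0.0
    cycle_ct: float = 0.0
    idt_ct: float = 0.0
    idt_cbct: float = 0.0
    m: int = 1

    @property
    def gan_total(self) -> float:
        return self.gan_d_ct + self.gan_g_cbct_ct + self.gan_d_cbct + self.gan_g_ct_cbct

    @property
    def cycle_total(self) -> float:
        return self.cycle_cbct + self.cycle_ct

    @property
    def idt_total(self) -> float:
        return self.idt_ct + self.idt_cbct

    def total(self, w: LossWeights = LossWeights()) -> float:
        return total_loss(self, w)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(
            gan_total=self.gan_total,
            cycle_total=self.cycle_total,
            idt_total=self.idt_total,
            total=self.total(),
        )
        return d


# ---------------------------------------------------------------------------
# helpers shared between the tensor and numeric paths


def _as_list(x):
    return x if isinstance(x, (list, tuple)) else [x]


def _reduce_score(s, target: float, reduction: str):
    """One LSGAN penalty term for a single score map (or scalar)."""
    if isinstance(s, Tensor):
        if reduction == "image_mean":
            d = s.mean() if s.data.ndim else s
            return (d - target).square()
        if reduction == "patch":
            return (s - target).square().mean()
    else:
        arr = np.asarray(s, dtype=np.float64)
        if reduction == "image_mean":
            return float((arr.mean() - target) ** 2)
        if reduction == "patch":
            return float(((arr - target) ** 2).mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def _sum(terms):
    it = iter(terms)
    acc = next(it)
    for t in it:
        acc = acc + t
    return acc


def _mean_abs(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = a if isinstance(a, Tensor) else Tensor(np.asarray(a))
        b = b if isinstance(b, Tensor) else Tensor(np.asarray(b))
        return (a - b).abs().mean()
    return float(np.mean(np.abs(np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64))))


# ---------------------------------------------------------------------------
# adversarial terms


def lsgan_d_loss(real_scores, fake_scores, m: int | None = None,
                 reduction: str = "image_mean"):
    """Discriminator least-squares loss.

    ``real_scores``/``fake_scores`` are equal-length collections of
    patch score maps (or pre-reduced scalars).
    """
    real, fake = _as_list(real_scores), _as_list(fake_scores)
    if len(real) != len(fake):
        raise ValueError("real and fake score collections differ in length")
    m = len(real) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    terms = [
        _reduce_score(r, 1.0, reduction) + _reduce_score(f, 0.0, reduction)
        for r, f in zip(real, fake)
    ]
    return _sum(terms) / (2.0 * m)


def lsgan_g_loss(fake_scores, m: int | None = None, reduction: str = "image_mean"):
    """Generator least-squares loss: pushes D(fake) toward the real label."""
    fake = _as_list(fake_scores)
    m = len(fake) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    terms = [_reduce_score(f, 1.0, reduction) for f in fake]
    return _sum(terms) / (2.0 * m)


# ---------------------------------------------------------------------------
# L1 terms


def l1_cycle_loss(recovered, original, m: int | None = None):
    """Mean absolute difference between round-trip and source images.

    Per-image pixel mean, then batch mean over the m pairs.
    """
    rec, orig = _as_list(recovered), _as_list(original)
    if len(rec) != len(orig):
        raise ValueError("recovered and original collections differ in length")
    m = len(rec) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return _sum([_mean_abs(r, o) for r, o in zip(rec, orig)]) / m


def l1_identity_loss(mapped_same_domain, original, m: int | None = None):
    """Identity constraint: a generator fed its own target domain should
    return the input (same functional form as the cycle term)."""
    return l1_cycle_loss(mapped_same_domain, original, m)


# ---------------------------------------------------------------------------
# totals


def total_loss(report: LossReport, w: LossWeights = LossWeights()) -> float:
    """Full objective: L_GAN + lambda_cycle*L_cycle + lambda_idt*L_idt."""
    return report.gan_total + w.lambda_cycle * report.cycle_total + w.lambda_idt * report.idt_total


def paired_cgan_loss(fake_scores, fake_image, target_image,
                     w: LossWeights = LossWeights(), reduction: str = "image_mean"):
    """Paired conditional objective: LSGAN generator term + weighted L1.

    Requires an aligned target; raises if the batch sizes disagree
    (unpaired data cannot be fed to the paired mode).
    """
    fakes = _as_list(fake_image)
    targets = _as_list(target_image)
    if len(fakes) != len(targets):
        raise ValueError("paired mode requires one target per generated image")
    adv = lsgan_g_loss(fake_scores, reduction=reduction)
    l1 = l1_cycle_loss(fakes, targets)
    return adv + w.lambda_l1_paired * l1
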