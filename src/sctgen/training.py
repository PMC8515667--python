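"""Training orchestration for the three synthesis modes.

Modes
-----
``aggan``
    Unpaired two-cycle adversarial training with attention-guided
    generators: CBCT -> sCT -> rCBCT and CT -> sCBCT -> rCT, two patch
    discriminators, least-squares adversarial + cycle + identity
    objectives.
``cyclegan``
    Identical loop with the attention branch disabled (the generator
    emits a single translated image directly), so the attention
    mechanism is the only difference between the two unpaired modes.
``pix2pix``
    Paired conditional baseline: one generator and one discriminator,
    LSGAN adversarial term plus a strong (lambda=100) L1 term against
    the registered target.

Per iteration the generators are updated first on the joint objective,
then each discriminator on its own least-squares loss against detached
generator outputs.  An epoch visits the larger slice pool once (the
smaller pool wraps around); both pools are reshuffled every epoch with
seeded, reproducible permutations.  The Adam learning rate is constant
for the first ``decay_start`` epochs and then decays linearly to zero.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import phantom as _phantom
from .losses import (
    LossReport,
    LossWeights,
    l1_cycle_loss,
    l1_identity_loss,
    lsgan_d_loss,
    lsgan_g_loss,
)
from .networks import AttentionGenerator, GeneratorConfig, PatchDiscriminator
from .nn import Adam, Tensor
from .volume_io import (
    HUVolume,
    clip_and_scale,
    load_volume,
    slices_to_volume,
    volume_to_slices,
)

MODES = ("aggan", "cyclegan", "pix2pix")

__all__ = [
    "MODES",
    "TrainingConfig",
    "CyclePair",
    "lr_schedule",
    "shuffle_unpaired",
    "load_slice_pools",
    "train",
    "TrainingRun",
    "save_checkpoint",
    "load_checkpoint",
    "synthesize_volume",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Training regimen; defaults follow the reference protocol."""

    mode: str = "aggan"
    epochs: int = 100
    decay_start: int = 50
    batch_size: int = 1
    lr0: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    checkpoint_every: int = 0  # epochs; 0 = only final
    image_size: int = 256
    n_masks: int = 10
    gen_channels: int = 64
    n_residual: int = 9
    disc_channels: int = 64
    lambda_cycle: float = 10.0
    lambda_idt: float = 5.0
    lambda_l1_paired: float = 100.0
    patch_reduction: str = "image_mean"
    use_image_pool: bool = False
    pool_size: int = 50

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not (0 <= self.decay_start <= self.epochs):
            raise ValueError("decay_start must lie in [0, epochs]")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")

    @property
    def weights(self) -> LossWeights:
        return LossWeights(self.lambda_cycle, self.lambda_idt, self.lambda_l1_paired)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            n_masks=self.n_masks,
            base_channels=self.gen_channels,
            n_residual=self.n_residual,
            use_attention=self.mode != "cyclegan",
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CyclePair:
    """Intermediate images of one iteration (numpy copies, for logging)."""

    sct: np.ndarray
    rcbct: np.ndarray
    scbct: np.ndarray | None = None
    rct: np.ndarray | None = None


def lr_schedule(epoch: int, config: TrainingConfig) -> float:
    """Constant ``lr0`` before ``decay_start``, then linear to 0 at ``epochs``."""
    if not (0 <= epoch <= config.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    if epoch < config.decay_start:
        return config.lr0
    span = config.epochs - config.decay_start
    if span == 0:
        return 0.0
    return config.lr0 * (config.epochs - epoch) / span


def shuffle_unpaired(n_cbct: int, n_ct: int, epoch: int, seed: int,
                     paired: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch iteration order over the two slice pools.

    Returns two index arrays of length ``max(n_cbct, n_ct)``; the
    smaller pool wraps around.  Unpaired mode draws independent
    permutations; paired mode uses a single shared permutation so
    alignment is preserved.  Reproducible given (seed, epoch).
    """
    if n_cbct < 1 or n_ct < 1:
        raise ValueError("empty slice pool")
    n_iter = max(n_cbct, n_ct)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, epoch])
    if paired:
        if n_cbct != n_ct:
            raise ValueError("paired mode requires pools of equal size")
        perm = rng.permutation(n_cbct)
        return perm, perm.copy()

    def cycle_perm(n):
        reps = []
        total = 0
        while total < n_iter:
            reps.append(rng.permutation(n))
            total += n
        return np.concatenate(reps)[:n_iter]

    return cycle_perm(n_cbct), cycle_perm(n_ct)


# ---------------------------------------------------------------------------
# data loading


def load_slice_pools(manifest: dict | str | Path, config: TrainingConfig,
                     split: str = "train"):
    """Load CBCT and CT slice pools (float32 arrays) for one split."""
    if not isinstance(manifest, dict):
        manifest = _phantom.load_manifest(manifest)
    root = Path(manifest.get("_root", "."))
    cbct_slices, ct_slices = [], []
    for rec in manifest["records"]:
        if rec["split"] != split:
            continue
        for key, pool in (("cbct", cbct_slices), ("ct", ct_slices)):
            vol = load_volume(root / rec[key])
            norm = clip_and_scale(vol)
            pool.extend(s.pixels for s in volume_to_slices(norm, config.image_size))
    if not cbct_slices or not ct_slices:
        raise ValueError(f"no slices found for split {split!r}")
    return np.stack(cbct_slices), np.stack(ct_slices)


class _ImagePool:
    """History buffer of generated images for discriminator updates."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, image: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return image
        if len(self.images) < self.size:
            self.images.append(image.copy())
            return image
        if self.rng.random() < 0.5:
            idx = int(self.rng.integers(len(self.images)))
            old = self.images[idx]
            self.images[idx] = image.copy()
            return old
        return image


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, nets: dict, config: TrainingConfig, epoch: int) -> None:
    """All weights plus the config, schema-versioned, in one .npz file."""
    arrays = {}
    for net_name, net in nets.items():
        for pname, arr in net.state_dict().items():
            arrays[f"{net_name}::{pname}"] = arr
    meta = json.dumps({"schema": 1, "epoch": epoch, "config": config.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Rebuild networks from a checkpoint; returns (nets, config, epoch)."""
    with np.load(path) as data:
        try:
            meta = json.loads(bytes(data["__meta__"]).decode())
        except KeyError as exc:
            raise ValueError(f"corrupt checkpoint {path}: no metadata") from exc
        if meta.get("schema") != 1:
            raise ValueError(f"unsupported checkpoint schema in {path}")
        config = TrainingConfig(**meta["config"])
        states: dict[str, dict] = {}
        for key in data.files:
            if key == "__meta__":
                continue
            net_name, pname = key.split("::", 1)
            states.setdefault(net_name, {})[pname] = data[key]
    rng = np.random.default_rng(0)
    nets = {}
    for net_name, state in states.items():
        if net_name.startswith("g_"):
            net = AttentionGenerator(config.generator_config(), rng=rng)
        else:
            net = PatchDiscriminator(config.disc_channels, rng=rng)
        net.load_state_dict(state)
        nets[net_name] = net
    return nets, config, meta["epoch"]


# ---------------------------------------------------------------------------
# the training loop


@dataclass
class TrainingRun:
    """Outcome of :func:`train`: networks, loss log and config."""

    nets: dict
    config: TrainingConfig
    loss_log: list[LossReport]
    checkpoint_paths: list[str]

    def log_frame(self):
        import pandas as pd

        rows = [r.to_dict() for r in self.loss_log]
        df = pd.DataFrame(rows)
        df.insert(0, "iteration", np.arange(len(rows)))
        return df

    @property
    def generator_cbct_to_ct(self) -> AttentionGenerator:
        return self.nets["g_cbct_ct"]


def _g_scalar(x) -> float:
    return float(x.data) if isinstance(x, Tensor) else float(x)


def train(config: TrainingConfig, manifest, out_dir=None,
          progress: bool = False) -> TrainingRun:
    """Run the full training regimen on a dataset manifest.

    ``manifest`` may be a manifest dict (from ``phantom.make_dataset``)
    or a path to one.  Checkpoints and a CSV loss log are written to
    ``out_dir`` when given.  Fully reproducible given ``config.seed``.
    """
    cbct_pool, ct_pool = load_slice_pools(manifest, config)
    if config.mode == "pix2pix" and len(cbct_pool) != len(ct_pool):
        raise ValueError("pix2pix requires paired pools of equal size")

    rng = np.random.default_rng(config.seed)
    gcfg = config.generator_config()
    nets = {"g_cbct_ct": AttentionGenerator(gcfg, rng=rng),
            "d_ct": PatchDiscriminator(config.disc_channels, rng=rng)}
    if config.mode != "pix2pix":
        nets["g_ct_cbct"] = AttentionGenerator(gcfg, rng=rng)
        nets["d_cbct"] = PatchDiscriminator(config.disc_channels, rng=rng)

    betas = (config.beta1, config.beta2)
    opt_g = Adam(
        sum((nets[k].parameters() for k in nets if k.startswith("g_")), []),
        lr=config.lr0, betas=betas,
    )
    opts_d = {k: Adam(nets[k].parameters(), lr=config.lr0, betas=betas)
              for k in nets if k.startswith("d_")}

    pool_rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xBEEF])
    pools = {k: _ImagePool(config.pool_size if config.use_image_pool else 0, pool_rng)
             for k in opts_d}

    w = config.weights
    red = config.patch_reduction
    paired = config.mode == "pix2pix"
    log: list[LossReport] = []
    ckpts: list[str] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        order_a, order_b = shuffle_unpaired(
            len(cbct_pool), len(ct_pool), epoch, config.seed, paired=paired
        )
        for ia, ib in zip(order_a, order_b):
            a = Tensor(cbct_pool[ia][None])  # CBCT slice
            b = Tensor(ct_pool[ib][None])    # CT slice
            report = LossReport(m=1)

            if paired:
                _pix2pix_step(nets, opt_g, opts_d, pools, a, b, w, red, lr, report)
            else:
                _cycle_step(nets, opt_g, opts_d, pools, a, b, w, red, lr, report)

            if not np.isfinite(report.total(w)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {report.to_dict()}"
                )
            log.append(report)
        if progress:
            print(f"epoch {epoch + 1}/{config.epochs} lr={lr:.2e} "
                  f"L={log[-1].total(w):.4f}", flush=True)
        if out_dir is not None and config.checkpoint_every and \
                (epoch + 1) % config.checkpoint_every == 0:
            p = out_dir / f"checkpoint_epoch{epoch + 1:04d}.npz"
            save_checkpoint(p, nets, config, epoch + 1)
            ckpts.append(str(p))

    if out_dir is not None:
        p = out_dir / "checkpoint_final.npz"
        save_checkpoint(p, nets, config, config.epochs)
        ckpts.append(str(p))
    run = TrainingRun(nets=nets, config=config, loss_log=log, checkpoint_paths=ckpts)
    if out_dir is not None:
        run.log_frame().to_csv(out_dir / "loss_log.csv", index=False)
    return run


def _cycle_step(nets, opt_g, opts_d, pools, a, b, w, red, lr, report):
    g_ab, g_ba = nets["g_cbct_ct"], nets["g_ct_cbct"]
    d_ct, d_cbct = nets["d_ct"], nets["d_cbct"]

    # ---- generator update (joint objective) ----
    opt_g.zero_grad()
    sct, _, _ = g_ab(a)
    rcbct, _, _ = g_ba(sct)
    scbct, _, _ = g_ba(b)
    rct, _, _ = g_ab(scbct)
    idt_ct, _, _ = g_ab(b)
    idt_cbct, _, _ = g_ba(a)

    adv_ct = lsgan_g_loss([d_ct(sct)], reduction=red)
    adv_cbct = lsgan_g_loss([d_cbct(scbct)], reduction=red)
    cyc_cbct = l1_cycle_loss([rcbct], [a])
    cyc_ct = l1_cycle_loss([rct], [b])
    i_ct = l1_identity_loss([idt_ct], [b])
    i_cbct = l1_identity_loss([idt_cbct], [a])
    loss_g = (adv_ct + adv_cbct
              + w.lambda_cycle * (cyc_cbct + cyc_ct)
              + w.lambda_idt * (i_ct + i_cbct))
    loss_g.backward()
    # discriminator params received gradients through the adv terms;
    # clear them so only the generator moves in this step
    for opt in opts_d.values():
        opt.zero_grad()
    opt_g.step(lr)

    report.gan_g_cbct_ct = _g_scalar(adv_ct)
    report.gan_g_ct_cbct = _g_scalar(adv_cbct)
    report.cycle_cbct = _g_scalar(cyc_cbct)
    report.cycle_ct = _g_scalar(cyc_ct)
    report.idt_ct = _g_scalar(i_ct)
    report.idt_cbct = _g_scalar(i_cbct)

    # ---- discriminator updates (detached fakes) ----
    sct_d = Tensor(pools["d_ct"].query(sct.data))
    scbct_d = Tensor(pools["d_cbct"].query(scbct.data))
    for name, disc, real, fake, attr in (
        ("d_ct", d_ct, b, sct_d, "gan_d_ct"),
        ("d_cbct", d_cbct, a, scbct_d, "gan_d_cbct"),
    ):
        opts_d[name].zero_grad()
        loss_d = lsgan_d_loss([disc(real)], [disc(fake)], reduction=red)
        loss_d.backward()
        opts_d[name].step(lr)
        setattr(report, attr, _g_scalar(loss_d))


def _pix2pix_step(nets, opt_g, opts_d, pools, a, b, w, red, lr, report):
    g_ab, d_ct = nets["g_cbct_ct"], nets["d_ct"]

    opt_g.zero_grad()
    sct, _, _ = g_ab(a)
    adv = lsgan_g_loss([d_ct(sct)], reduction=red)
    l1 = l1_cycle_loss([sct], [b])
    loss_g = adv + w.lambda_l1_paired * l1
    loss_g.backward()
    for opt in opts_d.values():
        opt.zero_grad()
    opt_g.step(lr)
    report.gan_g_cbct_ct = _g_scalar(adv)
    report.cycle_ct = _g_scalar(l1)  # paired L1 term, logged under cycle_ct

    sct_d = Tensor(pools["d_ct"].query(sct.data))
    opts_d["d_ct"].zero_grad()
    loss_d = lsgan_d_loss([d_ct(b)], [d_ct(sct_d)], reduction=red)
    loss_d.backward()
    opts_d["d_ct"].step(lr)
    report.gan_d_ct = _g_scalar(loss_d)


# ---------------------------------------------------------------------------
# inference


def synthesize_volume(cbct: HUVolume, checkpoint) -> HUVolume:
    """Slice-wise sCT synthesis for a whole CBCT volume.

    ``checkpoint`` may be a path, a :class:`TrainingRun`, or an
    :class:`AttentionGenerator`.  The volume is normalized, split into
    training-resolution axial slices, translated slice by slice, and
    reassembled on the input geometry; output HU lie in [-1000, 1500].
    """
    if isinstance(checkpoint, AttentionGenerator):
        gen = checkpoint
        size = None
    elif isinstance(checkpoint, TrainingRun):
        gen = checkpoint.generator_cbct_to_ct
        size = checkpoint.config.image_size
    else:
        nets, cfg, _ = load_checkpoint(checkpoint)
        if "g_cbct_ct" not in nets:
            raise ValueError("checkpoint does not provide the CBCT->CT generator")
        gen = nets["g_cbct_ct"]
        size = cfg.image_size
    norm = clip_and_scale(cbct)
    slices = volume_to_slices(norm, size or norm.shape[1])
    out_slices = []
    for s in slices:
        pixels, _ = gen.synthesize(s.pixels)
        out_slices.append(dataclasses.replace(s, pixels=np.clip(pixels, -1.0, 1.0)))
    return slices_to_volume(out_slices, spacing=cbct.spacing, origin=cbct.origin)
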