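"""Model/Results front-end over the training pipeline.

``CBCTSynthesis`` binds a dataset manifest to a training configuration;
``fit()`` runs the adversarial training and returns a
``SynthesisResults`` carrying the trained networks, the full loss log,
and evaluation helpers (per-volume image-quality metrics on the test
split, cohort summaries with paired Wilcoxon comparisons, slice-wise
volume synthesis).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import phantom as _phantom
from .metrics import evaluate_volume, paired_wilcoxon
from .training import TrainingConfig, TrainingRun, synthesize_volume, train
from .volume_io import HUVolume, load_volume


class CBCTSynthesis:
    """Unpaired (or paired) CBCT-to-CT translation model.

    Parameters
    ----------
    manifest : dict or path
        Dataset manifest produced by :func:`sctgen.phantom.make_dataset`
        (or hand-written in the same schema).
    mode : str
        ``"aggan"`` (attention-guided, unpaired), ``"cyclegan"``
        (no attention, unpaired) or ``"pix2pix"`` (paired).
    config : TrainingConfig, optional
        Full regimen; keyword overrides may be passed instead.
    """

    def __init__(self, manifest, mode: str = "aggan",
                 config: TrainingConfig | None = None, **overrides):
        if not isinstance(manifest, dict):
            manifest = _phantom.load_manifest(manifest)
        self.manifest = manifest
        if config is None:
            config = TrainingConfig(mode=mode, **overrides)
        elif overrides or config.mode != mode:
            config = dataclasses.replace(config, mode=mode, **overrides)
        self.config = config

    @classmethod
    def from_directory(cls, path, **kwargs) -> "CBCTSynthesis":
        return cls(_phantom.load_manifest(path), **kwargs)

    def fit(self, out_dir=None, progress: bool = False) -> "SynthesisResults":
        run = train(self.config, self.manifest, out_dir=out_dir, progress=progress)
        return SynthesisResults(self, run)


class SynthesisResults:
    """Fitted translation networks plus diagnostics."""

    def __init__(self, model: CBCTSynthesis, run: TrainingRun):
        self.model = model
        self.run = run
        self.config = run.config

    @property
    def loss_log(self):
        """Per-iteration loss terms as a DataFrame."""
        return self.run.log_frame()

    def synthesize(self, cbct: HUVolume) -> HUVolume:
        """Generate an sCT volume from a CBCT volume."""
        return synthesize_volume(cbct, self.run)

    def evaluate(self, split: str = "test", with_roi: bool = True):
        """Image-quality metrics per held-out volume.

        Returns a DataFrame with one row per (volume, method) where
        method is ``cbct`` (the uncorrected input) or ``sct`` (the
        translated output), both scored against the aligned CT.
        """
        import pandas as pd

        root = Path(self.model.manifest.get("_root", "."))
        rows = []
        for rec in self.model.manifest["records"]:
            if rec["split"] != split:
                continue
            ct = load_volume(root / rec["ct"])
            cbct = load_volume(root / rec["cbct"])
            roi = load_volume(root / rec["roi"]) if with_roi and "roi" in rec else None
            sct = self.synthesize(cbct)
            for method, vol in (("cbct", cbct), ("sct", sct)):
                tm = evaluate_volume(ct, vol, roi_labels=roi)
                rows.append({"id": rec["id"], "method": method, **tm.to_dict()})
        if not rows:
            raise ValueError(f"no volumes in split {split!r}")
        return pd.DataFrame(rows)

    @staticmethod
    def cohort_summary(metrics_frame):
        """Mean +/- SD across volumes per method, plus paired Wilcoxon
        comparisons between methods on each metric."""
        import pandas as pd

        num_cols = [c for c in ("mae", "ssim", "psnr") if c in metrics_frame]
        stats = metrics_frame.groupby("method")[num_cols].agg(["mean", "std"])
        tests = []
        methods = sorted(metrics_frame["method"].unique())
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1:]:
                a = metrics_frame[metrics_frame["method"] == m1].sort_values("id")
                b = metrics_frame[metrics_frame["method"] == m2].sort_values("id")
                for col in num_cols:
                    if len(a) >= 2:
                        stat, p, sig = paired_wilcoxon(a[col].values, b[col].values)
                    else:
                        stat, p, sig = float("nan"), float("nan"), False
                    tests.append({"metric": col, "a": m1, "b": m2,
                                  "statistic": stat, "p": p, "significant": sig})
        return stats, pd.DataFrame(tests)

    def summary(self) -> str:
        """Text summary of the fit: configuration and final-epoch losses."""
        df = self.loss_log
        n_per_epoch = max(len(df) // max(self.config.epochs, 1), 1)
        last = df.tail(n_per_epoch)
        lines = [
            "CBCT-to-sCT synthesis results",
            "=" * 64,
            f"mode:            {self.config.mode}",
            f"epochs:          {self.config.epochs} "
            f"(lr0={self.config.lr0:g}, decay from {self.config.decay_start})",
            f"slices/epoch:    {n_per_epoch}",
            f"generator:       {self.config.gen_channels} base ch, "
            f"{self.config.n_residual} residual blocks, n_masks={self.config.n_masks}",
            f"discriminator:   {self.config.disc_channels} base ch (patch)",
            f"loss weights:    cycle={self.config.lambda_cycle:g}, "
            f"idt={self.config.lambda_idt:g}",
            "-" * 64,
            "final-epoch mean losses:",
        ]
        for col in ("gan_d_ct", "gan_g_cbct_ct", "gan_d_cbct", "gan_g_ct_cbct",
                    "cycle_cbct", "cycle_ct", "idt_ct", "idt_cbct", "total"):
            if col in last and np.isfinite(last[col]).all():
                lines.append(f"  {col:<16s} {last[col].mean():10.5f}")
        lines.append("=" * 64)
        return "\n".join(lines)
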