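"""Image-quality evaluation: MAE, SSIM, PSNR, ROI HU statistics,
histograms, and paired significance testing.

Conventions: the reference volume is the (deformed/aligned) CT; the
data range for SSIM and PSNR defaults to the clipped HU dynamic range
(2500 HU) and is recorded in every report; SSIM is computed slice-wise
on axial planes with an 11x11 Gaussian window (sigma 1.5, K1=0.01,
K2=0.03) and averaged, with a 3-D windowed variant available.  Cohort
"mean +/- SD" summaries are across volumes, not voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import HU_RANGE, HUVolume

ROI_NAMES = {1: "lung", 2: "bone", 3: "soft_tissue"}

__all__ = [
    "TrialMetrics",
    "mae",
    "ssim",
    "psnr",
    "roi_stats",
    "hu_histogram",
    "paired_wilcoxon",
    "evaluate_volume",
    "ROI_NAMES",
]


def _voxels(v) -> np.ndarray:
    return v.voxels if isinstance(v, HUVolume) else np.asarray(v)


def _check_geometry(reference, test):
    if isinstance(reference, HUVolume) and isinstance(test, HUVolume):
        if not reference.same_geometry(test):
            raise ValueError("reference and test volumes have different geometry")
    elif _voxels(reference).shape != _voxels(test).shape:
        raise ValueError("reference and test arrays have different shapes")


@dataclass
class TrialMetrics:
    """Per-volume evaluation record."""

    mae: float
    ssim: float
    psnr: float
    data_range: float
    roi_hu: dict = field(default_factory=dict)  # name -> (mean, sd)
    histogram: tuple | None = None  # (edges, counts)

    def to_dict(self) -> dict:
        d = {"mae": self.mae, "ssim": self.ssim, "psnr": self.psnr,
             "data_range": self.data_range}
        for name, (mu, sd) in self.roi_hu.items():
            d[f"{name}_mean"] = mu
            d[f"{name}_sd"] = sd
        return d


def mae(reference, test, mask: np.ndarray | None = None) -> float:
    """Mean absolute difference in HU, optionally restricted to a mask."""
    _check_geometry(reference, test)
    diff = np.abs(_voxels(test).astype(np.float64) - _voxels(reference).astype(np.float64))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty evaluation mask")
        diff = diff[mask]
    return float(diff.mean())


def ssim(reference, test, data_range: float = HU_RANGE, slicewise: bool = True,
         K1: float = 0.01, K2: float = 0.03, sigma: float = 1.5,
         win_size: int = 11) -> float:
    """Structural similarity with a Gaussian window.

    Slice-wise on axial planes by default (mean over slices); set
    ``slicewise=False`` for a 3-D window.
    """
    from skimage.metrics import structural_similarity

    _check_geometry(reference, test)
    ref, tst = _voxels(reference).astype(np.float64), _voxels(test).astype(np.float64)
    kwargs = dict(
        data_range=data_range, gaussian_weights=True, sigma=sigma,
        win_size=win_size, use_sample_covariance=False, K1=K1, K2=K2,
    )
    if slicewise:
        vals = [structural_similarity(ref[k], tst[k], **kwargs) for k in range(ref.shape[0])]
        return float(np.mean(vals))
    return float(structural_similarity(ref, tst, **kwargs))


def psnr(reference, test, data_range: float = HU_RANGE) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical inputs."""
    _check_geometry(reference, test)
    mse = float(np.mean(
        (_voxels(test).astype(np.float64) - _voxels(reference).astype(np.float64)) ** 2
    ))
    if mse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(data_range / np.sqrt(mse)))


def roi_stats(vol, roi_labels, labels: dict[int, str] = ROI_NAMES) -> dict[str, tuple[float, float]]:
    """Mean and population SD of HU per labelled ROI.

    Raises if a requested label has no voxels.
    """
    v = _voxels(vol).astype(np.float64)
    lab = np.round(_voxels(roi_labels)).astype(int)
    if v.shape != lab.shape:
        raise ValueError("volume and label grids have different shapes")
    out = {}
    for value, name in labels.items():
        m = lab == value
        if not m.any():
            raise ValueError(f"ROI label {value} ({name}) has no voxels")
        sel = v[m]
        out[name] = (float(sel.mean()), float(sel.std()))
    return out


def hu_histogram(vol, bin_width: float = 10.0,
                 value_range: tuple[float, float] = (-1000.0, 1500.0)):
    """Uniform-bin HU histogram; counts sum to the voxel count.

    Values outside ``value_range`` are clipped into the edge bins, so
    the range must cover the data after HU clipping.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = value_range
    edges = np.arange(lo, hi + bin_width, bin_width, dtype=np.float64)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    v = np.clip(_voxels(vol).ravel(), lo, np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(v, bins=edges)
    return edges, counts


def paired_wilcoxon(sample_a, sample_b, alpha: float = 0.05,
                    alternative: str = "two-sided"):
    """Wilcoxon signed-rank test on paired samples.

    Exact null enumeration for n <= 12 without ties/zeros, normal
    approximation (with tie/zero correction) otherwise.  All-zero
    differences are degenerate: returns (0.0, 1.0, False) with the
    significance flag cleared.
    """
    from scipy import stats

    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0, False
    nonzero = d[d != 0]
    exact_ok = (
        len(nonzero) <= 12
        and len(nonzero) == len(d)
        and len(np.unique(np.abs(nonzero))) == len(nonzero)
    )
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(a, b, alternative=alternative, method=method,
                         correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def evaluate_volume(reference, test, roi_labels=None,
                    data_range: float = HU_RANGE,
                    histogram_bin_width: float | None = None) -> TrialMetrics:
    """Bundle MAE/SSIM/PSNR (plus ROI stats and histogram) for one volume."""
    tm = TrialMetrics(
        mae=mae(reference, test),
        ssim=ssim(reference, test, data_range=data_range),
        psnr=psnr(reference, test, data_range=data_range),
        data_range=data_range,
    )
    if roi_labels is not None:
        tm.roi_hu = roi_stats(test, roi_labels)
    if histogram_bin_width:
        tm.histogram = hu_histogram(test, histogram_bin_width)
    return tm
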