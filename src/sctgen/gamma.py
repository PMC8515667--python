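"""3-D gamma-index dose comparison and relative dose-difference maps.

The gamma index at a reference voxel r is

    gamma(r) = min over r' of sqrt( |r' - r|^2 / dta^2
                                  + (D_e(r') - D_r(r))^2 / dD^2 )

where the minimum runs over evaluated positions r' within the search
radius, ``dta`` is the distance-to-agreement criterion (mm) and ``dD``
the dose-difference criterion — a percentage of the maximum reference
dose under global normalization (the default), or of the local
reference dose when ``normalization="local"``.  A voxel passes when
gamma <= 1; the passing rate is reported over voxels above a low-dose
threshold (default 10% of the reference maximum, always recorded).

The search evaluates the minimum over a uniform grid of candidate
offsets (spacing ``step_fraction * dta`` mm, ball radius
``search_radius_factor * dta``), sampling the evaluated dose by
trilinear interpolation with edge clamping.  Offsets are visited in
order of increasing length so the scan can stop as soon as the
distance penalty alone exceeds every voxel's current minimum — the
result is identical to exhausting the full candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoseGrid",
    "GammaCriteria",
    "candidate_offsets",
    "gamma_map",
    "passing_rate",
    "relative_dose_difference_map",
    "gamma_report",
]


@dataclass(frozen=True)
class DoseGrid:
    """3-D dose distribution (cGy) with axis-aligned geometry.

    ``dose`` is (nz, ny, nx); ``spacing`` and ``origin`` are (x, y, z)
    in mm, matching the volume convention.
    """

    dose: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=np.float64)
        if d.ndim != 3:
            raise ValueError("dose must be 3-D")
        if d.size and d.min() < 0:
            raise ValueError("dose must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self):
        return self.dose.shape


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma acceptance criteria, e.g. ``GammaCriteria(2.0, 2.0)`` = 2 mm/2%."""

    dta_mm: float
    dose_diff_pct: float
    normalization: str = "global"
    low_dose_threshold_pct: float = 10.0

    def __post_init__(self):
        if self.dta_mm <= 0 or self.dose_diff_pct <= 0:
            raise ValueError("dta and dose difference criteria must be positive")
        if not (0 <= self.low_dose_threshold_pct < 100):
            raise ValueError("low-dose threshold must lie in [0, 100)")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")

    def label(self) -> str:
        return f"{self.dta_mm:g}mm/{self.dose_diff_pct:g}%"


def _same_geometry(a: DoseGrid, b: DoseGrid) -> bool:
    return (a.shape == b.shape and np.allclose(a.spacing, b.spacing)
            and np.allclose(a.origin, b.origin))


def _resample_to(reference: DoseGrid, evaluated: DoseGrid) -> np.ndarray:
    """Trilinear resampling of the evaluated dose onto the reference grid."""
    from scipy.ndimage import map_coordinates

    nz, ny, nx = reference.shape
    sx, sy, sz = reference.spacing
    ox, oy, oz = reference.origin
    ex, ey, ez = evaluated.spacing
    eox, eoy, eoz = evaluated.origin
    zi = (oz + np.arange(nz) * sz - eoz) / ez
    yi = (oy + np.arange(ny) * sy - eoy) / ey
    xi = (ox + np.arange(nx) * sx - eox) / ex
    zz, yy, xx = np.meshgrid(zi, yi, xi, indexing="ij")
    return map_coordinates(evaluated.dose, [zz, yy, xx], order=1, mode="nearest")


def candidate_offsets(criteria: GammaCriteria, search_radius_factor: float = 3.0,
                      step_fraction: float = 0.1) -> np.ndarray:
    """Search offsets in mm, shape (k, 3) as (dz, dy, dx), sorted by length.

    Uniform grid with spacing ``step_fraction * dta`` inside a ball of
    radius ``search_radius_factor * dta``; includes the zero offset.
    """
    step = step_fraction * criteria.dta_mm
    radius = search_radius_factor * criteria.dta_mm
    n = int(np.floor(radius / step + 1e-9))
    vals = np.arange(-n, n + 1) * step
    zz, yy, xx = np.meshgrid(vals, vals, vals, indexing="ij")
    offs = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    norms = np.linalg.norm(offs, axis=1)
    keep = norms <= radius + 1e-9
    offs, norms = offs[keep], norms[keep]
    order = np.argsort(norms, kind="stable")
    return offs[order]


def gamma_map(reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria,
              search_radius_factor: float = 3.0, step_fraction: float = 0.1) -> np.ndarray:
    """Gamma value per reference voxel.

    When the grids disagree geometrically the evaluated dose is first
    resampled onto the reference grid.  Raises if the reference
    maximum is zero.
    """
    from scipy.ndimage import shift as nd_shift

    ref = reference.dose
    dmax = ref.max()
    if dmax <= 0:
        raise ValueError("reference dose maximum is zero")
    ev = evaluated.dose if _same_geometry(reference, evaluated) \
        else _resample_to(reference, evaluated)

    if criteria.normalization == "global":
        dd = criteria.dose_diff_pct / 100.0 * dmax
    else:
        dd = np.maximum(criteria.dose_diff_pct / 100.0 * ref, 1e-12)

    offsets = candidate_offsets(criteria, search_radius_factor, step_fraction)
    sx, sy, sz = reference.spacing
    inv_spacing = np.array([1.0 / sz, 1.0 / sy, 1.0 / sx])
    dta2 = criteria.dta_mm**2

    gamma2 = ((ev - ref) / dd) ** 2  # zero-offset candidate
    for off in offsets:
        dist2 = float(off @ off) / dta2
        if dist2 == 0.0:
            continue
        if dist2 >= gamma2.max():
            break  # offsets are sorted: no later candidate can win
        shifted = nd_shift(ev, -off * inv_spacing, order=1, mode="nearest")
        cand = dist2 + ((shifted - ref) / dd) ** 2
        np.minimum(gamma2, cand, out=gamma2)
    return np.sqrt(gamma2)


def passing_rate(gamma_values: np.ndarray, reference: DoseGrid,
                 criteria: GammaCriteria) -> float:
    """Percent of above-threshold voxels with gamma <= 1."""
    ref = reference.dose
    if ref.size == 0 or ref.max() <= 0:
        raise ValueError("reference dose maximum is zero")
    thr = criteria.low_dose_threshold_pct / 100.0 * ref.max()
    sel = ref >= thr
    if not sel.any():
        raise ValueError("no voxels above the low-dose threshold")
    return float(100.0 * np.mean(gamma_values[sel] <= 1.0))


def relative_dose_difference_map(reference: DoseGrid, evaluated: DoseGrid) -> np.ndarray:
    """(evaluated - reference) / max(reference), signed fraction map."""
    dmax = reference.dose.max()
    if dmax <= 0:
        raise ValueError("reference dose maximum is zero")
    ev = evaluated.dose if _same_geometry(reference, evaluated) \
        else _resample_to(reference, evaluated)
    return (ev - reference.dose) / dmax


def gamma_report(reference: DoseGrid, evaluated: DoseGrid,
                 criteria_list: list[GammaCriteria],
                 search_radius_factor: float = 3.0,
                 step_fraction: float = 0.1) -> dict:
    """Passing rates under several criteria, with the settings recorded."""
    out = {}
    for crit in criteria_list:
        g = gamma_map(reference, evaluated, crit, search_radius_factor, step_fraction)
        out[crit.label()] = {
            "passing_rate_pct": passing_rate(g, reference, crit),
            "dta_mm": crit.dta_mm,
            "dose_diff_pct": crit.dose_diff_pct,
            "normalization": crit.normalization,
            "low_dose_threshold_pct": crit.low_dose_threshold_pct,
        }
    return out
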