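"""Synthetic thorax phantom with simulated CBCT artifacts.

Provides aligned CT/CBCT volume pairs (plus ROI labels and synthetic
dose grids) with the tissue statistics of a thoracic CT: an elliptical
body of soft tissue, two lung ellipses, a spine and rib cross-sections
of bone, air outside.  Default tissue means follow phantom CT
measurements (lung -755 HU, bone +716 HU, soft tissue -27.5 HU).

The CBCT transform layers the classical cone-beam degradations on top
of the CT, each independently switchable and additive in HU before the
final clip:

* lung HU depression (scatter-driven underestimation inside the lung),
* cupping — radially increasing negative bias, raised-cosine profile,
* streaks — angularly narrow ridges through the image centre with
  alternating sign, angles drawn per slice group,
* directional shading, a linear ramp across the field of view,
* white Gaussian noise.

Default amplitudes are calibrated so the composite lung mean lands near
-900 HU (the CBCT lung value reported for the physical phantom) and the
soft-tissue mean drops below its CT value, matching the orderings seen
in patient cohorts.  A zero-amplitude spec is the bit-exact identity.

No projection/reconstruction physics is simulated; artifacts are
image-domain models of the observed signatures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import HU_MAX, HU_MIN, HUVolume, save_volume

LABEL_BACKGROUND = 0
LABEL_LUNG = 1
LABEL_BONE = 2
LABEL_SOFT = 3

__all__ = [
    "PhantomSpec",
    "ArtifactSpec",
    "generate_phantom",
    "simulate_cbct",
    "artifact_fields",
    "lung_mask_from_labels",
    "make_dataset",
    "synthesize_dose",
    "LABEL_BACKGROUND",
    "LABEL_LUNG",
    "LABEL_BONE",
    "LABEL_SOFT",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue statistics of the digital thorax.

    Lengths are in voxels of the in-plane grid; HU means/SDs describe
    the voxel value distribution inside each ROI (SD is texture noise,
    not inter-subject spread).
    """

    shape: tuple[int, int, int] = (24, 64, 64)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)  # mm, (x, y, z)
    body_axes: tuple[float, float] = (0.45, 0.38)  # fractions of (nx, ny)
    lung_axes: tuple[float, float] = (0.16, 0.22)
    lung_centers: tuple[tuple[float, float], tuple[float, float]] = (
        (-0.22, -0.04),
        (0.22, -0.04),
    )  # fractional (x, y) offsets from body centre
    spine_radius: float = 0.07  # fraction of nx
    spine_center: tuple[float, float] = (0.0, 0.26)
    rib_radius: float = 0.035
    n_ribs: int = 8
    lung_hu: float = -755.0
    bone_hu: float = 716.2
    soft_hu: float = -27.5
    air_hu: float = -1000.0
    lung_sd: float = 40.0
    bone_sd: float = 60.0
    soft_sd: float = 25.0
    air_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("lung_hu", "bone_hu", "soft_hu"):
            v = getattr(self, name)
            if not (HU_MIN <= v <= HU_MAX):
                raise ValueError(f"{name}={v} outside [{HU_MIN}, {HU_MAX}]")
        if min(self.body_axes) <= 0 or min(self.lung_axes) <= 0:
            raise ValueError("ellipse axes must be positive")


@dataclass(frozen=True)
class ArtifactSpec:
    """CBCT degradation amplitudes, all in HU.  Zero spec = identity."""

    lung_shift: float = -110.0
    cupping_amplitude: float = -40.0
    cupping_width: float = 1.0  # radial profile width, fraction of body radius
    streak_count: int = 6
    streak_amplitude: float = 60.0
    streak_width_px: float = 1.5
    streak_slab: int = 8  # slices sharing one set of streak angles
    shading_amplitude: float = -30.0
    shading_direction: tuple[float, float] = (0.0, 1.0)  # (x, y), need not be unit
    noise_sd: float = 25.0
    seed: int = 0

    def is_identity(self) -> bool:
        return (
            self.lung_shift == 0
            and self.cupping_amplitude == 0
            and (self.streak_count == 0 or self.streak_amplitude == 0)
            and self.shading_amplitude == 0
            and self.noise_sd == 0
        )


# ---------------------------------------------------------------------------
# phantom geometry


def _roi_masks(spec: PhantomSpec):
    nz, ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax, ay = spec.body_axes[0] * nx, spec.body_axes[1] * ny
    body = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0

    lungs = np.zeros_like(body)
    for (fx, fy) in spec.lung_centers:
        lax, lay = spec.lung_axes[0] * nx, spec.lung_axes[1] * ny
        lcx, lcy = cx + fx * nx, cy + fy * ny
        lungs |= ((xx - lcx) / lax) ** 2 + ((yy - lcy) / lay) ** 2 <= 1.0
    lungs &= body

    bone = np.zeros_like(body)
    scx, scy = cx + spec.spine_center[0] * nx, cy + spec.spine_center[1] * ny
    bone |= (xx - scx) ** 2 + (yy - scy) ** 2 <= (spec.spine_radius * nx) ** 2
    # ribs: small circles along the body ellipse at 0.92 of its radius
    for i in range(spec.n_ribs):
        th = np.pi * (0.15 + 0.7 * i / max(spec.n_ribs - 1, 1))  # anterior arc
        for sgn in (+1.0, -1.0):
            rcx = cx + sgn * 0.92 * ax * np.sin(th)
            rcy = cy - 0.92 * ay * np.cos(th)
            bone |= (xx - rcx) ** 2 + (yy - rcy) ** 2 <= (spec.rib_radius * nx) ** 2
    bone &= body
    lungs &= ~bone
    soft = body & ~lungs & ~bone

    if not (lungs.any() and bone.any() and soft.any()):
        raise ValueError("degenerate phantom geometry: an ROI is empty")
    return body, lungs, bone, soft


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[HUVolume, HUVolume]:
    """Voxelize the phantom; returns (HU volume, integer ROI label volume).

    Deterministic given ``spec.seed``.  Labels: 0 air, 1 lung, 2 bone,
    3 soft tissue; the three tissue ROIs are pairwise disjoint by
    construction (bone wins over lung, lung over soft tissue).
    """
    spec.validate()
    _, lungs, bone, soft = _roi_masks(spec)
    nz = spec.shape[0]
    labels2d = np.zeros(spec.shape[1:], dtype=np.int16)
    labels2d[soft] = LABEL_SOFT
    labels2d[lungs] = LABEL_LUNG
    labels2d[bone] = LABEL_BONE
    labels = np.broadcast_to(labels2d, spec.shape).copy()

    rng = np.random.default_rng(spec.seed)
    hu = rng.normal(spec.air_hu, spec.air_sd, size=spec.shape)
    means = {LABEL_LUNG: (spec.lung_hu, spec.lung_sd),
             LABEL_BONE: (spec.bone_hu, spec.bone_sd),
             LABEL_SOFT: (spec.soft_hu, spec.soft_sd)}
    for lab, (mu, sd) in means.items():
        m = labels == lab
        hu[m] = rng.normal(mu, sd, size=int(m.sum()))
    np.clip(hu, HU_MIN, HU_MAX, out=hu)
    geom = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    return HUVolume(voxels=hu, **geom), HUVolume(voxels=labels.astype(np.float32), **geom)


def lung_mask_from_labels(labels: HUVolume | np.ndarray) -> np.ndarray:
    arr = labels.voxels if isinstance(labels, HUVolume) else np.asarray(labels)
    return np.round(arr).astype(int) == LABEL_LUNG


# ---------------------------------------------------------------------------
# CBCT artifact simulation


def artifact_fields(
    ct: HUVolume,
    spec: ArtifactSpec,
    labels: HUVolume | np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-component additive HU fields, keyed by component name.

    The composite CBCT is ``clip(ct + sum of fields)``.  When ``labels``
    is None the lung indicator falls back to an HU window
    (-950, -300) — adequate for phantom images where air sits at
    -1000 HU and soft tissue near 0.
    """
    nz, ny, nx = ct.shape
    rng = np.random.default_rng(spec.seed)
    fields: dict[str, np.ndarray] = {}

    if labels is not None:
        lung = lung_mask_from_labels(labels)
    else:
        lung = (ct.voxels > -950.0) & (ct.voxels < -300.0)

    if spec.lung_shift != 0:
        fields["lung_shift"] = spec.lung_shift * lung.astype(np.float64)

    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    if spec.cupping_amplitude != 0:
        rmax = spec.cupping_width * 0.5 * min(nx, ny)
        r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2) / max(rmax, 1e-9)
        profile = 0.5 * (1.0 - np.cos(np.pi * np.minimum(r, 1.0)))
        fields["cupping"] = np.broadcast_to(
            spec.cupping_amplitude * profile, ct.shape
        ).copy()

    if spec.streak_count > 0 and spec.streak_amplitude != 0:
        streaks = np.zeros(ct.shape)
        for z0 in range(0, nz, max(spec.streak_slab, 1)):
            z1 = min(z0 + max(spec.streak_slab, 1), nz)
            plane = np.zeros((ny, nx))
            angles = rng.uniform(0.0, np.pi, size=spec.streak_count)
            for j, th in enumerate(angles):
                # distance from the line through the centre at angle th
                d = np.abs(-(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th))
                sign = 1.0 if j % 2 == 0 else -1.0
                plane += sign * spec.streak_amplitude * np.exp(
                    -((d / spec.streak_width_px) ** 2)
                )
            streaks[z0:z1] = plane
        fields["streaks"] = streaks

    if spec.shading_amplitude != 0:
        dx, dy = spec.shading_direction
        norm = np.hypot(dx, dy)
        if norm == 0:
            raise ValueError("shading_direction must be non-zero")
        proj = (xx * dx + yy * dy) / norm
        proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-9)
        fields["shading"] = np.broadcast_to(
            spec.shading_amplitude * proj, ct.shape
        ).copy()

    if spec.noise_sd > 0:
        fields["noise"] = rng.normal(0.0, spec.noise_sd, size=ct.shape)

    return fields


def simulate_cbct(
    ct: HUVolume,
    spec: ArtifactSpec = ArtifactSpec(),
    labels: HUVolume | np.ndarray | None = None,
) -> HUVolume:
    """Apply the CBCT degradation model; deterministic given ``spec.seed``."""
    if spec.is_identity():
        return ct.with_voxels(ct.voxels.copy())
    total = np.zeros(ct.shape)
    for f in artifact_fields(ct, spec, labels).values():
        total += f
    out = np.clip(ct.voxels + total, HU_MIN, HU_MAX)
    return ct.with_voxels(out)


# ---------------------------------------------------------------------------
# dataset manifests


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator, frac: float) -> PhantomSpec:
    def j(v):
        return v * (1.0 + rng.uniform(-frac, frac))

    return dataclasses.replace(
        spec,
        body_axes=(j(spec.body_axes[0]), j(spec.body_axes[1])),
        lung_axes=(j(spec.lung_axes[0]), j(spec.lung_axes[1])),
        lung_centers=tuple(
            (c[0] + rng.uniform(-frac, frac) * 0.2, c[1] + rng.uniform(-frac, frac) * 0.2)
            for c in spec.lung_centers
        ),
        spine_radius=j(spec.spine_radius),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_dataset(
    out_dir,
    n_volumes: int,
    phantom_spec: PhantomSpec = PhantomSpec(),
    artifact_spec: ArtifactSpec = ArtifactSpec(),
    seed: int = 0,
    paired: bool = True,
    train_fraction: float = 0.8,
    jitter: float = 0.05,
    overwrite: bool = False,
):
    """Write an aligned CT/CBCT/ROI cohort plus a JSON manifest.

    Each volume gets seeded anatomy jitter (default 5% on ellipse axes
    and centres) so subjects differ.  The first ``train_fraction`` of
    volumes form the training split, the rest the test split.  In
    unpaired mode the manifest lists the CT and CBCT pools without
    linking them; the voxel data are aligned either way (alignment by
    construction is what makes every metric testable).

    Returns the manifest as a dict (also saved as ``manifest.json``).
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    n_train = max(1, int(round(train_fraction * n_volumes))) if n_volumes > 1 else 1
    records = []
    for i in range(n_volumes):
        vspec = _jitter_spec(phantom_spec, rng, jitter)
        ct, roi = generate_phantom(vspec)
        aspec = dataclasses.replace(artifact_spec, seed=int(rng.integers(0, 2**31 - 1)))
        cbct = simulate_cbct(ct, aspec, labels=roi)
        paths = {
            "ct": f"ct_{i:03d}.nii.gz",
            "cbct": f"cbct_{i:03d}.nii.gz",
            "roi": f"roi_{i:03d}.nii.gz",
        }
        save_volume(ct, out_dir / paths["ct"])
        save_volume(cbct, out_dir / paths["cbct"])
        save_volume(roi, out_dir / paths["roi"])
        records.append(
            {
                "id": f"vol_{i:03d}",
                "split": "train" if i < n_train else "test",
                "seed": vspec.seed,
                **paths,
            }
        )
    manifest = {
        "paired": bool(paired),
        "seed": int(seed),
        "dose_units": "cGy",
        "records": records,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(path):
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    with open(path) as fh:
        manifest = json.load(fh)
    manifest["_root"] = str(path.parent)
    return manifest


def synthesize_dose(
    target_center: tuple[float, float, float],
    target_radius: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    prescription: float = 5000.0,
    hotspot: float = 0.02,
):
    """Smooth synthetic dose ball: Gaussian falloff around the target.

    ``target_center`` is in mm, physical coordinates; the maximum dose,
    ``prescription * (1 + hotspot)`` cGy, sits at the grid voxel closest
    to the target centre.  Purely geometric — a stand-in for a planned
    dose distribution, adequate as gamma-analysis input.
    """
    from .gamma import DoseGrid

    nz, ny, nx = shape
    sx, sy, sz = spacing
    ox, oy, oz = origin
    zs = oz + np.arange(nz) * sz
    ys = oy + np.arange(ny) * sy
    xs = ox + np.arange(nx) * sx
    tx, ty, tz = target_center
    if not (xs[0] <= tx <= xs[-1] and ys[0] <= ty <= ys[-1] and zs[0] <= tz <= zs[-1]):
        raise ValueError("target centre lies outside the dose grid")
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    # snap the centre onto the nearest voxel so max(dose) is attained on-grid
    tx = xs[np.argmin(np.abs(xs - tx))]
    ty = ys[np.argmin(np.abs(ys - ty))]
    tz = zs[np.argmin(np.abs(zs - tz))]
    d2 = (xx - tx) ** 2 + (yy - ty) ** 2 + (zz - tz) ** 2
    dose = prescription * (1.0 + hotspot) * np.exp(-d2 / (2.0 * target_radius**2))
    return DoseGrid(dose=dose, spacing=spacing, origin=origin)
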