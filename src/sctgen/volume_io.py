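"""Volume I/O and intensity normalization.

CT-like volumes are held as :class:`HUVolume`: a 3-D scalar grid in
Hounsfield units with axis-aligned geometry, stored in ``(z, y, x)``
order so that ``voxels[k]`` is the k-th axial plane.  Intensities are
clipped to the thoracic window [-1000, 1500] HU and affinely mapped to
the network domain [-1, 1]; axial planes are resampled to the training
resolution (256 x 256 by default) with bilinear interpolation.

Supported on-disk formats: NIfTI (.nii / .nii.gz, via nibabel) and
axis-aligned DICOM CT series (via pydicom).  ROI label volumes use
integer NIfTI (0 background, 1 lung, 2 bone, 3 soft tissue).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

HU_MIN = -1000.0
HU_MAX = 1500.0
HU_RANGE = HU_MAX - HU_MIN  # 2500 HU dynamic range after clipping
TRAINING_SIZE = 256

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "HU_RANGE",
    "TRAINING_SIZE",
    "HUVolume",
    "NormalizedImage",
    "FormatError",
    "load_volume",
    "save_volume",
    "save_dicom_series",
    "clip_and_scale",
    "inverse_scale",
    "volume_to_slices",
    "slices_to_volume",
]


class FormatError(ValueError):
    """Unreadable or internally inconsistent volume file(s)."""


@dataclass(frozen=True)
class HUVolume:
    """3-D scalar grid with axis-aligned geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar values, HU unless stated otherwise by the caller.
    spacing : tuple of float
        Voxel spacing ``(sx, sy, sz)`` in mm, strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm, ``(ox, oy, oz)``.
    axes : str
        Storage-order tag; only ``"zyx"`` is supported.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "zyx"

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxel values must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.axes != "zyx":
            raise ValueError(f"unsupported axes order {self.axes!r}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "HUVolume":
        """Same geometry, new voxel data."""
        return dataclasses.replace(self, voxels=voxels)

    def same_geometry(self, other: "HUVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass(frozen=True)
class NormalizedImage:
    """One axial slice at training resolution, values in [-1, 1].

    Carries the source in-plane shape and slice index so a stack of
    slices can be reassembled into the original volume grid.
    """

    pixels: np.ndarray
    source_shape: tuple[int, int]
    index: int

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if px.size and (px.min() < -1.0 - 1e-6 or px.max() > 1.0 + 1e-6):
            raise ValueError("normalized pixels must lie in [-1, 1]")
        object.__setattr__(self, "pixels", px)


# ---------------------------------------------------------------------------
# intensity normalization


def clip_and_scale(vol):
    """Clip to [-1000, 1500] HU and scale affinely to [-1, 1].

    ``x -> ((clip(x) + 1000) / 2500) * 2 - 1``.  Total on finite input;
    monotone non-decreasing; idempotent in HU terms (values already in
    range are mapped exactly).  Accepts an :class:`HUVolume` (returns a
    volume with the same geometry) or a bare array.
    """
    arr = vol.voxels if isinstance(vol, HUVolume) else np.asarray(vol)
    clipped = np.clip(arr, HU_MIN, HU_MAX)
    scaled = (clipped - HU_MIN) / HU_RANGE * 2.0 - 1.0
    if isinstance(vol, HUVolume):
        return vol.with_voxels(scaled)
    return scaled


def inverse_scale(norm):
    """Map [-1, 1] back to HU: ``y -> (y + 1)/2 * 2500 - 1000``.

    Exact inverse of :func:`clip_and_scale` on [-1000, 1500] HU.
    Raises ``ValueError`` on out-of-range input (beyond a small
    floating-point tolerance).
    """
    arr = norm.voxels if isinstance(norm, HUVolume) else np.asarray(norm)
    if arr.size and (arr.min() < -1.0 - 1e-6 or arr.max() > 1.0 + 1e-6):
        raise ValueError("inverse_scale input must lie in [-1, 1]")
    hu = (np.clip(arr, -1.0, 1.0) + 1.0) / 2.0 * HU_RANGE + HU_MIN
    if isinstance(norm, HUVolume):
        return norm.with_voxels(hu)
    return hu


# ---------------------------------------------------------------------------
# slicing / reassembly


def _resize2d(plane: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    if plane.shape == tuple(shape):
        return plane.astype(np.float32, copy=True)
    down = shape[0] < plane.shape[0] or shape[1] < plane.shape[1]
    out = resize(
        plane.astype(np.float64),
        shape,
        order=1,
        mode="edge",
        anti_aliasing=down,
        preserve_range=True,
    )
    return out.astype(np.float32)


def volume_to_slices(vol: HUVolume, target_size: int = TRAINING_SIZE) -> list[NormalizedImage]:
    """Split a normalized volume into axial slices at training resolution.

    The volume must already be in the network domain [-1, 1] (use
    :func:`clip_and_scale` first).  Bilinear resampling, with an
    anti-aliasing prefilter when downscaling.  Returns one
    :class:`NormalizedImage` per axial index, in order.
    """
    if vol.voxels.size == 0 or vol.shape[0] == 0:
        raise ValueError("cannot slice an empty volume")
    if vol.voxels.min() < -1.0 - 1e-6 or vol.voxels.max() > 1.0 + 1e-6:
        raise ValueError("volume must be normalized to [-1, 1] before slicing")
    src_shape = vol.shape[1:]
    out = []
    for k in range(vol.shape[0]):
        px = _resize2d(vol.voxels[k], (target_size, target_size))
        np.clip(px, -1.0, 1.0, out=px)
        out.append(NormalizedImage(pixels=px, source_shape=src_shape, index=k))
    return out


def slices_to_volume(
    slices: Sequence[NormalizedImage],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> HUVolume:
    """Reassemble axial slices into an HU volume.

    Slices are resized back to their source in-plane grid, stacked in
    slice-index order, and mapped through :func:`inverse_scale`; input
    order is irrelevant.  Raises ``ValueError`` if indices are not the
    contiguous range 0..n-1 or the source shapes disagree.
    """
    if not slices:
        raise ValueError("no slices to assemble")
    shapes = {s.source_shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"slices disagree on source shape: {sorted(shapes)}")
    ordered = sorted(slices, key=lambda s: s.index)
    indices = [s.index for s in ordered]
    if indices != list(range(len(ordered))):
        missing = sorted(set(range(len(ordered))) - set(indices))
        raise ValueError(f"slice indices not contiguous, missing {missing}")
    src_shape = ordered[0].source_shape
    planes = [np.clip(_resize2d(s.pixels, src_shape), -1.0, 1.0) for s in ordered]
    hu = inverse_scale(np.stack(planes, axis=0))
    return HUVolume(voxels=hu, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# file I/O


def load_volume(path, format_hint: str | None = None) -> HUVolume:
    """Load a volume from a NIfTI file or a DICOM series directory.

    DICOM rescale slope/intercept are applied so values are HU.
    ``format_hint`` may be ``"nifti"`` or ``"dicom"``; by default the
    format is inferred (directory -> DICOM series, file -> NIfTI).
    """
    path = Path(path)
    if format_hint is None:
        format_hint = "dicom" if path.is_dir() else "nifti"
    if format_hint == "nifti":
        return _load_nifti(path)
    if format_hint == "dicom":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format hint {format_hint!r}")


def _load_nifti(path: Path) -> HUVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    # nibabel stores (x, y, z); internal convention is (z, y, x)
    voxels = np.transpose(data, (2, 1, 0))
    return HUVolume(voxels=voxels, spacing=tuple(float(z) for z in zooms), origin=origin)


def save_volume(vol: HUVolume, path) -> None:
    """Write as NIfTI with an axis-aligned affine built from the geometry."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    data = np.transpose(np.asarray(vol.voxels), (2, 1, 0))
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def _load_dicom_series(path: Path) -> HUVolume:
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() in {".dcm", ".ima"})
    if not files:
        files = sorted(p for p in Path(path).iterdir() if p.is_file())
    if not files:
        raise FormatError(f"no DICOM files found in {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise FormatError(f"cannot read DICOM file {f}: {exc}") from exc
        slices.append((f, ds))

    ref_orient = None
    ref_spacing = None
    planes = []
    for f, ds in slices:
        orient = tuple(float(v) for v in getattr(ds, "ImageOrientationPatient", (1, 0, 0, 0, 1, 0)))
        pix_spacing = tuple(float(v) for v in ds.PixelSpacing)
        if ref_orient is None:
            ref_orient, ref_spacing = orient, pix_spacing
        elif not np.allclose(orient, ref_orient, atol=1e-4):
            raise FormatError(f"inconsistent slice orientation in {f.name}")
        elif not np.allclose(pix_spacing, ref_spacing, atol=1e-6):
            raise FormatError(f"inconsistent pixel spacing in {f.name}")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        z = float(ds.ImagePositionPatient[2]) if hasattr(ds, "ImagePositionPatient") else float(
            getattr(ds, "InstanceNumber", len(planes))
        )
        planes.append((z, ds.pixel_array.astype(np.float32) * slope + intercept, ds))

    planes.sort(key=lambda t: t[0])
    zs = [p[0] for p in planes]
    if len(zs) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0:
            raise FormatError("duplicate or non-monotone slice positions in series")
        slice_spacing = float(np.mean(dz))
        if not np.allclose(dz, slice_spacing, atol=1e-3):
            raise FormatError("non-uniform slice spacing in series")
    else:
        slice_spacing = float(getattr(planes[0][2], "SliceThickness", 1.0))
    ds0 = planes[0][2]
    ipp = tuple(float(v) for v in getattr(ds0, "ImagePositionPatient", (0.0, 0.0, 0.0)))
    voxels = np.stack([p[1] for p in planes], axis=0)
    spacing = (ref_spacing[1], ref_spacing[0], slice_spacing)  # (col, row, z) -> (x, y, z)
    return HUVolume(voxels=voxels, spacing=spacing, origin=ipp)


def save_dicom_series(vol: HUVolume, directory) -> None:
    """Write an axis-aligned CT series, one file per axial slice.

    Values are stored as int16 with identity rescale, so reload agrees
    with the source within rescale quantization (0.5 HU).
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    sx, sy, sz = vol.spacing
    ox, oy, oz = vol.origin
    for k in range(vol.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "synthetic^phantom"
        ds.PatientID = "SYN000"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [ox, oy, oz + k * sz]
        ds.SliceThickness = sz
        ds.PixelSpacing = [sy, sx]  # row spacing, column spacing
        ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.round(vol.voxels[k]).astype(np.int16).tobytes()
        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)
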