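"""Image containers, readers/writers, min-max normalization, and slice augmentations.

The package works on plain scalar grids: 2D ``(rows, cols)`` slices or 3D
``(slices, rows, cols)`` volumes, with optional physical voxel spacing in mm.
CT intensities are kept in whatever units the source file uses; the pipeline
normalizes crops to a target interval (default [0, 1]) before computing
geodesic cue maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .exceptions import ArgumentError, DomainError, FormatError, ShapeError

__all__ = [
    "IntensityImage",
    "BinaryMask",
    "NormalizationSpec",
    "load_image",
    "load_mask",
    "save_image",
    "save_mask",
    "write_dicom_series",
    "normalize",
    "augment",
    "AUGMENTATIONS",
]


@dataclass
class IntensityImage:
    """A scalar 2D or 3D grid with optional physical metadata.

    Parameters
    ----------
    values : ndarray
        2D ``(H, W)`` or 3D ``(D, H, W)`` array of finite scalars.
    spacing : tuple of float, optional
        Physical size of one pixel/voxel along each axis, in mm.
    origin : tuple of float, optional
        Physical offset of the first voxel.
    """

    values: np.ndarray
    spacing: Optional[tuple] = None
    origin: Optional[tuple] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise DomainError(f"image must be 2D or 3D, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise DomainError(f"every axis must have length >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("image values must all be finite")
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != self.values.ndim:
                raise DomainError("spacing length must match image ndim")
        if self.origin is not None:
            self.origin = tuple(float(s) for s in self.origin)

    @property
    def shape(self):
        return self.values.shape

    @property
    def ndim(self):
        return self.values.ndim


@dataclass
class BinaryMask:
    """A {0,1} grid congruent with its image."""

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values)
        if not np.isin(arr, (0, 1)).all():
            raise DomainError("mask values must be 0 or 1")
        self.values = arr.astype(np.uint8)

    @property
    def shape(self):
        return self.values.shape

    def check_congruent(self, img: IntensityImage) -> None:
        if self.values.shape != img.values.shape:
            raise ShapeError(
                f"mask shape {self.values.shape} does not match image shape {img.values.shape}"
            )


@dataclass(frozen=True)
class NormalizationSpec:
    """Target interval [ef1, ef2] of the min-max rescale."""

    ef1: float = 0.0
    ef2: float = 1.0

    def __post_init__(self):
        if not self.ef1 < self.ef2:
            raise DomainError(f"require ef1 < ef2, got ({self.ef1}, {self.ef2})")


def normalize(img: IntensityImage, spec: NormalizationSpec = NormalizationSpec()) -> IntensityImage:
    """Min-max rescale so the image minimum maps to ef1 and the maximum to ef2.

    A constant image (zero range) maps to all-ef1 by convention.
    """
    x = img.values
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        out = np.full_like(x, spec.ef1, dtype=np.float64)
    else:
        out = spec.ef1 + (spec.ef2 - spec.ef1) * (x - lo) / (hi - lo)
    return IntensityImage(out, spacing=img.spacing, origin=img.origin)


def _rot90(a):
    return np.rot90(a)


AUGMENTATIONS = {
    "rot90": _rot90,
    "transpose": np.transpose,
    "hflip": np.fliplr,
    "vflip": np.flipud,
}


def augment(img: IntensityImage, op: str) -> IntensityImage:
    """Apply one of the four slice augmentations: rot90, transpose, hflip, vflip.

    3D volumes are transformed slice-wise on the two in-plane (last) axes.
    """
    try:
        fn = AUGMENTATIONS[op]
    except KeyError:
        raise ArgumentError(
            f"unknown augmentation {op!r}; choose from {sorted(AUGMENTATIONS)}"
        ) from None
    x = img.values
    if x.ndim == 2:
        out = fn(x)
    else:
        out = np.stack([fn(sl) for sl in x])
    return IntensityImage(np.ascontiguousarray(out), spacing=None, origin=None)


# ---------------------------------------------------------------------------
# I/O: DICOM series directories, NIfTI, PNG
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".png"):
        return "png"
    raise ArgumentError(f"cannot infer format of {path}; pass format explicitly")


def _load_dicom_dir(path: Path) -> IntensityImage:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no .dcm files in {path}")
    try:
        dsets = [pydicom.dcmread(str(f)) for f in files]
    except Exception as e:  # pragma: no cover - corrupt input path
        raise FormatError(f"unreadable DICOM in {path}: {e}") from e
    dsets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    slices = [d.pixel_array for d in dsets]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ShapeError(f"mixed slice shapes in DICOM series {path}: {sorted(shapes)}")
    vol = np.stack(slices).astype(np.float64)
    d0 = dsets[0]
    spacing = None
    if hasattr(d0, "PixelSpacing"):
        thick = float(getattr(d0, "SliceThickness", 1.0))
        spacing = (thick, float(d0.PixelSpacing[0]), float(d0.PixelSpacing[1]))
    return IntensityImage(vol, spacing=spacing)


def _load_nifti(path: Path) -> IntensityImage:
    import nibabel as nib

    try:
        nimg = nib.load(str(path))
        data = np.asanyarray(nimg.dataobj).astype(np.float64)
    except Exception as e:
        raise FormatError(f"unreadable NIfTI {path}: {e}") from e
    zooms = tuple(float(z) for z in nimg.header.get_zooms()[: data.ndim])
    if data.ndim not in (2, 3):
        data = np.squeeze(data)
    return IntensityImage(data, spacing=zooms if len(zooms) == data.ndim else None)


def _load_png(path: Path) -> IntensityImage:
    import imageio.v3 as iio

    try:
        arr = iio.imread(str(path))
    except Exception as e:
        raise FormatError(f"unreadable PNG {path}: {e}") from e
    if arr.ndim == 3:  # collapse RGB(A) to gray by channel mean
        arr = arr[..., :3].mean(axis=-1)
    return IntensityImage(arr.astype(np.float64))


def load_image(path, format: Optional[str] = None) -> IntensityImage:
    """Load an image from a DICOM series directory, a NIfTI file, or a PNG.

    Spacing is taken from file metadata when present, else left unset
    (interpreted as unit spacing downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    fmt = format or _detect_format(path)
    if fmt == "dicom_dir":
        return _load_dicom_dir(path)
    if fmt == "nifti":
        return _load_nifti(path)
    if fmt == "png":
        return _load_png(path)
    raise ArgumentError(f"unknown format {fmt!r}")


def load_mask(path, format: Optional[str] = None) -> BinaryMask:
    """Load a mask in any supported image format; nonzero values map to 1."""
    img = load_image(path, format=format)
    return BinaryMask((img.values != 0).astype(np.uint8))


def save_image(img: IntensityImage, path) -> None:
    """Write an image as NIfTI (.nii/.nii.gz) or PNG (8/16-bit gray, 2D only)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        if img.spacing is not None:
            for i, s in enumerate(img.spacing):
                affine[i, i] = s
        nib.save(nib.Nifti1Image(img.values.astype(np.float64), affine), str(path))
    elif name.endswith(".png"):
        import imageio.v3 as iio

        if img.ndim != 2:
            raise DomainError("PNG output requires a 2D image")
        x = img.values
        if np.all(x == np.round(x)) and x.min() >= 0 and x.max() <= 255:
            iio.imwrite(str(path), x.astype(np.uint8))
        else:  # rescale to 16-bit
            spec = NormalizationSpec(0, 65535)
            iio.imwrite(str(path), np.round(normalize(img, spec).values).astype(np.uint16))
    else:
        raise ArgumentError(f"unsupported output format for {path}")


def save_mask(mask: BinaryMask, path) -> None:
    path = Path(path)
    if path.name.lower().endswith(".png"):
        import imageio.v3 as iio

        iio.imwrite(str(path), (mask.values * 255).astype(np.uint8))
    else:
        save_image(IntensityImage(mask.values.astype(np.float64)), path)


def write_dicom_series(img: IntensityImage, directory) -> None:
    """Write a 3D volume as a minimal-tag DICOM series (one .dcm per slice).

    Intended for round-trip testing and phantom export; intensities are
    rounded to uint16.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if img.ndim != 3:
        raise DomainError("DICOM series output requires a 3D image")
    vol = img.values
    if vol.min() < 0 or vol.max() > 65535 or not np.all(vol == np.round(vol)):
        raise DomainError("DICOM series writer requires integer values in [0, 65535]")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    for k, sl in enumerate(vol.astype(np.uint16)):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = sl.shape
        if img.spacing is not None:
            ds.SliceThickness = img.spacing[0]
            ds.PixelSpacing = [img.spacing[1], img.spacing[2]]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = sl.tobytes()
        ds.save_as(str(directory / f"slice_{k:04d}.dcm"), enforce_file_format=True)
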