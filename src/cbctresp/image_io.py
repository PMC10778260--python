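"""Reading and writing HU-calibrated image slices and volumes.

Two on-disk layouts are supported:

``dicom_series``
    A directory of single-frame CT DICOM files sharing one series.  Stored
    values are converted to Hounsfield units with the DICOM rescale
    convention (``stored * RescaleSlope + RescaleIntercept``); slices are
    ordered by ``ImagePositionPatient`` along the slice axis.

``raster_stack``
    A dependency-light fixture layout: one 16-bit TIFF per slice plus a JSON
    sidecar (``stack.json``) carrying pixel spacing, slice thickness, slice
    order and an additive HU offset.  Round trips are lossless for integer
    HU in the int16 range.

All arrays use a (row, col) 0-based convention with row increasing downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Sequence

import numpy as np
import pydicom
import tifffile
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

SIDECAR_NAME = "stack.json"


class GeometryError(ValueError):
    """Raised when slices in a volume disagree on shape or spacing."""


@dataclass(frozen=True)
class ImageSlice:
    """A 2D grid of Hounsfield units with physical pixel spacing.

    Parameters
    ----------
    pixels : numpy.ndarray
        2D float array of HU values.
    spacing_row, spacing_col : float
        Pixel pitch in mm along rows (downward) and columns.
    slice_index : int
        Position of this slice in its volume.
    meta : dict
        Free-form source metadata (DICOM tags, sidecar fields, ...).
    """

    pixels: np.ndarray
    spacing_row: float
    spacing_col: float
    slice_index: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite HU values")
        if self.spacing_row <= 0 or self.spacing_col <= 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_row * self.spacing_col


@dataclass(frozen=True)
class ImageVolume:
    """An ordered stack of congruent :class:`ImageSlice` objects."""

    slices: tuple[ImageSlice, ...]
    slice_thickness: float

    def __post_init__(self) -> None:
        if len(self.slices) == 0:
            raise ValueError("volume needs at least one slice")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        ref = self.slices[0]
        for s in self.slices[1:]:
            if s.shape != ref.shape:
                raise GeometryError("inconsistent geometry: slice shapes differ")
            if not (
                abs(s.spacing_row - ref.spacing_row) < 1e-9
                and abs(s.spacing_col - ref.spacing_col) < 1e-9
            ):
                raise GeometryError("inconsistent geometry: pixel spacings differ")
        object.__setattr__(self, "slices", tuple(self.slices))

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, i: int) -> ImageSlice:
        return self.slices[i]

    @property
    def spacing(self) -> tuple[float, float]:
        return self.slices[0].spacing_row, self.slices[0].spacing_col

    def as_array(self) -> np.ndarray:
        """Stack the volume into a (n_slices, rows, cols) HU array."""
        return np.stack([s.pixels for s in self.slices])


def volume_from_array(
    voxels: np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
    slice_thickness: float = 1.0,
) -> ImageVolume:
    """Wrap a (n_slices, rows, cols) HU array into an :class:`ImageVolume`."""
    voxels = np.asarray(voxels, dtype=float)
    if voxels.ndim != 3:
        raise ValueError("expected a (n_slices, rows, cols) array")
    slices = tuple(
        ImageSlice(voxels[i], spacing[0], spacing[1], slice_index=i)
        for i in range(voxels.shape[0])
    )
    return ImageVolume(slices, slice_thickness)


# ---------------------------------------------------------------------------
# raster_stack fixture format
# ---------------------------------------------------------------------------

def write_raster_stack(volume: ImageVolume, path: str | Path, hu_offset: int = 0) -> Path:
    """Write a volume as 16-bit TIFF slices + JSON sidecar; returns the dir."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = []
    for i, s in enumerate(volume.slices):
        stored = np.round(s.pixels - hu_offset)
        if stored.min() < np.iinfo(np.int16).min or stored.max() > np.iinfo(np.int16).max:
            raise ValueError("HU values out of int16 range for the chosen hu_offset")
        name = f"slice_{i:04d}.tif"
        tifffile.imwrite(path / name, stored.astype(np.int16))
        names.append(name)
    sidecar = {
        "spacing_mm": [volume.spacing[0], volume.spacing[1]],
        "slice_thickness_mm": volume.slice_thickness,
        "hu_offset": hu_offset,
        "slices": names,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def _read_raster_stack(path: Path) -> ImageVolume:
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    spacing = tuple(float(v) for v in sidecar["spacing_mm"])
    offset = float(sidecar.get("hu_offset", 0))
    slices = []
    for i, name in enumerate(sidecar["slices"]):
        stored = tifffile.imread(path / name)
        slices.append(
            ImageSlice(
                stored.astype(float) + offset,
                spacing[0],
                spacing[1],
                slice_index=i,
                meta={"source": str(path / name)},
            )
        )
    return ImageVolume(tuple(slices), float(sidecar["slice_thickness_mm"]))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_series(path: Path) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise FileNotFoundError(f"no DICOM files found under {path}")

    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series_uids) != 1:
        raise GeometryError("inconsistent geometry: multiple DICOM series in directory")

    def z_pos(ds: Dataset) -> float:
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_pos)

    slices = []
    ref_spacing = None
    for i, ds in enumerate(datasets):
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError("missing rescale metadata (RescaleSlope/RescaleIntercept)")
        if "PixelSpacing" not in ds:
            raise ValueError("missing PixelSpacing")
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        if ref_spacing is None:
            ref_spacing = spacing
        elif not np.allclose(spacing, ref_spacing):
            raise GeometryError("inconsistent geometry: pixel spacings differ")
        hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(
            ImageSlice(
                hu,
                spacing[0],
                spacing[1],
                slice_index=i,
                meta={"sop_instance_uid": getattr(ds, "SOPInstanceUID", None)},
            )
        )
    thickness = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)
    return ImageVolume(tuple(slices), thickness)


def write_dicom_series(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as a minimal CT DICOM series (int16 HU, slope 1)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    for i, s in enumerate(volume.slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, i * volume.slice_thickness]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [volume.spacing[0], volume.spacing[1]]
        ds.SliceThickness = volume.slice_thickness
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        stored = np.round(s.pixels - ds.RescaleIntercept).astype(np.int16)
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.tobytes()
        ds.save_as(path / f"ct_{i:04d}.dcm", enforce_file_format=True)
    return path


def read_volume(
    path: str | Path, format: Literal["dicom_series", "raster_stack"]
) -> ImageVolume:
    """Read an image volume from disk and convert it to HU.

    Parameters
    ----------
    path : path-like
        Directory holding the series / stack.
    format : {"dicom_series", "raster_stack"}
        On-disk layout; see the module docstring.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if format == "dicom_series":
        return _read_dicom_series(path)
    if format == "raster_stack":
        return _read_raster_stack(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# central-slice selection
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=bool)


def _seeded_component_size(pixels: np.ndarray, seed_rc: tuple[int, int], iso_value: float) -> int:
    """Pixel count of the 8-connected component >= iso through seed_rc; 0 if none."""
    r, c = seed_rc
    mask = pixels >= iso_value
    if not mask[r, c]:
        return 0
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    return int(np.sum(labels == labels[r, c]))


def select_central_slice(
    volume: ImageVolume, seed: Sequence[int], iso_value: float
) -> int:
    """Pick the slice through the tumor's largest cross-section.

    Starting from the seeded slice, looks outward through the contiguous run
    of slices where the 8-connected region through ``(row, col)`` at
    ``iso_value`` is non-empty, and returns the index whose region pixel
    count is maximal (ties resolved toward the lower index).
    """
    k, r, c = (int(v) for v in seed)
    arr_shape = (len(volume),) + volume[0].shape
    if not (0 <= k < arr_shape[0] and 0 <= r < arr_shape[1] and 0 <= c < arr_shape[2]):
        raise IndexError(f"seed {tuple(seed)} outside volume bounds {arr_shape}")
    if volume[k].pixels[r, c] < iso_value:
        raise ValueError("seed voxel below iso value")

    counts = {k: _seeded_component_size(volume[k].pixels, (r, c), iso_value)}
    for j in range(k - 1, -1, -1):
        n = _seeded_component_size(volume[j].pixels, (r, c), iso_value)
        if n == 0:
            break
        counts[j] = n
    for j in range(k + 1, len(volume)):
        n = _seeded_component_size(volume[j].pixels, (r, c), iso_value)
        if n == 0:
            break
        counts[j] = n

    best = max(sorted(counts), key=lambda j: (counts[j], -j))
    return best
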