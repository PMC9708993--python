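"""Readers and writers for slices and annotation sidecars.

Slices travel as 16-bit grayscale PNG (intensities affinely packed into
uint16, with the scale recorded in the JSON sidecar) or as single-slice
DICOM secondary captures with rescale slope/intercept.  Annotations use a
simple JSON sidecar: {id, centroid, bbox, grade}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from PIL import Image

from .types import CTSlice, NoduleAnnotation

__all__ = [
    "write_png16", "read_png16", "write_dicom", "read_dicom",
    "write_annotation", "read_annotation",
]


def write_png16(slice_: CTSlice, path: str | Path) -> None:
    """Pack intensities into uint16 over the slice's own range; the affine
    (intercept, slope) and metadata go to a sibling ``.meta.json``."""
    path = Path(path)
    lo, hi = float(slice_.pixels.min()), float(slice_.pixels.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    packed = np.round((slice_.pixels - lo) / scale).astype(np.uint16)
    Image.fromarray(packed).save(path)
    meta = {"intercept": lo, "slope": scale, "spacing": slice_.spacing,
            "normalized": slice_.normalized, "id": slice_.id}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_png16(path: str | Path) -> CTSlice:
    path = Path(path)
    packed = np.asarray(Image.open(path), dtype=np.float64)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {"intercept": 0.0, "slope": 1.0, "spacing": 1.0,
                "normalized": False, "id": path.stem}
    pixels = packed * meta["slope"] + meta["intercept"]
    if meta["normalized"]:
        pixels = np.clip(pixels, 0.0, 1.0)
    return CTSlice(pixels, spacing=meta["spacing"],
                   normalized=meta["normalized"], id=meta["id"])


def write_dicom(slice_: CTSlice, path: str | Path) -> None:
    """Single-slice secondary-capture DICOM with rescale slope/intercept."""
    lo = float(slice_.pixels.min())
    hi = float(slice_.pixels.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    stored = np.round((slice_.pixels - lo) / slope).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = slice_.id or "phantom"
    ds.Rows, ds.Columns = slice_.shape
    ds.PixelSpacing = [slice_.spacing, slice_.spacing]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleIntercept = lo
    ds.RescaleSlope = slope
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_dicom(path: str | Path) -> CTSlice:
    ds = pydicom.dcmread(path)
    pixels = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept
    spacing = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else 1.0
    return CTSlice(pixels, spacing=spacing, normalized=False,
                   id=str(getattr(ds, "PatientID", "")))


def write_annotation(ann: NoduleAnnotation, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "id": ann.id, "centroid": list(ann.centroid),
        "bbox": list(ann.bbox), "grade": ann.grade,
    }))


def read_annotation(path: str | Path) -> NoduleAnnotation:
    data = json.loads(Path(path).read_text())
    return NoduleAnnotation(
        centroid=tuple(data["centroid"]), bbox=tuple(data["bbox"]),
        grade=data["grade"], id=data.get("id", ""),
    )
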