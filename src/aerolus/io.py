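"""Readers and writers for the standard on-disk formats.

Clips travel as multi-frame 8-bit grayscale TIFF plus a JSON sidecar with
pixel spacing and acquisition metadata (optionally as a DICOM multi-frame
cine); CT phantoms as NIfTI gray volume + integer-label lung mask with a
JSON sidecar naming the probe axis; ROI annotations and cohort manifests as
JSON / CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import tifffile

from .ct_aeration import CtVolume
from .errors import DomainError
from .lus_features import RoiSpec, UltrasoundClip


# ---------------------------------------------------------------------------
# Ultrasound clips


def write_clip_tiff(clip: UltrasoundClip, path: str | Path) -> Path:
    """Multi-frame grayscale TIFF with a ``<stem>.json`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, clip.frames.astype(np.uint8))
    sidecar = {
        "pixel_spacing_cm_per_px": clip.pixel_spacing_cm_per_px,
        "frame_rate_hz": clip.frame_rate_hz,
        "gain": clip.gain,
        "true_grade": clip.true_grade,
        "metadata": clip.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_clip_tiff(path: str | Path) -> UltrasoundClip:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return UltrasoundClip(
        frames=frames,
        pixel_spacing_cm_per_px=sidecar.get("pixel_spacing_cm_per_px", 0.01),
        frame_rate_hz=sidecar.get("frame_rate_hz", 15.0),
        gain=sidecar.get("gain", 74.0),
        true_grade=sidecar.get("true_grade"),
        metadata=sidecar.get("metadata", {}),
    )


def write_clip_dicom(clip: UltrasoundClip, path: str | Path) -> Path:
    """Minimal multi-frame secondary-capture DICOM export of the cine loop."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.NumberOfFrames = clip.n_frames
    ds.Rows = clip.height
    ds.Columns = clip.width
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.CineRate = int(round(clip.frame_rate_hz))
    # cm/px -> mm/px for PixelSpacing (row spacing, column spacing)
    mm = clip.pixel_spacing_cm_per_px * 10.0
    ds.PixelSpacing = [f"{mm:.6f}", f"{mm:.6f}"]
    ds.PixelData = clip.frames.astype(np.uint8).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_clip_dicom(path: str | Path, pixel_spacing_cm_per_px: float | None = None) -> UltrasoundClip:
    import pydicom

    ds = pydicom.dcmread(path)
    frames = ds.pixel_array
    if frames.ndim == 2:
        frames = frames[None]
    if pixel_spacing_cm_per_px is None:
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is None:
            raise DomainError("DICOM lacks PixelSpacing; pass pixel_spacing_cm_per_px")
        pixel_spacing_cm_per_px = float(spacing[0]) / 10.0
    return UltrasoundClip(
        frames=frames,
        pixel_spacing_cm_per_px=pixel_spacing_cm_per_px,
        frame_rate_hz=float(getattr(ds, "CineRate", 15.0)),
    )


def read_clip(path: str | Path) -> UltrasoundClip:
    """Dispatch on extension: .tif/.tiff or .dcm."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return read_clip_tiff(path)
    if path.suffix.lower() == ".dcm":
        return read_clip_dicom(path)
    raise DomainError(f"unrecognized clip format: {path.suffix}")


# ---------------------------------------------------------------------------
# ROI annotations: JSON records {clip_id: [roi, ...]}


def write_rois_json(rois_by_clip: dict[str, Sequence[RoiSpec]], path: str | Path) -> Path:
    path = Path(path)
    payload = {
        clip_id: [
            {
                "top_row": r.top_row,
                "left_col": r.left_col,
                "depth_cm": r.depth_cm,
                "width_px": r.width_px,
            }
            for r in rois
        ]
        for clip_id, rois in rois_by_clip.items()
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_rois_json(path: str | Path) -> dict[str, list[RoiSpec]]:
    payload = json.loads(Path(path).read_text())
    return {
        clip_id: [RoiSpec(**record) for record in records]
        for clip_id, records in payload.items()
    }


# ---------------------------------------------------------------------------
# CT volumes


def write_ct_nifti(ct: CtVolume, gray_path: str | Path, mask_path: str | Path) -> tuple[Path, Path]:
    """Gray volume + integer lung mask as NIfTI, probe axis in a JSON sidecar."""
    gray_path, mask_path = Path(gray_path), Path(mask_path)
    affine = np.diag(list(ct.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(ct.voxels.astype(np.float32), affine), gray_path)
    nib.save(nib.Nifti1Image(ct.lung_mask.astype(np.uint8), affine), mask_path)
    sidecar = {
        "probe_axis": ct.probe_axis,
        "true_superficial_air_fraction": ct.true_superficial_air_fraction,
        "metadata": ct.metadata,
    }
    _sidecar_path(gray_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return gray_path, mask_path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def read_ct_nifti(gray_path: str | Path, mask_path: str | Path) -> CtVolume:
    gray_path, mask_path = Path(gray_path), Path(mask_path)
    gray = nib.load(gray_path)
    mask = nib.load(mask_path)
    voxel_size = tuple(float(z) for z in gray.header.get_zooms()[:3])
    sidecar_path = _sidecar_path(gray_path)
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return CtVolume(
        voxels=np.asarray(gray.dataobj, np.float32),
        voxel_size_mm=voxel_size,
        lung_mask=np.asarray(mask.dataobj) > 0,
        probe_axis=sidecar.get("probe_axis", 0),
        true_superficial_air_fraction=sidecar.get("true_superficial_air_fraction"),
        metadata=sidecar.get("metadata", {}),
    )
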