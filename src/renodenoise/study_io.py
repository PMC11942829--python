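"""Reading and writing dynamic studies and ROI masks.

Formats: multiframe DICOM (modality NM, one frame per temporal slice),
compressed ``.npz`` array archives, and PNG mask files (0/255) with a JSON
sidecar naming each mask's role.  Pixel coordinates are 0-based, row-major,
origin top-left throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .phantom import DegenerateROIError, DynamicStudy, ROISet

__all__ = [
    "StudyRecord", "StudyFormatError",
    "read_dicom_study", "write_dicom_study",
    "read_array_study", "write_array_study",
    "read_roi_masks", "write_roi_masks",
]

_NM_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.20"   # Nuclear Medicine Image Storage
_PROTOCOL_SHAPE = (120, 128, 128)
_DEFAULT_FRAME_S = 10.0


class StudyFormatError(ValueError):
    """Raised when a file cannot be parsed into a valid study."""


@dataclass
class StudyRecord:
    """A study plus optional ROIs and provenance of the file it came from."""
    study: DynamicStudy
    rois: Optional[ROISet] = None
    source_path: str = ""
    warnings: tuple = ()

    @property
    def protocol_conformant(self) -> bool:
        """True when the acquisition matches the 120-frame 128x128 protocol."""
        return self.study.frames.shape == _PROTOCOL_SHAPE


def _parse_age_years(value: str) -> float:
    value = str(value).strip()
    if not value:
        return float("nan")
    unit = value[-1].upper()
    try:
        num = float(value[:-1] if unit in "DWMY" else value)
    except ValueError:
        return float("nan")
    return {"D": num / 365.25, "W": num / 52.18, "M": num / 12.0}.get(unit, num)


def write_dicom_study(record: StudyRecord, path) -> None:
    """Write a study as an uncompressed multiframe NM DICOM file."""
    study = record.study
    frames = study.frames
    if frames.max() > np.iinfo(np.uint16).max:
        raise StudyFormatError("counts exceed unsigned 16-bit storage")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _NM_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _NM_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.PatientID = study.study_id
    ds.PatientAge = f"{int(round(study.patient_age_years)):03d}Y"
    ds.SeriesDescription = f"provenance={study.provenance};scale={study.count_scale}"
    ds.NumberOfFrames = int(frames.shape[0])
    ds.Rows, ds.Columns = int(frames.shape[1]), int(frames.shape[2])
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    # frame timing, milliseconds per temporal slice
    ds.FrameTime = str(study.frame_duration_s * 1000.0)
    ds.PixelData = np.ascontiguousarray(frames.astype(np.uint16)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_dicom_study(path) -> StudyRecord:
    """Read a multiframe DICOM study, preserving stored integer counts."""
    path = Path(path)
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        raise StudyFormatError(f"cannot parse {path} as DICOM: {exc}") from exc
    if "PixelData" not in ds:
        raise StudyFormatError(f"{path} has no pixel data")
    try:
        pixels = ds.pixel_array
    except Exception as exc:
        raise StudyFormatError(f"{path}: undecodable pixel data: {exc}") from exc
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise StudyFormatError(f"{path}: expected a frame stack, got {pixels.shape}")

    warnings = []
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        pixels = np.round(pixels * slope + intercept).astype(np.int64)
        warnings.append("rescale tags applied and counts re-rounded")
    if "FrameTime" in ds:
        frame_s = float(ds.FrameTime) / 1000.0
    else:
        frame_s = _DEFAULT_FRAME_S
        warnings.append("no FrameTime tag; assuming 10 s per frame")

    age = _parse_age_years(getattr(ds, "PatientAge", ""))
    provenance = "dicom"
    scale = 1.0
    desc = str(getattr(ds, "SeriesDescription", ""))
    for part in desc.split(";"):
        if part.startswith("provenance="):
            provenance = part.split("=", 1)[1]
        elif part.startswith("scale="):
            scale = float(part.split("=", 1)[1])

    study = DynamicStudy(
        frames=np.asarray(pixels).astype(np.int64),
        frame_duration_s=frame_s,
        patient_age_years=age if age == age else 0.0,
        study_id=str(getattr(ds, "PatientID", path.stem)),
        provenance=provenance,
        count_scale=scale,
    )
    record = StudyRecord(study=study, source_path=str(path), warnings=tuple(warnings))
    if not record.protocol_conformant:
        record.warnings += ("acquisition does not match the 120x128x128 protocol",)
    return record


def write_array_study(record: StudyRecord, path) -> None:
    """Write a study as a compressed array archive."""
    study = record.study
    np.savez_compressed(
        path,
        frames=study.frames,
        age=study.patient_age_years,
        duration=study.frame_duration_s,
        seed=-1 if study.seed is None else study.seed,
        count_scale=study.count_scale,
        study_id=np.bytes_(study.study_id.encode()),
    )


def read_array_study(path) -> StudyRecord:
    path = Path(path)
    try:
        with np.load(path) as archive:
            study = DynamicStudy(
                frames=archive["frames"],
                frame_duration_s=float(archive["duration"]),
                patient_age_years=float(archive["age"]),
                study_id=bytes(archive["study_id"]).decode(),
                provenance="synthetic",
                count_scale=float(archive["count_scale"]),
                seed=None if int(archive["seed"]) < 0 else int(archive["seed"]),
            )
    except (KeyError, OSError, ValueError) as exc:
        raise StudyFormatError(f"cannot read study archive {path}: {exc}") from exc
    record = StudyRecord(study=study, source_path=str(path))
    if not record.protocol_conformant:
        record.warnings = ("acquisition does not match the 120x128x128 protocol",)
    return record


_ROLES = ("left_kidney", "right_kidney", "background")


def write_roi_masks(rois: ROISet, directory, stem: str = "roi") -> Path:
    """Write each mask as an 8-bit PNG (0/255) plus a JSON role sidecar."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {}
    for role in _ROLES:
        mask = getattr(rois, role)
        name = f"{stem}_{role}.png"
        Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(directory / name)
        sidecar[role] = name
    sidecar_path = directory / f"{stem}_rois.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def read_roi_masks(sidecar_path, expected_shape=None) -> ROISet:
    """Read masks named by a JSON sidecar; binarize at threshold 128."""
    from PIL import Image

    sidecar_path = Path(sidecar_path)
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise StudyFormatError(f"cannot read ROI sidecar {sidecar_path}: {exc}") from exc
    masks = {}
    for role in _ROLES:
        if role not in sidecar:
            raise StudyFormatError(f"ROI sidecar is missing role '{role}'")
        file_path = sidecar_path.parent / sidecar[role]
        arr = np.asarray(Image.open(file_path).convert("L"))
        if expected_shape is not None and arr.shape != tuple(expected_shape):
            raise StudyFormatError(
                f"mask {file_path} shape {arr.shape} does not match study "
                f"shape {tuple(expected_shape)}")
        masks[role] = arr >= 128
    return ROISet(**masks)  # ROISet enforces non-emptiness and disjointness
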