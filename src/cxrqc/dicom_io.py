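"""Reading and writing radiographs (DICOM, with a PNG + JSON-sidecar fallback).

Ingest normalizes every file to one canonical representation: a float64
image in ``[0, 1]`` scaled over the *stored* value range (so padding at
stored value 0 stays exactly 0), with MONOCHROME1 data inverted so that
higher intensity always means more radiodense.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from PIL import Image

from .records import (
    MONOCHROME1,
    MONOCHROME2,
    ACTION_EXCLUDE,
    MetadataRecord,
    QCResult,
    RadiographRecord,
)

_DEVIATION_INDEX_TAG = (0x0018, 0x1413)


def read_radiograph(path: Union[str, Path]) -> RadiographRecord:
    """Decode one radiograph into the canonical representation.

    Decode failures never raise: they return a record with ``image=None``
    and a single ``exclude`` QCResult (reason ``decode_error``) so a batch
    run is not halted by one corrupt file.
    """
    path = Path(path)
    try:
        if path.suffix.lower() == ".png":
            return _read_png(path)
        return _read_dicom(path)
    except Exception as exc:  # noqa: BLE001 - ingest isolates all decode faults
        meta = MetadataRecord(patient_id=path.stem)
        rec = RadiographRecord(image=None, metadata=meta,
                               provenance={"source": str(path), "transforms": []})
        rec.add_result(QCResult(stage="ingest", action=ACTION_EXCLUDE,
                                reasons=["decode_error"],
                                evidence={"detail": str(exc)[:200]}))
        return rec


def _read_dicom(path: Path) -> RadiographRecord:
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    arr = arr * slope + intercept

    bits_stored = int(getattr(ds, "BitsStored", 16))
    bits_stored = min(max(bits_stored, 8), 16)
    maxval = float(2 ** bits_stored - 1)
    img = np.clip(arr / maxval, 0.0, 1.0)

    photometric = str(getattr(ds, "PhotometricInterpretation", MONOCHROME2)).strip()
    if photometric not in (MONOCHROME1, MONOCHROME2):
        photometric = MONOCHROME2
    if photometric == MONOCHROME1:
        img = 1.0 - img

    wc = _first_float(getattr(ds, "WindowCenter", None))
    ww = _first_float(getattr(ds, "WindowWidth", None))
    meta = MetadataRecord(
        patient_id=str(getattr(ds, "PatientID", "") or ""),
        manufacturer=_str_or_none(getattr(ds, "Manufacturer", None)),
        deviation_index=_tag_float(ds, _DEVIATION_INDEX_TAG),
        sex=_norm_sex(getattr(ds, "PatientSex", None)),
        age=_parse_age(getattr(ds, "PatientAge", None)),
        ethnicity=_str_or_none(getattr(ds, "EthnicGroup", None)),
        series_description=_str_or_none(getattr(ds, "SeriesDescription", None)),
        photometric=photometric,
        bits_stored=bits_stored,
        window_center=None if wc is None else wc / maxval,
        window_width=None if ww is None else ww / maxval,
    )
    rec = RadiographRecord(image=img, metadata=meta,
                           provenance={"source": str(path), "transforms": []})
    rec.log_transform(f"ingest:dicom:{photometric}:{bits_stored}bit")
    return rec


def _read_png(path: Path) -> RadiographRecord:
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        bits = 8
    else:
        bits = 16
    img = arr.astype(np.float64) / float(2 ** bits - 1)

    sidecar = path.with_suffix(".json")
    meta_dict: dict = {}
    if sidecar.exists():
        meta_dict = json.loads(sidecar.read_text())
    meta_dict.setdefault("patient_id", path.stem)
    meta_dict.setdefault("bits_stored", bits)
    meta = MetadataRecord.from_dict(meta_dict)
    if meta.photometric == MONOCHROME1:
        img = 1.0 - img
    rec = RadiographRecord(image=np.clip(img, 0, 1), metadata=meta,
                           provenance={"source": str(path), "transforms": []})
    rec.log_transform(f"ingest:png:{bits}bit")
    return rec


def write_radiograph(record: RadiographRecord, path: Union[str, Path],
                     spec=None) -> Path:
    """Write a record to DICOM (or PNG + sidecar when path ends in .png).

    Pixels are quantized to the record's stored bit depth; metadata fields
    round-trip exactly through :func:`read_radiograph`. ``spec`` (a
    phantom parameterization) is serialized into a truth sidecar JSON when
    given, for fixture provenance.
    """
    if record.image is None:
        raise ValueError("cannot write a record without pixel data")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".png":
        return _write_png(record, path)

    meta = record.metadata
    bits_stored = int(meta.bits_stored)
    maxval = 2 ** bits_stored - 1
    img = record.image
    if meta.photometric == MONOCHROME1:
        img = 1.0 - img
    stored = np.round(img * maxval).astype(np.uint16 if bits_stored > 8 else np.uint8)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[meta.patient_id, str(path)])
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "DX"
    ds.PatientID = meta.patient_id
    if meta.manufacturer is not None:
        ds.Manufacturer = meta.manufacturer
    if meta.sex is not None:
        ds.PatientSex = {"M": "M", "F": "F"}.get(meta.sex, "O")
    if meta.age is not None:
        with warnings.catch_warnings():
            # age ranges ("40-49") are carried in PatientAge; pydicom warns
            # that this is not canonical AS format but keeps the string intact
            warnings.filterwarnings("ignore", message="Invalid value for VR AS")
            ds.PatientAge = _format_age(meta.age)
    if meta.ethnicity is not None:
        ds.EthnicGroup = meta.ethnicity
    if meta.series_description is not None:
        ds.SeriesDescription = meta.series_description
    if meta.deviation_index is not None:
        ds.add_new(_DEVIATION_INDEX_TAG, "DS", f"{meta.deviation_index:.4f}")
    if meta.window_center is not None and meta.window_width is not None:
        ds.WindowCenter = f"{meta.window_center * maxval:.2f}"
        ds.WindowWidth = f"{meta.window_width * maxval:.2f}"

    ds.PhotometricInterpretation = meta.photometric
    ds.SamplesPerPixel = 1
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16 if bits_stored > 8 else 8
    ds.BitsStored = bits_stored
    ds.HighBit = bits_stored - 1
    ds.PixelRepresentation = 0
    ds.PixelData = stored.tobytes()

    ds.save_as(path, enforce_file_format=True)

    if spec is not None:
        sidecar = path.with_suffix(".spec.json")
        sidecar.write_text(json.dumps(_spec_to_dict(spec), indent=0, sort_keys=True))
    return path


def _write_png(record: RadiographRecord, path: Path) -> Path:
    meta = record.metadata
    bits = 16 if meta.bits_stored > 8 else 8
    maxval = 2 ** bits - 1
    img = record.image
    if meta.photometric == MONOCHROME1:
        img = 1.0 - img
    stored = np.round(img * maxval).astype(np.uint16 if bits > 8 else np.uint8)
    Image.fromarray(stored).save(path)
    sidecar = path.with_suffix(".json")
    d = meta.to_dict()
    d["bits_stored"] = bits
    sidecar.write_text(json.dumps(d, indent=0, sort_keys=True))
    return path


def read_directory(directory: Union[str, Path]) -> list:
    """Read every .dcm/.png file in a directory (sorted), isolating failures."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".dcm", ".png"))
    return [read_radiograph(p) for p in paths]


# ---------------------------------------------------------------- helpers

def _str_or_none(v) -> Optional[str]:
    if v is None:
        return None
    s = str(v).strip()
    return s or None


def _norm_sex(v) -> Optional[str]:
    s = _str_or_none(v)
    if s is None:
        return None
    s = s.upper()
    if s in ("M", "F"):
        return s
    return "other"


def _parse_age(v) -> Union[float, str, None]:
    s = _str_or_none(v)
    if s is None:
        return None
    s = s.strip()
    if s.upper().endswith("Y"):
        body = s[:-1]
        try:
            return float(body)
        except ValueError:
            s = body
    if "-" in s:
        return s  # age range, resolved by curation.age_midpoint
    try:
        return float(s)
    except ValueError:
        return None


def _format_age(age: Union[float, str]) -> str:
    if isinstance(age, str):
        return age
    return f"{int(round(float(age))):03d}Y"


def _tag_float(ds, tag) -> Optional[float]:
    if tag in ds:
        try:
            return float(ds[tag].value)
        except (TypeError, ValueError):
            return None
    return None


def _first_float(v) -> Optional[float]:
    if v is None:
        return None
    try:
        if isinstance(v, (list, pydicom.multival.MultiValue)):
            v = v[0]
        return float(v)
    except (TypeError, ValueError, IndexError):
        return None


def _spec_to_dict(spec) -> dict:
    if hasattr(spec, "to_dict"):
        return spec.to_dict()
    if hasattr(spec, "__dict__"):
        return {k: v for k, v in vars(spec).items() if not k.startswith("_")}
    return dict(spec)
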