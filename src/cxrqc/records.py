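"""Core record types shared by every pipeline stage.

A radiograph travels through the pipeline as a :class:`RadiographRecord`:
a float image in ``[0, 1]`` (canonical polarity: higher = more radiodense,
so bone is bright and air is dark), the header fields the QC stages
inspect, and an append-only list of per-stage :class:`QCResult` verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Union

import numpy as np

ACTION_PASS = "pass"
ACTION_FLAG = "flag_for_review"
ACTION_EXCLUDE = "exclude"
ACTIONS = (ACTION_PASS, ACTION_FLAG, ACTION_EXCLUDE)

MONOCHROME1 = "MONOCHROME1"
MONOCHROME2 = "MONOCHROME2"


@dataclass
class MetadataRecord:
    """Header fields inspected by the pipeline.

    Missing values are ``None``, never 0: downstream curation must be able
    to distinguish an absent deviation index from a genuinely zero one.
    ``age`` may be numeric years or an age-range string such as ``"40-49"``
    (resolved later by :func:`cxrqc.curation.age_midpoint`).
    """

    patient_id: str = ""
    manufacturer: Optional[str] = None
    deviation_index: Optional[float] = None
    sex: Optional[str] = None  # "M", "F" or "other"
    age: Union[float, str, None] = None
    ethnicity: Optional[str] = None
    series_description: Optional[str] = None
    photometric: str = MONOCHROME2
    bits_stored: int = 12
    # Display window from the header (normalized to [0, 1] pixel units).
    window_center: Optional[float] = None
    window_width: Optional[float] = None

    def __post_init__(self) -> None:
        if not 8 <= int(self.bits_stored) <= 16:
            raise ValueError(f"bits_stored must be in [8, 16], got {self.bits_stored}")
        if self.photometric not in (MONOCHROME1, MONOCHROME2):
            raise ValueError(f"unsupported photometric {self.photometric!r}")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "manufacturer": self.manufacturer,
            "deviation_index": self.deviation_index,
            "sex": self.sex,
            "age": self.age,
            "ethnicity": self.ethnicity,
            "series_description": self.series_description,
            "photometric": self.photometric,
            "bits_stored": int(self.bits_stored),
            "window_center": self.window_center,
            "window_width": self.window_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetadataRecord":
        known = {f: d.get(f) for f in cls.__dataclass_fields__}
        known["patient_id"] = known.get("patient_id") or ""
        known["photometric"] = known.get("photometric") or MONOCHROME2
        known["bits_stored"] = int(known.get("bits_stored") or 12)
        return cls(**known)


@dataclass
class QCResult:
    """One stage's verdict: action, machine-readable reasons, and the
    numeric evidence that produced them."""

    stage: str
    action: str
    reasons: list = field(default_factory=list)
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.action != ACTION_PASS and not self.reasons:
            raise ValueError("non-pass QCResult requires at least one reason code")
        if self.action == ACTION_PASS and self.reasons:
            raise ValueError("pass QCResult must carry no reason codes")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "action": self.action,
            "reasons": list(self.reasons),
            "evidence": {k: _jsonify(v) for k, v in self.evidence.items()},
        }


def _jsonify(v: Any) -> Any:
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.bool_):
        return bool(v)
    return v


@dataclass
class RadiographRecord:
    """A radiograph plus its metadata and accumulated QC history.

    ``image`` is ``None`` only for ingest failures, which carry an
    ``exclude`` QCResult instead of pixels.
    """

    image: Optional[np.ndarray]
    metadata: MetadataRecord
    qc_results: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.provenance.setdefault("source", None)
        self.provenance.setdefault("transforms", [])
        if self.image is not None:
            img = np.asarray(self.image, dtype=np.float64)
            if img.ndim != 2 or img.shape[0] < 32 or img.shape[1] < 32:
                raise ValueError("image must be 2-D with at least 32 rows and columns")
            if not np.all(np.isfinite(img)):
                raise ValueError("image contains non-finite values")
            if img.min() < -1e-9 or img.max() > 1 + 1e-9:
                raise ValueError("image values must lie in [0, 1]")
            self.image = np.clip(img, 0.0, 1.0)

    def log_transform(self, name: str) -> None:
        self.provenance["transforms"].append(name)

    def add_result(self, result: QCResult) -> None:
        self.qc_results.append(result)

    @property
    def excluded(self) -> bool:
        return any(r.action == ACTION_EXCLUDE for r in self.qc_results)

    @property
    def flagged(self) -> bool:
        return any(r.action == ACTION_FLAG for r in self.qc_results)
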