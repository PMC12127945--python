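"""Synthetic chest-radiograph phantoms with complete ground truth.

Phantoms are geometric, not anatomically realistic: every pipeline stage
keys on a specific injected property (mirror symmetry, bright abdomen
band, burned-in glyphs, constant padding, near-black collimation, blur,
noise, vendor intensity curves), and each property is generated with an
exact truth record so detectors can be scored without human annotation.

Glyphs are rendered from a built-in 5x7 block font (rectangles with gaps)
so truth text masks are pixel-exact without any font dependency.

The vendor model mimics how raw detector data differ between
manufacturers: each vendor applies its own gamma/gain/offset curve to the
underlying anatomy, producing distribution shifts, and writes a display
window (center/width) into the header that maps its own output range onto
a common display band. Stage-1 windowing therefore harmonizes vendors,
compressing over-contrasted raw data toward the shared band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import CropBox
from .records import MetadataRecord, RadiographRecord

# 5x7 block glyphs; strings are rows, "1" marks an ink pixel.
_FONT: Dict[str, Tuple[str, ...]] = {
    "A": ("01110", "10001", "10001", "11111", "10001", "10001", "10001"),
    "C": ("01111", "10000", "10000", "10000", "10000", "10000", "01111"),
    "E": ("11111", "10000", "10000", "11110", "10000", "10000", "11111"),
    "F": ("11111", "10000", "10000", "11110", "10000", "10000", "10000"),
    "L": ("10000", "10000", "10000", "10000", "10000", "10000", "11111"),
    "P": ("11110", "10001", "10001", "11110", "10000", "10000", "10000"),
    "R": ("11110", "10001", "10001", "11110", "10100", "10010", "10001"),
    "T": ("11111", "00100", "00100", "00100", "00100", "00100", "00100"),
    " ": ("00000",) * 7,
}
GLYPH_ROWS, GLYPH_COLS = 7, 5

# vendor intensity curves: raw = clip(offset + gain * anatomy**gamma, 0, 1).
# Vendor B is systematically brighter and lower-contrast with a mild gamma
# bend: a distortion a linear display window can largely undo, which is the
# regime in which windowing harmonizes vendors.
VENDOR_CURVES: Dict[str, Tuple[float, float, float]] = {
    "Vendor A": (1.00, 1.00, 0.00),  # (gamma, gain, offset) - reference detector
    "Vendor B": (1.03, 0.90, 0.12),
}

# anatomy black/white reference points used for the vendor display window
_LO_REF, _HI_REF = 0.10, 0.92


@dataclass
class TextItem:
    text: str
    row: int
    col: int
    intensity: float = 1.0
    scale: int = 2


@dataclass
class PhantomSpec:
    """Full parameterization of one phantom; serves as ground truth."""

    projection: str = "frontal"  # frontal | lateral
    size: Tuple[int, int] = (256, 224)
    text_items: List[TextItem] = field(default_factory=list)
    pad_width: int = 0
    collim_widths: Tuple[int, int, int, int] = (0, 0, 0, 0)  # top, bottom, left, right
    rotation: int = 0  # CCW degrees in {0, 90, 180, 270}
    blur_sigma: float = 0.0
    noise_sd: float = 0.01
    gamma: float = 1.0
    gain: float = 1.0
    offset: float = 0.0
    ambiguity: float = 0.0  # 0 = textbook anatomy, 1 = maximally atypical
    write_window: bool = True
    header: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.projection not in ("frontal", "lateral"):
            raise ValueError(f"unknown projection {self.projection!r}")
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError("rotation must be a multiple of 90 in [0, 270]")
        nrows, ncols = self.size
        for name, w, dim in (("pad+collim rows", self.pad_width * 2 + self.collim_widths[0] + self.collim_widths[1], nrows),
                             ("pad+collim cols", self.pad_width * 2 + self.collim_widths[2] + self.collim_widths[3], ncols)):
            if w >= 0.45 * dim:
                raise ValueError(f"{name} = {w} exceeds 45% of dimension {dim}")
        if self.blur_sigma < 0 or self.noise_sd < 0 or self.gamma <= 0:
            raise ValueError("invalid degradation parameters")
        for item in self.text_items:
            h = GLYPH_ROWS * item.scale
            w = (GLYPH_COLS + 1) * item.scale * len(item.text)
            if item.row < 0 or item.col < 0 or item.row + h > nrows or item.col + w > ncols:
                raise ValueError(f"text item {item.text!r} outside frame")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["text_items"] = [asdict(t) for t in self.text_items]
        return d


def render_text(canvas: np.ndarray, item: TextItem,
                mask: Optional[np.ndarray] = None) -> None:
    """Burn a text item into ``canvas`` (and its truth ``mask``) in place."""
    r, c = item.row, item.col
    for ch in item.text.upper():
        glyph = _FONT.get(ch, _FONT[" "])
        bitmap = np.array([[p == "1" for p in row] for row in glyph], dtype=bool)
        big = np.kron(bitmap, np.ones((item.scale, item.scale), dtype=bool))
        h, w = big.shape
        canvas[r:r + h, c:c + w][big] = item.intensity
        if mask is not None:
            mask[r:r + h, c:c + w][big] = True
        c += w + item.scale  # one-stroke gap between characters


def _frontal_anatomy(nrows: int, ncols: int, rng: np.random.Generator,
                     ambiguity: float) -> Tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:nrows, 0:ncols].astype(np.float64)
    img = np.full((nrows, ncols), 0.12)
    cy, cx = 0.52 * nrows, 0.50 * ncols

    body = ((yy - cy) / (0.55 * nrows)) ** 2 + ((xx - cx) / (0.46 * ncols)) ** 2 <= 1.0
    img[body] = 0.48
    abdomen = body & (yy > 0.76 * nrows)
    img[abdomen] = 0.80
    mediastinum = body & (np.abs(xx - cx) < 0.08 * ncols) & (yy > 0.14 * nrows)
    img[mediastinum] = 0.70

    # paired lungs; ambiguity shifts/shrinks one side to break symmetry
    dx = ambiguity * rng.uniform(-0.06, 0.06) * ncols
    shrink = 1.0 - 0.5 * ambiguity * rng.uniform(0.0, 0.6)
    lung_mask = np.zeros((nrows, ncols), dtype=bool)
    for sign, sc in ((-1, 1.0), (1, shrink)):
        lcx = cx + sign * 0.24 * ncols + (sign > 0) * dx
        lung = (((yy - 0.44 * nrows) / (0.26 * nrows)) ** 2
                + ((xx - lcx) / (sc * 0.15 * ncols)) ** 2 <= 1.0)
        lung &= yy < 0.76 * nrows
        img[lung] = 0.22
        lung_mask |= lung

    _add_blobs(img, body, rng, n=3)
    img = ndimage.gaussian_filter(img, 2.0)
    return np.clip(img, 0.0, 1.0), lung_mask


def _lateral_anatomy(nrows: int, ncols: int, rng: np.random.Generator,
                     ambiguity: float) -> Tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:nrows, 0:ncols].astype(np.float64)
    img = np.full((nrows, ncols), 0.12)
    cy, cx = 0.52 * nrows, 0.50 * ncols

    body = ((yy - cy) / (0.55 * nrows)) ** 2 + ((xx - cx) / (0.44 * ncols)) ** 2 <= 1.0
    img[body] = 0.50
    abdomen = body & (yy > 0.76 * nrows)
    img[abdomen] = 0.78
    # spine: bright band off to one side
    spine = body & (np.abs(xx - 0.74 * ncols) < 0.06 * ncols) & (yy > 0.12 * nrows)
    img[spine] = 0.68

    # single offset lung; ambiguity pulls it toward the midline (more frontal-like)
    lcx = (0.40 + ambiguity * rng.uniform(0.0, 0.08)) * ncols
    lung = (((yy - 0.42 * nrows) / (0.28 * nrows)) ** 2
            + ((xx - lcx) / (0.20 * ncols)) ** 2 <= 1.0)
    lung &= yy < 0.76 * nrows
    img[lung] = 0.25
    lung_mask = lung.copy()

    _add_blobs(img, body, rng, n=3)
    img = ndimage.gaussian_filter(img, 2.0)
    return np.clip(img, 0.0, 1.0), lung_mask


def _add_blobs(img: np.ndarray, body: np.ndarray, rng: np.random.Generator,
               n: int) -> None:
    nrows, ncols = img.shape
    yy, xx = np.mgrid[0:nrows, 0:ncols].astype(np.float64)
    for _ in range(n):
        by = rng.uniform(0.2, 0.8) * nrows
        bx = rng.uniform(0.2, 0.8) * ncols
        br = rng.uniform(0.05, 0.12) * min(nrows, ncols)
        amp = rng.uniform(-0.05, 0.05)
        blob = np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * br ** 2)))
        img += np.where(body, amp * blob, 0.0)


def _rot_sides(sides: Tuple[int, int, int, int], k: int) -> Tuple[int, int, int, int]:
    """Rotate (top, bottom, left, right) border widths by k CCW quarter-turns."""
    top, bottom, left, right = sides
    for _ in range(k % 4):
        # CCW: old right edge becomes the new top
        top, bottom, left, right = right, left, top, bottom
    return top, bottom, left, right


def generate_phantom(spec: PhantomSpec) -> Tuple[RadiographRecord, dict]:
    """Render one phantom and its truth.

    Truth dict keys: ``text_mask``, ``lung_mask`` (booleans in the final
    frame), ``crop_box`` (content box after padding+collimation, final
    frame), ``rotation`` (CCW degrees applied), ``projection``.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.size
    if spec.projection == "frontal":
        img, lung_mask = _frontal_anatomy(nrows, ncols, rng, spec.ambiguity)
        other, _ = _lateral_anatomy(nrows, ncols, rng, 0.0)
    else:
        img, lung_mask = _lateral_anatomy(nrows, ncols, rng, spec.ambiguity)
        other, _ = _frontal_anatomy(nrows, ncols, rng, 0.0)
    if spec.ambiguity > 0:
        # blend toward the opposite projection's prototype: at ambiguity 1
        # the film is a 50/50 mixture and the projection is genuinely hard
        # to call from anatomy alone
        lam = 0.5 * spec.ambiguity
        img = (1.0 - lam) * img + lam * other

    # acquisition-side degradations act on detector units, before the
    # vendor's processing chain: blur (focal spot / motion), then detector
    # noise, then the manufacturer-dependent intensity transform. Burned-in
    # annotations are digital overlays rendered last, so they stay crisp.
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, 1.0)

    img = np.clip(spec.offset + spec.gain * np.power(img, spec.gamma), 0.0, 1.0)

    # annotation "white" is display white: the vendor curve's output at the
    # anatomy white point, so burned-in text lands at the same display
    # brightness for every vendor once the header window is applied
    white = float(np.clip(spec.offset + spec.gain * _HI_REF ** spec.gamma, 0.0, 1.0))
    text_mask = np.zeros_like(img, dtype=bool)
    for item in spec.text_items:
        scaled = TextItem(item.text, item.row, item.col,
                          intensity=item.intensity * white, scale=item.scale)
        render_text(img, scaled, text_mask)
    img = np.clip(img, 1.0 / 4096.0, 1.0)  # keep content pixels strictly above padding

    # header display window: a fixed per-vendor calibration mapping the
    # vendor curve's output over the canonical anatomy range onto the
    # central [0.15, 0.85] display band. Fixed (not per-image) windows
    # preserve natural image-to-image variability after standardization,
    # the way a vendor's display LUT behaves.
    wc = ww = None
    if spec.write_window:
        lo_v = spec.offset + spec.gain * _LO_REF ** spec.gamma
        hi_v = spec.offset + spec.gain * _HI_REF ** spec.gamma
        span = max(float(hi_v - lo_v), 1e-3)
        ww = span / 0.7
        wc = float(lo_v + hi_v) / 2.0

    # collimation: near-black bands with slight texture
    top, bottom, left, right = spec.collim_widths
    collim_val = 0.02

    def band(shape):
        return np.clip(collim_val + rng.normal(0.0, 0.005, shape), 0.004, 0.05)

    if top:
        img[:top, :] = band(img[:top, :].shape)
    if bottom:
        img[nrows - bottom:, :] = band(img[nrows - bottom:, :].shape)
    if left:
        img[:, :left] = band(img[:, :left].shape)
    if right:
        img[:, ncols - right:] = band(img[:, ncols - right:].shape)
    for m in (text_mask, lung_mask):
        if top:
            m[:top, :] = False
        if bottom:
            m[nrows - bottom:, :] = False
        if left:
            m[:, :left] = False
        if right:
            m[:, ncols - right:] = False

    # constant-value padding
    pw = spec.pad_width
    if pw:
        img = np.pad(img, pw, constant_values=0.0)
        text_mask = np.pad(text_mask, pw, constant_values=False)
        lung_mask = np.pad(lung_mask, pw, constant_values=False)

    # rotation (CCW quarter turns), applied last
    k = spec.rotation // 90
    if k:
        img = np.rot90(img, k)
        text_mask = np.rot90(text_mask, k)
        lung_mask = np.rot90(lung_mask, k)

    sides = (pw + top, pw + bottom, pw + left, pw + right)
    t, b, l, r = _rot_sides(sides, k)
    final_rows, final_cols = img.shape
    crop_box = CropBox(t, final_rows - b, l, final_cols - r)

    header = dict(spec.header)
    meta = MetadataRecord(
        patient_id=header.get("patient_id", f"SYN{spec.seed:07d}"),
        manufacturer=header.get("manufacturer"),
        deviation_index=header.get("deviation_index"),
        sex=header.get("sex"),
        age=header.get("age"),
        ethnicity=header.get("ethnicity"),
        series_description=header.get("series_description"),
        photometric=header.get("photometric", "MONOCHROME2"),
        bits_stored=int(header.get("bits_stored", 12)),
        window_center=wc,
        window_width=ww,
    )
    record = RadiographRecord(image=np.ascontiguousarray(img), metadata=meta,
                              provenance={"source": f"synthetic:{spec.seed}",
                                          "transforms": ["synthetic:render"]})
    truth = {
        "text_mask": np.ascontiguousarray(text_mask),
        "lung_mask": np.ascontiguousarray(lung_mask),
        "crop_box": crop_box,
        "rotation": spec.rotation,
        "projection": spec.projection,
    }
    return record, truth


@dataclass
class DatasetConfig:
    """Sampling distribution for a synthetic cohort.

    Defaults describe a plausibly messy clinical mix: two vendors with
    distinct intensity curves, burned-in projection tokens on most films,
    occasional padding/collimation/rotation, mild blur and noise, and a
    small rate of missing header fields.
    """

    size: Tuple[int, int] = (256, 224)
    frontal_fraction: float = 0.5
    manufacturers: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(VENDOR_CURVES))
    text_prob: float = 0.9
    text_class_correlation: float = 1.0  # P(token matches projection)
    side_marker_prob: float = 0.5
    pad_prob: float = 0.5
    pad_range: Tuple[int, int] = (4, 16)
    collim_prob: float = 0.3
    collim_range: Tuple[int, int] = (8, 28)
    rotation_prob: float = 0.1
    blur_sigma_range: Tuple[float, float] = (0.0, 1.0)
    noise_sd_range: Tuple[float, float] = (0.005, 0.02)
    ambiguity_range: Tuple[float, float] = (0.0, 0.3)
    jewelry_prob: float = 0.0  # bright disk artifact in the lung field
    missing_metadata_rate: float = 0.1
    multi_image_rate: float = 0.15
    age_range_prob: float = 0.2
    series_token_rate: float = 0.6
    series_token_error_rate: float = 0.03
    write_window: bool = True

    frontal_token: str = "PA"
    lateral_token: str = "LAT"


_ETHNICITIES = ("White", "Black", "Asian", "Mixed")


def sample_spec(config: DatasetConfig, rng: np.random.Generator,
                index: int, patient_id: str) -> PhantomSpec:
    """Draw one PhantomSpec from the configured marginals."""
    nrows, ncols = config.size
    projection = "frontal" if rng.random() < config.frontal_fraction else "lateral"
    manufacturer = list(config.manufacturers)[rng.integers(len(config.manufacturers))]
    gamma, gain, offset = config.manufacturers[manufacturer]

    pad = int(rng.integers(*config.pad_range)) if rng.random() < config.pad_prob else 0
    collim = [0, 0, 0, 0]
    for i in range(4):
        if rng.random() < config.collim_prob:
            collim[i] = int(rng.integers(*config.collim_range))

    # tokens are burned into the exposed field (annotation happens on the
    # final display image, after collimation), so offset them clear of the
    # sampled border bands
    text_items: List[TextItem] = []
    if rng.random() < config.text_prob:
        match = rng.random() < config.text_class_correlation
        if (projection == "frontal") == match:
            token = config.frontal_token
        else:
            token = config.lateral_token
        scale = 2
        text_items.append(TextItem(token,
                                   row=collim[0] + int(rng.integers(4, 16)),
                                   col=collim[2] + int(rng.integers(4, 20)),
                                   intensity=1.0, scale=scale))
        if rng.random() < config.side_marker_prob:
            text_items.append(TextItem(
                "R" if rng.random() < 0.5 else "L",
                row=collim[0] + int(rng.integers(4, 16)),
                col=int(ncols - collim[3] - 24 - rng.integers(0, 8)),
                intensity=1.0, scale=scale))
    rotation = 0
    if rng.random() < config.rotation_prob:
        rotation = int(rng.choice([90, 180, 270]))

    # header metadata
    sex = "M" if rng.random() < 0.5 else "F"
    age_years = float(rng.uniform(18, 95))
    age: Union[float, str]
    if rng.random() < config.age_range_prob:
        lo = int(age_years // 10) * 10
        age = f"{lo}-{lo + 9}"
    else:
        age = round(age_years, 1)
    if rng.random() < config.series_token_rate:
        wrong = rng.random() < config.series_token_error_rate
        shown = projection if not wrong else ("lateral" if projection == "frontal" else "frontal")
        series = "CHEST PA ERECT" if shown == "frontal" else "CHEST LAT"
    else:
        series = "XR CHEST"
    header = {
        "patient_id": patient_id,
        "manufacturer": manufacturer,
        "deviation_index": round(float(rng.normal(0.0, 2.0)), 2),
        "sex": sex,
        "age": age,
        "ethnicity": _ETHNICITIES[rng.integers(len(_ETHNICITIES))],
        "series_description": series,
        "bits_stored": 12,
    }
    if rng.random() < config.missing_metadata_rate:
        drop = rng.choice(["manufacturer", "deviation_index", "sex", "age", "ethnicity"])
        header[drop] = None

    return PhantomSpec(
        projection=projection, size=config.size, text_items=text_items,
        pad_width=pad, collim_widths=tuple(collim), rotation=rotation,
        blur_sigma=float(rng.uniform(*config.blur_sigma_range)),
        noise_sd=float(rng.uniform(*config.noise_sd_range)),
        gamma=gamma, gain=gain, offset=offset,
        ambiguity=float(rng.uniform(*config.ambiguity_range)),
        write_window=config.write_window, header=header,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def generate_curation_table(n: int, config: DatasetConfig = DatasetConfig(),
                            seed: int = 0) -> pd.DataFrame:
    """Sample a curation table (metadata only, no pixel rendering).

    Same sampling distribution as :func:`generate_dataset` but orders of
    magnitude faster when only dataset-level curation is under study.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    patient_counter = 0
    prev_patient = None
    for i in range(n):
        if prev_patient is not None and rng.random() < config.multi_image_rate:
            patient_id = prev_patient
        else:
            patient_counter += 1
            patient_id = f"P{patient_counter:05d}"
        prev_patient = patient_id
        spec = sample_spec(config, rng, i, patient_id)
        h = spec.header
        rows.append({
            "image_id": f"img{i:05d}", "patient_id": patient_id,
            "manufacturer": h.get("manufacturer"),
            "deviation_index": h.get("deviation_index"),
            "sex": h.get("sex"), "age": h.get("age"),
            "ethnicity": h.get("ethnicity"),
            "series_description": h.get("series_description"),
            "projection": spec.projection,
        })
    return pd.DataFrame(rows)


def add_jewelry(record: RadiographRecord, truth: dict,
                rng: np.random.Generator, radius: int = 30) -> None:
    """Inject a bright disk (necklace/pendant analogue) into the lung field."""
    lung = truth["lung_mask"]
    if not lung.any():
        return
    rows, cols = np.nonzero(lung)
    i = rng.integers(len(rows))
    cy, cx = int(rows[i]), int(cols[i])
    yy, xx = np.ogrid[0:record.image.shape[0], 0:record.image.shape[1]]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    img = record.image.copy()
    img[disk] = 0.97
    record.image = img
    record.log_transform("synthetic:jewelry")


def generate_dataset(n: int, config: DatasetConfig = DatasetConfig(),
                     seed: int = 0, out_dir: Optional[Union[str, Path]] = None
                     ) -> Tuple[List[Tuple[RadiographRecord, dict]], pd.DataFrame]:
    """Sample ``n`` phantoms, optionally writing DICOM + truth fixtures.

    Returns the (record, truth) list and a curation table with one row per
    image (image_id, patient_id and the stratification fields).
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records: List[Tuple[RadiographRecord, dict]] = []
    rows = []
    patient_counter = 0
    prev_patient = None
    for i in range(n):
        if prev_patient is not None and rng.random() < config.multi_image_rate:
            patient_id = prev_patient
        else:
            patient_counter += 1
            patient_id = f"P{patient_counter:05d}"
        prev_patient = patient_id
        spec = sample_spec(config, rng, i, patient_id)
        record, truth = generate_phantom(spec)
        if config.jewelry_prob and rng.random() < config.jewelry_prob:
            add_jewelry(record, truth, rng)
        truth["spec"] = spec
        records.append((record, truth))
        m = record.metadata
        rows.append({
            "image_id": f"img{i:05d}", "patient_id": patient_id,
            "manufacturer": m.manufacturer, "deviation_index": m.deviation_index,
            "sex": m.sex, "age": m.age, "ethnicity": m.ethnicity,
            "series_description": m.series_description,
            "projection": spec.projection,
        })
    table = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "dicom").mkdir(parents=True, exist_ok=True)
        (out_dir / "truth").mkdir(parents=True, exist_ok=True)
        from .dicom_io import write_radiograph
        from PIL import Image
        for i, (record, truth) in enumerate(records):
            name = f"img{i:05d}"
            write_radiograph(record, out_dir / "dicom" / f"{name}.dcm",
                             spec=truth["spec"])
            for key in ("text_mask", "lung_mask"):
                Image.fromarray((truth[key] * 255).astype(np.uint8), mode="L").save(
                    out_dir / "truth" / f"{name}_{key}.png")
            (out_dir / "truth" / f"{name}.json").write_text(json.dumps({
                "crop_box": list(truth["crop_box"].as_tuple()),
                "rotation": truth["rotation"],
                "projection": truth["projection"],
            }))
        table.to_csv(out_dir / "curation.csv", index=False)
    return records, table
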