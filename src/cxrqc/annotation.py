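"""Stage 3: burned-in text detection, inpainting, and outcome grading.

Detection is rule-based: a white top-hat transform isolates small bright
structure against the anatomy, and connected components are kept only when
they have text-like geometry (character-scale height, stroke-like fill,
near a border or part of a collinear run). The detector is deliberately a
pluggable function so a learned detector can be swapped in behind the same
interface.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .records import QCResult, ACTION_FLAG


@dataclass
class AnnotationConfig:
    """Tunables for the rule-based text detector.

    ``char_height_band`` is the admissible connected-component height as a
    fraction of image height; ``contrast_threshold`` is the minimum top-hat
    response (local brightness excess over the anatomy background).
    """

    tophat_size: int = 11
    contrast_threshold: float = 0.18
    peak_threshold: float = 0.30
    char_height_band: Tuple[float, float] = (0.01, 0.08)
    max_width_frac: float = 0.30
    fill_ratio_band: Tuple[float, float] = (0.08, 1.0)
    min_area: int = 4
    border_margin_frac: float = 0.30
    dilate_margin: int = 2
    max_mask_fraction: float = 0.50


@dataclass
class AnnotationMask:
    """Boolean mask of annotation pixels plus its connected components'
    bounding boxes (row_start, row_end, col_start, col_end, half-open)."""

    mask: np.ndarray
    components: List[Tuple[int, int, int, int]] = field(default_factory=list)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "AnnotationMask":
        mask = np.asarray(mask, dtype=bool)
        labels = measure.label(mask, connectivity=2)
        comps = [tuple(int(v) for v in (r.bbox[0], r.bbox[2], r.bbox[1], r.bbox[3]))
                 for r in measure.regionprops(labels)]
        return cls(mask=mask, components=comps)

    @classmethod
    def empty(cls, shape: Tuple[int, int]) -> "AnnotationMask":
        return cls(mask=np.zeros(shape, dtype=bool), components=[])

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())

    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class RemovalOutcome:
    category: str  # complete | partial | none_present | failed
    fraction_removed: float
    inpainted_in_lung: bool


class MaskTooLargeError(Exception):
    """Refusing to inpaint a mask covering more than half the image."""


def detect_annotations(image: np.ndarray,
                       config: AnnotationConfig = AnnotationConfig()) -> AnnotationMask:
    """Detect candidate burned-in characters.

    Pipeline: white top-hat (structuring element larger than a text
    stroke) -> threshold -> connected-component geometry filters ->
    border/collinearity arrangement filter -> dilation by a safety margin.
    """
    image = np.asarray(image, dtype=np.float64)
    nrows, ncols = image.shape
    footprint = morphology.footprint_rectangle((config.tophat_size, config.tophat_size))
    tophat = morphology.white_tophat(image, footprint=footprint)
    cand = tophat >= config.contrast_threshold
    if not cand.any():
        return AnnotationMask.empty(image.shape)

    labels = measure.label(cand, connectivity=2)
    regions = measure.regionprops(labels, intensity_image=tophat)
    h_lo = config.char_height_band[0] * nrows
    h_hi = config.char_height_band[1] * nrows
    w_hi = config.max_width_frac * ncols

    keep: List = []
    for r in regions:
        rh = r.bbox[2] - r.bbox[0]
        rw = r.bbox[3] - r.bbox[1]
        if r.area < config.min_area:
            continue
        if not (h_lo <= rh <= h_hi) or rw > w_hi:
            continue
        fill = r.area / (rh * rw)
        if not (config.fill_ratio_band[0] <= fill <= config.fill_ratio_band[1]):
            continue
        # burned-in strokes are near-saturated, so their top-hat response
        # peaks far above the extent threshold; smooth anatomy ridges (the
        # bright wedge at the lung's upper-outer corner) cross the extent
        # threshold but never peak this high
        if float(r.intensity_max) < config.peak_threshold:
            continue
        # thin slivers pressed flat against the frame edge are body-outline
        # rim responses (a steep body-air step also excites the top-hat),
        # not characters
        touches_lr = r.bbox[1] == 0 or r.bbox[3] == ncols
        touches_tb = r.bbox[0] == 0 or r.bbox[2] == nrows
        if (touches_lr and rw <= 6) or (touches_tb and rh <= 6):
            continue
        keep.append(r)

    # arrangement filter: near a border, or collinear with another candidate
    mr = config.border_margin_frac * nrows
    mc = config.border_margin_frac * ncols
    accepted = []
    for i, r in enumerate(keep):
        cy, cx = r.centroid
        near_border = (cy < mr or cy > nrows - mr or cx < mc or cx > ncols - mc)
        if near_border:
            accepted.append(r)
            continue
        rh = r.bbox[2] - r.bbox[0]
        for j, s in enumerate(keep):
            if j != i and abs(s.centroid[0] - cy) <= max(rh, s.bbox[2] - s.bbox[0]):
                accepted.append(r)
                break

    if not accepted:
        return AnnotationMask.empty(image.shape)
    mask = np.zeros(image.shape, dtype=bool)
    for r in accepted:
        mask[labels == r.label] = True
    if config.dilate_margin > 0:
        size = 2 * config.dilate_margin + 1
        halo = ndimage.binary_dilation(
            mask, structure=np.ones((size, size), dtype=bool)) & ~mask
        # the margin exists to catch sub-threshold blur spill around the
        # strokes; keep only halo pixels with some local brightness excess
        # so the mask does not bleed onto dark anatomy (e.g. a lung apex
        # right below a corner marker)
        mask |= halo & (tophat >= 0.25 * config.contrast_threshold)
    return AnnotationMask.from_mask(mask)


def inpaint(image: np.ndarray, mask: AnnotationMask,
            max_mask_fraction: float = 0.50,
            match_noise: bool = True) -> np.ndarray:
    """Fill masked pixels by distance-ordered neighborhood averaging.

    Mask pixels are processed in order of increasing Euclidean distance to
    the mask boundary; each is assigned the mean of its already-known
    8-neighbors, so values propagate inward. The smooth fill is then
    re-textured with noise matched to the rest of the image
    (``match_noise``): without it the fill is a conspicuously flat,
    mask-shaped scar that downstream models can learn from — the exact
    artifact annotation removal is meant to eliminate. The noise draw is
    deterministic in the image + mask content. Unmasked pixels are
    returned bit-identical.
    """
    image = np.asarray(image, dtype=np.float64)
    m = mask.mask if isinstance(mask, AnnotationMask) else np.asarray(mask, dtype=bool)
    if m.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if m.mean() > max_mask_fraction:
        raise MaskTooLargeError(
            f"mask covers {m.mean():.0%} of the image (> {max_mask_fraction:.0%})")
    if not m.any():
        return image.copy()

    out = image.copy()
    known = ~m
    out[m] = 0.0
    dist = ndimage.distance_transform_edt(m)
    kernel = np.ones((3, 3), dtype=np.float64)
    for d in np.unique(dist[m]):
        layer = dist == d
        ksum = ndimage.convolve(np.where(known, out, 0.0), kernel, mode="constant")
        kcnt = ndimage.convolve(known.astype(np.float64), kernel, mode="constant")
        fill = np.divide(ksum, kcnt, out=np.zeros_like(ksum), where=kcnt > 0)
        out[layer] = fill[layer]
        known |= layer

    if match_noise:
        sigma = _noise_sigma(image, ~m)
        if sigma > 0:
            seed = zlib.crc32(m.tobytes()) ^ zlib.crc32(image.tobytes())
            rng = np.random.default_rng(seed & 0x7FFFFFFF)
            out[m] += rng.normal(0.0, sigma, int(m.sum()))
    return np.clip(out, 0.0, 1.0)


def _noise_sigma(image: np.ndarray, region: np.ndarray) -> float:
    """Robust pixel-noise estimate: scaled median absolute deviation of the
    residual against a 3x3 median filter, over ``region``."""
    resid = image - ndimage.median_filter(image, size=3)
    vals = resid[region]
    if vals.size == 0:
        return 0.0
    mad = float(np.median(np.abs(vals - np.median(vals))))
    return 1.4826 * mad


def mask_too_large_result(mask: AnnotationMask) -> QCResult:
    return QCResult(stage="annotation", action=ACTION_FLAG,
                    reasons=["annotation_mask_too_large"],
                    evidence={"mask_fraction": round(mask.fraction, 6)})


def removal_outcome(pred_mask: AnnotationMask, truth_mask: AnnotationMask,
                    lung_region: Optional[np.ndarray] = None) -> RemovalOutcome:
    """Grade a predicted mask against a truth mask.

    ``complete`` requires >= 99% of truth pixels covered, ``failed``
    <= 1%; ``inpainted_in_lung`` is true when predicted pixels fall inside
    the lung region without being true annotation (false-positive
    inpainting over anatomy, the failure mode caused by jewelry-like
    artifacts)."""
    pred = pred_mask.mask if isinstance(pred_mask, AnnotationMask) else np.asarray(pred_mask, bool)
    truth = truth_mask.mask if isinstance(truth_mask, AnnotationMask) else np.asarray(truth_mask, bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes must agree")
    if lung_region is None:
        lung_region = central_box_region(pred.shape)
    if lung_region.shape != pred.shape:
        raise ValueError("lung region shape must agree with masks")

    in_lung = bool((pred & lung_region & ~truth).any())
    if not truth.any():
        return RemovalOutcome("none_present", 0.0, in_lung)
    frac = float((pred & truth).sum() / truth.sum())
    if frac >= 0.99:
        cat = "complete"
    elif frac <= 0.01:
        cat = "failed"
    else:
        cat = "partial"
    return RemovalOutcome(cat, frac, in_lung)


def central_box_region(shape: Tuple[int, int], frac: float = 0.60) -> np.ndarray:
    """Heuristic lung region when no segmentation is available: the central
    ``frac`` box of the image."""
    region = np.zeros(shape, dtype=bool)
    r_m = int(shape[0] * (1 - frac) / 2)
    c_m = int(shape[1] * (1 - frac) / 2)
    region[r_m:shape[0] - r_m, c_m:shape[1] - c_m] = True
    return region


def remove_annotations(image: np.ndarray,
                       config: AnnotationConfig = AnnotationConfig()):
    """Detect + inpaint in one step. Returns (cleaned image, mask, QCResult|None);
    a too-large mask refuses inpainting and returns the original image with
    a flag result."""
    mask = detect_annotations(image, config)
    if mask.fraction > config.max_mask_fraction:
        return image.copy(), mask, mask_too_large_result(mask)
    return inpaint(image, mask, config.max_mask_fraction), mask, None
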