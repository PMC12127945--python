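"""Stage 4: no-reference quality scoring.

Four failure axes, each with its own score: excessive sharpness
(over-processed edge enhancement), low contrast, blurring, and residual
border area left after cropping. Thresholds were calibrated as mean +/- 3
SD of each score over a clean synthetic cohort (no blur beyond the
anatomy's intrinsic smoothness, no injected degradations); they are
configuration, not constants of nature, and should be recalibrated for a
new image domain.

Known limitation, inherited from the metric set itself: thin scratch or
pixel-dropout artifacts barely move any of the four scores and are NOT
reliably flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Set

import numpy as np
from scipy import ndimage

from .geometry import EmptyContentError, detect_border_crop
from .records import ACTION_FLAG, ACTION_PASS, QCResult

FLAG_OVER_SHARPENED = "over_sharpened"
FLAG_LOW_CONTRAST = "low_contrast"
FLAG_BLURRED = "blurred"
FLAG_LARGE_BORDER = "large_border"


@dataclass(frozen=True)
class QualityThresholds:
    """Default values come from the clean-phantom calibration run
    (mean +/- 3 SD per score; see docs/methods.md)."""

    sharpness_hi: float = 7.0e-3
    contrast_lo: float = 0.564
    blur_hi: float = 0.9816
    border_frac_hi: float = 0.05


@dataclass
class QualityReport:
    sharpness: float
    contrast: float
    blur_index: float
    residual_border_fraction: float
    flags: Set[str] = field(default_factory=set)


def quality_metrics(image: np.ndarray) -> QualityReport:
    """Compute the four quality scores (no flags yet).

    sharpness: variance of the discrete-Laplacian response.
    contrast: robust intensity spread (1st-99th percentile).
    blur_index: 1 - (high-frequency / total AC spectral energy); rises
        monotonically with Gaussian blur.
    residual_border_fraction: fraction of pixels in constant/near-black
        bands still present (re-running border detection post-crop).
    """
    image = np.asarray(image, dtype=np.float64)
    lap = ndimage.laplace(image)
    sharpness = float(lap.var())
    p1, p99 = np.percentile(image, [1, 99])
    contrast = float(p99 - p1)
    blur_index = _blur_index(image)
    try:
        box = detect_border_crop(image)
        residual = 1.0 - (box.shape[0] * box.shape[1]) / image.size
    except EmptyContentError:
        residual = 1.0
    return QualityReport(sharpness=sharpness, contrast=contrast,
                         blur_index=blur_index,
                         residual_border_fraction=float(residual))


def _blur_index(image: np.ndarray, cutoff: float = 0.05,
                median_size: int = 3) -> float:
    """1 - fraction of AC spectral energy above the radial frequency
    ``cutoff`` (cycles/pixel), computed after a light median prefilter.

    The prefilter matters: detector noise is added *after* any optical or
    motion blur, so an unfiltered spectrum of a blurred-but-noisy image is
    dominated by the noise floor and hides the high-frequency deficit.
    Constant images return 0.
    """
    if median_size:
        image = ndimage.median_filter(image, size=median_size)
    f = np.fft.fft2(image - image.mean())
    power = np.abs(f) ** 2
    fy = np.fft.fftfreq(image.shape[0])[:, None]
    fx = np.fft.fftfreq(image.shape[1])[None, :]
    radius = np.sqrt(fy ** 2 + fx ** 2)
    total = power.sum()
    if total <= 0:
        return 0.0
    high = power[radius > cutoff].sum()
    return float(1.0 - high / total)


def quality_flag(report: QualityReport,
                 thresholds: QualityThresholds = QualityThresholds()) -> QCResult:
    """Apply thresholds; flag with the union of triggered reasons."""
    flags = set()
    if report.sharpness > thresholds.sharpness_hi:
        flags.add(FLAG_OVER_SHARPENED)
    if report.contrast < thresholds.contrast_lo:
        flags.add(FLAG_LOW_CONTRAST)
    if report.blur_index > thresholds.blur_hi:
        flags.add(FLAG_BLURRED)
    if report.residual_border_fraction > thresholds.border_frac_hi:
        flags.add(FLAG_LARGE_BORDER)
    report.flags = flags
    evidence = {
        "sharpness": report.sharpness,
        "contrast": report.contrast,
        "blur_index": report.blur_index,
        "residual_border_fraction": report.residual_border_fraction,
    }
    if flags:
        return QCResult(stage="quality", action=ACTION_FLAG,
                        reasons=sorted(flags), evidence=evidence)
    return QCResult(stage="quality", action=ACTION_PASS, reasons=[],
                    evidence=evidence)


def assess_quality(image: np.ndarray,
                   thresholds: Optional[QualityThresholds] = None) -> QCResult:
    return quality_flag(quality_metrics(image), thresholds or QualityThresholds())
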