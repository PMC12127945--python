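"""Stage 1: pixel-intensity standardization and harmonization statistics.

Standardization applies the header display window (VOI) as a linear map
when the header provides one, and falls back to a percentile auto-window
otherwise. The harmonization statistics (coefficient of variation, SD,
Shannon entropy, and between-manufacturer standardized mean difference)
quantify how much the transform pulls different vendors' intensity
distributions toward a common display band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np


@dataclass
class IntensityStats:
    mean: float
    sd: float
    cv: Optional[float]  # sd/mean; None only when mean == 0 with sd > 0
    entropy: float       # bits, over an nbins equal-width histogram of [0, 1]


def apply_windowing(image: np.ndarray, center: Optional[float] = None,
                    width: Optional[float] = None) -> np.ndarray:
    """Linear VOI windowing: ``<= center - width/2 -> 0``,
    ``>= center + width/2 -> 1``, linear in between.

    When either parameter is missing, an auto-window is computed from the
    1st-99th percentiles of the non-zero pixels (exact-zero padding is
    excluded so it stays at 0).
    """
    image = np.asarray(image, dtype=np.float64)
    if width is not None and width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    if center is None or width is None:
        center, width = auto_window(image)
    lo = center - width / 2.0
    return np.clip((image - lo) / width, 0.0, 1.0)


def auto_window(image: np.ndarray, low_pct: float = 1.0,
                high_pct: float = 99.0) -> Tuple[float, float]:
    """Percentile window over non-zero pixels; maps [p_low, p_high] onto [0, 1]."""
    vals = image[image > 0]
    if vals.size == 0:
        vals = image.ravel()
    p_lo, p_hi = np.percentile(vals, [low_pct, high_pct])
    width = max(float(p_hi - p_lo), 1.0 / 4096.0)
    center = float(p_lo + p_hi) / 2.0
    return center, width


def intensity_stats(image: np.ndarray, nbins: int = 256) -> IntensityStats:
    """Mean, SD, coefficient of variation and histogram entropy (bits)."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("image is empty")
    mean = float(image.mean())
    sd = float(image.std())
    if mean > 0:
        cv: Optional[float] = sd / mean
    else:
        cv = 0.0 if sd == 0 else None
    hist, _ = np.histogram(image, bins=nbins, range=(0.0, 1.0))
    p = hist[hist > 0] / image.size
    entropy = float(-(p * np.log2(p)).sum()) if p.size else 0.0
    return IntensityStats(mean=mean, sd=sd, cv=cv, entropy=entropy)


def standardized_mean_difference(values_a: Sequence[float],
                                 values_b: Sequence[float]) -> float:
    """|mean_a - mean_b| / pooled SD, pooled SD = sqrt((sd_a^2 + sd_b^2)/2).

    Sample SDs (ddof=1). Zero pooled SD returns 0 for equal means and
    +inf otherwise.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sd_a = a.std(ddof=1)
    sd_b = b.std(ddof=1)
    pooled = np.sqrt((sd_a ** 2 + sd_b ** 2) / 2.0)
    diff = abs(float(a.mean() - b.mean()))
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / float(pooled)


def standardize(record, nbins: int = 256):
    """Stage-1 entry point: window a record's image using its header
    window when present, auto-window otherwise. Returns (record, pre-stats,
    post-stats); the record's image is replaced by the windowed image."""
    meta = record.metadata
    pre = intensity_stats(record.image, nbins=nbins)
    windowed = apply_windowing(record.image, meta.window_center, meta.window_width)
    post = intensity_stats(windowed, nbins=nbins)
    record.image = windowed
    mode = "header" if (meta.window_center is not None and meta.window_width is not None) else "auto"
    record.log_transform(f"intensity:window:{mode}")
    return record, pre, post
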