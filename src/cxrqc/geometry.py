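"""Stage 2: geometric standardization.

Three tools: border detection/cropping (exact-constant padding plus
near-black collimation bands), 90-degree rotation correction driven by an
upright-orientation score, and aspect-ratio screening against configured
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from skimage.transform import resize

from .records import ACTION_FLAG, ACTION_PASS, QCResult

DEFAULT_PAD_TOL = 1.0 / 1024.0
DEFAULT_COLLIM_THRESHOLD = 0.04  # "near-black" cutoff on the stored [0,1] scale
MAX_CROP_FRACTION = 0.45  # safety bound: never remove more than this per dimension

DEFAULT_ASPECT_LOWER = 0.85
DEFAULT_ASPECT_UPPER = 1.48


class EmptyContentError(Exception):
    """The whole image was classified as border."""


@dataclass(frozen=True)
class CropBox:
    """Half-open, 0-based crop window [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end and 0 <= self.col_start < self.col_end):
            raise ValueError(f"degenerate crop box {self}")

    @classmethod
    def full(cls, shape: Tuple[int, int]) -> "CropBox":
        return cls(0, shape[0], 0, shape[1])

    def apply(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_start:self.row_end, self.col_start:self.col_end]

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.row_start, self.row_end, self.col_start, self.col_end)

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)


@dataclass(frozen=True)
class AspectRatioBounds:
    lower: float = DEFAULT_ASPECT_LOWER
    upper: float = DEFAULT_ASPECT_UPPER

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError(f"invalid aspect bounds {self}")


def detect_border_crop(image: np.ndarray,
                       pad_tol: float = DEFAULT_PAD_TOL,
                       collim_threshold: float = DEFAULT_COLLIM_THRESHOLD) -> CropBox:
    """Find the content box after stripping padding and collimation borders.

    Two passes: (1) peel border rows/columns that are exact-constant within
    ``pad_tol`` (digital padding); (2) peel contiguous border bands whose
    line mean falls below the absolute ``collim_threshold`` on the stored
    [0, 1] scale. Unexposed collimation is near-black on the stored scale
    regardless of content, so an absolute cutoff separates it from exposed
    free air; content-relative cutoffs (quantiles or median fractions) fail
    when the band itself dominates the dark tail or the content is dark.
    Total removal per dimension is capped at 45%; an image that is all
    border raises :class:`EmptyContentError`.
    """
    image = np.asarray(image, dtype=np.float64)
    nrows, ncols = image.shape
    r0, r1, c0, c1 = 0, nrows, 0, ncols
    row_budget = int(MAX_CROP_FRACTION * nrows)
    col_budget = int(MAX_CROP_FRACTION * ncols)

    def rows_removed() -> int:
        return r0 + (nrows - r1)

    def cols_removed() -> int:
        return c0 + (ncols - c1)

    # pass 1: exact-constant padding
    changed = True
    while changed:
        changed = False
        if rows_removed() < row_budget and _is_constant(image[r0, c0:c1], pad_tol):
            r0 += 1
            changed = True
        if rows_removed() < row_budget and _is_constant(image[r1 - 1, c0:c1], pad_tol):
            r1 -= 1
            changed = True
        if cols_removed() < col_budget and _is_constant(image[r0:r1, c0], pad_tol):
            c0 += 1
            changed = True
        if cols_removed() < col_budget and _is_constant(image[r0:r1, c1 - 1], pad_tol):
            c1 -= 1
            changed = True

    # pass 2: near-black collimation bands
    thresh = float(collim_threshold)
    changed = True
    while changed:
        changed = False
        if rows_removed() < row_budget and image[r0, c0:c1].mean() < thresh:
            r0 += 1
            changed = True
        if rows_removed() < row_budget and image[r1 - 1, c0:c1].mean() < thresh:
            r1 -= 1
            changed = True
        if cols_removed() < col_budget and image[r0:r1, c0].mean() < thresh:
            c0 += 1
            changed = True
        if cols_removed() < col_budget and image[r0:r1, c1 - 1].mean() < thresh:
            c1 -= 1
            changed = True

    remaining = image[r0:r1, c0:c1]
    if _is_constant(remaining.ravel(), pad_tol) or remaining.mean() < thresh:
        raise EmptyContentError("entire image classified as border/constant")
    return CropBox(r0, r1, c0, c1)


def _is_constant(line: np.ndarray, tol: float) -> bool:
    return float(line.max() - line.min()) <= tol


def crop_result(image: np.ndarray, box: CropBox) -> QCResult:
    nrows, ncols = image.shape
    frac = 1.0 - (box.shape[0] * box.shape[1]) / (nrows * ncols)
    return QCResult(stage="geometry_crop", action=ACTION_PASS, reasons=[],
                    evidence={"crop_box": list(box.as_tuple()),
                              "cropped_fraction": round(frac, 6)})


def upright_score(image: np.ndarray, downsample: int = 64) -> float:
    """Score how plausibly upright an image is.

    Combines bottom-minus-top mean-intensity asymmetry (the radiodense
    abdomen/diaphragm sits at the bottom of an upright chest film in the
    canonical polarity) with vertical-mirror symmetry (high for upright or
    inverted frontal films, low when rotated sideways).
    """
    small = resize(np.asarray(image, dtype=np.float64), (downsample, downsample),
                   anti_aliasing=True, mode="reflect")
    q = downsample // 4
    asym = float(small[-q:].mean() - small[:q].mean())
    sym = -float(np.mean(np.abs(small - small[:, ::-1])))
    return asym + 0.5 * sym


def correct_rotation(image: np.ndarray) -> Tuple[np.ndarray, int]:
    """Return the 90-degree multiple (counter-clockwise) that maximizes the
    upright score, and the rotated image. Ties prefer 0, then 90, 180, 270."""
    best_k, best_score = 0, -np.inf
    for k in range(4):
        s = upright_score(np.rot90(image, k))
        if s > best_score + 1e-12:
            best_k, best_score = k, s
    return np.rot90(image, best_k), best_k * 90


def aspect_ratio_check(image: np.ndarray,
                       bounds: AspectRatioBounds = AspectRatioBounds()) -> QCResult:
    """Pass iff ncols/nrows lies within the (inclusive) configured bounds."""
    nrows, ncols = image.shape
    ratio = ncols / nrows
    evidence = {"aspect_ratio": round(float(ratio), 6),
                "lower": bounds.lower, "upper": bounds.upper}
    if bounds.lower <= ratio <= bounds.upper:
        return QCResult(stage="geometry_aspect", action=ACTION_PASS,
                        reasons=[], evidence=evidence)
    return QCResult(stage="geometry_aspect", action=ACTION_FLAG,
                    reasons=["aspect_ratio"], evidence=evidence)
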