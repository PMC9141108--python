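"""Frame preprocessing and histogram-projection ROI calibration.

The preprocessing chain (median noise reduction, optional histogram
equalisation, optional morphological open/close) conditions raw 8-bit frames
before motion analysis.  ROI calibration binarises one frame, projects the
binary image onto each axis and crops the detection region to the liquid
body between the bottle walls; the ROI is computed once per sequence
(fixed-camera assumption) and reused for every frame.

Coordinates are 0-based, row-major, top-left origin; all intervals are
half-open [start, end).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Tuple, Union

import numpy as np
from scipy import ndimage, signal
from skimage import exposure, filters, morphology

from .synthetic import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    median_kernel: int = 3
    equalize: Literal["global", "clahe", "none"] = "none"
    morph_kernel: int = 0
    morph_op: Literal["open", "close", "none"] = "none"
    binarize_threshold: Union[Literal["otsu"], float] = "otsu"

    def validate(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ConfigurationError("median_kernel must be odd and >= 1")


@dataclass(frozen=True)
class ROIBox:
    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def validate(self, shape: Tuple[int, int] | None = None) -> None:
        if not (0 <= self.row_start < self.row_end and 0 <= self.col_start < self.col_end):
            raise ConfigurationError(f"degenerate ROI {self}")
        if shape is not None and (self.row_end > shape[0] or self.col_end > shape[1]):
            raise ConfigurationError(f"ROI {self} exceeds frame shape {shape}")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)


def preprocess(frame: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Median-filter and optionally equalise/morph one 8-bit frame.

    Output keeps the input shape and the uint8 range.  With
    ``median_kernel=1``, ``equalize='none'`` and ``morph_op='none'`` this is
    the identity.
    """
    params.validate()
    out = np.asarray(frame, dtype=np.uint8)
    if params.median_kernel > 1:
        out = ndimage.median_filter(out, size=params.median_kernel, mode="nearest")
    if params.equalize == "global":
        out = (exposure.equalize_hist(out) * 255).round().astype(np.uint8)
    elif params.equalize == "clahe":
        out = (exposure.equalize_adapthist(out) * 255).round().astype(np.uint8)
    if params.morph_op != "none" and params.morph_kernel > 1:
        selem = morphology.footprint_rectangle((params.morph_kernel, params.morph_kernel))
        op = morphology.opening if params.morph_op == "open" else morphology.closing
        out = op(out, selem)
    return out


def binarize(frame: np.ndarray, threshold: Union[Literal["otsu"], float] = "otsu") -> np.ndarray:
    """Threshold a frame to a boolean mask (foreground = above threshold)."""
    frame = np.asarray(frame)
    if threshold == "otsu":
        if frame.min() == frame.max():  # constant frame: Otsu undefined
            return np.zeros(frame.shape, dtype=bool)
        thr = filters.threshold_otsu(frame)
    else:
        thr = float(threshold)
    return frame > thr


def project_histogram(binary: np.ndarray, axis: Literal["rows", "cols"]) -> np.ndarray:
    """Per-row or per-column foreground counts of a binary mask."""
    binary = np.asarray(binary, dtype=bool)
    return binary.sum(axis=1 if axis == "rows" else 0).astype(np.int64)


def _axis_bounds(profile: np.ndarray, inset: int = 2) -> Tuple[int, int] | None:
    """Bounds of the dominant region of a projection profile.

    Smooths with a 5-sample moving average, then tries two-peak wall
    localisation (region strictly between the two highest local maxima);
    when the profile has no two distinct peaks (e.g. a plateau), uses the
    widest contiguous run at or above half the maximum.  Returns half-open
    (start, end) inset by ``inset`` px, or None when degenerate.
    """
    if profile.max() <= 0:
        return None
    smooth = np.convolve(profile.astype(float), np.ones(5) / 5.0, mode="same")
    peaks, props = signal.find_peaks(smooth, height=0.25 * smooth.max())
    if len(peaks) >= 2:
        order = np.argsort(props["peak_heights"])[::-1]
        a, b = sorted(int(peaks[i]) for i in order[:2])
        lo, hi = a + 1 + inset, b - inset
        if hi - lo >= 4:
            return lo, hi
    mask = smooth >= 0.5 * smooth.max()
    # widest contiguous run
    best, cur_start, best_run = None, None, 0
    for i, v in enumerate(np.append(mask, False)):
        if v and cur_start is None:
            cur_start = i
        elif not v and cur_start is not None:
            if i - cur_start > best_run:
                best, best_run = (cur_start, i), i - cur_start
            cur_start = None
    if best is None:
        return None
    lo, hi = best[0] + inset, best[1] - inset
    return (lo, hi) if hi - lo >= 1 else None


def locate_roi(frame: np.ndarray, params: PreprocessParams | None = None) -> ROIBox:
    """Locate the detection ROI from one frame by histogram projection.

    The frame is binarised (Otsu by default) and projected on both axes; the
    ROI is the interior region bounded by the dominant profile structure on
    each axis.  Falls back to the full frame with a warning when no structure
    is found (e.g. a uniform frame).
    """
    params = params or PreprocessParams()
    rows, cols = frame.shape
    binary = binarize(frame, params.binarize_threshold)
    col_bounds = _axis_bounds(project_histogram(binary, "cols"))
    row_bounds = _axis_bounds(project_histogram(binary, "rows"))
    if col_bounds is None and row_bounds is None:
        warnings.warn("no profile structure found; falling back to full-frame ROI",
                      stacklevel=2)
        logger.warning("locate_roi: full-frame fallback")
        return ROIBox(0, rows, 0, cols)
    r0, r1 = row_bounds if row_bounds else (0, rows)
    c0, c1 = col_bounds if col_bounds else (0, cols)
    roi = ROIBox(max(0, r0), min(rows, r1), max(0, c0), min(cols, c1))
    roi.validate((rows, cols))
    return roi


def crop(frame: np.ndarray, roi: ROIBox) -> np.ndarray:
    """Extract the ROI sub-frame (a view; copy if you mutate)."""
    roi.validate(frame.shape[:2])
    return frame[roi.row_start : roi.row_end, roi.col_start : roi.col_end]
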