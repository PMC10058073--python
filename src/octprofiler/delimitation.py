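"""Lateral lesion delimitation from the dermatoscopy image.

The scanner overlays a white line on the dermatoscopy image marking the
OCT scan path. A band of rows around that line is extracted, the
saturated line rows are masked out, and Otsu's threshold splits the band
into dark (pigmented lesion) and light (surrounding skin) pixels. The
longest run of columns that are mostly dark gives the lesion's lateral
extent, which is then mapped affinely into B-scan column coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import DelimitationError, LesionNotFoundError

__all__ = [
    "DermatoscopyView",
    "LesionBounds",
    "extract_scanline_band",
    "otsu_threshold",
    "find_lesion_bounds",
    "map_bounds_to_oct",
]

# Rec. 601 luma weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])

# a band row is considered part of the saturated white scan line when its
# median luminance exceeds this level
_LINE_LUMA = 250.0


@dataclass
class DermatoscopyView:
    """Dermatoscopy RGB image with the scan-line geometry.

    ``scan_span_cols`` is the half-open column interval of the image that
    the OCT scan path covers; lesion bounds found inside it are expressed
    in full-image column coordinates.
    """

    rgb_image: np.ndarray
    scanline_row: int
    scan_span_cols: Tuple[int, int]

    def __post_init__(self) -> None:
        img = np.asarray(self.rgb_image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise DelimitationError(f"rgb_image must be HxWx3, got shape {img.shape}")
        self.rgb_image = img
        h, w = img.shape[:2]
        if not 0 <= self.scanline_row < h:
            raise DelimitationError(f"scanline_row {self.scanline_row} outside image height {h}")
        s0, s1 = self.scan_span_cols
        if not (0 <= s0 < s1 <= w):
            raise DelimitationError(f"scan_span_cols {self.scan_span_cols} invalid for width {w}")


@dataclass(frozen=True)
class LesionBounds:
    """Half-open lateral interval [start_col, end_col) in a named frame."""

    start_col: int
    end_col: int
    frame: str  # "dermatoscopy" | "bscan"

    def __post_init__(self) -> None:
        if self.frame not in ("dermatoscopy", "bscan"):
            raise DelimitationError(f"unknown frame {self.frame!r}")
        if not 0 <= self.start_col < self.end_col:
            raise DelimitationError(
                f"invalid bounds [{self.start_col}, {self.end_col})"
            )

    @property
    def width(self) -> int:
        return self.end_col - self.start_col


def extract_scanline_band(view: DermatoscopyView, margin: int = 10) -> np.ma.MaskedArray:
    """Grayscale band of rows around the scan line, line rows masked.

    Rows ``[scanline_row - margin, scanline_row + margin]`` (clamped at
    the image borders) are converted to luminance and restricted to the
    scan span. Rows whose median luminance saturates (the white line
    itself) are masked so they do not skew the threshold statistics.
    """
    if margin <= 0:
        raise DelimitationError("margin must be positive (no usable band rows otherwise)")
    h = view.rgb_image.shape[0]
    r0 = max(0, view.scanline_row - margin)
    r1 = min(h - 1, view.scanline_row + margin)
    s0, s1 = view.scan_span_cols
    band_rgb = view.rgb_image[r0 : r1 + 1, s0:s1, :].astype(float)
    gray = band_rgb @ _LUMA
    line_rows = np.median(gray, axis=1) > _LINE_LUMA
    if line_rows.all():
        raise DelimitationError("entire band is saturated scan line")
    mask = np.broadcast_to(line_rows[:, None], gray.shape)
    return np.ma.MaskedArray(gray, mask=mask)


def otsu_threshold(gray_values) -> int:
    """Otsu's threshold over a 256-bin histogram of 8-bit gray values.

    Returns the gray level ``t`` maximizing the between-class variance of
    the split ``{v <= t} | {v > t}`` (lowest level on ties). Inputs are
    clipped/rounded into [0, 255] before histogramming.
    """
    if isinstance(gray_values, np.ma.MaskedArray):
        vals = gray_values.compressed()
    else:
        vals = np.asarray(gray_values).ravel()
    if vals.size == 0:
        raise DelimitationError("no gray values to threshold")
    levels = np.clip(np.rint(vals), 0, 255).astype(np.int64)
    hist = np.bincount(levels, minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DelimitationError("need >= 2 distinct gray levels for Otsu threshold")
    n = hist.sum()
    lv = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * lv)
    total = m0[-1]
    w1 = n - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (total - m0) / w1
        var_between = w0 * w1 * (mean0 - mean1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(var_between[:255]))


def find_lesion_bounds(band: np.ndarray, col_offset: int = 0) -> LesionBounds:
    """Locate the lesion as the longest run of mostly-dark columns.

    The band is binarized at the Otsu threshold (lesion = at or below
    the threshold, pigmented lesions being darker than skin). Columns
    whose dark-pixel fraction exceeds 0.5 are lesion candidates; the
    longest contiguous run wins (first run on ties). ``col_offset``
    shifts the result into full-image coordinates.

    A constant band has no threshold: if it is dark (below mid-gray) the
    lesion fills the scan and the full span is returned, otherwise no
    lesion is present.
    """
    arr0 = np.ma.asarray(band)
    try:
        t = otsu_threshold(band)
    except DelimitationError:
        level = float(arr0.compressed()[0]) if arr0.count() else 255.0
        if level < 128.0:
            w = arr0.shape[1]
            return LesionBounds(col_offset, col_offset + w, frame="dermatoscopy")
        raise LesionNotFoundError("band is uniformly light: no lesion")
    arr = np.ma.asarray(band)
    dark = np.ma.filled(arr <= t, False)
    valid = ~np.ma.getmaskarray(arr)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_valid > 0, (dark & valid).sum(axis=0) / np.maximum(n_valid, 1), 0.0)
    is_lesion = frac > 0.5
    if not is_lesion.any():
        raise LesionNotFoundError("no column has dark fraction above 0.5")
    # enumerate runs of consecutive lesion columns
    padded = np.concatenate([[False], is_lesion, [False]])
    diffs = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = diffs[0::2], diffs[1::2]
    best = int(np.argmax(ends - starts))
    return LesionBounds(
        start_col=int(starts[best]) + col_offset,
        end_col=int(ends[best]) + col_offset,
        frame="dermatoscopy",
    )


def map_bounds_to_oct(
    bounds: LesionBounds, view: DermatoscopyView, bscan_width: int
) -> LesionBounds:
    """Co-register dermatoscopy bounds onto B-scan columns.

    Fractional position along the scan span maps affinely onto
    ``[0, bscan_width)``; rounding is half-up, results are clipped to the
    valid range and kept non-degenerate.
    """
    if bounds.frame != "dermatoscopy":
        raise DelimitationError("expected bounds in the dermatoscopy frame")
    s0, s1 = view.scan_span_cols
    if not (s0 <= bounds.start_col and bounds.end_col <= s1):
        raise DelimitationError(
            f"bounds [{bounds.start_col}, {bounds.end_col}) outside scan span [{s0}, {s1})"
        )
    span = s1 - s0

    def _map(col: int) -> int:
        frac = (col - s0) / span
        return int(np.floor(frac * bscan_width + 0.5))  # round half-up

    start = min(max(_map(bounds.start_col), 0), bscan_width - 1)
    end = min(max(_map(bounds.end_col), start + 1), bscan_width)
    return LesionBounds(start_col=start, end_col=end, frame="bscan")
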