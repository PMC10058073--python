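"""ROI extraction: lesion-centre and adjacent-healthy patches, surface
flattening, and depth truncation.

The lesion ROI is a 100-px-wide patch centred on the delimited lesion;
healthy ROIs flank it immediately on whichever sides have room. Each
patch is then "flattened": per A-scan the air gap and surface
overelevation are removed by shifting the column so the tissue entry
(the annotated surface row, refined to the entry peak when one is
present) sits at row 0. Finally the patch is truncated in depth — 150 px
(~0.4 mm) retains all informative signal for attenuation fitting, and
most structure sits above 75 px (~0.2 mm) for texture analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .delimitation import LesionBounds
from .errors import AnnotationError, RoiError

__all__ = [
    "BScan",
    "SurfaceAnnotation",
    "RoiPatch",
    "lesion_center_roi",
    "healthy_adjacent_roi",
    "flatten",
    "truncate_depth",
]


@dataclass
class BScan:
    """A calibrated OCT cross-section (rows = depth, columns = lateral).

    ``axial_pitch_um`` is the in-tissue axial pitch (µm/px) — the value
    used for every depth conversion downstream of the tissue surface.
    """

    intensity: np.ndarray
    axial_pitch_um: float
    lateral_pitch_um: float
    id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity)
        if arr.ndim != 2:
            raise RoiError(f"B-scan must be 2-D, got shape {arr.shape}")
        if arr.min() < 0 or arr.max() > 255:
            raise RoiError("B-scan values must lie in [0, 255]")
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise RoiError("pixel pitches must be positive")
        self.intensity = arr

    @property
    def depth_px(self) -> int:
        return self.intensity.shape[0]

    @property
    def width_px(self) -> int:
        return self.intensity.shape[1]


@dataclass
class SurfaceAnnotation:
    """Per-column row index where tissue starts (the rough surface line)."""

    surface_rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.surface_rows, dtype=int)
        if rows.ndim != 1:
            raise AnnotationError("surface_rows must be 1-D")
        if (rows < 0).any():
            raise AnnotationError("surface rows must be non-negative")
        self.surface_rows = rows

    def validate_against(self, bscan: BScan) -> None:
        if len(self.surface_rows) != bscan.width_px:
            raise AnnotationError(
                f"annotation length {len(self.surface_rows)} != B-scan width {bscan.width_px}"
            )
        if (self.surface_rows >= bscan.depth_px).any():
            raise AnnotationError("surface rows exceed B-scan depth")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"column_index": np.arange(len(self.surface_rows)), "surface_row": self.surface_rows}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurfaceAnnotation":
        df = pd.read_csv(path)
        df = df.sort_values("column_index")
        return cls(surface_rows=df["surface_row"].to_numpy())


@dataclass
class RoiPatch:
    """A depth x width sub-image of a B-scan.

    After :func:`flatten`, row 0 is the tissue entry in every column and
    rows vacated at the bottom are zero-filled (zeros are treated as
    padding by the attenuation fit).
    """

    pixels: np.ndarray
    origin_col: int
    label: str  # "lesion" | "healthy"
    flattened: bool = False
    depth_limit_px: Optional[int] = None
    clipped: bool = False
    annotation_rows: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.label not in ("lesion", "healthy"):
            raise RoiError(f"unknown ROI label {self.label!r}")
        self.pixels = np.asarray(self.pixels)

    @property
    def depth_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def lesion_center_roi(bscan: BScan, bounds: LesionBounds, half_width: int = 50) -> RoiPatch:
    """Patch of ``2 * half_width`` columns centred on the lesion midpoint.

    The centre is the floor midpoint of the bounds (left-biased for
    even-width lesions). Patches are clipped at image borders with a
    warning and the clipping recorded.
    """
    if bounds.frame != "bscan":
        raise RoiError("lesion bounds must be in the bscan frame")
    if bounds.width < 1:
        raise RoiError(f"degenerate lesion bounds: width {bounds.width}")
    centre = (bounds.start_col + bounds.end_col) // 2
    c0, c1 = centre - half_width, centre + half_width
    clipped = c0 < 0 or c1 > bscan.width_px
    if clipped:
        warnings.warn("lesion ROI clipped at B-scan border", stacklevel=2)
        c0, c1 = max(c0, 0), min(c1, bscan.width_px)
    return RoiPatch(
        pixels=bscan.intensity[:, c0:c1].copy(),
        origin_col=c0,
        label="lesion",
        clipped=clipped,
    )


def healthy_adjacent_roi(
    bscan: BScan, bounds: LesionBounds, width: int = 100, guard_px: int = 0
) -> List[RoiPatch]:
    """Healthy patches immediately flanking the lesion.

    Each side contributes a patch of ``width`` columns when it has room
    (after an optional guard gap); both are returned when both qualify
    and their A-scans are pooled downstream.
    """
    if bounds.frame != "bscan":
        raise RoiError("lesion bounds must be in the bscan frame")
    patches: List[RoiPatch] = []
    left_end = bounds.start_col - guard_px
    if left_end - width >= 0:
        c0 = left_end - width
        patches.append(
            RoiPatch(pixels=bscan.intensity[:, c0:left_end].copy(), origin_col=c0, label="healthy")
        )
    right_start = bounds.end_col + guard_px
    if right_start + width <= bscan.width_px:
        patches.append(
            RoiPatch(
                pixels=bscan.intensity[:, right_start : right_start + width].copy(),
                origin_col=right_start,
                label="healthy",
            )
        )
    if not patches:
        raise RoiError("no healthy tissue: neither side has enough columns outside the lesion")
    return patches


def flatten(
    patch: RoiPatch,
    annotation: SurfaceAnnotation,
    search_px: int = 15,
    peak_factor: float = 2.0,
) -> RoiPatch:
    """Shift each column so the tissue entry sits at row 0.

    The entry defaults to the annotated surface row. If within
    ``[annotated, annotated + search_px)`` the column has a local maximum
    exceeding ``peak_factor`` times the column median — the bright peak
    where the beam first hits skin — that peak row becomes the entry
    instead. The first (shallowest) qualifying peak is taken: the entry
    peak sits at the very start of the signal, and deeper speckle
    maxima must not outrank it. Rows vacated at the bottom are
    zero-filled.
    """
    h, w = patch.pixels.shape
    rows = annotation.surface_rows
    if patch.origin_col < 0 or patch.origin_col + w > len(rows):
        raise AnnotationError(
            f"annotation does not cover patch columns "
            f"[{patch.origin_col}, {patch.origin_col + w})"
        )
    ann = rows[patch.origin_col : patch.origin_col + w]
    if (ann >= h).any():
        raise AnnotationError("annotated surface row beyond patch depth")
    out = np.zeros_like(patch.pixels)
    entry_rows = np.empty(w, dtype=int)
    for j in range(w):
        col = patch.pixels[:, j].astype(float)
        a = int(ann[j])
        start = a
        med = np.median(col)
        hi = min(a + search_px, h)
        for r in range(a, hi):
            up = col[r - 1] if r > 0 else -np.inf
            down = col[r + 1] if r < h - 1 else -np.inf
            if col[r] >= up and col[r] >= down and col[r] > peak_factor * med:
                start = r
                break
        entry_rows[j] = start
        out[: h - start, j] = patch.pixels[start:, j]
    return RoiPatch(
        pixels=out,
        origin_col=patch.origin_col,
        label=patch.label,
        flattened=True,
        clipped=patch.clipped,
        annotation_rows=entry_rows,
    )


def truncate_depth(patch: RoiPatch, limit: int) -> RoiPatch:
    """Keep rows [0, limit) of a flattened patch."""
    if limit <= 0:
        raise RoiError(f"depth limit must be positive, got {limit}")
    if limit > patch.depth_px:
        raise RoiError(f"depth limit {limit} exceeds patch depth {patch.depth_px}")
    return RoiPatch(
        pixels=patch.pixels[:limit].copy(),
        origin_col=patch.origin_col,
        label=patch.label,
        flattened=patch.flattened,
        depth_limit_px=limit,
        clipped=patch.clipped,
        annotation_rows=patch.annotation_rows,
    )
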