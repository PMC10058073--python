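"""Depth-sectioned GLCM texture features.

The flattened, 75-px-deep ROI is split into three depth sections
(0-25, 25-50, 50-75 px; roughly stratum corneum / epidermis / upper
dermis after flattening) and each section is tiled with non-overlapping
boxes. Per box a gray-level co-occurrence matrix (GLCM) is computed at
pixel offset d for the four axis directions, five Haralick-style
features are derived and averaged over directions, and each section is
summarized by the median and IQR of its boxes. Gray levels are
uniformly requantized (default 64) before counting, since a 25 x 25 box
cannot meaningfully populate a 256 x 256 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import TextureError
from .roi import RoiPatch

__all__ = [
    "GlcmConfig",
    "GlcmFeatures",
    "TextureSummary",
    "glcm",
    "glcm_features",
    "sectioned_features",
]

FEATURES = ("contrast", "dissimilarity", "homogeneity", "energy", "correlation")

# (row, col) unit offsets: 0 deg -> right, 90 -> up, 180 -> left, 270 -> down
_OFFSETS: Dict[int, Tuple[int, int]] = {0: (0, 1), 90: (-1, 0), 180: (0, -1), 270: (1, 0)}


@dataclass(frozen=True)
class GlcmConfig:
    """Texture-analysis parameters.

    ``distance_d`` is the pixel offset between co-occurring pairs (2 or
    5); ``box_px`` the tile side; ``sections`` the half-open depth row
    intervals of the flattened ROI. ``symmetric`` additionally counts
    each pair in the reversed order (equivalent to averaging opposite
    angles, which the default four-angle list already does).
    """

    distance_d: int = 2
    angles: Tuple[int, ...] = (0, 90, 180, 270)
    levels: int = 64
    box_px: int = 25
    sections: Tuple[Tuple[int, int], ...] = ((0, 25), (25, 50), (50, 75))
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.distance_d < 1:
            raise TextureError("distance_d must be >= 1")
        if self.distance_d >= self.box_px:
            raise TextureError("distance_d must be smaller than box_px")
        if not 2 <= self.levels <= 256:
            raise TextureError("levels must be in [2, 256]")
        for angle in self.angles:
            if angle % 360 not in _OFFSETS:
                raise TextureError(f"unsupported angle {angle}")
        for r0, r1 in self.sections:
            if not 0 <= r0 < r1:
                raise TextureError(f"invalid section ({r0}, {r1})")


@dataclass(frozen=True)
class GlcmFeatures:
    contrast: float
    dissimilarity: float
    homogeneity: float
    energy: float
    correlation: float
    correlation_defined: bool = True

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in FEATURES}


@dataclass
class TextureSummary:
    """Per-box feature table and per-section median/IQR summary."""

    per_box: pd.DataFrame  # section, box_row, box_col + five features
    summary: pd.DataFrame  # section, feature, median, iqr, n_boxes
    label: str
    config: GlcmConfig = field(default_factory=GlcmConfig)

    def section_median(self, section: int, feature: str) -> float:
        rows = self.summary[
            (self.summary["section"] == section) & (self.summary["feature"] == feature)
        ]
        return float(rows["median"].iloc[0])


def quantize_levels(box: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly map 8-bit gray values in [0, 255] onto [0, levels)."""
    arr = np.asarray(box, dtype=float)
    q = np.floor(arr * levels / 256.0).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(box: np.ndarray, d: int = 2, angle: int = 0, levels: int = 64) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix of one box.

    Counts ordered pairs (p, q) where q sits at the (row, col) offset of
    ``d`` steps along ``angle`` from p, after uniform quantization into
    ``levels`` gray levels; the matrix is normalized to sum 1. P[i, j]
    is the joint frequency of source level i and target level j.
    """
    arr = np.asarray(box)
    if arr.ndim != 2:
        raise TextureError("box must be 2-D")
    if angle % 360 not in _OFFSETS:
        raise TextureError(f"unsupported angle {angle}")
    dr, dc = _OFFSETS[angle % 360]
    dr, dc = dr * d, dc * d
    h, w = arr.shape
    if h <= abs(dr) or w <= abs(dc):
        raise TextureError(f"box {arr.shape} too small for offset ({dr}, {dc})")
    q = quantize_levels(arr, levels)
    src = q[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
    dst = q[max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)]
    counts = np.bincount(
        (src * levels + dst).ravel(), minlength=levels * levels
    ).reshape(levels, levels)
    return counts / counts.sum()


def glcm_features(P: np.ndarray) -> GlcmFeatures:
    """Contrast, dissimilarity, homogeneity, energy, and correlation of
    a normalized GLCM.

    Energy is the square root of the angular second moment. Correlation
    of a zero-variance matrix is reported as 1 (perfectly predictable)
    with ``correlation_defined=False``.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise TextureError("P must be a square matrix")
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise TextureError("P must be normalized to sum 1")
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    diff = i - j
    contrast = float((P * diff**2).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    energy = float(np.sqrt((P**2).sum()))
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    denom = np.sqrt(var_i * var_j)
    if denom < 1e-12:
        correlation, defined = 1.0, False
    else:
        correlation = float((P * (i - mu_i) * (j - mu_j)).sum() / denom)
        defined = True
    return GlcmFeatures(
        contrast=contrast,
        dissimilarity=dissimilarity,
        homogeneity=homogeneity,
        energy=energy,
        correlation=correlation,
        correlation_defined=defined,
    )


def box_features(box: np.ndarray, cfg: GlcmConfig) -> Dict[str, float]:
    """Five features of one box, averaged over the configured angles."""
    acc = {name: 0.0 for name in FEATURES}
    for angle in cfg.angles:
        P = glcm(box, d=cfg.distance_d, angle=angle, levels=cfg.levels)
        if cfg.symmetric:
            P = (P + P.T) / 2.0
        feats = glcm_features(P).as_dict()
        for name in FEATURES:
            acc[name] += feats[name]
    return {name: v / len(cfg.angles) for name, v in acc.items()}


def sectioned_features(patch: RoiPatch, cfg: GlcmConfig = GlcmConfig()) -> TextureSummary:
    """Tile each depth section with boxes and summarize feature medians.

    Boxes are non-overlapping, anchored at each section's top-left;
    partial boxes at the right or bottom edge are discarded. A section
    that yields no complete box is an error.
    """
    if not patch.flattened:
        raise TextureError("patch must be flattened before texture analysis")
    max_row = max(r1 for _, r1 in cfg.sections)
    if patch.depth_px < max_row:
        raise TextureError(
            f"patch depth {patch.depth_px} shallower than deepest section row {max_row}"
        )
    records = []
    for s_idx, (r0, r1) in enumerate(cfg.sections):
        sect = patch.pixels[r0:r1]
        n_down = (r1 - r0) // cfg.box_px
        n_across = patch.width_px // cfg.box_px
        if n_down * n_across == 0:
            raise TextureError(
                f"section {s_idx} ({r0}-{r1} px) yields no complete {cfg.box_px}px box"
            )
        for bi in range(n_down):
            for bj in range(n_across):
                box = sect[
                    bi * cfg.box_px : (bi + 1) * cfg.box_px,
                    bj * cfg.box_px : (bj + 1) * cfg.box_px,
                ]
                rec = {"section": s_idx, "box_row": bi, "box_col": bj}
                rec.update(box_features(box, cfg))
                records.append(rec)
    per_box = pd.DataFrame.from_records(records)
    rows = []
    for s_idx in range(len(cfg.sections)):
        sub = per_box[per_box["section"] == s_idx]
        for name in FEATURES:
            q1, med, q3 = np.percentile(sub[name], [25, 50, 75])
            rows.append(
                {
                    "section": s_idx,
                    "feature": name,
                    "median": float(med),
                    "iqr": float(q3 - q1),
                    "n_boxes": len(sub),
                }
            )
    return TextureSummary(
        per_box=per_box, summary=pd.DataFrame(rows), label=patch.label, config=cfg
    )
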