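"""Layered-skin phantom generator.

Patient OCT data for pigmented lesions is ethics-restricted, so the
pipeline is exercised on a synthetic phantom with the statistical
structure the analysis assumes: an air gap over an uneven tissue
surface (with a smooth overelevation bump above the lesion), a bright
entry peak at the surface followed by single-scattering Beer-Lambert
decay per A-scan, region-dependent total attenuation (lesion columns
attenuate more strongly than healthy skin), multiplicative unit-mean
speckle, and 8-bit quantization. A paired dermatoscopy image shows the
lesion as a dark blob crossed by the white scan-line marker, so the
delimitation stage can be tested end to end against ground truth.

All randomness flows from a single integer seed; the same config
produces bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .calibration import DeviceSpec, axial_pitch, lateral_pitch
from .delimitation import DermatoscopyView
from .errors import ConfigError
from .roi import BScan, SurfaceAnnotation

__all__ = ["PhantomConfig", "PhantomTruth", "beer_lambert_profile", "make_phantom"]


def beer_lambert_profile(A: float, mu_t: float, C: float, depths_mm: np.ndarray) -> np.ndarray:
    """Round-trip Beer-Lambert intensity profile ``A * exp(-2 mu_t z) + C``.

    ``mu_t`` is the single-pass total attenuation coefficient in 1/mm;
    the factor 2 accounts for the double path of backscattered light.
    """
    z = np.asarray(depths_mm, dtype=float)
    if mu_t < 0:
        raise ConfigError(f"mu_t must be >= 0, got {mu_t}")
    if z.size and (z < 0).any():
        raise ConfigError("depths must be non-negative")
    if z.size > 1 and (np.diff(z) <= 0).any():
        raise ConfigError("depths must be strictly increasing")
    return A * np.exp(-2.0 * mu_t * z) + C


@dataclass
class PhantomConfig:
    """Parameters of one synthetic lesion acquisition.

    Attenuation defaults sit in the ranges reported for pigmented skin
    at 1300 nm: healthy dermis ~0.6-1.0 /mm, lesions ~0.8-2.9 /mm.
    ``speckle_shape`` is the Gamma shape k of the multiplicative speckle
    (unit mean, variance 1/k); ``None`` disables speckle. The optional
    per-region ``lesion_speckle_shape`` makes lesion texture rougher or
    smoother than healthy tissue, and ``grain_px`` > 1 renders speckle
    in square cells for a coarser texture at fixed variance.
    """

    spec: DeviceSpec = field(default_factory=DeviceSpec)
    healthy_mu_t: float = 0.8
    lesion_mu_t: float = 2.0
    lesion_cols: Tuple[int, int] = (150, 300)
    entry_amplitude: float = 180.0
    noise_floor: float = 4.0
    surface_base_row: int = 40
    surface_wave_px: float = 5.0
    lesion_bump_px: float = 12.0
    surface_profile: Optional[np.ndarray] = None  # overrides the analytic profile
    speckle_shape: Optional[float] = 20.0
    lesion_speckle_shape: Optional[float] = None  # defaults to speckle_shape
    grain_px: int = 1
    quantize_8bit: bool = True
    seed: int = 0
    # dermatoscopy geometry
    derm_shape: Tuple[int, int] = (400, 850)
    derm_scanline_row: int = 200
    derm_scan_span: Tuple[int, int] = (25, 825)
    derm_line_halfwidth: int = 1

    def __post_init__(self) -> None:
        if self.healthy_mu_t <= 0:
            raise ConfigError("healthy_mu_t must be > 0")
        if self.lesion_mu_t < 0:
            raise ConfigError("lesion_mu_t must be >= 0")
        w = self.spec.n_lateral_px
        l0, l1 = self.lesion_cols
        if not (0 <= l0 < l1 <= w):
            raise ConfigError(f"lesion_cols {self.lesion_cols} outside image width {w}")
        for k in (self.speckle_shape, self.lesion_speckle_shape):
            if k is not None and k <= 0:
                raise ConfigError("speckle shape must be positive")
        if self.grain_px < 1:
            raise ConfigError("grain_px must be >= 1")


@dataclass
class PhantomTruth:
    """Generator ground truth for scoring the pipeline."""

    mu_t_map: np.ndarray  # per-column single-pass mu_t, 1/mm
    surface_rows: np.ndarray  # per-column tissue-start row
    lesion_cols: Tuple[int, int]
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "mu_t_map": np.asarray(self.mu_t_map).tolist(),
            "surface_rows": np.asarray(self.surface_rows).astype(int).tolist(),
            "lesion_cols": list(self.lesion_cols),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PhantomTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mu_t_map=np.asarray(payload["mu_t_map"], dtype=float),
            surface_rows=np.asarray(payload["surface_rows"], dtype=int),
            lesion_cols=tuple(payload["lesion_cols"]),
            seed=int(payload["seed"]),
        )


def _surface_profile(config: PhantomConfig) -> np.ndarray:
    """Smooth surface row per column: slow wave plus an overelevation
    bump (raised cosine) over the lesion, which lifts the surface."""
    if config.surface_profile is not None:
        rows = np.asarray(config.surface_profile, dtype=float)
        if rows.shape != (config.spec.n_lateral_px,):
            raise ConfigError("surface_profile length must equal n_lateral_px")
    else:
        w = config.spec.n_lateral_px
        c = np.arange(w)
        rows = config.surface_base_row + config.surface_wave_px * np.sin(
            2 * np.pi * 1.5 * c / w
        )
        l0, l1 = config.lesion_cols
        in_lesion = (c >= l0) & (c < l1)
        phase = (c[in_lesion] - l0) / max(l1 - l0, 1)
        rows[in_lesion] -= config.lesion_bump_px * 0.5 * (1 - np.cos(2 * np.pi * phase))
    rows = np.clip(np.rint(rows), 1, config.spec.n_axial_px - 2).astype(int)
    return rows


def _speckle_field(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative Gamma speckle, per-region shape, optional
    blocky grain."""
    h, w = config.spec.n_axial_px, config.spec.n_lateral_px
    if config.speckle_shape is None and config.lesion_speckle_shape is None:
        return np.ones((h, w))
    k_healthy = config.speckle_shape
    k_lesion = config.lesion_speckle_shape if config.lesion_speckle_shape is not None else k_healthy
    g = config.grain_px
    hc, wc = -(-h // g), -(-w // g)
    k_map = np.full(wc, np.inf)
    cols = np.arange(wc) * g  # coarse cell -> representative column
    l0, l1 = config.lesion_cols
    in_lesion = (cols >= l0) & (cols < l1)
    if k_healthy is not None:
        k_map[~in_lesion] = k_healthy
    if k_lesion is not None:
        k_map[in_lesion] = k_lesion
    k2d = np.broadcast_to(k_map, (hc, wc))
    finite = np.isfinite(k2d)
    field_c = np.ones((hc, wc))
    if finite.any():
        kvals = k2d[finite]
        field_c[finite] = rng.gamma(shape=kvals, scale=1.0 / kvals)
    return np.repeat(np.repeat(field_c, g, axis=0), g, axis=1)[:h, :w]


def _render_bscan(config: PhantomConfig, surface: np.ndarray, mu_map: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    h, w = config.spec.n_axial_px, config.spec.n_lateral_px
    pitch_mm = axial_pitch(config.spec, in_tissue=True) / 1000.0
    rows = np.arange(h)[:, None]
    depth_px = rows - surface[None, :]
    in_tissue = depth_px >= 0
    z = np.where(in_tissue, depth_px, 0) * pitch_mm
    signal = config.entry_amplitude * np.exp(-2.0 * mu_map[None, :] * z)
    speckle = _speckle_field(config, rng)
    air = rng.uniform(0.0, 2.0, size=(h, w))
    img = np.where(in_tissue, signal * speckle + config.noise_floor, air)
    if config.quantize_8bit:
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return np.clip(img, 0, 255)


def _render_dermatoscopy(config: PhantomConfig, rng: np.random.Generator) -> DermatoscopyView:
    """Skin-toned RGB image with a dark lesion blob at the scan line's
    fractional lesion position and the white scan-line marker."""
    hd, wd = config.derm_shape
    skin = np.array([205.0, 170.0, 145.0])
    lesion = np.array([70.0, 50.0, 45.0])
    img = np.empty((hd, wd, 3))
    img[:] = skin
    s0, s1 = config.derm_scan_span
    span = s1 - s0
    wb = config.spec.n_lateral_px
    l0, l1 = config.lesion_cols
    d0 = s0 + l0 / wb * span
    d1 = s0 + l1 / wb * span
    cx, a = (d0 + d1) / 2.0, (d1 - d0) / 2.0
    cy, b = float(config.derm_scanline_row), 80.0
    yy, xx = np.mgrid[0:hd, 0:wd]
    # superellipse exponent 4: near-vertical blob edges across the band
    inside = ((xx - cx) / a) ** 4 + ((yy - cy) / b) ** 4 <= 1.0
    img[inside] = lesion
    img += rng.normal(0.0, 5.0, size=img.shape)
    r0 = config.derm_scanline_row - config.derm_line_halfwidth
    r1 = config.derm_scanline_row + config.derm_line_halfwidth
    img[r0 : r1 + 1, s0:s1, :] = 255.0
    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return DermatoscopyView(
        rgb_image=rgb,
        scanline_row=config.derm_scanline_row,
        scan_span_cols=config.derm_scan_span,
    )


def make_phantom(
    config: PhantomConfig,
) -> Tuple[BScan, DermatoscopyView, SurfaceAnnotation, PhantomTruth]:
    """Generate one paired (B-scan, dermatoscopy, annotation, truth) case."""
    rng = np.random.default_rng(config.seed)
    surface = _surface_profile(config)
    w = config.spec.n_lateral_px
    mu_map = np.full(w, config.healthy_mu_t)
    l0, l1 = config.lesion_cols
    mu_map[l0:l1] = config.lesion_mu_t
    intensity = _render_bscan(config, surface, mu_map, rng)
    derm = _render_dermatoscopy(config, rng)
    bscan = BScan(
        intensity=intensity,
        axial_pitch_um=axial_pitch(config.spec, in_tissue=True),
        lateral_pitch_um=lateral_pitch(config.spec),
        id=f"phantom-seed{config.seed}",
    )
    annotation = SurfaceAnnotation(surface_rows=surface.copy())
    truth = PhantomTruth(
        mu_t_map=mu_map,
        surface_rows=surface,
        lesion_cols=(l0, l1),
        seed=config.seed,
    )
    return bscan, derm, annotation, truth


def noiseless(config: PhantomConfig) -> PhantomConfig:
    """Copy of a config with speckle and quantization disabled, so the
    generated columns lie exactly in the Beer-Lambert model class."""
    return replace(
        config, speckle_shape=None, lesion_speckle_shape=None, quantize_8bit=False
    )
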