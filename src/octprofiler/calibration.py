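"""Device geometry and pixel-to-physical conversions.

A time-domain dermatological OCT scanner images up to ``depth_range_mm``
of tissue onto ``n_axial_px`` rows; the lateral field of view (FOV) is
selectable, with the pixel count scaling so the lateral pitch stays
constant. Axial optical path length shortens inside tissue by the
refractive index, so the axial pitch has an in-air and an in-tissue
value; all depth conversions downstream use the in-tissue pitch.

Pitches are carried unrounded; rounding happens only when values are
printed in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import InvalidSpecError

__all__ = ["DeviceSpec", "axial_pitch", "lateral_pitch", "px_to_physical", "device_from_config"]


@dataclass(frozen=True)
class DeviceSpec:
    """Geometry of the OCT scanner.

    Parameters
    ----------
    depth_range_mm:
        Maximum imaging depth in air, mm.
    n_axial_px:
        Number of pixels along depth (rows of a B-scan).
    fov_mm:
        Lateral field of view, mm (selectable 3-12 mm on the device).
    n_lateral_px:
        Number of A-scans (columns of a B-scan), 425-1700 matching FOV.
    refractive_index:
        Bulk tissue refractive index; 1.4 is the standard value for
        human skin at 1300 nm.
    wavelength_nm:
        Centre wavelength, informational only.
    """

    depth_range_mm: float = 1.9
    n_axial_px: int = 512
    fov_mm: float = 3.0
    n_lateral_px: int = 425
    refractive_index: float = 1.4
    wavelength_nm: float = 1300.0

    def __post_init__(self) -> None:
        if self.depth_range_mm <= 0:
            raise InvalidSpecError(f"depth_range_mm must be > 0, got {self.depth_range_mm}")
        if self.n_axial_px < 2:
            raise InvalidSpecError(f"n_axial_px must be >= 2, got {self.n_axial_px}")
        if self.refractive_index < 1:
            raise InvalidSpecError(f"refractive_index must be >= 1, got {self.refractive_index}")
        if self.fov_mm <= 0:
            raise InvalidSpecError(f"fov_mm must be > 0, got {self.fov_mm}")
        if self.n_lateral_px <= 0:
            raise InvalidSpecError(f"n_lateral_px must be > 0, got {self.n_lateral_px}")


def axial_pitch(spec: DeviceSpec, in_tissue: bool = False) -> float:
    """Axial pixel pitch in µm/pixel.

    In air this is ``depth_range_mm * 1000 / n_axial_px`` (3.71 µm/px for
    1.9 mm over 512 px). Inside tissue the optical path is compressed by
    the refractive index, giving 2.65 µm/px at n = 1.4.
    """
    pitch = spec.depth_range_mm * 1000.0 / spec.n_axial_px
    if in_tissue:
        pitch /= spec.refractive_index
    return pitch


def lateral_pitch(spec: DeviceSpec) -> float:
    """Lateral pixel pitch in µm/pixel (constant ~7.06 across the FOV range)."""
    return spec.fov_mm * 1000.0 / spec.n_lateral_px


def px_to_physical(count: float, pitch_um: float) -> float:
    """Convert a pixel count to a physical length in mm given a pitch in µm/px."""
    if count < 0:
        raise InvalidSpecError(f"pixel count must be >= 0, got {count}")
    return count * pitch_um / 1000.0


def device_from_config(config: Mapping) -> DeviceSpec:
    """Build a :class:`DeviceSpec` from a config mapping.

    Accepts either the full config (with a ``device:`` block) or the
    block itself; unspecified fields take the defaults.
    """
    block = config.get("device", config) if isinstance(config, Mapping) else config
    allowed = {f for f in DeviceSpec.__dataclass_fields__}
    unknown = set(block) - allowed
    if unknown:
        raise InvalidSpecError(f"unknown device fields: {sorted(unknown)}")
    return DeviceSpec(**dict(block))
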