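"""Per-A-scan attenuation estimation.

Under a single-scattering model the backscattered OCT intensity decays
as I(z) = A exp(-2 mu_t z) + C, where mu_t (1/mm) is the single-pass
total attenuation coefficient (absorption + scattering), the factor 2
accounts for the round trip of detected light, and C is the noise
floor. Each column of a flattened ROI is fitted by bounded nonlinear
least squares; a region is summarized by the median and interquartile
range of the converged per-column estimates. A and C are in arbitrary
display units and are not interpreted; only mu_t carries physical
meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, QualityError
from .roi import RoiPatch

__all__ = ["AScanFit", "AttenuationSummary", "fit_ascan", "roi_attenuation", "median_difference"]

#: beyond this depth (px) the signal carries no tissue information
FIT_DEPTH_CAP_PX = 150

#: the offset C is the dark noise floor of an 8-bit display image; it is
#: bounded to this fraction of the profile peak (see fit_ascan notes)
C_REL_CAP = 0.04

_MIN_SAMPLES = 10


@dataclass(frozen=True)
class AScanFit:
    """Beer-Lambert parameters of one A-scan."""

    amplitude_A: float
    mu_t: float  # single-pass, 1/mm
    offset_C: float
    rss: float
    converged: bool
    n_samples: int = 0


@dataclass(frozen=True)
class AttenuationSummary:
    """Median/IQR of converged per-column mu_t values in one region."""

    median_mu_t: float
    q1: float
    q3: float
    iqr: float
    n_ascans: int
    label: str
    excluded: int = 0


def _model(z, A, mu, C):
    return A * np.exp(-2.0 * mu * z) + C


def _initial_guess(y: np.ndarray, z: np.ndarray, c0: float):
    a0 = max(y[0] - c0, 1e-6)
    resid = np.maximum(y - c0, 1e-9)
    slope = np.polyfit(z, np.log(resid), 1)[0]
    mu0 = max(-slope / 2.0, 0.0)
    return a0, mu0, max(c0, 0.0)


def fit_ascan(
    profile: Sequence[float],
    axial_pitch_tissue_um: float,
    depth_cap_px: int = FIT_DEPTH_CAP_PX,
    c_rel_cap: float = C_REL_CAP,
) -> AScanFit:
    """Fit I(z) = A exp(-2 mu_t z) + C to one depth profile.

    The depth grid is z_k = k * pitch (mm) with k = 0 at the entry peak.
    Trailing zeros (flattening padding) are excluded and the window is
    capped at ``depth_cap_px`` rows. Initialization: C0 from the tail
    mean (clamped into the C box), A0 = I_0 - C0, mu_t0 from the
    log-linear slope of the offset-corrected profile; a second start at
    C0 ~ 0 is tried and the lower-residual solution kept.

    All three parameters are box-constrained non-negative (intensities
    sit on a non-negative display scale). The offset is additionally
    capped at ``c_rel_cap`` times the profile peak: C is the dark noise
    floor of the image, an order of magnitude below the entry peak. The
    cap matters because the fit window retains a large fraction of the
    signal for shallow decays (mu_t below ~1.25/mm over ~0.4 mm), where
    an unconstrained C is nearly unidentifiable from the late signal and
    least squares acquires a spurious basin in which C absorbs the
    profile tail and mu_t inflates. The cap is scale-free, so fits are
    equivariant under rescaling the profile. Profiles with a genuinely
    brighter floor need a larger ``c_rel_cap``.
    """
    y_full = np.asarray(profile, dtype=float)
    if y_full.ndim != 1:
        raise FitError("profile must be 1-D")
    nz = np.flatnonzero(y_full)
    n = min(len(y_full), depth_cap_px, (int(nz[-1]) + 1) if nz.size else 0)
    if n < _MIN_SAMPLES:
        raise FitError(f"profile too short: {n} usable samples (< {_MIN_SAMPLES})")
    y = y_full[:n]
    z = np.arange(n) * axial_pitch_tissue_um / 1000.0
    if np.ptp(y) == 0:
        return AScanFit(
            amplitude_A=0.0, mu_t=0.0, offset_C=float(y[0]), rss=0.0, converged=True, n_samples=n
        )
    c_max = max(c_rel_cap * float(np.max(y)), 1e-9)
    tail = float(np.mean(y[-min(10, n) :]))
    starts = [min(tail, 0.5 * c_max), 0.0]
    best = None
    for c_start in starts:
        try:
            a0, mu0, c0 = _initial_guess(y, z, c_start)
            p0 = (a0, mu0, min(c0, c_max * (1 - 1e-9)))
            popt, _ = curve_fit(
                _model,
                z,
                y,
                p0=p0,
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, c_max]),
                maxfev=2000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _model(z, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return AScanFit(
            amplitude_A=np.nan, mu_t=np.nan, offset_C=np.nan, rss=np.inf,
            converged=False, n_samples=n,
        )
    (a, mu, c), rss = best
    return AScanFit(
        amplitude_A=float(a), mu_t=float(mu), offset_C=float(c), rss=rss,
        converged=True, n_samples=n,
    )


def fit_patch(patch: RoiPatch, axial_pitch_tissue_um: float) -> List[AScanFit]:
    """Fit every column of a flattened patch; unusable columns are
    returned as non-converged fits rather than raising."""
    fits: List[AScanFit] = []
    for j in range(patch.width_px):
        try:
            fits.append(fit_ascan(patch.pixels[:, j], axial_pitch_tissue_um))
        except FitError:
            fits.append(
                AScanFit(amplitude_A=np.nan, mu_t=np.nan, offset_C=np.nan,
                         rss=np.inf, converged=False)
            )
    return fits


def roi_attenuation(
    patches: Union[RoiPatch, Iterable[RoiPatch]],
    axial_pitch_tissue_um: float,
) -> AttenuationSummary:
    """Median/quartile summary of per-column mu_t over one region.

    Accepts a single flattened, depth-truncated patch or several (the
    two healthy flanks), in which case all A-scans are pooled into one
    summary. Non-converged fits are dropped and counted; fewer than half
    converging is a quality failure.
    """
    if isinstance(patches, RoiPatch):
        patches = [patches]
    patches = list(patches)
    if not patches:
        raise QualityError("no patches to summarize")
    labels = {p.label for p in patches}
    if len(labels) != 1:
        raise QualityError(f"cannot pool patches with mixed labels {labels}")
    fits: List[AScanFit] = []
    for p in patches:
        fits.extend(fit_patch(p, axial_pitch_tissue_um))
    mu = np.array([f.mu_t for f in fits if f.converged])
    excluded = len(fits) - len(mu)
    if len(mu) < 0.5 * len(fits) or len(mu) == 0:
        raise QualityError(
            f"only {len(mu)}/{len(fits)} A-scan fits converged"
        )
    q1, med, q3 = np.percentile(mu, [25, 50, 75])  # linear interpolation
    return AttenuationSummary(
        median_mu_t=float(med), q1=float(q1), q3=float(q3), iqr=float(q3 - q1),
        n_ascans=len(mu), label=labels.pop(), excluded=excluded,
    )


def median_difference(lesion: AttenuationSummary, healthy: AttenuationSummary) -> float:
    """Lesion-minus-healthy median attenuation, reported to 2 decimals (1/mm)."""
    if lesion.n_ascans == 0 or healthy.n_ascans == 0:
        raise QualityError("summaries must be nonempty")
    return round(lesion.median_mu_t - healthy.median_mu_t, 2)
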