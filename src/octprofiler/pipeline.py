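"""End-to-end case orchestration.

``run_case`` chains the full analysis — phantom generation (or image
loading), lesion delimitation on the dermatoscopy band, co-registration
onto the B-scan, lesion-centre and adjacent-healthy ROI extraction,
surface flattening, attenuation fitting over 150 px of depth, and
sectioned texture features over 75 px — and returns a ``CaseResult``
mirroring a lesion-vs-healthy comparison row. ``compare_cases`` stacks
several results into one table.

Every stage failure is re-raised as a ``StageError`` naming the stage;
all outputs are deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import device_from_config
from .delimitation import (
    DermatoscopyView,
    LesionBounds,
    extract_scanline_band,
    find_lesion_bounds,
    map_bounds_to_oct,
)
from .errors import ConfigError, OctProfilerError, StageError
from .io import load_case, write_case
from .optics import (
    AttenuationSummary,
    fit_patch,
    median_difference,
    roi_attenuation,
)
from .phantom import PhantomConfig, PhantomTruth, make_phantom
from .roi import BScan, RoiPatch, SurfaceAnnotation, flatten, healthy_adjacent_roi, lesion_center_roi, truncate_depth
from .texture import FEATURES, GlcmConfig, TextureSummary, sectioned_features

__all__ = ["CaseResult", "run_case", "compare_cases"]

OPTICS_DEPTH_PX = 150
TEXTURE_DEPTH_PX = 75


@dataclass
class CaseResult:
    """All per-case outputs plus provenance."""

    case_id: str
    diagnosis_label: str
    lesion_attenuation: AttenuationSummary
    healthy_attenuation: AttenuationSummary
    lesion_texture: TextureSummary
    healthy_texture: TextureSummary
    median_difference: float
    bounds_bscan: LesionBounds
    truth: Optional[PhantomTruth] = None
    provenance: Dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> Dict:
        def _summary(s: AttenuationSummary) -> Dict:
            return dataclasses.asdict(s)

        return {
            "case_id": self.case_id,
            "diagnosis": self.diagnosis_label,
            "lesion_attenuation": _summary(self.lesion_attenuation),
            "healthy_attenuation": _summary(self.healthy_attenuation),
            "median_difference": self.median_difference,
            "bounds_bscan": [self.bounds_bscan.start_col, self.bounds_bscan.end_col],
            "lesion_texture": self.lesion_texture.summary.to_dict(orient="records"),
            "healthy_texture": self.healthy_texture.summary.to_dict(orient="records"),
            "provenance": self.provenance,
        }


@contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - tag and re-raise
        raise StageError(name, exc) from exc


def _load_config(config: Union[str, Path, Mapping]) -> Dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config file {config} did not parse to a mapping")
        return dict(loaded)
    return dict(config)


def _phantom_from_config(cfg: Dict, seed: Optional[int]) -> PhantomConfig:
    block = dict(cfg.get("phantom", {}))
    if "lesion_cols" in block:
        block["lesion_cols"] = tuple(block["lesion_cols"])
    if seed is not None:
        block["seed"] = seed
    spec = device_from_config(cfg) if "device" in cfg else None
    if spec is not None:
        block["spec"] = spec
    return PhantomConfig(**block)


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _pool_healthy(patches: Sequence[RoiPatch]) -> RoiPatch:
    """Concatenate healthy flank patches laterally so texture boxes and
    A-scan pools cover both sides."""
    if len(patches) == 1:
        return patches[0]
    pixels = np.concatenate([p.pixels for p in patches], axis=1)
    return RoiPatch(
        pixels=pixels,
        origin_col=patches[0].origin_col,
        label="healthy",
        flattened=all(p.flattened for p in patches),
        depth_limit_px=patches[0].depth_limit_px,
    )


def run_case(
    config: Union[str, Path, Mapping],
    out_dir: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> CaseResult:
    """Execute the full pipeline for one case config.

    The config carries either a ``phantom:`` block (synthetic case,
    generated on the fly) or an ``images:`` block pointing at a case
    directory on disk; optional ``device:``, ``analysis:``, and
    ``glcm:`` blocks override geometry and analysis defaults. ``seed``
    overrides the phantom seed. When ``out_dir`` is given, result
    tables, a JSON summary, and a stage log are written there.
    """
    cfg = _load_config(config)
    case_id = str(cfg.get("case_id", "case"))
    diagnosis = str(cfg.get("diagnosis", "NA"))
    analysis = dict(cfg.get("analysis", {}))
    margin = int(analysis.get("scanline_margin_px", 10))
    half_width = int(analysis.get("lesion_half_width_px", 50))
    healthy_width = int(analysis.get("healthy_width_px", 100))
    guard_px = int(analysis.get("healthy_guard_px", 0))
    optics_depth = int(analysis.get("optics_depth_px", OPTICS_DEPTH_PX))
    texture_depth = int(analysis.get("texture_depth_px", TEXTURE_DEPTH_PX))
    glcm_cfg = GlcmConfig(**cfg.get("glcm", {}))

    log: List[str] = []
    truth: Optional[PhantomTruth] = None

    with _stage("inputs"):
        if "phantom" in cfg:
            pconf = _phantom_from_config(cfg, seed)
            bscan, derm, annotation, truth = make_phantom(pconf)
            log.append(f"stage=inputs mode=phantom seed={pconf.seed}")
        elif "images" in cfg:
            bscan, derm, annotation, truth = load_case(cfg["images"])
            log.append(f"stage=inputs mode=images dir={cfg['images']}")
        else:
            raise ConfigError("config needs a 'phantom' or 'images' block")
        annotation.validate_against(bscan)
        log.append(
            f"stage=inputs bscan_sha={_sha256(bscan.intensity)} "
            f"derm_sha={_sha256(derm.rgb_image)}"
        )

    with _stage("delimit"):
        band = extract_scanline_band(derm, margin=margin)
        bounds_derm = find_lesion_bounds(band, col_offset=derm.scan_span_cols[0])
        bounds = map_bounds_to_oct(bounds_derm, derm, bscan.width_px)
        log.append(
            f"stage=delimit derm=[{bounds_derm.start_col},{bounds_derm.end_col}) "
            f"bscan=[{bounds.start_col},{bounds.end_col})"
        )

    with _stage("roi"):
        lesion_raw = lesion_center_roi(bscan, bounds, half_width=half_width)
        healthy_raw = healthy_adjacent_roi(bscan, bounds, width=healthy_width, guard_px=guard_px)
        lesion_flat = flatten(lesion_raw, annotation)
        healthy_flat = [flatten(p, annotation) for p in healthy_raw]
        log.append(
            f"stage=roi lesion_origin={lesion_flat.origin_col} "
            f"healthy_origins={[p.origin_col for p in healthy_flat]}"
        )

    with _stage("optics"):
        lesion_optics = truncate_depth(lesion_flat, optics_depth)
        healthy_optics = [truncate_depth(p, optics_depth) for p in healthy_flat]
        lesion_att = roi_attenuation(lesion_optics, bscan.axial_pitch_um)
        healthy_att = roi_attenuation(healthy_optics, bscan.axial_pitch_um)
        diff = median_difference(lesion_att, healthy_att)
        log.append(
            f"stage=optics lesion_median={lesion_att.median_mu_t:.4f} "
            f"healthy_median={healthy_att.median_mu_t:.4f} diff={diff:.2f}"
        )

    with _stage("texture"):
        lesion_tex = sectioned_features(truncate_depth(lesion_flat, texture_depth), glcm_cfg)
        healthy_tex = sectioned_features(
            _pool_healthy([truncate_depth(p, texture_depth) for p in healthy_flat]), glcm_cfg
        )
        log.append(
            f"stage=texture n_boxes_lesion={len(lesion_tex.per_box)} "
            f"n_boxes_healthy={len(healthy_tex.per_box)}"
        )

    provenance = {
        "config": _jsonable(cfg),
        "seed_override": seed,
        "octprofiler_version": __version__,
    }
    result = CaseResult(
        case_id=case_id,
        diagnosis_label=diagnosis,
        lesion_attenuation=lesion_att,
        healthy_attenuation=healthy_att,
        lesion_texture=lesion_tex,
        healthy_texture=healthy_tex,
        median_difference=diff,
        bounds_bscan=bounds,
        truth=truth,
        provenance=provenance,
    )

    if out_dir is not None:
        with _stage("write"):
            _write_outputs(Path(out_dir), result, bscan, lesion_optics, healthy_optics, log)
    return result


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _write_outputs(out, result, bscan, lesion_optics, healthy_optics, log):
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
    rows = []
    for patch in [lesion_optics, *healthy_optics]:
        for j, fit in enumerate(fit_patch(patch, bscan.axial_pitch_um)):
            rows.append(
                {
                    "label": patch.label,
                    "bscan_col": patch.origin_col + j,
                    "amplitude_A": fit.amplitude_A,
                    "mu_t": fit.mu_t,
                    "offset_C": fit.offset_C,
                    "rss": fit.rss,
                    "converged": fit.converged,
                }
            )
    pd.DataFrame(rows).to_csv(out / "ascan_fits.csv", index=False)
    pd.concat(
        [
            result.lesion_texture.summary.assign(label="lesion"),
            result.healthy_texture.summary.assign(label="healthy"),
        ]
    ).to_csv(out / "texture_summary.csv", index=False)
    (out / "run.log").write_text("\n".join(log) + "\n")


def compare_cases(results: Sequence[CaseResult]) -> pd.DataFrame:
    """One comparison row per case: attenuation medians/IQRs, their
    difference, and per-section texture medians, sorted by diagnosis.

    Every cell is copied from the ``CaseResult`` fields — nothing is
    recomputed at render time.
    """
    results = list(results)
    if not results:
        raise OctProfilerError("no case results to compare")
    ids = [r.case_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise OctProfilerError(f"duplicate case_id(s): {dupes}")
    rows = []
    for r in results:
        row = {
            "case_id": r.case_id,
            "diagnosis": r.diagnosis_label,
            "lesion_median_mu_t": r.lesion_attenuation.median_mu_t,
            "lesion_iqr_mu_t": r.lesion_attenuation.iqr,
            "healthy_median_mu_t": r.healthy_attenuation.median_mu_t,
            "healthy_iqr_mu_t": r.healthy_attenuation.iqr,
            "median_difference": r.median_difference,
        }
        n_sections = len(r.lesion_texture.config.sections)
        for label, tex in (("lesion", r.lesion_texture), ("healthy", r.healthy_texture)):
            for s in range(n_sections):
                for feat in FEATURES:
                    row[f"{feat}_s{s + 1}_{label}"] = tex.section_median(s, feat)
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values(["diagnosis", "case_id"])
        .reset_index(drop=True)
    )
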