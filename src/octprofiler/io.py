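"""Reading and writing case files.

A case on disk is a directory holding ``bscan.tiff`` (8-bit grayscale,
rows = depth), ``dermatoscopy.png`` (RGB), ``annotation.csv``
(column_index, surface_row), a ``meta.json`` with pitches and scan-line
geometry, and — for phantoms — a ``truth.json`` ground-truth sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile
from PIL import Image

from .delimitation import DermatoscopyView
from .phantom import PhantomTruth
from .roi import BScan, SurfaceAnnotation

__all__ = ["write_case", "load_case"]


def write_case(
    out_dir,
    bscan: BScan,
    derm: DermatoscopyView,
    annotation: SurfaceAnnotation,
    truth: Optional[PhantomTruth] = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = bscan.intensity
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    tifffile.imwrite(out / "bscan.tiff", img)
    Image.fromarray(derm.rgb_image, mode="RGB").save(out / "dermatoscopy.png")
    annotation.to_csv(out / "annotation.csv")
    meta = {
        "axial_pitch_um": bscan.axial_pitch_um,
        "lateral_pitch_um": bscan.lateral_pitch_um,
        "bscan_id": bscan.id,
        "scanline_row": derm.scanline_row,
        "scan_span_cols": list(derm.scan_span_cols),
    }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    if truth is not None:
        truth.to_json(out / "truth.json")
    return out


def load_case(
    case_dir,
) -> Tuple[BScan, DermatoscopyView, SurfaceAnnotation, Optional[PhantomTruth]]:
    case = Path(case_dir)
    with open(case / "meta.json") as fh:
        meta = json.load(fh)
    bscan = BScan(
        intensity=tifffile.imread(case / "bscan.tiff"),
        axial_pitch_um=meta["axial_pitch_um"],
        lateral_pitch_um=meta["lateral_pitch_um"],
        id=meta.get("bscan_id", case.name),
    )
    derm = DermatoscopyView(
        rgb_image=np.asarray(Image.open(case / "dermatoscopy.png").convert("RGB")),
        scanline_row=meta["scanline_row"],
        scan_span_cols=tuple(meta["scan_span_cols"]),
    )
    annotation = SurfaceAnnotation.from_csv(case / "annotation.csv")
    truth = None
    if (case / "truth.json").exists():
        truth = PhantomTruth.from_json(case / "truth.json")
    return bscan, derm, annotation, truth
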