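"""Synthetic phantom scenario library.

Eight phantom configurations — two each for compound nevus (CN),
intradermal nevus (IN), melanoma in-situ (MIS), and superficial
spreading melanoma (SSM) — whose lesion/healthy attenuation pairs span
the medians measured for those subtypes in pigmented skin at 1300 nm.
They are synthetic fixtures for exercising and scoring the pipeline,
not claims of clinical equivalence: only the per-column attenuation
contrast is matched, not any morphology.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .phantom import PhantomConfig

__all__ = ["SCENARIOS", "scenario_phantom", "scenario_config", "random_study_configs"]

#: case_id -> (diagnosis label, lesion mu_t, healthy mu_t) in 1/mm
SCENARIOS: Dict[str, Tuple[str, float, float]] = {
    "CN-1": ("CN", 1.14, 0.62),
    "CN-2": ("CN", 1.60, 1.52),
    "IN-1": ("IN", 1.94, 0.96),
    "IN-2": ("IN", 1.10, 0.90),
    "MIS-1": ("MIS", 0.84, 0.60),
    "MIS-2": ("MIS", 1.34, 0.75),
    "SSM-1": ("SSM", 1.37, 0.62),
    "SSM-2": ("SSM", 2.82, 0.86),
}


def scenario_phantom(case_id: str, seed: int = 0) -> PhantomConfig:
    """Phantom config for one library scenario."""
    label, lesion_mu, healthy_mu = SCENARIOS[case_id]
    return PhantomConfig(
        healthy_mu_t=healthy_mu,
        lesion_mu_t=lesion_mu,
        seed=seed,
    )


def random_study_configs(n: int, seed: int = 0) -> List[PhantomConfig]:
    """``n`` phantoms sampling the study conditions.

    Healthy attenuation is drawn from 0.6-1.0 /mm and lesion attenuation
    from 0.8-2.9 /mm (the ranges observed for healthy skin and pigmented
    lesions); lesion width and position vary, with at least one healthy
    flank of 100+ columns; surface geometry varies per case. Each
    phantom gets its own sub-seed, so the set is reproducible from
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    configs: List[PhantomConfig] = []
    base = PhantomConfig()
    w = base.spec.n_lateral_px
    for _ in range(n):
        width = int(rng.integers(80, 200))
        start = int(rng.integers(105, w - 105 - width))
        configs.append(
            PhantomConfig(
                healthy_mu_t=float(rng.uniform(0.6, 1.0)),
                lesion_mu_t=float(rng.uniform(0.8, 2.9)),
                lesion_cols=(start, start + width),
                surface_base_row=int(rng.integers(30, 55)),
                lesion_bump_px=float(rng.uniform(5, 18)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return configs


def scenario_config(case_id: str, seed: int = 0) -> dict:
    """Full run-case config dict for one library scenario."""
    label, lesion_mu, healthy_mu = SCENARIOS[case_id]
    return {
        "case_id": case_id,
        "diagnosis": label,
        "phantom": {
            "healthy_mu_t": healthy_mu,
            "lesion_mu_t": lesion_mu,
            "seed": seed,
        },
    }
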