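"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: Otsu
by exhaustive threshold search over an explicit python loop, and GLCM
features by direct enumeration of pixel pairs.
"""

from __future__ import annotations

import numpy as np


def otsu_brute_force(values) -> int:
    """Exhaustive search of the threshold maximizing between-class
    variance of the split {v <= t} | {v > t} over a 256-bin histogram."""
    vals = np.clip(np.rint(np.asarray(values, dtype=float).ravel()), 0, 255).astype(int)
    best_t, best_var = None, -1.0
    for t in range(255):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        var = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-9:
            best_var, best_t = var, t
    if best_t is None:
        raise ValueError("constant input")
    return best_t


_OFFSETS = {0: (0, 1), 90: (-1, 0), 180: (0, -1), 270: (1, 0)}


def glcm_brute_force(box: np.ndarray, d: int, angle: int, levels: int) -> np.ndarray:
    """Pair enumeration with an explicit double loop over pixels."""
    q = np.clip(np.floor(np.asarray(box, float) * levels / 256.0), 0, levels - 1).astype(int)
    dr, dc = _OFFSETS[angle % 360]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    P = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[q[r, c], q[r2, c2]] += 1
    return P / P.sum()


def glcm_features_brute_force(P: np.ndarray) -> dict:
    """Feature sums accumulated entry by entry."""
    n = P.shape[0]
    contrast = dissimilarity = homogeneity = asm = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            contrast += p * (i - j) ** 2
            dissimilarity += p * abs(i - j)
            homogeneity += p / (1 + (i - j) ** 2)
            asm += p * p
            mu_i += p * i
            mu_j += p * j
    var_i = var_j = cov = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            var_i += p * (i - mu_i) ** 2
            var_j += p * (j - mu_j) ** 2
            cov += p * (i - mu_i) * (j - mu_j)
    denom = (var_i * var_j) ** 0.5
    correlation = 1.0 if denom < 1e-12 else cov / denom
    return {
        "contrast": contrast,
        "dissimilarity": dissimilarity,
        "homogeneity": homogeneity,
        "energy": asm**0.5,
        "correlation": correlation,
    }
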