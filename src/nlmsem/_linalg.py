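"""Small symmetric-matrix utilities shared across modules.

The half-vectorization order used everywhere in this package is the
row-major upper triangle, i.e. the order produced by ``np.triu_indices``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def vech(a: np.ndarray) -> np.ndarray:
    """Upper-triangle (row-major) half-vectorization of a symmetric matrix."""
    p = a.shape[-1]
    iu = np.triu_indices(p)
    return a[..., iu[0], iu[1]]


def unvech(v: np.ndarray, p: int) -> np.ndarray:
    """Inverse of :func:`vech`: rebuild the full symmetric matrix."""
    out = np.zeros((p, p), dtype=float)
    iu = np.triu_indices(p)
    out[iu] = v
    out.T[iu] = v
    return out


@lru_cache(maxsize=8)
def duplication_matrix(p: int) -> np.ndarray:
    """Matrix D with vec(A) = D @ vech(A) for symmetric p x p A.

    Consistent with the triu-row-major vech order above.
    """
    iu = np.triu_indices(p)
    m = len(iu[0])
    d = np.zeros((p * p, m))
    for k, (i, j) in enumerate(zip(iu[0], iu[1])):
        d[i * p + j, k] = 1.0
        d[j * p + i, k] = 1.0
    return d


def nearest_psd(a: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-floored symmetric projection; used for starting values only."""
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    lo = floor * max(1.0, float(np.abs(w).max()))
    if w.min() >= lo:
        return a
    w = np.clip(w, lo, None)
    return (v * w) @ v.T


def is_pd(a: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(0.5 * (a + a.T))
        return True
    except np.linalg.LinAlgError:
        return False
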