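"""Shared numerical helpers: RNG coercion, guarded Cholesky, SPD projection."""
from __future__ import annotations

import warnings

import numpy as np

__all__ = ["as_rng", "chol_with_jitter", "nearest_spd", "LOG_2PI"]

LOG_2PI = float(np.log(2.0 * np.pi))


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def chol_with_jitter(mat: np.ndarray, warn: bool = True) -> np.ndarray:
    """Lower Cholesky factor; on failure add jitter 1e-10*trace/d to the diagonal.

    The jitter is only applied when the plain factorization fails, and a warning
    is emitted so that chains relying on it can be diagnosed.
    """
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        d = mat.shape[0]
        jitter = 1e-10 * max(np.trace(mat), 1.0) / d
        if warn:
            warnings.warn(
                f"covariance not positive definite; adding jitter {jitter:.3g}",
                RuntimeWarning,
                stacklevel=2,
            )
        for _ in range(12):
            try:
                return np.linalg.cholesky(mat + jitter * np.eye(d))
            except np.linalg.LinAlgError:
                jitter *= 10.0
        raise


def nearest_spd(mat: np.ndarray, floor_scale: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Symmetrize and floor the eigenvalues of ``mat`` at floor_scale*trace.

    Returns (projected matrix, clipped flag).  Used where an approximation can
    push an aggregate scale matrix off the SPD cone.
    """
    sym = 0.5 * (mat + mat.T)
    floor = floor_scale * max(abs(np.trace(sym)), 1e-300)
    vals, vecs = np.linalg.eigh(sym)
    if vals[0] >= floor:
        return sym, False
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T, True
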