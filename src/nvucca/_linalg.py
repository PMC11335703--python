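"""Symmetric matrix square roots shared by the simulator and the CCA solver."""

from __future__ import annotations

import numpy as np

#: Eigenvalue floor applied before inverting; guards near-collinear sets.
EIG_FLOOR = 1e-10


def sym_sqrt(S: np.ndarray) -> np.ndarray:
    """Symmetric positive-semidefinite square root via eigendecomposition."""
    w, v = np.linalg.eigh(np.asarray(S, dtype=float))
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def sym_inv_sqrt(S: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Symmetric inverse square root with an eigenvalue floor.

    Eigenvalues below ``floor`` are raised to it before inversion, which keeps
    the whitening transform bounded for rank-deficient covariance estimates.
    """
    w, v = np.linalg.eigh(np.asarray(S, dtype=float))
    w = np.clip(w, floor, None)
    return (v / np.sqrt(w)) @ v.T


def polar_orthonormal(W: np.ndarray) -> np.ndarray:
    """Closest matrix with orthonormal columns (polar factor of ``W``).

    Computed from the thin SVD ``W = U S V^T`` as ``U V^T``; columns of ``W``
    that are numerically zero are completed with an arbitrary but
    deterministic orthonormal basis from the SVD.
    """
    u, _, vt = np.linalg.svd(np.asarray(W, dtype=float), full_matrices=False)
    return u @ vt
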