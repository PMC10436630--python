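"""Shared symmetric eigen-decomposition helpers.

Both the monitoring model and contrastive learning decompose a symmetric
(covariance or covariance-difference) matrix; keeping one solver here makes
their spectra bit-consistent.
"""

from __future__ import annotations

import numpy as np

#: eigenvalues smaller than this (relative to the largest) are treated as zero
EIGVAL_FLOOR = 1e-12


def eig_descending(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose a symmetric matrix, eigenvalues in descending order.

    Eigenvector signs are fixed deterministically: the entry of largest
    absolute value in each column is made positive (first such entry on ties).

    Returns
    -------
    eigvals : (D,) ndarray, descending
    eigvecs : (D, D) ndarray, column i pairs with eigvals[i]
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {S.shape}")
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    return eigvals, fix_signs(eigvecs)


def fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-|entry| element of every column positive."""
    vectors = np.array(vectors, dtype=float, copy=True)
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def floor_eigvals(eigvals: np.ndarray, rel_tol: float = EIGVAL_FLOOR) -> np.ndarray:
    """Clip numerically-zero (or slightly negative) eigenvalues to exactly 0."""
    eigvals = np.asarray(eigvals, dtype=float)
    scale = max(float(eigvals.max(initial=0.0)), 0.0)
    out = eigvals.copy()
    out[out < rel_tol * max(scale, 1.0)] = 0.0
    return out
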