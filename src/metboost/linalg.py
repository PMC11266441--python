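"""Shared SVD helpers.

All SVD-based feature constructions in the pipeline (environmental-covariate
compression, relationship-matrix scores, the factorized Kronecker decomposition)
go through :func:`svd_decompose` so the sign convention and the definition of
explained variance are identical everywhere.

Sign convention: within each component the right-singular-vector entry of
largest magnitude is made positive.  This removes the arbitrary sign flip of
singular vectors and makes scores reproducible across runs and BLAS builds.
"""

from __future__ import annotations

import numpy as np


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    for j in range(Vt.shape[0]):
        idx = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, idx] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U, Vt


def svd_decompose(
    X: np.ndarray, center: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full (economy) SVD with the package sign convention.

    Returns ``(U, s, Vt)``.  With ``center=True`` columns are mean-centered
    first (the default is uncentered, matching a TruncatedSVD-style
    decomposition of the raw matrix).
    """
    X = np.asarray(X, dtype=float)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, Vt = _fix_signs(U, Vt)
    return U, s, Vt


def svd_scores(
    X: np.ndarray, k: int, center: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Top-``k`` component scores ``U_k @ diag(s_k)`` and explained-variance ratios.

    Explained variance is measured on the decomposed matrix (uncentered sum of
    squares unless ``center=True``), so the ratios of all components sum to 1.
    """
    U, s, Vt = svd_decompose(X, center=center)
    k = int(min(k, len(s)))
    total = float(np.sum(s**2))
    evr = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return U[:, :k] * s[:k], evr
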