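"""Rank-based (nonparanormal) covariance surrogates.

ChIP-seq fold-change signal is far from Gaussian even after log
transformation. Under a Gaussian copula — each factor is some unknown
strictly increasing transform of a latent Gaussian — the latent correlation
matrix is identified from Spearman rank correlations through

    S_hat[i, j] = 2 * sin(pi * rho[i, j] / 6)    (i != j),  S_hat[i, i] = 1.

S_hat replaces the sample covariance in the downstream D-trace problem; a
projection step guards against indefiniteness of the transformed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationEstimate",
    "spearman_matrix",
    "sin_transform",
    "nearest_psd",
    "estimate_covariance",
]

DEFAULT_EIGEN_FLOOR = 1e-4


@dataclass
class CorrelationEstimate:
    """Spearman matrix and its sine-transformed covariance surrogate."""

    rho: np.ndarray
    S_hat: np.ndarray
    psd_projected: bool
    condition: int = 0


def _as_array(X) -> np.ndarray:
    # accept a SignalMatrix or a plain n x J array
    return np.asarray(getattr(X, "X", X), dtype=float)


def _factor_names(X, J: int) -> list[str]:
    return list(getattr(X, "factors", [str(j) for j in range(J)]))


def spearman_matrix(X) -> np.ndarray:
    """Spearman correlation across columns, average ranks for ties.

    Raises if any column is constant (its rank correlation is undefined).
    """
    A = _as_array(X)
    n, J = A.shape
    if n < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    const = np.all(A == A[0, :], axis=0)
    if const.any():
        names = _factor_names(X, J)
        bad = [names[j] for j in np.flatnonzero(const)]
        raise ValueError(f"constant signal column(s), Spearman undefined: {bad}")
    if J == 1:
        return np.ones((1, 1))
    rho = stats.spearmanr(A, axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if rho.shape == (1, 1):  # spearmanr collapses J=2 to a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return rho


def sin_transform(rho: np.ndarray) -> np.ndarray:
    """Map Spearman correlations to latent Gaussian correlations."""
    rho = np.asarray(rho, dtype=float)
    S = 2.0 * np.sin(np.pi * rho / 6.0)
    np.fill_diagonal(S, 1.0)
    return S


def nearest_psd(
    S: np.ndarray, floor: float = DEFAULT_EIGEN_FLOOR
) -> tuple[np.ndarray, bool]:
    """Clip eigenvalues below ``floor`` and rescale the diagonal back to 1.

    Returns ``(matrix, projected)``; ``projected`` is False when the input
    already satisfies the eigenvalue floor and is returned unchanged.
    Clipping inflates the diagonal, and rescaling can push the smallest
    eigenvalue slightly below the floor again, so the two steps repeat
    until the floor holds.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("nearest_psd requires a symmetric matrix")
    w = np.linalg.eigvalsh(S)
    if w[0] >= floor:
        return S, False
    A = S.copy()
    for _ in range(100):
        w, V = np.linalg.eigh(A)
        if w[0] >= floor:
            break
        # clip slightly above the floor so the diagonal rescale cannot
        # push the smallest eigenvalue back under it indefinitely
        A = (V * np.maximum(w, 1.1 * floor)) @ V.T
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
        A = (A + A.T) / 2.0
        np.fill_diagonal(A, 1.0)
    return A, True


def estimate_covariance(
    X, condition: int | None = None, floor: float = DEFAULT_EIGEN_FLOOR
) -> CorrelationEstimate:
    """Full rank-based pipeline: Spearman -> sine transform -> PSD projection."""
    rho = spearman_matrix(X)
    S = sin_transform(rho)
    S, projected = nearest_psd(S, floor=floor)
    if condition is None:
        condition = int(getattr(X, "condition", 0))
    return CorrelationEstimate(
        rho=rho, S_hat=S, psd_projected=projected, condition=condition
    )
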