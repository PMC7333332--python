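"""Sparse precision-difference estimation via the lasso-penalized D-trace loss.

The difference Delta = Theta1 - Theta0 of two precision matrices satisfies
Sigma1 @ Delta @ Sigma0 = Sigma1 - Sigma0, so Delta can be estimated
directly — without estimating either precision matrix — by minimizing

    l(Delta) = 1/2 tr(Delta S1 Delta S0) - tr(Delta (S1 - S0))
               + lam * sum_ij |Delta_ij|

over symmetric matrices, where S0 and S1 are (rank-based) covariance
surrogates with unit diagonal. The penalty covers every entry, diagonal
included, following the double sum in the objective as written; this is
configurable via ``penalize_diagonal``.

The solver is ADMM on the splitting Delta = Z: the smooth quadratic is
minimized exactly in Delta (a linear system in vec(Delta), prefactored once
per penalty parameter), the l1 term is handled by soft-thresholding in Z,
and both blocks are symmetrized every iteration. The returned estimate is
the soft-thresholded iterate Z, which is exactly sparse — edge supports
need no epsilon thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["DeltaEstimate", "dtrace_loss", "solve_delta", "edges_from_delta"]


@dataclass
class DeltaEstimate:
    """Solution of the penalized D-trace problem at one penalty value."""

    Delta: np.ndarray
    lam: float
    loss: float
    iterations: int
    converged: bool
    kkt_residual: float


def _check_pair(S1: np.ndarray, S0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    S1 = np.asarray(S1, dtype=float)
    S0 = np.asarray(S0, dtype=float)
    if S1.ndim != 2 or S1.shape[0] != S1.shape[1]:
        raise ValueError("S1 must be square")
    if S1.shape != S0.shape:
        raise ValueError(f"dimension mismatch: S1 {S1.shape} vs S0 {S0.shape}")
    return S1, S0


def dtrace_loss(
    Delta: np.ndarray, S1: np.ndarray, S0: np.ndarray, lam: float
) -> float:
    """Penalized D-trace objective, penalty summed over all entries."""
    S1, S0 = _check_pair(S1, S0)
    Delta = np.asarray(Delta, dtype=float)
    if Delta.shape != S1.shape:
        raise ValueError(f"Delta shape {Delta.shape} does not match {S1.shape}")
    quad = 0.5 * np.trace(Delta @ S1 @ Delta @ S0)
    lin = np.trace(Delta @ (S1 - S0))
    return float(quad - lin + lam * np.abs(Delta).sum())


def _smooth_gradient(
    Delta: np.ndarray, S1: np.ndarray, S0: np.ndarray
) -> np.ndarray:
    """Gradient of the smooth part over symmetric matrices."""
    return 0.5 * (S1 @ Delta @ S0 + S0 @ Delta @ S1) - (S1 - S0)


def kkt_residual(
    Delta: np.ndarray,
    S1: np.ndarray,
    S0: np.ndarray,
    lam: float,
    penalize_diagonal: bool = True,
) -> float:
    """Maximum violation of the stationarity conditions at ``Delta``.

    Zero entries require |grad| <= lam; nonzero entries require
    grad + lam * sign = 0.
    """
    G = _smooth_gradient(Delta, S1, S0)
    zero = Delta == 0.0
    res_zero = np.maximum(np.abs(G) - lam, 0.0)
    res_nonzero = np.abs(G + lam * np.sign(Delta))
    res = np.where(zero, res_zero, res_nonzero)
    if not penalize_diagonal:
        d = np.abs(np.diag(G))
        np.fill_diagonal(res, d)
    return float(res.max()) if res.size else 0.0


def _soft(V: np.ndarray, t: float) -> np.ndarray:
    return np.sign(V) * np.maximum(np.abs(V) - t, 0.0)


def solve_delta(
    S1: np.ndarray,
    S0: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 2000,
    rho: float = 1.0,
    penalize_diagonal: bool = True,
) -> DeltaEstimate:
    """Minimize the lasso-penalized D-trace loss by ADMM.

    Parameters
    ----------
    S1, S0
        Symmetric covariance surrogates for the two conditions, positive
        definite (enforce upstream, e.g. with :func:`~tfrewire.nonparanormal.nearest_psd`).
    lam
        Non-negative l1 penalty; larger values give sparser differences.
    tol
        Convergence tolerance on the KKT stationarity residual.
    max_iter
        Iteration cap; non-convergence returns the best iterate with
        ``converged=False`` and a warning.
    rho
        Initial ADMM step parameter, self-tuned by residual balancing.
    penalize_diagonal
        Whether the l1 penalty covers the diagonal (default True, as in
        the objective's double sum over all i, j).
    """
    S1, S0 = _check_pair(S1, S0)
    if lam < 0:
        raise ValueError("lam must be non-negative")
    J = S1.shape[0]

    # Shortcut: if the two surrogates coincide, Delta = 0 is a KKT point
    # for every lam >= 0 (the linear term vanishes).
    if np.array_equal(S1, S0):
        Z = np.zeros((J, J))
        return DeltaEstimate(Z, lam, 0.0, 0, True, 0.0)

    A = S1 - S0

    # vec (column-major) representation of the symmetrized quadratic form:
    # vec(1/2 (S1 X S0 + S0 X S1)) = 1/2 (S0 kron S1 + S1 kron S0) vec(X).
    Q = 0.5 * (np.kron(S0, S1) + np.kron(S1, S0))

    def factor(rho_val: float):
        return cho_factor(Q + rho_val * np.eye(J * J), lower=True)

    chol = factor(rho)
    Z = np.zeros((J, J))
    U = np.zeros((J, J))
    kkt = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        rhs = A + rho * (Z - U)
        Delta = cho_solve(chol, rhs.flatten(order="F")).reshape((J, J), order="F")
        Delta = (Delta + Delta.T) / 2.0
        Z_old = Z
        V = Delta + U
        Z = _soft(V, lam / rho)
        if not penalize_diagonal:
            np.fill_diagonal(Z, np.diag(V))
        Z = (Z + Z.T) / 2.0
        U = U + Delta - Z

        if it % 5 == 0 or it == max_iter:
            kkt = kkt_residual(Z, S1, S0, lam, penalize_diagonal)
            if kkt <= tol:
                break
            r_primal = np.linalg.norm(Delta - Z)
            r_dual = rho * np.linalg.norm(Z - Z_old)
            if r_primal > 10.0 * r_dual:
                rho *= 2.0
                U = U / 2.0
                chol = factor(rho)
            elif r_dual > 10.0 * r_primal:
                rho /= 2.0
                U = U * 2.0
                chol = factor(rho)

    converged = kkt <= tol
    if not converged:
        warnings.warn(
            f"D-trace ADMM did not reach KKT tolerance {tol:g} in "
            f"{max_iter} iterations (residual {kkt:.3g})"
        )
    loss = dtrace_loss(Z, S1, S0, lam)
    return DeltaEstimate(
        Delta=Z,
        lam=float(lam),
        loss=loss,
        iterations=it,
        converged=bool(converged),
        kkt_residual=float(kkt),
    )


def edges_from_delta(est: DeltaEstimate) -> set[tuple[int, int, float]]:
    """Weighted undirected edges {(i, j, |Delta_ij|) : i < j, Delta_ij != 0}.

    Operates on the exactly-sparse iterate, so no epsilon threshold is
    applied.
    """
    if not est.converged:
        warnings.warn(
            "extracting edges from a non-converged estimate "
            f"(KKT residual {est.kkt_residual:.3g})"
        )
    D = est.Delta
    iu, ju = np.triu_indices(D.shape[0], k=1)
    nz = D[iu, ju] != 0.0
    return {
        (int(i), int(j), float(abs(D[i, j])))
        for i, j in zip(iu[nz], ju[nz])
    }
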