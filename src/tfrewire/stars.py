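"""Stability-based selection (StARS) of the sparsity penalty.

The penalty lambda is chosen by subsampling bins: for each subsample and
each grid value, the differential network is re-estimated and each edge
gets an indicator psi. With theta the per-edge selection frequency over
subsamples, xi = 2 * theta * (1 - theta) measures how often subsamples
disagree about the edge, and the total instability at density parameter
Lambda = 1 / lambda is

    D_hat(Lambda) = sum_{i<j} xi_ij(Lambda) / C(J, 2).

D_hat is forced monotone by a running supremum D_bar along increasing
Lambda, and the selected penalty is the densest network (largest Lambda)
with D_bar <= beta. Default study settings: S = 100 subsamples of half the
bins, beta = 0.005, and a 12-point log-spaced lambda grid on [0.01, 10].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .dtrace import edges_from_delta, solve_delta
from .nonparanormal import estimate_covariance

__all__ = [
    "StabilityProfile",
    "default_lambda_grid",
    "subsample_bins",
    "instability_profile",
    "monotonize",
    "select_lambda",
]

DEFAULT_BETA = 0.005


def default_lambda_grid(num: int = 12) -> np.ndarray:
    """Log-spaced penalties from 10 down to 0.01 (i.e. increasing Lambda)."""
    return np.logspace(np.log10(10.0), np.log10(0.01), num)


@dataclass
class StabilityProfile:
    """Edge-selection frequencies and instability across the penalty grid.

    ``lambda_grid`` is ordered by decreasing lambda, i.e. increasing
    Lambda = 1 / lambda, so running maxima along the arrays follow
    increasing network density. ``psi`` has shape (S, M, n_pairs) over the
    strictly upper triangle; ``valid`` flags (s, m) cells whose solver run
    converged and is included in the frequencies.
    """

    lambda_grid: np.ndarray
    S: int
    fraction: float
    psi: np.ndarray
    valid: np.ndarray
    theta: np.ndarray
    xi: np.ndarray
    D_hat: np.ndarray
    seed: int
    n_factors: int
    D_bar: np.ndarray | None = None
    beta: float | None = None
    lambda_opt: float | None = None

    def summary_frame(self):
        import pandas as pd

        edge_counts = self.psi.sum(axis=2).mean(axis=0)
        return pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "Lambda": 1.0 / self.lambda_grid,
                "D_hat": self.D_hat,
                "D_bar": self.D_bar if self.D_bar is not None else np.nan,
                "mean_edges": edge_counts,
            }
        )


def subsample_bins(
    n: int, fraction: float, S: int, seed: int
) -> list[np.ndarray]:
    """S index sets of floor(fraction * n) bins, drawn without replacement."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    size = int(np.floor(fraction * n))
    if size < 2:
        raise ValueError(f"subsample size {size} too small (need >= 2)")
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(n, size=size, replace=False)) for _ in range(S)]


def _as_array(X) -> np.ndarray:
    return np.asarray(getattr(X, "X", X), dtype=float)


def instability_profile(
    X0,
    X1,
    lambda_grid: np.ndarray | None = None,
    S: int = 100,
    fraction: float = 0.5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    penalize_diagonal: bool = True,
) -> StabilityProfile:
    """Per-edge selection frequencies and instability over the penalty grid.

    For every subsample the covariance surrogates are re-estimated on the
    subsampled rows and the D-trace problem re-solved at every grid value.
    Fits are independent across (subsample, lambda) cells; a non-converged
    fit is excluded from that cell's frequency denominator with a warning.
    """
    A0, A1 = _as_array(X0), _as_array(X1)
    if A0.shape != A1.shape:
        raise ValueError("condition matrices must share bins and factors")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    lambda_grid = np.sort(lambda_grid)[::-1]  # decreasing lambda
    n, J = A0.shape
    iu, ju = np.triu_indices(J, k=1)
    n_pairs = len(iu)
    M = len(lambda_grid)

    subsets = subsample_bins(n, fraction, S, seed)
    psi = np.zeros((S, M, n_pairs), dtype=bool)
    valid = np.ones((S, M), dtype=bool)
    for s, idx in enumerate(subsets):
        est0 = estimate_covariance(A0[idx])
        est1 = estimate_covariance(A1[idx])
        for m, lam in enumerate(lambda_grid):
            fit = solve_delta(
                est1.S_hat,
                est0.S_hat,
                lam,
                tol=tol,
                max_iter=max_iter,
                penalize_diagonal=penalize_diagonal,
            )
            if not fit.converged:
                valid[s, m] = False
                warnings.warn(
                    f"subsample {s}, lambda {lam:.4g}: solver did not "
                    "converge; cell excluded from selection frequencies"
                )
                continue
            psi[s, m] = fit.Delta[iu, ju] != 0.0

    counts = valid.sum(axis=0).astype(float)  # per grid point
    counts = np.maximum(counts, 1.0)
    theta = np.where(valid[:, :, None], psi, False).sum(axis=0) / counts[:, None]
    xi = 2.0 * theta * (1.0 - theta)
    denom = J * (J - 1) / 2.0
    D_hat = xi.sum(axis=1) / denom
    return StabilityProfile(
        lambda_grid=lambda_grid,
        S=S,
        fraction=fraction,
        psi=psi,
        valid=valid,
        theta=theta,
        xi=xi,
        D_hat=D_hat,
        seed=seed,
        n_factors=J,
    )


def monotonize(profile: StabilityProfile) -> StabilityProfile:
    """Running supremum of D_hat along increasing Lambda (decreasing lambda)."""
    return replace(profile, D_bar=np.maximum.accumulate(profile.D_hat))


def select_lambda(
    profile: StabilityProfile, beta: float = DEFAULT_BETA
) -> tuple[float, StabilityProfile]:
    """Largest Lambda (densest network) whose monotone instability <= beta.

    Falls back to the largest grid lambda (sparsest network) with a warning
    when no grid point satisfies the threshold.
    """
    if profile.lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    prof = profile if profile.D_bar is not None else monotonize(profile)
    ok = np.flatnonzero(prof.D_bar <= beta)
    if ok.size:
        lam_opt = float(prof.lambda_grid[ok[-1]])
    else:
        lam_opt = float(prof.lambda_grid[0])
        warnings.warn(
            f"no grid value satisfies instability threshold beta={beta}; "
            "returning the sparsest (largest) lambda"
        )
    prof = replace(prof, beta=float(beta), lambda_opt=lam_opt)
    return lam_opt, prof
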