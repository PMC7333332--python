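"""Independent brute-force oracles used across the test suite.

Each function re-derives a quantity by the most naive method available
(per-base scans, explicit loops, generic numerical optimization) and is
kept free of the code paths it checks.
"""

import numpy as np
from scipy.optimize import minimize


def bases_covered(chroms, starts, ends) -> dict[str, set[int]]:
    """Expand an interval set into per-chromosome sets of covered bases."""
    out: dict[str, set[int]] = {}
    for c, s, e in zip(chroms, starts, ends):
        out.setdefault(str(c), set()).update(range(int(s), int(e)))
    return out


def bins_overlapping(grid, intervals) -> list[int]:
    """Per-base scan: indices of bins sharing >= 1 base with any interval."""
    cov = bases_covered(intervals.chroms, intervals.starts, intervals.ends)
    hits = []
    for idx, (c, s, e) in enumerate(zip(grid.chroms, grid.starts, grid.ends)):
        bases = cov.get(str(c), set())
        if any(b in bases for b in range(int(s), int(e))):
            hits.append(idx)
    return hits


def jaccard_by_bases(a, b) -> float:
    ca = bases_covered(a.chroms, a.starts, a.ends)
    cb = bases_covered(b.chroms, b.starts, b.ends)
    inter = sum(len(ca.get(c, set()) & cb.get(c, set())) for c in set(ca) | set(cb))
    union = sum(len(ca.get(c, set()) | cb.get(c, set())) for c in set(ca) | set(cb))
    return inter / union


def aggregate_by_bases(grid, track) -> np.ndarray:
    """Expand a bedGraph to per-base values, then mean per bin (0 off-track)."""
    per_base: dict[tuple[str, int], float] = {}
    for row in track.itertuples():
        for b in range(int(row.start), int(row.end)):
            per_base[(str(row.chrom), b)] = float(row.value)
    out = np.zeros(len(grid))
    for idx, (c, s, e) in enumerate(zip(grid.chroms, grid.starts, grid.ends)):
        vals = [per_base.get((str(c), b), 0.0) for b in range(int(s), int(e))]
        out[idx] = float(np.mean(vals))
    return out


def dtrace_loss_by_loops(Delta, S1, S0, lam) -> float:
    """Term-by-term expansion of the penalized D-trace objective."""
    J = Delta.shape[0]
    quad = 0.0
    for i in range(J):
        for j in range(J):
            for k in range(J):
                for l in range(J):
                    quad += Delta[i, j] * S1[j, k] * Delta[k, l] * S0[l, i]
    lin = sum(
        Delta[i, j] * (S1[j, i] - S0[j, i]) for i in range(J) for j in range(J)
    )
    pen = sum(abs(Delta[i, j]) for i in range(J) for j in range(J))
    return 0.5 * quad - lin + lam * pen


def minimize_dtrace_blackbox(S1, S0, lam, starts) -> float:
    """Best objective found by a generic derivative-free minimizer.

    Optimizes over the free entries of a symmetric matrix from several
    starting points and returns the best objective value reached.
    """
    J = S1.shape[0]
    iu = np.triu_indices(J)

    def unpack(x):
        D = np.zeros((J, J))
        D[iu] = x
        return D + D.T - np.diag(np.diag(D))

    def obj(x):
        D = unpack(x)
        quad = 0.5 * np.trace(D @ S1 @ D @ S0)
        lin = np.trace(D @ (S1 - S0))
        return quad - lin + lam * np.abs(D).sum()

    best = np.inf
    for x0 in starts:
        res = minimize(
            obj,
            np.asarray(x0)[iu] if np.ndim(x0) == 2 else x0,
            method="Nelder-Mead",
            options=dict(maxiter=20000, maxfev=40000, xatol=1e-10, fatol=1e-12),
        )
        best = min(best, res.fun)
    return float(best)


def f1_score(edges, support) -> float:
    """F1 of a weighted edge set against a ground-truth support set."""
    got = {(i, j) for i, j, _ in edges}
    tp = len(got & support)
    fp = len(got - support)
    fn = len(support - got)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


def stars_by_double_loop(X0, X1, lambda_grid, S, fraction, seed,
                         tol=1e-6, max_iter=2000):
    """Naive StARS: materialize every psi indicator and aggregate by loops."""
    from tfrewire import estimate_covariance, solve_delta, subsample_bins

    n, J = X0.shape
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]
    subsets = subsample_bins(n, fraction, S, seed)
    pairs = [(i, j) for i in range(J) for j in range(i + 1, J)]
    psi = np.zeros((S, len(lambda_grid), len(pairs)))
    for s, idx in enumerate(subsets):
        e0 = estimate_covariance(X0[idx])
        e1 = estimate_covariance(X1[idx])
        for m, lam in enumerate(lambda_grid):
            fit = solve_delta(e1.S_hat, e0.S_hat, lam, tol=tol, max_iter=max_iter)
            for p, (i, j) in enumerate(pairs):
                psi[s, m, p] = 1.0 if fit.Delta[i, j] != 0 else 0.0
    theta = np.zeros((len(lambda_grid), len(pairs)))
    for m in range(len(lambda_grid)):
        for p in range(len(pairs)):
            theta[m, p] = sum(psi[s, m, p] for s in range(S)) / S
    xi = 2.0 * theta * (1.0 - theta)
    D_hat = np.array(
        [xi[m].sum() / (J * (J - 1) / 2) for m in range(len(lambda_grid))]
    )
    return lambda_grid, theta, D_hat
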