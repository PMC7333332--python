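"""Differential co-regulation networks, hub ranking, and consistency.

Nodes are the profiled factors; an edge (i, j) with weight |Delta_ij| marks
a pair whose conditional dependence changes between the two conditions.
Factors are ranked by their number of gained/lost partners (degree in the
differential network); hub calls are scored for consistency by repeating
the whole fit on random subsamples of the bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dtrace import DeltaEstimate, edges_from_delta, solve_delta
from .nonparanormal import estimate_covariance
from .stars import subsample_bins

__all__ = [
    "DifferentialNetwork",
    "build_differential_network",
    "rank_hubs",
    "hub_consistency",
    "export_network",
    "read_network",
    "possible_edges",
]


def possible_edges(J: int, convention: str = "choose2") -> float:
    """Number of possible edges among J nodes.

    ``choose2`` gives C(J, 2) = J(J-1)/2; ``half-square`` gives J^2/2, a
    convention that effectively counts self-pairs as well.
    """
    if convention == "choose2":
        return J * (J - 1) / 2.0
    if convention == "half-square":
        return J * J / 2.0
    raise ValueError(f"unknown convention: {convention!r}")


@dataclass
class DifferentialNetwork:
    """Weighted undirected edge set over factors, with solver metadata."""

    factors: list[str]
    edges: list[tuple[int, int, float]]  # (i, j, |Delta_ij|), i < j
    lambda_used: float
    estimate: DeltaEstimate | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for i, j, _ in self.edges:
            if i >= j:
                raise ValueError("edges must have i < j (no self-loops)")
        self.edges = sorted(self.edges)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def degrees(self) -> dict[str, int]:
        deg = {f: 0 for f in self.factors}
        for i, j, _ in self.edges:
            deg[self.factors[i]] += 1
            deg[self.factors[j]] += 1
        return deg

    @property
    def edge_fraction(self) -> float:
        """Share of realized edges among C(J, 2) possible pairs."""
        if self.n_factors < 2:
            return 0.0
        return len(self.edges) / possible_edges(self.n_factors, "choose2")

    @property
    def edge_fraction_half_square(self) -> float:
        """Edge share under the J^2/2 denominator convention."""
        if self.n_factors < 1:
            return 0.0
        return len(self.edges) / possible_edges(self.n_factors, "half-square")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.factors)
        g.add_weighted_edges_from(
            (self.factors[i], self.factors[j], w) for i, j, w in self.edges
        )
        return g


def build_differential_network(
    X0,
    X1,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 2000,
    penalize_diagonal: bool = True,
) -> DifferentialNetwork:
    """Full-data covariance surrogates -> D-trace fit -> edge extraction."""
    A0 = np.asarray(getattr(X0, "X", X0), dtype=float)
    A1 = np.asarray(getattr(X1, "X", X1), dtype=float)
    if A0.shape != A1.shape:
        raise ValueError("condition matrices must share bins and factors")
    factors = list(getattr(X0, "factors", [str(j) for j in range(A0.shape[1])]))
    f1 = list(getattr(X1, "factors", factors))
    if f1 != factors:
        raise ValueError("factor columns differ between conditions")
    est0 = estimate_covariance(A0)
    est1 = estimate_covariance(A1)
    fit = solve_delta(
        est1.S_hat, est0.S_hat, lam, tol=tol, max_iter=max_iter,
        penalize_diagonal=penalize_diagonal,
    )
    edges = sorted((i, j, w) for i, j, w in edges_from_delta(fit))
    J = len(factors)
    net = DifferentialNetwork(
        factors=factors,
        edges=edges,
        lambda_used=float(lam),
        estimate=fit,
        metadata={
            "n_bins": A0.shape[0],
            "edge_fraction_choose2": (
                len(edges) / possible_edges(J, "choose2") if J > 1 else 0.0
            ),
            "edge_fraction_half_square": (
                len(edges) / possible_edges(J, "half-square") if J > 0 else 0.0
            ),
            "psd_projected": (est0.psd_projected, est1.psd_projected),
        },
    )
    return net


def _hub_flags(net: DifferentialNetwork, rule: str, k: int, z: float) -> pd.DataFrame:
    """Degree table sorted descending (ties lexicographic) with hub calls."""
    deg = net.degrees
    df = pd.DataFrame(
        {"factor": list(deg), "degree": list(deg.values())}
    ).sort_values(["degree", "factor"], ascending=[False, True], ignore_index=True)
    if rule == "top_k":
        if len(df) == 0:
            df["hub_flag"] = pd.Series(dtype=bool)
            return df
        # every factor tied with the k-th degree is flagged, all-or-none
        cutoff = df["degree"].iloc[min(k, len(df)) - 1]
        df["hub_flag"] = df["degree"] >= max(cutoff, 1)
    elif rule == "zscore":
        mu, sd = df["degree"].mean(), df["degree"].std(ddof=0)
        df["hub_flag"] = df["degree"] > mu + z * sd
    else:
        raise ValueError(f"unknown hub rule: {rule!r}")
    return df


def rank_hubs(
    net: DifferentialNetwork, rule: str = "top_k", k: int = 8, z: float = 2.0
) -> pd.DataFrame:
    """Rank factors by differential degree and flag hubs.

    ``top_k`` (default k=8) flags the k highest-degree factors, extending
    through ties and never flagging degree-0 factors; ``zscore`` flags
    degree > mean + z * SD.
    """
    if not net.edges:
        warnings.warn("empty differential network; hub report has no hubs")
    df = _hub_flags(net, rule, k, z)
    df["percent_inclusion"] = np.nan
    return df


def hub_consistency(
    X0,
    X1,
    lam: float,
    rounds: int = 100,
    fraction: float = 0.5,
    rule: str = "top_k",
    k: int = 8,
    z: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Percent of subsampling rounds in which each factor is called a hub.

    Repeats the whole network fit on ``rounds`` random subsamples of the
    bins (default half the genome, 100 rounds) and applies the hub rule to
    each refit. Rounds whose solver fails to converge are dropped from the
    denominator with a warning.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    A0 = np.asarray(getattr(X0, "X", X0), dtype=float)
    A1 = np.asarray(getattr(X1, "X", X1), dtype=float)
    full = build_differential_network(
        X0, X1, lam, tol=tol, max_iter=max_iter
    )
    report = _hub_flags(full, rule, k, z)
    hits = {f: 0 for f in full.factors}
    n_valid = 0
    for idx in subsample_bins(A0.shape[0], fraction, rounds, seed):
        sub = build_differential_network(
            A0[idx], A1[idx], lam, tol=tol, max_iter=max_iter
        )
        if sub.estimate is not None and not sub.estimate.converged:
            warnings.warn("non-converged subsample round excluded from percentages")
            continue
        n_valid += 1
        sub.factors = full.factors  # keep labels when raw arrays were passed
        flags = _hub_flags(sub, rule, k, z)
        for f in flags.loc[flags["hub_flag"], "factor"]:
            hits[f] += 1
    if n_valid == 0:
        raise RuntimeError("no subsampling round converged")
    report["percent_inclusion"] = [
        100.0 * hits[f] / n_valid for f in report["factor"]
    ]
    return report


def export_network(
    net: DifferentialNetwork, path: str | Path, format: str = "edge-list"
) -> Path:
    """Write the edge set as TSV (``edge-list``) or a Circos link table."""
    path = Path(path)
    rows = [
        (net.factors[i], net.factors[j], w) for i, j, w in net.edges
    ]
    if format == "edge-list":
        df = pd.DataFrame(rows, columns=["factor_i", "factor_j", "weight"])
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "circos-table":
        # Circos link format: one line per link end pair, no header
        with open(path, "w") as fh:
            for fi, fj, w in rows:
                fh.write(f"{fi}\t{fj}\t{w:.17g}\n")
    else:
        raise ValueError(f"unknown export format: {format!r}")
    return path


def read_network(
    path: str | Path, factors: list[str], lam: float = float("nan")
) -> DifferentialNetwork:
    """Read an ``edge-list`` TSV back into a DifferentialNetwork."""
    df = pd.read_csv(path, sep="\t")
    index = {f: i for i, f in enumerate(factors)}
    edges = [
        (
            min(index[r.factor_i], index[r.factor_j]),
            max(index[r.factor_i], index[r.factor_j]),
            float(r.weight),
        )
        for r in df.itertuples()
    ]
    return DifferentialNetwork(factors=list(factors), edges=edges, lambda_used=lam)
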