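"""Synthetic paired data with known precision-difference ground truth.

Two generators replace real ChIP-seq compendia during development and
testing:

* :func:`make_truth` / :func:`sample_paired` build a pair of latent
  Gaussian models whose precision matrices differ in a known sparse set of
  entries, then push samples through strictly increasing marginal
  transforms — a Gaussian copula mimicking the heavy-tailed, non-Gaussian
  distribution of binding signal. Rank-based estimators must be invariant
  to these transforms.
* :func:`generate_mini_genome` writes a toy genome (chrom.sizes, blacklist
  BED, per-factor peak BEDs and bedGraph tracks) whose binned signal
  matrix reproduces a :func:`sample_paired` draw, so the whole file
  pipeline can be exercised without any download.

Precision matrices use an Erdos–Renyi-style random support with diagonal
dominance, a standard controllable-sparsity construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "SyntheticTruth",
    "MiniGenomeSpec",
    "MiniGenome",
    "make_truth",
    "sample_paired",
    "generate_mini_genome",
]

TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "exp": lambda x: np.exp(x / 2.0),
    "cube": lambda x: x**3,
}


@dataclass
class SyntheticTruth:
    """Paired latent Gaussian models with a known sparse precision difference."""

    J: int
    mu0: np.ndarray
    mu1: np.ndarray
    Sigma0: np.ndarray
    Sigma1: np.ndarray
    Theta0: np.ndarray
    Theta1: np.ndarray
    DeltaTrue: np.ndarray
    edge_support: set[tuple[int, int]]
    transforms: tuple[list[str], list[str]]  # per-condition, per-factor names
    seed: int


@dataclass
class MiniGenomeSpec:
    """Parameters of the toy genome written by :func:`generate_mini_genome`."""

    chrom_sizes: dict[str, int]
    n_factors: int
    peak_density: float = 0.3
    signal_noise: float = 0.0
    blacklist_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be positive")
        for name in ("peak_density", "blacklist_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.signal_noise < 0:
            raise ValueError("signal_noise must be non-negative")


@dataclass
class MiniGenome:
    """File bundle plus the exact matrices the pipeline should recover."""

    root: Path
    manifest: dict
    X0: np.ndarray
    X1: np.ndarray
    factors: list[str] = field(default_factory=list)


def _random_pairs(rng: np.random.Generator, J: int, k: int, exclude=frozenset()):
    all_pairs = [
        (i, j) for i in range(J) for j in range(i + 1, J) if (i, j) not in exclude
    ]
    if k > len(all_pairs):
        raise ValueError(f"requested {k} pairs but only {len(all_pairs)} available")
    idx = rng.choice(len(all_pairs), size=k, replace=False)
    return [all_pairs[i] for i in sorted(idx)]


def _cholesky_ok(A: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(A)
        return True
    except np.linalg.LinAlgError:
        return False


def make_truth(
    J: int,
    n_shared_edges: int,
    n_diff_edges: int,
    effect_size: float,
    seed: int,
    transform_family: str = "default",
) -> SyntheticTruth:
    """Build paired precision matrices differing in ``n_diff_edges`` entries.

    Theta0 gets ``n_shared_edges`` random off-diagonal entries (magnitude
    0.2–0.4, random sign); Theta1 perturbs ``n_diff_edges`` further random
    pairs by +/- ``effect_size``. A common diagonal large enough for strict
    diagonal dominance of both matrices guarantees positive definiteness
    and keeps the true difference supported exactly on the perturbed pairs.

    ``transform_family`` is ``"default"`` (exponential and cubic maps
    alternating by column, strongly non-Gaussian) or ``"identity"``.
    """
    if J < 2:
        raise ValueError("J must be >= 2")
    if n_diff_edges > J * (J - 1) // 2:
        raise ValueError("n_diff_edges exceeds the number of unordered pairs")
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    base = np.zeros((J, J))
    shared = _random_pairs(rng, J, n_shared_edges)
    for i, j in shared:
        v = rng.uniform(0.2, 0.4) * rng.choice([-1.0, 1.0])
        base[i, j] = base[j, i] = v

    pert = np.zeros((J, J))
    diff = _random_pairs(rng, J, n_diff_edges, exclude=frozenset(shared))
    for i, j in diff:
        v = effect_size * rng.choice([-1.0, 1.0])
        pert[i, j] = pert[j, i] = v

    off0, off1 = base, base + pert
    # common diagonal: strict dominance for both conditions
    row_max = np.maximum(
        np.abs(off0).sum(axis=1), np.abs(off1).sum(axis=1)
    ).max()
    d = 1.0 + 1.25 * row_max
    Theta0 = off0 + d * np.eye(J)
    Theta1 = off1 + d * np.eye(J)
    for _ in range(50):
        if _cholesky_ok(Theta0) and _cholesky_ok(Theta1):
            break
        Theta0 += 0.1 * np.eye(J)
        Theta1 += 0.1 * np.eye(J)
    else:
        raise RuntimeError(
            f"could not reach positive definiteness (J={J}, "
            f"shared={n_shared_edges}, diff={n_diff_edges}, "
            f"effect={effect_size}, seed={seed})"
        )

    Sigma0 = np.linalg.inv(Theta0)
    Sigma1 = np.linalg.inv(Theta1)
    DeltaTrue = Theta1 - Theta0
    support = {(i, j) for i, j in zip(*np.triu_indices(J, k=1)) if DeltaTrue[i, j] != 0}
    if transform_family == "default":
        names = ["exp" if j % 2 == 0 else "cube" for j in range(J)]
    elif transform_family == "identity":
        names = ["identity"] * J
    else:
        raise ValueError(f"unknown transform family: {transform_family!r}")
    return SyntheticTruth(
        J=J,
        mu0=np.zeros(J),
        mu1=np.zeros(J),
        Sigma0=Sigma0,
        Sigma1=Sigma1,
        Theta0=Theta0,
        Theta1=Theta1,
        DeltaTrue=DeltaTrue,
        edge_support={(int(i), int(j)) for i, j in support},
        transforms=(list(names), list(names)),
        seed=seed,
    )


def sample_paired(
    truth: SyntheticTruth, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n observations per condition and apply the marginal transforms."""
    if n < 2:
        raise ValueError("n must be >= 2")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(2)
    out = []
    for d, (mu, Sigma, stream) in enumerate(
        [(truth.mu0, truth.Sigma0, streams[0]), (truth.mu1, truth.Sigma1, streams[1])]
    ):
        rng = np.random.default_rng(stream)
        L = np.linalg.cholesky(Sigma)
        Z = rng.standard_normal((n, truth.J))
        X = mu + Z @ L.T
        for j, name in enumerate(truth.transforms[d]):
            X[:, j] = TRANSFORMS[name](X[:, j])
        out.append(X)
    return out[0], out[1]


def _runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs [first, last] within a sorted integer array."""
    if len(indices) == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(indices) - 1]])
    return [(int(indices[a]), int(indices[b])) for a, b in zip(starts, ends)]


def generate_mini_genome(
    spec: MiniGenomeSpec,
    truth: SyntheticTruth,
    outdir: str | Path,
    bin_width: int = 100,
) -> MiniGenome:
    """Write a toy genome bundle whose binned matrix matches a paired draw.

    Layout under ``outdir``: ``chrom.sizes``, ``blacklist.bed``,
    ``peaks/cond{d}_{factor}.bed``, ``signal/cond{d}_{factor}.bedGraph``
    and ``manifest.json`` recording the expected bin count after each
    filter stage. Peaks and blacklist are placed at bin granularity so the
    expected counts are exact; signal values are constant within each bin,
    so with ``signal_noise=0`` the pipeline reproduces the sampled
    matrices exactly.
    """
    if truth.J != spec.n_factors:
        raise ValueError("truth.J must equal spec.n_factors")
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "signal").mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(spec.seed)
    rng_bl, rng_pk, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    # global bin table (chrom, start, end), truncated last bin per chromosome
    chroms, starts, ends = [], [], []
    for chrom, size in spec.chrom_sizes.items():
        edges = list(range(0, size, bin_width)) + [size]
        for a, b in zip(edges[:-1], edges[1:]):
            chroms.append(chrom)
            starts.append(a)
            ends.append(b)
    chroms = np.array(chroms, dtype=object)
    starts = np.array(starts, dtype=np.int64)
    ends = np.array(ends, dtype=np.int64)
    n_raw = len(starts)

    n_black = int(round(spec.blacklist_fraction * n_raw))
    black_idx = np.sort(rng_bl.choice(n_raw, size=n_black, replace=False))
    usable = np.setdiff1d(np.arange(n_raw), black_idx)

    factors = [f"F{j:02d}" for j in range(spec.n_factors)]
    # per factor/condition peak bins; guarantee every factor keeps >= 1 bin
    peak_bins: dict[tuple[int, str], np.ndarray] = {}
    for d in (0, 1):
        for f_i, f in enumerate(factors):
            mask = rng_pk.random(len(usable)) < spec.peak_density
            if not mask.any():
                mask[rng_pk.integers(len(usable))] = True
            peak_bins[(d, f)] = usable[mask]
    kept = np.sort(
        np.unique(np.concatenate([v for v in peak_bins.values()]))
    )
    n_kept = len(kept)
    if n_kept < 2:
        raise RuntimeError("mini genome kept fewer than 2 bins; raise peak_density")

    X0, X1 = sample_paired(truth, n_kept, spec.seed)
    if spec.signal_noise > 0:
        X0 = X0 + rng_noise.normal(0.0, spec.signal_noise, X0.shape)
        X1 = X1 + rng_noise.normal(0.0, spec.signal_noise, X1.shape)

    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in spec.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    def write_bed(path: Path, idx: np.ndarray) -> None:
        with open(path, "w") as fh:
            # merge adjacent bins into single intervals, per chromosome
            for chrom in dict.fromkeys(chroms[idx]) if len(idx) else []:
                sub = idx[chroms[idx] == chrom]
                for a, b in _runs(sub):
                    fh.write(f"{chrom}\t{starts[a]}\t{ends[b]}\n")

    write_bed(outdir / "blacklist.bed", black_idx)

    kept_pos = {int(b): row for row, b in enumerate(kept)}
    for (d, f), idx in peak_bins.items():
        write_bed(outdir / "peaks" / f"cond{d}_{f}.bed", idx)
    for d, X in ((0, X0), (1, X1)):
        for f_i, f in enumerate(factors):
            with open(outdir / "signal" / f"cond{d}_{f}.bedGraph", "w") as fh:
                for b in kept:
                    v = X[kept_pos[int(b)], f_i]
                    fh.write(f"{chroms[b]}\t{starts[b]}\t{ends[b]}\t{v:.17g}\n")

    manifest = {
        "bin_width": bin_width,
        "n_factors": spec.n_factors,
        "factors": factors,
        "seed": spec.seed,
        "raw_bins": int(n_raw),
        "blacklisted_bins": int(n_black),
        "post_blacklist_bins": int(n_raw - n_black),
        "post_peak_filter_bins": int(n_kept),
        "signal_noise": spec.signal_noise,
        "files": {
            "chrom_sizes": "chrom.sizes",
            "blacklist": "blacklist.bed",
            "peaks": sorted(f"peaks/cond{d}_{f}.bed" for d, f in peak_bins),
            "signal": sorted(
                f"signal/cond{d}_{f}.bedGraph" for d in (0, 1) for f in factors
            ),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return MiniGenome(root=outdir, manifest=manifest, X0=X0, X1=X1, factors=factors)
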