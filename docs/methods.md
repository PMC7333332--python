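# Methods

## Signal pipeline

The unit of observation is a 100 bp genomic bin (`bin_width` configurable).
`make_bins` tiles each chromosome left to right, truncating the final bin
at the chromosome end. Two filters follow, both using a ≥ 1 bp overlap
criterion (the BEDTools default): `filter_blacklist` drops bins touching
any gap/low-mappability interval, and `filter_by_peaks` keeps only bins
touching at least one peak from the pooled peak calls of **all** factors in
**both** conditions — bins outside every peak carry no usable co-binding
information and would otherwise dominate the rank statistics with zeros.
`aggregate_signal` scores each bin with the base-pair-weighted mean of the
fold-change track over the bin, counting uncovered bases as 0 (fold-change
tracks are defined where reads exist; absence is treated as no
enrichment). Replicates and multi-lab experiments are combined by a simple
unweighted mean per factor. All coordinates are 0-based half-open
throughout; restricting the analysis to autosomes is the caller's choice
of `chrom.sizes`, not hard-coded.

Two peak-level statistics support the interpretation of rewired factors:
`jaccard_statistic` (base-pair intersection over union after per-set
merging; undefined — an error, not 0 — when the union is empty) and
`tss_proximal_fraction` (share of peaks whose nearest base is within a 5 kb
window of a single-base TSS anchor, distance 0 on overlap). Whether a
caller reports the Jaccard similarity or its complement as a "distance" is
left to the caller.

## Nonparanormal covariance surrogates

Binned ChIP-seq signal is zero-inflated and heavy-tailed; a Gaussian
likelihood on the raw columns is untenable. We therefore assume a Gaussian
copula — for each condition there exist strictly increasing marginal maps
making the columns jointly Gaussian — and estimate the latent correlation
without ever estimating those maps: Spearman's ρ̂ (average ranks for ties,
the standard definition; ties are pervasive in zero-inflated signal) is
mapped through Ŝᵢⱼ = 2 sin(π ρ̂ᵢⱼ / 6) off the diagonal, 1 on it. A constant
column has no rank correlation and raises an error naming the factor.

The sine transform applied entrywise need not yield a positive
semidefinite matrix. `nearest_psd` eigendecomposes, clips eigenvalues
below a floor (default 1e−4), reconstructs, and rescales the diagonal back
to exactly 1; because the rescale can push the smallest eigenvalue
slightly under the floor again, clip-and-rescale iterates until the floor
holds. The floor keeps the surrogate a well-conditioned correlation-like
matrix, which the D-trace solver's linear algebra assumes.

## Penalized D-trace estimation of Δ

The loss is used exactly as stated above, with the ℓ1 penalty covering
every entry of Δ including the diagonal (the objective's double sum runs
over all i, j); `penalize_diagonal=False` is available for the variant
that leaves the diagonal unpenalized.

The solver is two-block ADMM on the splitting Δ = Z. The Δ-step minimizes
the smooth quadratic plus the proximal term exactly by solving the
symmetrized Sylvester system ½(Ŝ⁽¹⁾ΔŜ⁽⁰⁾ + Ŝ⁽⁰⁾ΔŜ⁽¹⁾) + ρΔ = C in vec
form: the operator ½(Ŝ⁽⁰⁾⊗Ŝ⁽¹⁾ + Ŝ⁽¹⁾⊗Ŝ⁽⁰⁾) + ρI is symmetric positive
definite and is Cholesky-factored once, then reused every iteration
(refactored only when ρ changes). This is O(J⁶) once plus O(J⁴) per
iteration — deliberately chosen for exactness and robustness at the
dozens-of-factors scale this package targets, rather than asymptotic
scalability. The Z-step is entrywise soft-thresholding at λ/ρ; both blocks
are symmetrized every iteration (the printed loss does not itself force
symmetry). ρ starts at 1 and is self-tuned by standard residual balancing
(×2 or ÷2 when primal and dual residuals diverge by more than 10×, with
the scaled dual variable rescaled accordingly).

Convergence is declared on the KKT stationarity residual of the sparse
iterate Z (checked every 5 iterations): zero entries must satisfy
|∇| ≤ λ, nonzero entries ∇ + λ·sign(Z) = 0, within `tol` (default 1e−6,
`max_iter` 2000; non-convergence returns the iterate flagged with a
warning). The returned Δ is the soft-thresholded iterate, so its zeros are
exact and the edge set {(i, j, |Δᵢⱼ|) : i < j, Δᵢⱼ ≠ 0} needs no epsilon
threshold. Two analytic shortcuts are worth noting: identical inputs make
0 a KKT point, returned immediately (this guarantees the exact-null
property), and for diagonal surrogates the problem separates into
entrywise soft-thresholds — both serve as solver oracles in the tests,
alongside a generic derivative-free minimizer on small instances.

## StARS penalty selection

Defaults mirror the intended study settings: S = 100 subsamples of half
the bins drawn without replacement, a 12-point log-spaced λ grid on
[0.01, 10] (the grid endpoints span essentially-empty to essentially-full
networks; the number of points is configurable), and instability threshold
β = 0.005. For every (subsample, λ) cell the covariance surrogates are
re-estimated on the subsampled rows and the D-trace problem re-solved; the
edge indicators ψ are aggregated into selection frequencies θ,
disagreements ξ = 2θ(1−θ), and the instability D̂(Λ) = Σ_{i<j} ξᵢⱼ / C(J,2).
D̂ is made monotone by a running maximum along increasing Λ = 1/λ and the
selected λ is the largest Λ (densest network) with D̄ ≤ β; if no grid point
qualifies, the sparsest grid λ is returned with a warning. Cells whose
solver run failed to converge are excluded from the frequency denominators
with a warning.

Every (s, λ) fit is cold-started and independent, so results are invariant
to execution order and bit-identical to a naive loop over all cells; this
costs some speed relative to warm-starting along the grid but makes the
computation trivially parallelizable and exactly reproducible.

## Hubs and consistency

Factors are ranked by degree in the differential network (number of
gained/lost partners), ties broken lexicographically. Because no single
operational hub definition is canonical, two rules are provided: `top_k`
(default k = 8, extended through ties, never flagging degree-0 factors)
and `zscore` (degree > mean + z·SD). `hub_consistency` repeats the entire
fit on random half-subsamples of the bins (default 100 rounds) and reports
the percentage of rounds each factor is called a hub. Edge fractions are
reported under both the C(J,2) denominator (used by the instability
formula) and the J²/2 convention, since both appear in practice.

## Synthetic ground truth

`make_truth` builds Θ⁽⁰⁾ with an Erdős–Rényi random off-diagonal support
(`n_shared_edges` entries, magnitudes uniform on [0.2, 0.4], random sign)
and Θ⁽¹⁾ by perturbing `n_diff_edges` further random pairs by
±`effect_size`; a common diagonal 1 + 1.25·(largest off-diagonal row sum)
enforces strict diagonal dominance of both matrices, so both are SPD by
construction (a diagonal-loading fallback guards the degenerate case) and
the true Δ is supported exactly on the perturbed pairs. Samples are latent
Gaussian draws pushed through strictly increasing marginals — exp(x/2) and
x³ alternating by column by default — giving strongly non-Gaussian data
whose rank structure is untouched; `transform_family="identity"` disables
this. A single integer seed expands into independent per-stream substates,
so every artifact is reproducible bit for bit.

`generate_mini_genome` emits a complete toy file bundle (chrom.sizes,
blacklist BED, per-factor/per-condition peak BEDs, bedGraph tracks, JSON
manifest). Blacklist and peaks are placed at bin granularity and signal is
constant within each bin, so the expected bin count after every filter
stage is exact and the rebuilt matrix equals the sampled one up to the
v·w/w floating-point arithmetic of bin averaging (exact zeros of noise are
available with `signal_noise=0`). The generator emulates file-format and
bookkeeping reality, not biological reality: no read-level noise, no peak
caller, no replicate structure beyond the Gaussian-copula marginals —
passing pipeline tests therefore validates the plumbing and the
statistics, not robustness to peak-calling artifacts.

## Problem sizes and numerical defaults

The bundled study runs at desk scale: J = 15 factors, n = 3 000 bins, 10
shared plus 5 differential edges of magnitude 0.6, 10 replicate seeds,
S = 100 subsamples (support recovery); J = 5, n = 5 000, 20 seeds
(covariance recovery); J = 6, 50 rounds (hub consistency). Solver
tolerance 1e−6 on the KKT residual (tightened to 1e−12 when checking
closed forms), PSD floor 1e−4, λ grid as above.

## Known limitations

* **β = 0.5% is calibrated for very large bin counts.** The stability
  threshold is meaningful when subsample-to-subsample noise in the rank
  correlations is tiny (at a million-plus bins, entrywise noise is
  ~1e−3). At thousands of bins the noise is ~0.03, each true edge's
  selection threshold varies across subsamples, and the instability
  profile shows a bump of D̂ ≈ 0.01–0.02 in the λ region where true edges
  first enter. The monotone envelope then blocks every denser network and
  the default selection returns an empty or near-empty graph even when
  some grid λ recovers the planted edges perfectly — visible in the
  bundled acceptance run, where the best-grid F1 is 1.0 but the F1 at the
  selected λ is 0. The classic StARS default β = 0.05 does not exhibit
  this at these sizes; users working with few bins should treat β as a
  quantity to scale with n rather than a universal constant. The package
  keeps 0.005 as the default deliberately and exposes `beta` everywhere.
* The solver's Kronecker-based Δ-step is exact but O(J⁶) in memory/time at
  factorization; beyond a few hundred factors an iterative linear solver
  would be needed.
* Rank-based surrogates identify the latent **correlation**, not
  covariance; Δ is therefore a difference of correlation-scale precision
  matrices. When the two conditions' marginal variances differ strongly,
  entries outside the true precision-difference support can leak small
  nonzero values; the ℓ1 penalty suppresses these at moderate λ, and the
  effect was not limiting at the bundled effect sizes.
* The Jaccard and TSS statistics describe peak geometry only; no
  statistical test is attached to them.
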