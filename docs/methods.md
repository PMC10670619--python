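# Methods

This note records the model as implemented, the numerical choices, what the
synthetic generators do and do not emulate, and the design decisions taken
where the mathematics left genuine freedom.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and likelihood

Links are undirected, binary, without self-ties.  For dyad {i,j} at period t
the latent index is

    index_ij,t = Σ_{p=1..q} α_p C_ij,t−p + β′X_ij,t + D_ij,t + A_ij

and `C_ij,t = 1{index > ε_ij,t}` with standard-logistic shocks, i.e. a
conditionally Bernoulli link with `p = exp(index)/(1+exp(index))`.  The four
channels and their containers:

* **Persistence** `α ∈ R^q`, ‖α‖ < 1 enforced at simulation time (estimates
  may leave the region and remain representable).  Pre-sample lags are zero
  matrices unless supplied.
* **Homophily** `β` on a symmetric pair transform of node covariates;
  default elementwise product `X_i ⊙ X_j` (the benchmark design's
  `X_i X_j′β` form), absolute difference and Euclidean distance selectable.
* **Triadic memory** `D_ij,t`, cumulative shared-partner counts.  The
  printed definition sums periods t′ ≤ t, which would let `C_t` enter its
  own formation rule; the default is the predetermined convention t′ ≤ t−1
  (`strict_past`), with `inclusive` retained behind a flag for evaluation of
  a given panel.  Simulation under `inclusive` is refused as circular.
  `D` enters with coefficient 1, so on dense panels it saturates link
  probabilities quickly; the benchmark DGP (below) omits it.
* **Heterogeneity** node effects `A_i` mapped to a pair effect by a
  symmetric rule: `additive` (`A_i + A_j`) or `absolute_difference`
  (`|A_i − A_j|`).

Per-dyad log-likelihood `l = c log p + (1−c) log(1−p)`; probabilities are
clipped to `[κ, 1−κ]`, κ = 1e−12, inside likelihood computations only —
never applied to simulated draws.  Both the raw sum over i<j, t and a
`(NT)^{−1/2}`-scaled version are reported; scaling does not move the argmax.

## Estimation

`fit_mle` maximizes the joint log-likelihood over `(θ, a_N)` under the
location normalization `ι′a_N = 0`, imposed by optimizing the first N−1
effects with `A_N = −Σ_{k<N} A_k`.  With the additive pair rule the index is
linear in all parameters, so the objective is concave; the solver is damped
Newton (analytic gradient and Hessian, halving line search, sup-norm score
tolerance 1e−6, max 60 iterations) with a least-squares fallback when the
Hessian solve fails.  The `absolute_difference` rule is not concave in
`a_N` and is deliberately not estimable; it exists for simulation fidelity.

*Separation.*  A node whose every usable dyad-period outcome is constant
(all 0 or all 1) pushes its effect to ±∞.  Such nodes are flagged in
`diagnostics["separation_nodes"]`; an optional ridge (concave penalty
`−ρ/2‖φ‖²`) restores convergence.  Non-convergence is flagged, never raised.

*Inference.*  Standard errors come from the observed profile information in
θ, the Schur complement `H_θθ − H_θa H_aa^{−1} H_aθ` of the negative Hessian
at the optimum — equivalently the negative curvature of the profile
log-likelihood, which the tests verify against a finite-difference oracle in
the one-parameter case.  A near-singular effects block raises with its
condition number.  In this model each node effect is informed by (N−1)T
observations, so the incidental-parameter bias is an order smaller than in
scalar panels; the measured 95% CI coverage at N=40, T=10 sits inside
[0.90, 0.99] without correction.  A split-panel jackknife over the time
dimension (`2θ̂ − mean of half-panel estimates`, each half keeping its own
lags) is provided for settings where the dynamic-panel bias matters.

*Kernel estimators.*  The dyadic contrast

    δ̂_ij(x) = Σ_{l,t} (C_il,t − C_jl,t) K̃(x − X_l,t)

uses self-normalized weights (they sum to one over all partner-period pairs)
so that δ̂ is an average and converges to the population contrast; a printed
variant with an extra 1/(NT) prefactor would vanish identically and is not
used.  K defaults to Epanechnikov (compact support), bandwidth
`1.06·sd(X)·N^{−1/5}`; a truncated Gaussian is available.  Since the weights
do not depend on the dyad, `δ̂_ij(x) = v_i(x) − v_j(x)`, giving antisymmetry
by construction and an O(N² + NT) all-pairs computation.

The kernel fixed-effect estimator is

    Â_l(θ) = (1/N) · [Σ_{i<j, l∉{i,j}} w_ij s_ij(θ)] / [Σ w_ij],
    w_ij = L(δ̂_ij(x_l)/σ_N),  L Gaussian,  σ_N by the same bandwidth rule
    on the δ̂ values.

The scalar collapse `s_ij(θ)` is fixed as the symmetrized contraction
`½[(ι′X_il,t)(X_jl,t′β) + (ι′X_jl,t)(X_il,t′β)]` averaged over t, using the
covariate (β) block of θ only — the persistence block multiplies lagged
links, not covariates, so no dimensionally consistent reading can involve
it.  Readings that contract the full θ against the d×d outer product were
rejected as dimensionally inconsistent whenever q + dim(β) ≠ dim(β).  Under
this (or any covariate-based) construction the estimand is the
covariate-predictable component of heterogeneity: effects orthogonal to the
covariates are invisible.  The recovery experiment therefore generates
`A_i = 0.8(x_i² − mean) + noise` with noise at 30% of the signal's standard
deviation — correlated heterogeneity, which is the setting the estimator is
for — and tracks the correlation between `(Â_l)` and `(A_l)`.

## Entropy

Each dyad-period contributes `ℓ̃ = exp(l) = p^c(1−p)^{1−c} ∈ (0,1)`; the
entropy is `H(C) = Σ −ℓ̃ log ℓ̃`, equal to the series `Σ_k ℓ̃(1−ℓ̃)^k/k`
(the identity `−log x = Σ_k (1−x)^k/k`).  The series is truncated at the
smallest k with worst-case tail `(1−ℓ̃)^k/k < 1e−10` (capped at 2·10⁵), and
the agreement of the two forms is the module's central oracle test.  Natural
log is the default; the reference entropies take a base argument.  Both the
raw sum and the per-dyad-period normalization (bounded by 1/e) are reported
because published comparison tables do not state theirs.

*Bounds.*  Both topology bounds are evaluated verbatim with a component
breakdown.  The upper bound's chain constant `K = Σ log[z/(1+z)²]
= Σ log[p(1−p)]` is strictly negative, and the chained-dyad residual
`ρ_t = Σ_{k<l} ℓ̃_kl − Σ_k [ℓ̃_{k,k+1} + ℓ̃_{kN}]` is negative on homogeneous
instances (at p = 0.5, N = 3: ρ = −0.5 by hand), so the printed expression
usually leaves the domain of the logarithm.  The implementation reports the
components and a `defined` flag rather than a fabricated number; bound
violations are logged diagnostics, never assertions.  K spans all periods
while ρ is per-period; the bound is evaluated per period with the global K
and summed.  The lower bound normalizes average outcome likelihoods over a
later (`t > lag`) and an earlier (`t ≤ T−lag`) window into dyad
distributions ρ_F, ρ_F′ (each summing to 1) and evaluates
`−Σ ρ_F log ρ_F′ − (1/ln 2)Σ(ρ_F² − ρ_F ρ_F′)/ρ_F′`; at lag 0 it reduces
exactly to the Shannon entropy of the dyad distribution.

*Reference measures.*  Erdős–Rényi entropy: `C(N,2)` independent-edge binary
entropies at the given density.  Degree-Shannon entropy: `−Σ_d q_d log q_d`
over the final-period empirical degree distribution.  These are the
conventional definitions; the published comparison-table values use
unstated normalizations and are not reproduction targets.

## Generators

*Benchmark panel DGP* (`dgp_section4`): T = 15, q = 10, β = 0.5, parity
covariates `X_i = 1 − 2·1{i even}` (1-based), effects
`A_i = ((N−i)/(N−1)) log N` with pair rule `|A_i − A_j|`, α drawn uniform on
(−1,1)^q and rescaled to norm 0.9 (the α law is unstated; the uniform cube
is the simplest reproducible choice meeting ‖α‖ < 1).  The displayed
benchmark rule carries no shared-partner term, so the panel is simulated
without memory.  One seeded uniform stream drives all logistic draws by
inverse CDF, one draw per unordered pair.

*Estimation DGP* (tests and acceptance): additive effects drawn uniform on
(−0.5, 0.5) and centered, ±1 covariates under the product transform,
θ = (0.3, 0.5), q = 1, memory off — probabilities stay in roughly
(0.2, 0.8), so every dyad is informative.  Problem sizes: recovery at
(N,T) = (40,10) vs (80,20) over 20 seeds (ideal error ratio 0.5, accepted
within a factor of 2); coverage at (40,10) over 200 replicates.

*Baselines*: G(N,p) with one Bernoulli draw per pair; preferential
attachment with m = 5 links per arrival from a seed graph of density 0.5
(standard preferential attachment has no per-link probability; the stated
"connection probability" is read as the seed-graph density).  A tiny weight
floor keeps zero-degree nodes reachable when the sparse seed graph has fewer
than m positive-degree nodes.

*OTU tables*: log-normal base abundances (σ = 2), per-taxon-per-sample
log-normal shifts (σ = 0.5), multinomial sampling at log-normally varying
depth (mean 3·10⁴), optional planted co-abundance blocks sharing a
per-sample log-normal factor, and an exact count of global singletons
(defaults 3831 taxa / 19 samples / 1779 singletons, matching the reference
18S rRNA survey's shape; tests use 120 taxa for speed).  The generator
emulates sparsity, compositionality, taxonomy strings and block
co-abundance; it does not emulate phylogenetic correlation, true ecological
interaction dynamics, or sequencing error, so passing tests demonstrate
pipeline correctness and detectability of planted structure, not field
performance on real surveys.

## Application pipeline

Samples play the role of observation periods and per-sample relative
abundances are the node covariates.  After removing global singletons
(total count exactly 1 across all samples), edge presence is gated by a
score — fitted pairwise probabilities when available, otherwise the absolute
centered-association (Pearson) value — thresholded at the across-pair
median + 1 MAD (configurable absolute cutoff); edge signs always come from
the centered association, with conflicts resolved by the larger absolute
value.  Sign mismatches on a shared edge count as one false positive and one
false negative, since the reference definition classifies only same-sign
agreement; consequently TP+FP+FN+TN exceeds C(n,2) by exactly the number of
mismatches, and the tests check that identity.  Undefined ratios (zero
denominators) surface as NaN rather than errors.  Louvain community
detection is seeded; partition significance uses the degree-preserving
double-edge-swap null (10·|E| swaps per replicate, add-one p-value), chosen
over Erdős–Rényi resampling to isolate mesoscale structure from the degree
sequence.  The degree "randomness" test is chi-square against a Poisson law
with ML mean, bins pooled to expected counts ≥ 5, dof = bins − 2; a Monte
Carlo variant against matched G(N,p) graphs is available behind a flag.

## Known limitations

* The upper entropy bound is reported as printed and is typically undefined
  on realistic instances (see above); it is an audit object, not a usable
  bound.
* `fit_mle` stores the full dense design; above a few hundred nodes the
  effects block should be profiled out blockwise, which is not implemented.
* The kernel fixed-effect estimator cannot recover heterogeneity orthogonal
  to covariates (inherent to its construction, not a bug).
* The co-occurrence edge-sign source for model-gated networks is a package
  convention (centered association), as no canonical definition exists.
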