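# latentlink

Dynamic latent-index network formation: simulation, conditional
maximum-likelihood estimation with node fixed effects, a Shannon-type entropy
of dynamic networks, and a microbial co-occurrence evaluation pipeline.

## The problem

Many observed networks — microbial co-occurrence networks above all — evolve
over time and are shaped by three forces at once: **persistence** (a dyad that
was linked tends to stay linked), **homophily** (similar nodes link more), and
**unobserved heterogeneity** (some nodes simply link more, for reasons no
measured covariate captures).  `latentlink` implements a dyadic
link-formation model that carries all three, together with the estimation
theory needed to recover its parameters and an information-theoretic summary
of how predictable the resulting network dynamics are.

## The model

For an undirected binary panel `C_{ij,t}` on `N` nodes over `T` periods,
links form by the latent-index rule

    C_ij,t = 1{ Σ_{p=1..q} α_p C_ij,t−p + β′X_ij,t + D_ij,t + A_ij − ε_ij,t > 0 }

with i.i.d. standard-logistic shocks `ε_ij,t`, so conditionally on history

    p_ij,t = z_ij,t / (1 + z_ij,t),   z_ij,t = exp(index_ij,t).

* `α` (with ‖α‖ < 1) weights the dyad's own `q` lagged links — persistence;
* `β` acts on a symmetric transform `X_ij,t` of the two node covariate
  vectors (elementwise product by default) — homophily;
* `D_ij,t` counts the common neighbours the dyad accumulated in the past —
  a triadic-closure (shared partner) channel;
* `A_ij` is built from node effects `A_1..A_N` (additive `A_i + A_j` for
  estimation; `|A_i − A_j|` in the benchmark simulation design).

Estimation is joint conditional MLE of `(θ, a_N)`, `θ = (α, β)`, under the
normalization `Σ_i A_i = 0`.  The objective is concave, maximized by damped
Newton with analytic derivatives; standard errors come from the observed
profile information (Schur complement in `θ`), and a split-panel jackknife
over time is available for bias correction.  Kernel estimators provide a
second route to heterogeneity: the dyadic contrast
`δ̂_ij(x) = Σ_{l,t} (C_il,t − C_jl,t) K̃(x − X_l,t)` and a kernel-weighted
homophily average `Â_l(θ)` that recovers the covariate-predictable component
of `A_l`.

Each realized dyad-period carries the likelihood mass
`ℓ̃_ij,t = p^c (1−p)^{1−c} ∈ (0,1)`, and the **dynamic-network entropy** is

    H(C) = Σ_{i<j,t} −ℓ̃ log ℓ̃ = Σ_{i<j,t} Σ_{k≥1} ℓ̃ (1−ℓ̃)^k / k,

zero when every outcome was perfectly predicted and at most `1/e` per
dyad-period.  Closed-form topology bounds, an Erdős–Rényi reference entropy
and the degree-distribution Shannon entropy are provided for comparison, as
are Erdős–Rényi / Barabási–Albert baseline generators, a Poisson
goodness-of-fit "randomness" test on degree sequences, and a
degree-preserving permutation test of partition modularity.

The application layer turns a taxon×sample OTU count table into a signed
co-occurrence network (after removing global singletons), detects Louvain
communities, and scores the network against a reference interaction network
by sensitivity / specificity / precision / F1 and Jaccard overlap.

## Worked example

```bash
python examples/fit_panel.py
```

```
converged in 5 Newton steps, loglik = -15782.2
alpha_1 (persistence)  true  0.30  estimate  0.304 +/- 0.019
beta (homophily)       true  0.50  estimate  0.504 +/- 0.014
node effects: sum = 0.00e+00 (normalized), corr with truth = 0.974
split-panel jackknife estimate: [0.302 0.5  ] (removes the leading short-panel bias)
```

A 60-node, 15-period panel is simulated with known persistence 0.3 and
homophily 0.5; the joint MLE recovers both inside one standard error, the
node effects are estimated up to the sum-zero normalization (correlation
0.97 with the truth), and the jackknife leaves the point estimates nearly
unchanged — the short-panel bias is small at this size.

Other capabilities, one script each, under `examples/`:
`simulate_and_entropy.py` (benchmark DGP and H(C) against the reference
entropies), `kernel_heterogeneity.py` (kernel recovery of node effects),
`cooccurrence_pipeline.py` (planted OTU table → communities → edge
recovery), `benchmark_tables.py` (replicated generator comparison).  A thin
CLI mirrors the pipeline: `latentlink simulate | fit | entropy | stats |
communities | benchmark`.

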