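# Methods

## Dynamics model

Abundance profiles are propagated with the generalized Lotka-Volterra
equations in discrete form: each observed time point is treated as one unit
step (`dt = 1` by default; real timestamp spacings are ignored for stepping,
which matches the view of each time point as one sample of the temporal
profile). After every step, raw abundances are clamped at zero — relative
abundances cannot be negative — and renormalised to sum to one, so the state
remains a composition throughout. No saturation / carrying-capacity term is
included: communities are not assumed to have known carrying capacities.

The interaction convention is `A[i, j]` = per-unit-abundance effect of OTU
*j* on the growth of OTU *i* (the acting OTU indexes the column). This is
the orientation implied by the update's summation `Σ_j A_ij x_j` and is used
consistently by the simulator, the optimiser and every file writer; the
edge-list format states it in a header comment because the opposite prose
convention is common.

## Community dynamics prior

Ground-truth matrices (for simulation) and the reference distribution of
interaction strengths (for the inference penalty) come from
`A = (N H) ∘ G · s` with

| parameter | meaning | default | rationale |
|---|---|---|---|
| `n` | number of OTUs | 10 | standard benchmark community size |
| `sigma` | std of nominal strengths `N_ij` | 1.0 | unit-variance nominal scale |
| `alpha` | power-law exponent of `H_ii` | 0.6 | mid-range heterogeneity |
| `p` | Erdős–Rényi edge probability | 0.4 | moderately sparse network |
| `s` | global scale | 0.1 | keeps per-step composition changes moderate at n=10 |
| `h_bounds` | power-law truncation | (1, 10) | see below |
| growth prior | `r_i ~ Uniform(0,1)` | — | positive, bounded growth |

The heterogeneity distribution is realised as a *truncated* power law with
density ∝ `x^(−α)` on `h_bounds`, sampled by inverse CDF: an unbounded
Pareto with α ≤ 1 has no mean, so truncation is required for finite
simulations. The truncation upper bound is 10: together with `sigma = 1` and
`s = 0.1` this puts the variance of nonzero interaction strengths near 0.3,
i.e. coefficients of magnitude ≲ 1 and inferred-vs-truth matrix MSEs of
order 0.1–1 — the regime in which the error metrics of this kind of
benchmark are typically reported. A wider support (e.g. `[1, 100]`) inflates
nonzero-strength variance to ~20 and pushes every MSE an order of magnitude
higher; the bounds are config-exposed for users who want heavier tails.
`H` scales columns (`A_ij ∝ N_ij · H_jj`): the *acting* OTU's influence
level is modulated, modelling a minority of highly influential taxa; a
config flag switches to row-wise scaling.

Initial abundances are `Uniform(0, 1)` draws normalised to a composition.

## Inference

The genetic algorithm encodes a candidate network as a chromosome of
`round(sparsity_prior · L²)` genes — unique (row, col) positions with real
values — plus `L` growth genes. Growth rates are inferred as part of the
chromosome by default; they can instead be fixed (`fixed_growth`) when known.

Fitness (minimised) is `f1 + λ·f2`:

* `f1` — mean Bray-Curtis dissimilarity between the observed profile and the
  profile reconstructed from the candidate using the observed initial
  composition. Reported accuracy is `(1 − f1)·100%`. The mean runs over
  exactly the `T` compared columns (the first column always contributes 0).
  A time point at which both profiles are all-zero contributes 0 (identical
  empty samples are maximally similar; avoids 0/0).
* `f2` — two-sample Kolmogorov-Smirnov statistic between the candidate's
  nonzero coefficients (after zeroing entries with `|value| <
  zero_threshold`, default 1e-3 absolute) and a reference sample of
  `ks_reference_size` (default 1000) nonzero strengths `s·N_ij·H_jj` drawn
  from the configured community prior. If zeroing leaves no nonzero entry,
  `f2 = 1` (maximal penalty). The reference conditions on the configured
  prior, not on the candidate's own sparsity.
* `λ` (`lambda_ks`) defaults to 1.0; both terms live in [0, 1]. The additive
  combination keeps the decomposition `fitness = f1 + λ·f2` assertable on
  every evaluation.

Search: tournament selection (size 3) with 1 elite carried unchanged,
single-point crossover at a uniform cut (duplicate positions keep the first
occurrence, later duplicates are redrawn uniformly from unused positions;
growth genes are spliced at an independent cut), and mutation that perturbs
gene values by `Normal(0, mutation_scale²)` or, with probability
`relocation_rate`, relocates a gene to a fresh unused position — the Monte
Carlo gene introduction that lets rare OTUs enter the network. Defaults:
population 100, 500 generations, mutation rate 0.1, relocation rate 0.2,
mutation scale 0.1, stopping early when the best fitness improves by less
than 1e-6 over 100 generations. None of these is sacred; all are
config-exposed. Population fitness is evaluated with batched gLV steps
(one einsum per time step for the whole population), which is what makes
500-generation runs take seconds rather than minutes.

Multi-restart inference runs `restarts` (default 10) independent searches
with per-restart seeds spawned deterministically from the root seed,
retains every solution within `retention_margin` (default 2 percentage
points — differences of 1–2% in reconstruction accuracy are within the
noise of microbial data and do not identify a superior network) of the best
accuracy, and clusters retained matrices by single linkage on pairwise MSE
at threshold `delta_distinct` (default 0.1). Clusters are distinct candidate
networks; reporting several of them, rather than only the best, is the
point of the method.

## Synthetic data: what it does and does not emulate

The simulator generates exactly the data-generating process the inference
assumes: gLV dynamics driven by a community-model matrix, uniform initial
abundances, and (optionally) i.i.d. Gaussian measurement noise applied to
the observed profile only — the underlying trajectory stays clean, i.e.
noise is observational, not process noise. Real microbiome series violate
all of this: interactions drift over time, sequencing noise is
compositional and depth-dependent rather than additive Gaussian, sampling
is irregular, and the true dynamics are not gLV. Passing tests on this
generator therefore demonstrates correct implementation and recoverability
*within the model class*, not field performance on real data.

Default experiment sizes: T = 100 time points per simulated profile,
5 replicates per sweep cell (both config-exposed). Test-suite runs scale
these down (shorter horizons, smaller GA budgets) where only functional
behaviour — not benchmark quality — is being checked; the package's
benchmark defaults are unchanged.

## Numerical choices and degenerate inputs

* All-zero abundance columns stay all-zero under normalisation; Bray-Curtis
  of two all-zero vectors is 0; Bray-Curtis is clamped at 1.0 against
  few-ulp floating-point overshoot on disjoint supports.
* The KS statistic is computed exactly at the pooled sample points via
  sorted-array `searchsorted`; it handles ties and equals both a brute-force
  ECDF evaluation and `scipy.stats.ks_2samp` on random pairs (tested).
* Inverse-CDF power-law sampling switches to the logarithmic closed form at
  α = 1 to avoid the removable singularity.
* Ties in selection and sorting use stable orderings; all randomness flows
  from `numpy.random.Generator` seeded from the run seed, making every
  pipeline bit-for-bit reproducible from (config, seed). File writers keep
  12 significant digits so written networks round-trip.

## Known limitations

* One interaction coefficient per OTU pair for the whole series:
  time-varying interactions are out of scope.
* No continuous-time ODE integration and no stochastic (process-noise) gLV
  variant.
* The community prior's parameters (σ, α, p, s) are user-specified, not
  estimated from data.
* The retained-solution spread under measurement noise is an extreme
  statistic (a maximum over all retained pairs); it grows with the number
  of restarts and is sensitive to the prior's tail weight.
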