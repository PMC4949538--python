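# Methods

## Scope and models

`oucheck` studies model choice between Brownian motion (BM) and the
single-stationary-peak Ornstein–Uhlenbeck (OU) model for a single
continuous trait on a rooted, binary, ultrametric phylogeny. Under BM the
tip values are multivariate normal with mean `x0` and covariance
`sigma2 * S`, `S_ij` the root-to-MRCA path length. The OU variant fitted
here constrains the optimum to equal the root state (`mu = X(0)`), giving
unit-rate covariance

    V_ij(alpha) = exp(-2 alpha (T - s_ij)) (1 - exp(-2 alpha s_ij)) / (2 alpha),

which nests BM in the limit `alpha -> 0`. Multi-optimum OU models, OU with
a free root state, PGLS regression with OU errors, non-ultrametric
(fossil) trees and AIC-based comparison are out of scope. Trees are
rescaled to height 1 before fitting, because `alpha` only has meaning per
unit of tree height.

## Likelihood and ML fitting

For fixed `alpha`, the mean and rate have closed-form GLS maximizers
(`mu_hat = 1'V⁻¹x / 1'V⁻¹1`, `sigma2_hat = RSS/n`), so fitting reduces to
a 1-D profile likelihood in `alpha`. Because `V_ij` is an increasing
function of `s_ij` alone, `V` is itself a tree covariance with transformed
node depths, and all Gaussian quantities (`1'V⁻¹1`, `1'V⁻¹x`, `x'V⁻¹x`,
`log det V`) are computed by an O(n) bottom-up pruning pass
(Sherman–Morrison on the shared edge below each node). A dense Cholesky
path is kept as a fallback for trees with zero-length terminal edges and
serves as the independent oracle in the tests (agreement to 1e-8 on small
trees).

Numerical choices:

- `alpha < 1e-8` switches analytically to the BM covariance (avoids the
  0/0 in `(1-e^{-2 alpha s})/(2 alpha)`).
- The `alpha` search uses `[0, 20]` by default (configurable). Empirically
  the ML estimate only reaches this bound under strong measurement error;
  implementations elsewhere use bounds up to 150, and the bound is
  reported via `alpha_at_bound`.
- The maximizer is located by a 25-point scan (0 plus a log-spaced grid)
  followed by bounded Brent refinement on the bracketing interval; the
  `alpha = 0` endpoint is always evaluated, so `loglik_OU >= loglik_BM`
  holds by construction. Log-likelihood ties within 1e-8 resolve toward
  smaller `alpha` (the simpler interpretation).
- Constant trait vectors are rejected (`DegenerateDataError`); the exact
  phylogenetic-mean vector would drive `sigma2_hat -> 0`.

The LRT compares `2 (loglik_OU - loglik_BM)` (clamped at 0) to
chi-square(1) at the 5% level. This is deliberately the plain 1-df test —
the convention whose type-I behaviour the study characterizes — although
`alpha` sits on the boundary of its parameter space under the null; the
50:50 point-mass/chi-square(1) mixture is available via
`lrt(..., boundary_mixture=True)`. Profile curves report the set of
`alpha` within 1.92 log-likelihood units of the maximum (the 1-df 5%
cutoff); on BM data this set typically includes 0 even when the point
estimate does not.

## Interpretation helpers

`half_life(alpha) = ln(2)/alpha` is the time for a lineage to close half
the gap to the optimum; values large relative to tree height mean the fit
is effectively Brownian regardless of the test verdict.
`interpret_alpha` applies the `-ln(alpha)` reading for unit-height trees
(+4 almost Brownian, -4 essentially white noise).
`expected_correlation(alpha, s) = (e^{2 alpha s} - 1)/(e^{2 alpha} - 1)`
gives the between-species trait correlation as a function of relative
shared time; the report renders it for weak (0–0.5), moderate (1–5) and
strong (10–50) attraction, showing why small fitted `alpha` is
indistinguishable from BM and large `alpha` from phylogeny-free noise.

## Bayesian fitting

The posterior targets the prior times the full MVN likelihood at the
sampled `(mu, sigma2[, alpha])` — nothing is profiled. Priors follow the
study design: `alpha ~ Exponential(mean 1)`, `Exponential(mean 10)` or
`Uniform(0, 20)`; `mu ~ Uniform(-100, 100)`; `sigma2 ~ Uniform(0, 100)`.
Sampling is component-wise Gaussian random-walk Metropolis on
`(mu, ln sigma2, ln alpha)` with scales adapted toward ~35% acceptance
during burn-in only; convergence is monitored by split-R-hat over
independent chains. Marginal likelihoods use stepping-stone sampling with
the tempering ladder at the quantiles of Beta(0.4, 1) (dense near the
prior), warm-started stone chains, and log-sum-exp assembly. Bayes factors
are reported as `2 ln BF` with `> 2` read as evidence for OU (a `raw`
scale switch exists because that threshold convention is ambiguous in
parts of the literature).

Default sizes are working-scale (50k-iteration chains; 20 stones x 2000
iterations) so that grid cells remain tractable; `ChainSettings.paper()`
and `SteppingStoneSettings.paper()` give the full-scale settings
(1e6-iteration chains; 50 stones x 20 000 iterations). The estimator is
validated two ways: a generic pure-Python stepping-stone engine
(`stepping_stone_evidence`) reproduces the closed-form evidence of a
conjugate normal-mean toy model to < 0.05, and the tree-model sampler is
checked against semi-analytic quadrature of the BM evidence (the `mu`
integral done in closed form, `sigma2` by quadrature). The MCMC inner loop
is JIT-compiled with numba; a same-source Python fallback runs when numba
is unavailable (results then differ in the random stream, not in
distribution).

Posterior point estimates of `alpha` are reported as the marginal mode,
estimated by a Gaussian KDE on `ln alpha` back-transformed with the
Jacobian. For BM-generated data the marginal posterior of `alpha`
typically decreases from zero, so modal estimates are small almost by
construction.

## Synthetic data

The generators define the study conditions; their defaults are the
conditions summarized in the study tables.

- **Pure birth (Yule)**: constant per-lineage rate 1, conditioned on `n`
  by forward simulation; the present is the epoch at which the (n+1)-th
  birth would occur. Conditional on tree height, the non-root branching
  times are then i.i.d. with CDF `(e^t - 1)/(e^T - 1)` — an analytic law
  the tests verify by probability transform. The absolute rate is
  immaterial because every tree is rescaled to height 1 for fitting; only
  relative branching structure matters. (The generalized sampling approach
  is a documented alternative conditioning scheme; the simple forward
  scheme is used here.)
- **Birth–death**: birth rate 1, death rate equal to the extinction
  fraction `d/b` in {0.25, 0.5, 0.75}; started from the root split,
  restarted on total extinction, stopped when `n` lineages are first
  alive; extinct lineages pruned and unifurcations suppressed
  (reconstructed tree). The sign of the extinction effect on tree shape
  (Pybus–Harvey gamma) is checked against dendropy's independent
  birth–death simulator.
- **Time-varying rate**: per-lineage speciation rate `t^beta` (time from
  the root), `beta` in {0.2, 0.5, 2, 5}, simulated by inverting the
  cumulative rate `Lambda(t) = t^{beta+1}/(beta+1)`. Large `beta`
  concentrates branching near the present ("tippy" trees), the shape that
  most inflates OU wins; the grid labels map `beta = 2, 5` to slow/rapid
  speed-up and `beta = 0.5, 0.2` to slow/rapid slow-down, the ordering
  implied by their tippiness.
- **Traits**: BM with `sigma2 = 1`, `x0 = 0` — without loss of generality,
  since the LRT statistic and `alpha` estimates are invariant to trait
  location and scale (asserted as a test). Simulation is by O(n) edge-wise
  normal increments; a dense Cholesky route exists and the two are checked
  to agree in distribution. OU traits (for parameter-recovery checks) are
  drawn exactly via the same recursion on OU-transformed depths.
- **Measurement error**: every terminal edge is elongated by 1%, 5% or 10%
  of tree height *before* trait simulation, adding independent variance
  `sigma2 * fraction * T` per tip; fitting then uses the original tree.
  This emulates unmodelled intraspecific variation, not a specific
  within-species sampling design (known per-species error variances are
  out of scope).

What the generators do *not* emulate: empirical trees (sampling bias,
polytomies, branch-length error), non-normal trait variation, and
correlated measurement error. Passing tests therefore demonstrate the
statistical behaviour of the estimators under the stated generating
processes, not the fidelity of any particular empirical dataset.

## Study grid and reproducibility

`run_cell` simulates each replicate as: tree -> rescale to height 1 ->
optional tip elongation -> BM trait -> fit BM and OU on the *original*
unit-height tree -> decision rule. Replicate streams derive from
`SeedSequence([master_seed, cell_key, replicate])`, so cells are
independent and individually re-runnable; the decision method is excluded
from the key so LRT and Bayes cells of the same condition form a paired
design on identical datasets. Failures are excluded and counted; more
than 1% aborts the cell. Outputs are written atomically with a manifest.

`alpha` summaries are reported on the simulated-tree timescale by default
(`alpha_timescale="simulated"`): fitting happens on the unit-height tree,
and the estimate is divided by the replicate's original height — an exact
operation, since the model is equivariant under time rescaling. This is
the scale on which per-size summary tables of this kind are conventionally
printed (a unit-height reading is available via
`alpha_timescale="unit_height"`; rejection rates are identical either
way). Median-`alpha` summaries include replicates whose estimate sat at
the search bound; the bound-hit fraction is reported separately.

Problem sizes: the acceptance script runs 1000 replicates per headline
cell (200 for the 1000-tip cell) and finishes in minutes on one CPU; the
test suite uses 200-replicate cells with tolerances widened to three
binomial (or bootstrap) standard errors, and a 100-replicate paired cell
for the Bayesian comparison at the working-scale ladder.

## Known limitations

- The birth–death conditioning scheme (stop at first passage to `n`
  extant) is one of several defensible choices; tree-shape statistics of
  reconstructed birth–death trees differ slightly across schemes, which
  shifts `alpha`-bias summaries (not rejection rates) for high extinction
  fractions.
- The Metropolis sampler is adequate for the 3-parameter posteriors here
  but makes no attempt at gradient-based efficiency; very large trees at
  full-scale chain settings are slow.
- Credible-interval coverage is checked empirically at working scale; it
  is approximately, not exactly, nominal.
- The LRT's boundary problem means even the 1000-tip rejection rate sits
  below the nominal 5%; the package reports what the conventional test
  does rather than correcting it, because that convention is the object
  of study.
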