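# Methods

## The modelling problem

Ecological spatio-temporal studies of air pollution and health observe disease
counts `Y_kt` for `K` non-overlapping areal units over `T` consecutive periods,
together with externally standardised expected counts `E_kt` (absorbing
population size and age–sex structure) and covariates `x_kt` (pollution plus
confounders such as deprivation).  All models in this package share the first
level

    Y_kt | E_kt, R_kt ~ Poisson(E_kt · R_kt),
    ln R_kt = x_kt' β + φ_kt,

so the covariate effects `β` are log relative risks — reported per one standard
deviation of each covariate — and `φ_kt` is a random effect absorbing residual
spatio-temporal autocorrelation that the covariates do not explain.  The
scientific difficulty is that globally smooth random-effect fields are close to
collinear with spatially smooth covariates such as pollution, degrading the
estimation of exactly the coefficient the study exists to estimate.  The
package's central contribution is a model in which each adjacency relation of
the random-effect field is a binary quantity to be *estimated*, so smoothing is
applied only where the data support it.

## Model families

* **glm** — quasi-Poisson regression, no random effects.  Dispersion is
  estimated as Pearson `X²/(n − p)` and Wald intervals are scaled by its square
  root.  Residuals are raw (`Y` minus fitted mean).
* **bym_separable** — a common spatial surface (intrinsic CAR on the spatial
  graph + iid noise, precisions τ₁, τ₂) plus a common temporal trend
  (first-order random walk + iid, τ₃, τ₄).  The spatial pattern cannot change
  over time.
* **bym_nonseparable** — one spatio-temporal ICAR component on the `KT × KT`
  block adjacency `W` (diagonal blocks: the spatial adjacency per period;
  off-diagonal blocks between consecutive periods: the identity, i.e. each
  area is its own temporal neighbour) plus an iid component.
* **localised_nonseparable** — a single vector `φ̃ = (φ, φ*)` of length
  `KT + 1`.  Every spatial and temporal adjacency element of `W` is binary and
  estimable.  The global effect `φ*` is linked to cell `(k, t)` exactly when at
  least one of that cell's permitted relations is currently 0 (absent temporal
  relations at the first and last periods are skipped, not counted as zeros);
  this guarantees every cell keeps a positive conditional degree and hence a
  finite conditional variance `1/(τ·degree)`.  With all elements 1 the prior
  collapses to the pure non-separable ICAR; with all elements 0 it collapses to
  iid effects around `φ*`.
* **localised_separable** — the analogous localisation of the separable model:
  the estimable elements live in a single spatial adjacency `U` shared by all
  periods, extended with a global spatial effect, while the temporal trend
  keeps the random-walk-plus-noise form.  (This family is a reconstruction:
  the minimal localisation of the separable model consistent with the
  non-separable construction.)

Priors: `β ~ N(0, 1000)` (read as variance 1000, the conventional vague
prior); every precision `τ ~ Gamma(shape 1, rate 0.0005)` (prior mean 2000).
Improper ICAR log-densities use `(rank(Q)/2)·ln τ` as the pseudo-normalising
constant, with `rank(Q) = n − (number of connected components)`, so that DIC is
comparable across adjacency states.

## Posterior computation

Inference is Markov chain Monte Carlo (a deterministic nested-Laplace scheme
would also satisfy the contract; MCMC keeps the package dependency-light and
the intervals exact in the long-chain limit):

* **Precisions** — conjugate Gamma full conditionals
  `Gamma(a + rank/2, b + φ'Qφ/2)`.
* **Random effects** — chromatic single-site Metropolis: the conditional
  dependence graph of each component is greedy-coloured once, and all cells of
  one colour are proposed and accepted simultaneously (valid because
  same-colour cells are conditionally independent given the rest; a rook
  lattice plus temporal self-links is 2-colourable).  Proposal scales adapt by
  Robbins–Monro during burn-in (target acceptance 0.45).
* **Global effect `φ*`** — exact Gibbs: it never enters the likelihood, so its
  full conditional is Gaussian with mean the average of its linked cells.
* **β** — joint random-walk proposal preconditioned by the quasi-Poisson GLM
  covariance, adaptive scale (target 0.3), plus *translation moves*: a proposal
  that shifts `β_j` and simultaneously shifts the random-effect field along the
  direction that cancels the change in the linear predictor (exactly for
  identity-mapped components; via the covariate's spatial/temporal ANOVA
  profiles for the separable families, with a likelihood correction for the
  remainder).  These moves traverse the β–φ collinearity ridge that otherwise
  cripples mixing — the same collinearity the localised model exists to
  address.
* **Identifiability** — each intrinsic component is recentred every sweep and
  the removed level absorbed into the intercept.

Default run: 3 chains × 20 000 iterations (10 000 burn-in, thin 10), split-R̂
reported and `converged` flagged false above 1.1.  The fast profile
(1 chain, 5 000/2 500, thin 5) is used for the iterative algorithm's inner
fits, where only interval overlap is needed.

Model metrics: `DIC = D̄ + pD` with `pD = D̄ − D(θ̄)` evaluated at the
posterior means of the linear-predictor components; per-observation CPO by the
harmonic-mean estimator in log space (log-sum-exp guarded); raw residuals from
posterior-mean plug-ins.

## The localisation algorithm

1. Fit the independence model (every estimable element 0, so each cell is iid
   around the global effect) to obtain a starting posterior.
2. Iterate: (a) set each estimable element to 1 exactly when the marginal 95%
   credible intervals of its two random effects overlap (closed intervals —
   touching endpoints count as overlap, a measure-zero convention fixed for
   determinism), else 0; (b) refit the model under the implied extended
   adjacency.
3. Terminate at a fixed point (Case 1: the structure equals the previous one),
   at a revisited state (Case 2: a cycle — the member with the smallest mean
   per-period |Moran's I| of the raw residuals on the full spatial graph is
   chosen; ties resolve to the earliest member), or at a hard cap
   (default 30) reported as non-convergence.

Every inner fit reuses one fixed seed and one fixed warm start (the
independence fit's coefficient means).  With common random numbers the fitted
posterior — hence the overlap rule — is a deterministic function of the
adjacency state, so the trajectory lives in a finite state space and Case 1/2
termination is guaranteed, mirroring the determinism a Laplace-approximation
backend would provide.  Per-iteration reseeding would instead leave a few
marginally-overlapping elements flipping indefinitely under Monte-Carlo
quantile noise.  The chosen structure is refitted (by default at the same
control settings; pass `final_control` for a full-quality refit) before
reporting.

The tie-break statistic uses raw residuals per period averaged as mean |I_t|;
temporal autocorrelation is not part of the statistic.  Both choices are
package conventions (the aggregation is not otherwise pinned down); they only
matter in the rare Case-2 terminations.

## Diagnostics

Moran's I uses binary weights with the classical `K/S₀` normalisation (no row
standardisation — the CAR models are binary-weight throughout); its
permutation null mean is `−1/(K−1)`.  The permutation test is two-sided
(consistent with the |I| tie-break), with `p = (1 + #{|I_perm| ≥ |I_obs|})/(1 + n_perm)`
and a default of 10 000 permutations.  Separability is probed by Pearson
correlations between yearly residual surfaces; overdispersion by Pearson
`X²/(n − p)`.

## The synthetic-data generator

The generator emulates an urban health-board study on a rook lattice:

* **Expected counts** `E_kt ~ Uniform` on one of three prevalence bands
  [10, 25], [50, 100], [150, 200] (rare to common disease).
* **Covariates** — a pollution-like surface and three confounders.  Each is
  a persistent smooth spatial base (a Gaussian field with precision
  `Q(U) + 0.5·I`, correlation range of a few cells — district-scale variation,
  the realistic regime for pollution at neighbourhood resolution) plus
  smaller per-year spatial innovations of the same form (surfaces change
  differentially across areas year to year, as modelled pollution fields do;
  the default mix gives the pollution covariate a year-to-year correlation
  near 0.8) and a mild common temporal trend; each standardised to unit
  standard deviation so effects are per-sd.  A purely additive
  space-plus-time covariate would have no space–time interaction component
  at all, making it impossible for an unmodelled interaction in the random
  effects to confound it — the innovations are what give the
  separable-vs-non-separable model comparison its bite.  True log relative
  risks: ln(1.03) for pollution; ln(1.212), ln(0.899), ln(0.993) for the
  confounders (deprivation-, house-price- and ethnicity-like magnitudes
  typical of urban respiratory studies); intercept 0.
* **Random effects** — `φ ~ N(M·template, [τ(Q(W) + 0.01·I)]⁻¹)` where the
  template is a piecewise-constant {−1, 0, +1} surface of contiguous cluster
  patches covering ≈35% of areas (patches grown by seeded breadth-first
  search; separable scenarios repeat the surface each year, non-separable ones
  let patches grow/shrink at their boundaries while staying connected), `M ∈
  {0.5, 1}` scales the localised structure, and τ is set so the marginal sd of
  the smooth part is ≈0.2.  The regularisation ε = 0.01 makes the intrinsic
  precision proper for simulation.  The non-separable evolution rate
  (1.5·K boundary moves per period) is calibrated so that covariate-only GLM
  residual surfaces from generated data correlate year-to-year at the
  moderate level (roughly 0.3–0.65 on a 10×10 lattice) reported for real
  urban respiratory panels — clearly non-separable structure rather than a
  near-static surface.
* **Counts** — `Y ~ Poisson(E·exp(Xβ + φ))`.

What this generator does *not* emulate: a real irregular geography (a lattice
has homogeneous degrees), measurement error in pollution, covariates that are
themselves fixed real surfaces, and population-driven heterogeneity in `E`
within a band.  Passing simulation tests therefore demonstrates internal
consistency of estimation under the stated data-generating process, not
performance on any particular real dataset.

## Study problem sizes

The shipped evaluation studies are desk-scale by design: the interval-coverage
cells run on a 10×10 lattice with T = 5 (100 replicates for the GLM cell, 50
for each GMRF cell, single 8 000-iteration chains), and the
algorithm-convergence profile on a 5×5 lattice with T = 3 (216 runs over the
full scenario grid, 8 000-iteration inner chains).  Full-scale profiles
(hundreds of areas, 500 replicates) are a matter of passing larger arguments
to the same functions.  Two caveats about reading desk-scale results against city-scale
ones (K ≈ 271): chance collinearity between a smooth covariate and the
random-effect field grows as the lattice shrinks, so absolute coverage of the
naive GLM is substantially lower at K = 36–100 than at K = 271, and the
penalty for a misspecified (separable) structure is likewise
scale-dependent.  Directional orderings — GLM undercovers; the generating
localised family is near nominal; misspecified separable models undercover on
non-separable data — are the scale-stable findings.

## Numerical choices and edge cases

* Cells are vectorised time-major (`(k, t) → t·K + k`), keeping `W`
  block-tridiagonal.
* Isolated areas are accepted with a warning; their cells rely on temporal
  links and the global effect.  `T = 1` collapses to a purely spatial
  localised CAR and is flagged.
* Interval-overlap and Moran tie-break conventions are fixed as above for
  bit-reproducibility; seeded runs are reproducible per backend version.
* The linear predictor is updated incrementally during sweeps and recomputed
  from scratch every 200 sweeps to prevent floating-point drift.
* The sweep itself runs as a numba-compiled kernel consuming pre-generated
  random draws in a fixed order; a pure-Python twin of the same function is
  kept as the reference implementation and the two agree to ~1e-15 (exact
  bit-parity is not guaranteed because the compiled libm rounds differently
  by ~1 ulp).  Longer chains are what stabilise the credible intervals the
  localisation algorithm thresholds, so sampler speed directly improves the
  algorithm's termination behaviour.
* Zero-variance inputs to Moran's I raise; permutation p-values respect the
  `1/(n_perm + 1)` lower bound.
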