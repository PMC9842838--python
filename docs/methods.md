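# Methods

## Model

mbarkit estimates dimensionless free energies `f_i` of `K` thermodynamic
states from pooled samples using the multistate Bennett acceptance ratio
(MBAR) equations.  A state is a reduced potential
`u_i(x) = beta_i [U_i(x) + p_i V(x) + mu_i^T n(x)]`; the pressure-volume and
chemical-potential terms enter only when the state declares a pressure or
chemical potentials, so constant-volume analyses never need volumes.  The
estimator assumes the `N_j` samples of each state are drawn from that
state's equilibrium distribution and are mutually uncorrelated; correlated
input biases the uncertainty estimates long before it biases the point
estimates, which is why the package ships a stride subsampler and reports
block-averaged errors that inflate under residual correlation.

Free energies are defined up to one additive constant; we anchor
`f_1 = 0`.  Everything downstream — target-state free energies, averages,
PMFs — consumes the per-sample log-denominator
`ln sum_k N_k exp(f_k - u_k(x_n))`, cached at the solution, so reweighting
to a new target is a single pass over the pooled samples.

### Input-preparation modes

* **restraint** (umbrella sampling): the shared system potential cancels
  between windows, so the matrix holds only the restraint energies
  `k_i (z - z_i_ref)^2`.  The spring convention is `k dz^2` with no 1/2
  factor; engines using `(1/2) k dz^2` are accommodated by the `half_spring`
  flag, which converts on input.  Periodic collective variables wrap by
  minimum image on a declared period; the default is non-periodic.
* **scaling** (temperature ladders): `u_k = beta_k U_system`.  In an NPT
  analysis a declared pressure adds `beta_k p V(x)`; the target-state
  reduced potential includes the same terms as the state definition.
* **accumulation** (alchemical FEP): estimated pairwise from neighbor
  reduced-energy columns, never through a full matrix.  Each pair is the
  `K = 2` case of the MBAR equations, which is exactly Bennett's
  self-consistent acceptance-ratio estimator, and the endpoint difference
  is the sum of pair differences.  Non-neighbor energies are neither needed
  nor read; `+inf` entries (overlapping cores at decoupled endpoints) carry
  zero Boltzmann weight.  A single beta per chain is assumed (isothermal
  transformation).
* **full** (REST/gREST, dual-level reweighting): each state references a
  named column of whole-system energies, optionally plus a per-state
  restraint.  The dual-level workflow samples on a low-level surface with
  restraints and reweights to the unrestrained high-level target column.

### Solver

The fixed point is also the stationary point of the standard convex MBAR
objective `sum_n ln sum_k N_k e^{f_k - u_kn} - sum_k N_k f_k`.  The solver
runs plain self-consistent sweeps until the max-norm self-consistency
residual falls below 1e-2, then switches to Newton steps on the `K - 1`
free components using the objective's gradient and Hessian, with step
halving and a self-consistent fallback whenever a step fails to reduce the
residual.  Defaults: tolerance 1e-8 on the residual, at most 1e5
iterations; both are free parameters with no physical meaning beyond
"converged".  All sums are log-sum-exp; no intermediate exponential can
overflow.  Convergence failures raise an error carrying the residual trace
rather than returning a half-converged result.

Overlap is diagnosed, not guessed: for every state (including appended
zero-count targets) the effective sample size `ESS_k = 1 / sum_n w_kn^2` of
the normalized weights is reported, with a warning below 50.  Free energies
of states with tiny ESS can be formally converged and still essentially
unconstrained by the data.

### Reweighting and PMFs

Target-state weights are `w_n ∝ exp[-u_target(x_n) - L_n]`, normalized.
Averages of general-sign observables use the direct weighted sum; for
non-negative observables this coincides with the two-free-energy form
`exp[f_target - f_target_A]`, and the equivalence is asserted in tests.
PMFs are indicator-observable free energies per collective-variable bin:
`-ln` of the bin's total weight, in kT, min-shifted to zero over non-empty
bins (a display convention; the offset is pure gauge).  Bins are half-open
with the last bin closed.  One- and two-dimensional PMFs are supported;
higher dimensions are rejected.  A flag converts kT to kcal/mol at a
declared temperature.

When comparing two profiles (estimate vs quadrature, MBAR vs WHAM), the
tests first remove the mean offset over well-sampled bins.  Min-shift
anchoring would add the anchor bin's noise to every other bin and double
the apparent error; the offset carries no physical content.

### Uncertainties

* **Block averaging** (default, B = 10): blocks are contiguous time slices
  within each state, so slowly decaying correlations inflate the block
  spread as they should.  `SE = std(blocks, ddof=1)/sqrt(B)`.
* **Bootstrap** (default R = 50, seeded): resamples with replacement
  independently within each state; assumes decorrelated input.  Replicates
  that fail are dropped with a warning; at least half must survive.

Both re-run the full estimator (MBAR refit warm-started from the point
estimate, then reweighting) on each replicate, so the uncertainty of the
window free energies propagates into per-bin PMF errors.  For the FEP
chain, the default total SE comes from whole-chain block averaging: each
block re-estimates every pair on its own slice of every state's series, so
the correlation induced by interior states shared between adjacent pairs is
carried through.  Root-sum-square pair combination is available as a fast
alternative with an explicit independence caveat.

### WHAM reference

A binned WHAM solver (density update + window normalization, iterated in
log space to 1e-8 on the window free energies, restraints evaluated at bin
centers, first window anchored) is included purely as a cross-check: MBAR
is WHAM's zero-bin-width limit, so the two PMFs must agree up to binning
bias, and the tests assert that refining the bins does not widen the gap.

## Synthetic studies

The generators stand in for MD output with analytically known answers; all
reference values are computed by quadrature or closed form inside the
generator at run time, never hard-coded, and every generator emits a
manifest (parameters + seed) sufficient for bit-identical regeneration.

* **Gaussian states** (`gen_harmonic_states`): exact draws from
  `u_i = (x - mu_i)^2 / (2 sigma_i^2)` with closed-form
  `f_i = -ln(sigma_i sqrt(2 pi))`; the exactness oracle for the solver.
* **Umbrella study**: a double well `U = h((z/w)^2 - 1)^2` with barrier
  h = 3 kcal/mol at beta = 1, 21 windows on [-1.4, 1.4], spring k = 25
  (so that `k * spacing` exceeds the landscape gradient at the outermost
  windows — with weaker springs the edge windows cannot hold their centers
  and the ladder does not cover its nominal range), N = 2000/window,
  Metropolis with step 0.3 and keep-stride 20 (kept-sample lag-1
  autocorrelation is ~0.2 at stride 10, honoring the uncorrelated-samples
  premise requires the longer stride).  PMF bins: 24 over [-1.3, 1.3],
  sized so that every bin's effective count is >1000 and sampling noise
  sits below the ~0.1 kT resolution the comparison claims.  At these
  sample sizes the max-abs deviation from quadrature has a sampling
  distribution of roughly 0.05-0.13 kT, dominated by the random walk of
  window free energies along the ladder.
* **Temperature ladder**: tilted double well (h = 4, tilt 0.5), betas
  (1.0, 0.8, 0.64, 0.51), N = 6000/temperature, and a 60000-sample
  single-temperature reference run.  The reference histogram's SE is block
  averaged, because well occupancy decorrelates much more slowly than the
  within-well coordinate and a multinomial SE would be optimistic.
* **Alchemical chain**: `U_start = k x^2`, `U_end = k (x - a)^2 + b`
  (a = 1.5, b = 2 kcal/mol), 11 equidistant lambdas, N = 2000/state.  The
  linear mixture of two harmonic wells is harmonic, so states are sampled
  exactly; the closed-form total is `beta * b`, and per-pair references
  come from quadrature.
* **Dual-level study**: the umbrella low-level surface plus a bounded
  smooth high-level correction `1 kT * sin(2.5 z)`; high-level reference
  PMF by quadrature.
* A 2-D periodic toy (two dihedral-like coordinates) exercises the 2-D PMF
  plumbing without a quantitative oracle.

What the generators do **not** emulate: real force-field energetics,
kinetic trapping beyond what a short-stride Metropolis walk shows,
multimodal orthogonal degrees of freedom, or correlated noise in the
energy columns.  Passing tests therefore demonstrate estimator
correctness — unbiasedness against known ground truth, solver agreement
with independent oracles, calibrated uncertainties on decorrelated input —
not robustness to the pathologies of under-sampled real simulations, where
the ESS diagnostics are the intended guard.

## Numerical choices

* kB = 0.0019872041 kcal/mol/K; energies in kcal/mol, temperatures in K;
  reduction to dimensionless happens exactly once, at matrix build.
* `+inf` reduced potentials are legal everywhere and mean zero weight; NaN
  and `-inf` are rejected loudly.  A pooled sample infinite in every
  sampled state is an input error.
* Zero-count states are allowed only as appended targets; elsewhere they
  are configuration errors (they contribute nothing to the denominator).
* Degenerate inputs: empty files, all-empty PMF bins, non-permutation
  exchange maps, and mixed modes in one matrix raise typed errors naming
  the offending field, file, or line.
* Text output is written as the shortest decimal that round-trips the
  float64, making reruns byte-comparable; readers wanting bitwise equality
  should parse with round-trip float precision.

## Known limitations

* No analytic asymptotic covariance; uncertainties are resampling-based
  by design.
* Autocorrelation-time estimation is out of scope; the stride subsampler
  requires a user-chosen stride.
* WHAM is one-dimensional and umbrella-only (it exists as a reference,
  not a production path).
* PMFs above two dimensions and engine-specific log formats are
  deliberately unsupported.
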