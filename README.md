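# mbarkit

Free-energy estimation from pooled molecular-simulation data with the
multistate Bennett acceptance ratio (MBAR) estimator, for people who run
umbrella sampling, temperature replica exchange, alchemical free-energy
perturbation, or dual-level (low-level/high-level theory) reweighting and
need free-energy differences, unbiased averages, and potentials of mean
force with uncertainties afterwards.

## The estimator

State *i* is defined by its reduced potential over configurations *x*,

```
u_i(x) = beta_i [ U_i(x) + p_i V(x) + mu_i^T n(x) ]
```

and its dimensionless free energy `f_i = -ln ∫ exp(-u_i(x)) dx`.  Given
`N_j` decorrelated samples from each of `K` states, MBAR solves the coupled
self-consistent equations

```
f_i = -ln sum_{j,n}  exp[-u_i(x_jn)] / sum_k N_k exp[f_k - u_k(x_jn)]
```

for all `f_i` simultaneously (anchored `f_1 = 0`; only differences are
meaningful).  It is the statistically optimal multistate generalization of
Bennett's two-state acceptance-ratio method, and the zero-bin-width limit of
WHAM.  Averages and PMFs in any target state — sampled or not — follow by
reweighting the pooled samples with `w_n ∝ exp[-u_target(x_n)] / D_n`, where
`D_n` is the denominator above.

The practical appeal is that each usage mode needs only a small slice of
data:

| mode | example | required input |
|---|---|---|
| `restraint` | umbrella sampling | CV trajectories + window centers + spring constants |
| `scaling` | T-REMD | per-sample `U_system` + the temperature ladder |
| `accumulation` | alchemical FEP | neighbor-state reduced energies only |
| `full` | REST/gREST, LL→HL reweighting | per-state total energy columns |

The solver combines self-consistent sweeps with damped Newton steps on the
convex MBAR objective, evaluates everything in log space (so `+inf` energies
from overlapping-core endpoints are benign), and reports per-state effective
sample sizes as an overlap diagnostic.  Uncertainties come from block
averaging or within-state bootstrap; a binned WHAM solver is included as an
independent cross-check for umbrella data.

## Worked example

Estimate the free-energy difference between two harmonic states with widths
sigma = 1 and 2 — the exact answer is `-ln 2 ≈ -0.6931`:

```python
import numpy as np
import mbarkit as mk
from mbarkit import synthetic as syn

ds = syn.gen_harmonic_states([1.0, 2.0], n_samples=10000, seed=3)
res = mk.solve_mbar(ds.matrix)
print(f"delta_f = {res.delta_f(1):.4f}  (analytic {-np.log(2):.4f})")
print(f"converged in {res.n_iterations} iterations, ESS {np.round(res.ess)}")
```

prints

```
delta_f = -0.6906  (analytic -0.6931)
converged in 5 iterations, ESS [17281. 17281.]
```

A full umbrella-sampling workflow on a synthetic double well — sample 21
restrained windows, solve, and recover the PMF of the unrestrained
landscape:

```python
pot = syn.double_well(height=3.0)              # barrier 3 kcal/mol
centers = mk.window_ladder(-1.4, 1.4, 0.14)    # 21 windows
data = syn.gen_umbrella_windows(pot, centers, spring_k=25.0, beta=1.0,
                                n_per_window=2000, seed=0,
                                step_size=0.3, stride=20)
states = [mk.ThermoState(mode="restraint", beta=1.0, spring_k=[25.0],
                         z_ref=[c]) for c in centers]
sets = [mk.SampleSet(origin_state=i, cv=t)
        for i, t in enumerate(data.trajectories)]
matrix = mk.build_reduced_matrix(states, sets)
result = mk.solve_mbar(matrix)
prof = mk.compute_pmf(result, np.zeros(matrix.n_total),
                      np.concatenate(data.trajectories),
                      np.linspace(-1.3, 1.3, 25))
ref = syn.pmf_reference(pot, 1.0, np.linspace(-1.3, 1.3, 25))
dev = (prof.pmf - ref); dev -= dev.mean()
print(f"max |PMF - quadrature| = {np.abs(dev).max():.3f} kT")
```

prints `max |PMF - quadrature| = 0.066 kT` — the estimated profile tracks
the exact Boltzmann quadrature of the toy landscape to well under 0.1 kT.

The same pipeline is scriptable from the shell: `mbarkit umbrella --config
run.yaml --out results/` (subcommands `umbrella | remd | fep | full | pmf |
synth`; the CLI is a thin dispatch over the library and produces identical
numbers).

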