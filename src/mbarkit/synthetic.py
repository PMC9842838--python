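"""Synthetic data with known ground truth for every estimation mode.

These generators stand in for molecular-dynamics output: one-dimensional toy
potentials sampled by Metropolis Monte Carlo (or exactly, where the target
density is Gaussian), with every reference free energy or PMF produced by
numerical quadrature or closed form inside the generator itself.  That keeps
each claim of the estimators checkable against an independent analytic
answer at test time.  All generators are seeded and emit a manifest of their
parameters sufficient to regenerate the data bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._exceptions import InputError
from .accumulate import NeighborEnergySet
from .states import ReducedPotentialMatrix, restraint_energy

__all__ = [
    "ToyPotential",
    "harmonic",
    "double_well",
    "periodic_cosine",
    "from_table",
    "free_energy_quadrature",
    "pmf_reference",
    "gen_harmonic_states",
    "mcmc_sample",
    "gen_umbrella_windows",
    "gen_temperature_ladder",
    "gen_fep_chain",
    "gen_dual_level",
    "gen_periodic_2d",
]


@dataclass(frozen=True)
class ToyPotential:
    """A 1-D potential energy function U(z) in kcal/mol.

    ``kind`` tags the symbolic form; ``params`` holds its parameters; the
    domain bounds delimit where quadrature integrates.  Periodic potentials
    declare their period.
    """

    kind: str
    params: dict
    domain: tuple[float, float]
    period: float | None = None
    _fn: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def energy(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = self._fn(z)
        if not np.all(np.isfinite(u) | np.isposinf(u)):
            raise InputError(f"{self.kind} potential produced non-finite energy")
        return u

    __call__ = energy

    def manifest(self) -> dict:
        return {
            "kind": self.kind,
            "params": dict(self.params),
            "domain": list(self.domain),
            "period": self.period,
        }


def harmonic(k: float = 1.0, center: float = 0.0, offset: float = 0.0,
             domain=None) -> ToyPotential:
    """U(z) = k (z - center)^2 + offset."""
    if domain is None:
        half = 8.0 / math.sqrt(max(k, 1e-12))
        domain = (center - half, center + half)
    return ToyPotential(
        "harmonic",
        {"k": k, "center": center, "offset": offset},
        tuple(domain),
        _fn=lambda z: k * (z - center) ** 2 + offset,
    )


def double_well(height: float = 3.0, half_width: float = 1.0,
                tilt: float = 0.0, domain=None) -> ToyPotential:
    """U(z) = height ((z/half_width)^2 - 1)^2 + tilt * z.

    Minima near +-half_width separated by a barrier of ~height (kcal/mol);
    a nonzero tilt makes the wells inequivalent.
    """
    if domain is None:
        domain = (-2.5 * half_width, 2.5 * half_width)
    return ToyPotential(
        "double_well",
        {"height": height, "half_width": half_width, "tilt": tilt},
        tuple(domain),
        _fn=lambda z: height * ((z / half_width) ** 2 - 1.0) ** 2 + tilt * z,
    )


def periodic_cosine(amplitude: float = 2.0, period: float = 360.0,
                    phase: float = 0.0) -> ToyPotential:
    """U(z) = (amplitude/2) (1 - cos(2 pi (z - phase)/period)), dihedral-like."""
    w = 2.0 * math.pi / period
    return ToyPotential(
        "periodic_cosine",
        {"amplitude": amplitude, "period": period, "phase": phase},
        (0.0, period),
        period=period,
        _fn=lambda z: 0.5 * amplitude * (1.0 - np.cos(w * (np.asarray(z) - phase))),
    )


def from_table(z_grid, u_grid, period=None) -> ToyPotential:
    """Piecewise-linear potential interpolated from a table."""
    z_grid = np.asarray(z_grid, dtype=float)
    u_grid = np.asarray(u_grid, dtype=float)
    if z_grid.shape != u_grid.shape or z_grid.ndim != 1:
        raise InputError("table potential needs matching 1-D grids")
    return ToyPotential(
        "custom_table",
        {"z": z_grid.tolist(), "u": u_grid.tolist()},
        (float(z_grid[0]), float(z_grid[-1])),
        period=period,
        _fn=lambda z: np.interp(z, z_grid, u_grid),
    )


def _mix(u_start: ToyPotential, u_end: ToyPotential, lam: float):
    """Linear alchemical mixture (1-lambda) U_start + lambda U_end."""
    lo = min(u_start.domain[0], u_end.domain[0])
    hi = max(u_start.domain[1], u_end.domain[1])
    return ToyPotential(
        "mixture",
        {"lambda": lam, "start": u_start.manifest(), "end": u_end.manifest()},
        (lo, hi),
        _fn=lambda z: (1.0 - lam) * u_start.energy(z) + lam * u_end.energy(z),
    )


# ---------------------------------------------------------------------------
# quadrature references

def free_energy_quadrature(potential, beta: float, domain=None,
                           n_points: int = 20001) -> float:
    """Dimensionless f = -ln integral exp(-beta U(z)) dz by trapezoid rule."""
    lo, hi = domain if domain is not None else potential.domain
    z = np.linspace(lo, hi, n_points)
    w = -beta * potential.energy(z)
    m = np.max(w)
    return float(-(m + np.log(np.trapezoid(np.exp(w - m), z))))


def pmf_reference(potential, beta: float, bin_edges,
                  points_per_bin: int = 200) -> np.ndarray:
    """Exact binned PMF in kT: -ln of the Boltzmann mass per bin, min-shifted.

    Integrates exp(-beta U) within each bin, matching the indicator-function
    binning of the estimated PMF rather than a point density.
    """
    edges = np.asarray(bin_edges, dtype=float)
    mass = np.empty(len(edges) - 1)
    for b in range(len(edges) - 1):
        z = np.linspace(edges[b], edges[b + 1], points_per_bin)
        mass[b] = np.trapezoid(np.exp(-beta * potential.energy(z)), z)
    pmf = -np.log(mass / mass.sum())
    return pmf - pmf.min()


# ---------------------------------------------------------------------------
# exactness oracle: Gaussian states

@dataclass
class HarmonicDataset:
    """Exact Gaussian draws from K harmonic states plus their analytic f."""

    samples: list[np.ndarray]
    matrix: ReducedPotentialMatrix
    f_analytic: np.ndarray
    manifest: dict


def gen_harmonic_states(sigmas, centers=None, n_samples: int = 5000,
                        seed: int = 0) -> HarmonicDataset:
    """Samples from u_i(x) = (x - mu_i)^2 / (2 sigma_i^2), drawn exactly.

    The reduced potentials are already dimensionless, and each state's free
    energy has the closed form f_i = -ln(sigma_i sqrt(2 pi)) (the Gaussian
    normalization); this is the exactness oracle for the solver.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas <= 0):
        raise InputError("sigmas must be positive")
    centers = (
        np.zeros_like(sigmas) if centers is None
        else np.asarray(centers, dtype=float)
    )
    if centers.shape != sigmas.shape:
        raise InputError("centers and sigmas must have equal length")
    if n_samples < 1:
        raise InputError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [
        rng.normal(mu, s, size=n_samples) for mu, s in zip(centers, sigmas)
    ]
    pooled = np.concatenate(samples)
    u = np.vstack(
        [(pooled - mu) ** 2 / (2.0 * s**2) for mu, s in zip(centers, sigmas)]
    )
    counts = np.full(len(sigmas), n_samples, dtype=np.int64)
    origin = np.repeat(np.arange(len(sigmas)), n_samples)
    f_analytic = -np.log(sigmas * math.sqrt(2.0 * math.pi))
    return HarmonicDataset(
        samples=samples,
        matrix=ReducedPotentialMatrix(u, counts, origin),
        f_analytic=f_analytic,
        manifest={
            "generator": "gen_harmonic_states",
            "sigmas": sigmas.tolist(),
            "centers": centers.tolist(),
            "n_samples": n_samples,
            "seed": seed,
            "f_analytic": f_analytic.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# Metropolis sampling

def mcmc_sample(
    potential: ToyPotential,
    beta: float,
    n_samples: int,
    *,
    restraint=None,
    step_size: float = 0.5,
    burn_in: int = 1000,
    stride: int = 10,
    n_walkers: int = 8,
    init=None,
    seed: int = 0,
):
    """Metropolis chain targeting exp(-beta [U(z) + U_restraint(z)]).

    ``restraint`` is an optional (spring_k, z_ref) pair using the k (dz)^2
    convention.  ``n_walkers`` independent walkers run in parallel (a
    vectorized sweep per step); after discarding ``burn_in`` steps, every
    ``stride``-th state of each walker is kept until ``n_samples`` values are
    pooled.  Returns (samples, acceptance_rate).
    """
    if step_size <= 0:
        raise InputError("step_size must be positive")
    if n_samples < 1 or n_walkers < 1:
        raise InputError("n_samples and n_walkers must be >= 1")
    rng = np.random.default_rng(seed)

    if restraint is not None:
        k_r, z_r = restraint
        def total_u(z):
            return potential.energy(z) + restraint_energy(
                k_r, z[:, None], [z_r],
                periodic=None if potential.period is None else [potential.period],
            )
    else:
        def total_u(z):
            return potential.energy(z)

    lo, hi = potential.domain
    if init is None:
        if restraint is not None:
            z = np.full(n_walkers, float(z_r)) + 0.01 * rng.standard_normal(n_walkers)
        else:
            z = rng.uniform(lo, hi, size=n_walkers)
    else:
        z = np.full(n_walkers, float(init)) + 0.01 * rng.standard_normal(n_walkers)

    per_walker = -(-n_samples // n_walkers)  # ceil
    n_steps = burn_in + per_walker * stride
    u_cur = beta * total_u(z)
    n_acc = 0
    kept = []
    for t in range(n_steps):
        prop = z + rng.uniform(-step_size, step_size, size=n_walkers)
        if potential.period is not None:
            prop = np.mod(prop, potential.period)
        u_prop = beta * total_u(prop)
        accept = np.log(rng.uniform(size=n_walkers)) < (u_cur - u_prop)
        z = np.where(accept, prop, z)
        u_cur = np.where(accept, u_prop, u_cur)
        n_acc += int(accept.sum())
        if t >= burn_in and (t - burn_in) % stride == stride - 1:
            kept.append(z.copy())
    samples = np.concatenate(kept)[:n_samples] if kept else np.empty(0)
    return samples, n_acc / (n_steps * n_walkers)


@dataclass
class UmbrellaDataset:
    """Biased CV trajectories from a ladder of harmonic umbrella windows."""

    trajectories: list[np.ndarray]
    centers: np.ndarray
    spring_k: float
    beta: float
    potential: ToyPotential
    acceptance: np.ndarray
    manifest: dict


def gen_umbrella_windows(
    potential: ToyPotential,
    centers,
    spring_k: float,
    beta: float,
    n_per_window: int,
    seed: int = 0,
    **mcmc_kwargs,
) -> UmbrellaDataset:
    """Umbrella-sampling analog: one restrained Metropolis run per window."""
    centers = np.asarray(centers, dtype=float)
    trajs, acc = [], []
    for i, c in enumerate(centers):
        t, a = mcmc_sample(
            potential, beta, n_per_window,
            restraint=(spring_k, c),
            seed=np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31),
            **mcmc_kwargs,
        )
        trajs.append(t)
        acc.append(a)
    return UmbrellaDataset(
        trajectories=trajs,
        centers=centers,
        spring_k=spring_k,
        beta=beta,
        potential=potential,
        acceptance=np.asarray(acc),
        manifest={
            "generator": "gen_umbrella_windows",
            "potential": potential.manifest(),
            "centers": centers.tolist(),
            "spring_k": spring_k,
            "beta": beta,
            "n_per_window": n_per_window,
            "seed": seed,
            "mcmc": dict(mcmc_kwargs),
        },
    )


@dataclass
class LadderDataset:
    """Per-temperature CV trajectories and system energies."""

    trajectories: list[np.ndarray]
    energies: list[np.ndarray]
    betas: np.ndarray
    potential: ToyPotential
    manifest: dict


def gen_temperature_ladder(
    potential: ToyPotential,
    betas,
    n_per_state: int,
    seed: int = 0,
    **mcmc_kwargs,
) -> LadderDataset:
    """Temperature-ladder analog: independent runs at each beta.

    ``betas`` must be strictly decreasing (temperatures increasing), lowest
    temperature first, matching how replica-exchange ladders are declared.
    U_system is recorded per sample; that plus the ladder is the entire
    input the scaling mode needs.
    """
    betas = np.asarray(betas, dtype=float)
    if np.any(np.diff(betas) >= 0):
        raise InputError(
            "betas must be strictly decreasing (temperature increasing)"
        )
    trajs, energies = [], []
    for i, b in enumerate(betas):
        t, _ = mcmc_sample(
            potential, b, n_per_state,
            seed=np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31),
            **mcmc_kwargs,
        )
        trajs.append(t)
        energies.append(potential.energy(t))
    return LadderDataset(
        trajectories=trajs,
        energies=energies,
        betas=betas,
        potential=potential,
        manifest={
            "generator": "gen_temperature_ladder",
            "potential": potential.manifest(),
            "betas": betas.tolist(),
            "n_per_state": n_per_state,
            "seed": seed,
            "mcmc": dict(mcmc_kwargs),
        },
    )


@dataclass
class FEPDataset:
    """Lambda-chain samples, neighbor reduced energies, and quadrature truth."""

    neighbor_sets: list[NeighborEnergySet]
    full_matrix: ReducedPotentialMatrix
    lambdas: np.ndarray
    beta: float
    ref_pair_delta_f: np.ndarray
    ref_total: float
    samples: list[np.ndarray]
    manifest: dict


def _sample_mixture(u_start, u_end, lam, beta, n, rng, mcmc_kwargs, seed):
    both_harmonic = u_start.kind == "harmonic" and u_end.kind == "harmonic"
    if both_harmonic:
        # The linear mixture of two harmonic wells is harmonic; sample exactly.
        k1, c1 = u_start.params["k"], u_start.params["center"]
        k2, c2 = u_end.params["k"], u_end.params["center"]
        k = (1 - lam) * k1 + lam * k2
        if k > 0:
            mean = ((1 - lam) * k1 * c1 + lam * k2 * c2) / k
            sigma = 1.0 / math.sqrt(2.0 * beta * k)
            return rng.normal(mean, sigma, size=n)
    mixed = _mix(u_start, u_end, lam)
    t, _ = mcmc_sample(mixed, beta, n, seed=seed, **mcmc_kwargs)
    return t


def gen_fep_chain(
    u_start: ToyPotential,
    u_end: ToyPotential,
    lambdas,
    beta: float,
    n_per_state: int,
    seed: int = 0,
    **mcmc_kwargs,
) -> FEPDataset:
    """Alchemical chain through U(z; lambda) = (1-lambda) U_start + lambda U_end.

    Samples every mixed state (exactly when both endpoints are harmonic,
    else by Metropolis), evaluates the neighbor reduced energies exactly,
    and returns per-pair reference free-energy differences by quadrature.
    The full K x N matrix is also assembled for cross-checks against the
    chained estimate.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas < 0) or np.any(lambdas > 1):
        raise InputError("lambda schedule must lie in [0, 1]")
    if np.any(np.diff(lambdas) <= 0):
        raise InputError("lambda schedule must be strictly increasing")
    k_states = len(lambdas)
    if k_states < 2:
        raise InputError("need at least two lambda states")
    rng = np.random.default_rng(seed)
    mixed = [_mix(u_start, u_end, lam) for lam in lambdas]
    samples = []
    for i, lam in enumerate(lambdas):
        sub_seed = np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        samples.append(
            _sample_mixture(
                u_start, u_end, lam, beta, n_per_state, rng, mcmc_kwargs,
                sub_seed,
            )
        )

    neighbor_sets = []
    for i in range(k_states):
        z = samples[i]
        neighbor_sets.append(
            NeighborEnergySet(
                state_index=i,
                u_self=beta * mixed[i].energy(z),
                u_prev=None if i == 0 else beta * mixed[i - 1].energy(z),
                u_next=None if i == k_states - 1 else beta * mixed[i + 1].energy(z),
            )
        )

    pooled = np.concatenate(samples)
    u_full = np.vstack([beta * m.energy(pooled) for m in mixed])
    counts = np.full(k_states, n_per_state, dtype=np.int64)
    origin = np.repeat(np.arange(k_states), n_per_state)
    full_matrix = ReducedPotentialMatrix(u_full, counts, origin)

    f_ref = np.array(
        [free_energy_quadrature(m, beta) for m in mixed]
    )
    ref_pairs = np.diff(f_ref)
    return FEPDataset(
        neighbor_sets=neighbor_sets,
        full_matrix=full_matrix,
        lambdas=lambdas,
        beta=beta,
        ref_pair_delta_f=ref_pairs,
        ref_total=float(f_ref[-1] - f_ref[0]),
        samples=samples,
        manifest={
            "generator": "gen_fep_chain",
            "u_start": u_start.manifest(),
            "u_end": u_end.manifest(),
            "lambdas": lambdas.tolist(),
            "beta": beta,
            "n_per_state": n_per_state,
            "seed": seed,
            "mcmc": dict(mcmc_kwargs),
            "ref_pair_delta_f": ref_pairs.tolist(),
        },
    )


def gen_periodic_2d(
    amplitudes=(2.0, 1.0),
    period: float = 360.0,
    beta: float = 1.0,
    n_samples: int = 2000,
    *,
    step_size: float = 30.0,
    burn_in: int = 1000,
    stride: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Two dihedral-like periodic coordinates sampled by 2-D Metropolis.

    A smoke-test dataset for two-dimensional PMF plumbing (no quantitative
    oracle): U(phi, psi) = sum_d (A_d/2)(1 - cos(2 pi phi_d / period)).
    Returns (samples of shape (n_samples, 2), manifest).
    """
    a = np.asarray(amplitudes, dtype=float)
    w = 2.0 * math.pi / period
    rng = np.random.default_rng(seed)

    def u(z):
        return np.sum(0.5 * a * (1.0 - np.cos(w * z)), axis=-1)

    z = rng.uniform(0, period, size=(8, 2))
    u_cur = beta * u(z)
    kept = []
    per_walker = -(-n_samples // 8)
    for t in range(burn_in + per_walker * stride):
        prop = np.mod(z + rng.uniform(-step_size, step_size, size=z.shape), period)
        u_prop = beta * u(prop)
        accept = np.log(rng.uniform(size=8)) < (u_cur - u_prop)
        z = np.where(accept[:, None], prop, z)
        u_cur = np.where(accept, u_prop, u_cur)
        if t >= burn_in and (t - burn_in) % stride == stride - 1:
            kept.append(z.copy())
    samples = np.concatenate(kept)[:n_samples]
    manifest = {
        "generator": "gen_periodic_2d",
        "amplitudes": a.tolist(),
        "period": period,
        "beta": beta,
        "n_samples": n_samples,
        "seed": seed,
    }
    return samples, manifest


@dataclass
class DualLevelDataset:
    """Low-level umbrella samples with paired high-level energies.

    Emulates the dual-theory workflow: restrained sampling on a cheap
    low-level surface, single-point high-level energies on the stored
    snapshots, and reweighting to the unrestrained high-level ensemble.
    """

    trajectories: list[np.ndarray]
    u_ll: list[np.ndarray]
    u_hl: list[np.ndarray]
    centers: np.ndarray
    spring_k: float
    beta: float
    ll_potential: ToyPotential
    hl_potential: ToyPotential
    manifest: dict

    def hl_pmf_reference(self, bin_edges) -> np.ndarray:
        """Quadrature PMF of the high-level surface on the given bins."""
        return pmf_reference(self.hl_potential, self.beta, bin_edges)


def gen_dual_level(
    ll_potential: ToyPotential,
    hl_potential: ToyPotential,
    centers,
    spring_k: float,
    beta: float,
    n_per_window: int,
    seed: int = 0,
    **mcmc_kwargs,
) -> DualLevelDataset:
    """Umbrella sampling on the low-level surface, both energies recorded.

    The high-level surface is expected to be the low-level one plus a
    bounded smooth correction; its reference PMF comes from quadrature via
    :meth:`DualLevelDataset.hl_pmf_reference`.
    """
    um = gen_umbrella_windows(
        ll_potential, centers, spring_k, beta, n_per_window, seed,
        **mcmc_kwargs,
    )
    u_ll = [ll_potential.energy(t) for t in um.trajectories]
    u_hl = [hl_potential.energy(t) for t in um.trajectories]
    return DualLevelDataset(
        trajectories=um.trajectories,
        u_ll=u_ll,
        u_hl=u_hl,
        centers=um.centers,
        spring_k=spring_k,
        beta=beta,
        ll_potential=ll_potential,
        hl_potential=hl_potential,
        manifest={
            "generator": "gen_dual_level",
            "ll_potential": ll_potential.manifest(),
            "hl_potential": hl_potential.manifest(),
            "centers": um.centers.tolist(),
            "spring_k": spring_k,
            "beta": beta,
            "n_per_window": n_per_window,
            "seed": seed,
            "mcmc": dict(mcmc_kwargs),
        },
    )
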