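"""Thermodynamic state definitions and reduced-potential matrix construction.

A thermodynamic state is defined by an inverse temperature beta together with
mode-specific parameters: a harmonic restraint (umbrella windows), a bare
scaling of the system potential (temperature ladders), an alchemical lambda
(FEP strata), or a named column of full potential energies (REST/gREST and
dual-level reweighting).  The reduced potential of state i evaluated on a
sample x is the dimensionless

    u_i(x) = beta_i * [ U_i(x) + p_i * V(x) + mu_i^T n(x) ]

where the pressure-volume and chemical-potential terms contribute only when
the corresponding state parameters are declared.  Stacking u_i over all pooled
samples yields the K x N matrix consumed by the MBAR solver.

Four usage modes determine which energy terms survive in the matrix:

``restraint``
    Umbrella sampling.  The shared system potential cancels between states, so
    only the restraint energies k_i * (z - z_i_ref)^2 enter; the input reduces
    to the collective-variable trajectories, window centers and spring
    constants.
``scaling``
    Temperature ladders (T-REMD).  u_k = beta_k * U_system; the only inputs
    are the per-sample system energies and the ladder of temperatures.
``accumulation``
    Alchemical FEP over a lambda schedule.  Handled pairwise from neighbor
    reduced-energy tables by :mod:`mbarkit.accumulate`, never as a full matrix
    here.
``full``
    Whole-system potential energies per state, optionally plus a per-state
    restraint (the dual-level low-level/high-level reweighting layout).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, InputError, SampleError

__all__ = [
    "Mode",
    "ThermoState",
    "SampleSet",
    "ReducedPotentialMatrix",
    "restraint_energy",
    "reduce_potential",
    "build_reduced_matrix",
    "window_ladder",
]


class Mode(str, enum.Enum):
    """Input-preparation mode a state belongs to."""

    RESTRAINT = "restraint"
    SCALING = "scaling"
    ACCUMULATION = "accumulation"
    FULL = "full"


def _as_mode(mode) -> Mode:
    if isinstance(mode, Mode):
        return mode
    try:
        return Mode(str(mode).lower())
    except ValueError:
        raise ConfigError(
            f"unknown mode {mode!r}; expected one of "
            f"{[m.value for m in Mode]}"
        ) from None


@dataclass(frozen=True)
class ThermoState:
    """One thermodynamic state.

    Parameters
    ----------
    mode
        Usage mode; decides which fields are required and which energy terms
        enter the reduced potential.
    beta
        Inverse temperature in 1/(kcal/mol).  Must be positive.
    pressure
        Optional pressure such that ``pressure * volume`` is in kcal/mol.
        When set, a p*V term is added for sample sets that carry volumes.
    chem_potentials
        Optional per-component chemical potentials (kcal/mol per molecule).
    spring_k
        Harmonic restraint constant(s), kcal/mol per squared CV unit, using
        the k*(dz)^2 convention (no 1/2 factor).  Scalar or one per CV
        dimension.
    z_ref
        Restraint center(s) in CV units.
    periodic
        Optional per-CV period; displacements are wrapped to the minimum
        image.  ``None`` entries mean non-periodic.
    lambda_value
        Alchemical coupling in [0, 1] (accumulation mode metadata).
    energy_column
        Name of the energy column holding U_i for ``full`` mode.
    """

    mode: Mode
    beta: float
    pressure: float | None = None
    chem_potentials: np.ndarray | None = None
    spring_k: np.ndarray | None = None
    z_ref: np.ndarray | None = None
    periodic: np.ndarray | None = None
    lambda_value: float | None = None
    energy_column: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "mode", _as_mode(self.mode))
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ConfigError(f"beta must be positive and finite, got {self.beta}")
        if self.lambda_value is not None and not 0.0 <= self.lambda_value <= 1.0:
            raise ConfigError(
                f"lambda_value must lie in [0, 1], got {self.lambda_value}"
            )
        for name in ("chem_potentials", "spring_k", "z_ref", "periodic"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(
                    self, name, np.atleast_1d(np.asarray(v, dtype=float))
                )
        if self.mode is Mode.RESTRAINT:
            if self.spring_k is None or self.z_ref is None:
                raise ConfigError(
                    "restraint mode requires spring_k and z_ref"
                )
            if np.any(self.spring_k < 0):
                raise ConfigError("spring_k must be >= 0")
        if self.mode is Mode.FULL and self.energy_column is None:
            raise ConfigError("full mode requires energy_column")

    @property
    def has_restraint(self) -> bool:
        return self.spring_k is not None and self.z_ref is not None


@dataclass
class SampleSet:
    """Samples drawn at one origin state.

    ``cv`` is an (N, d) table of collective-variable values; ``energies`` maps
    column names (``U_system``, ``U_LL``, ``U_HL``, ...) to length-N arrays in
    kcal/mol.  ``volume`` and ``mol_counts`` are optional NPT / grand-canonical
    columns.
    """

    origin_state: int
    cv: np.ndarray | None = None
    energies: pd.DataFrame | Mapping[str, np.ndarray] | None = None
    volume: np.ndarray | None = None
    mol_counts: np.ndarray | None = None

    def __post_init__(self):
        if self.cv is not None:
            cv = np.asarray(self.cv, dtype=float)
            if cv.ndim == 1:
                cv = cv[:, None]
            self.cv = cv
        if self.energies is not None and not isinstance(self.energies, pd.DataFrame):
            self.energies = pd.DataFrame(
                {k: np.asarray(v, dtype=float) for k, v in self.energies.items()}
            )
        if self.volume is not None:
            self.volume = np.asarray(self.volume, dtype=float)
        if self.mol_counts is not None:
            mc = np.asarray(self.mol_counts)
            if mc.ndim == 1:
                mc = mc[:, None]
            self.mol_counts = mc
        lengths = {
            name: len(arr)
            for name, arr in (
                ("cv", self.cv),
                ("energies", self.energies),
                ("volume", self.volume),
                ("mol_counts", self.mol_counts),
            )
            if arr is not None
        }
        if not lengths:
            raise InputError("SampleSet must carry at least one data column")
        if len(set(lengths.values())) > 1:
            raise InputError(f"column length mismatch in SampleSet: {lengths}")
        self._n = next(iter(lengths.values()))

    @property
    def n_samples(self) -> int:
        return self._n

    def energy_column(self, name: str) -> np.ndarray:
        """Return one named energy column, validating presence and finiteness.

        +inf is a legal sentinel (zero Boltzmann weight); NaN and -inf are not.
        """
        if self.energies is None or name not in self.energies.columns:
            have = [] if self.energies is None else list(self.energies.columns)
            raise InputError(
                f"sample set from state {self.origin_state} is missing energy "
                f"column {name!r} (available: {have})"
            )
        col = self.energies[name].to_numpy(dtype=float)
        bad = np.flatnonzero(np.isnan(col) | np.isneginf(col))
        if bad.size:
            raise SampleError(
                f"energy column {name!r} has non-finite values at rows "
                f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}",
                indices=bad,
            )
        return col


@dataclass
class ReducedPotentialMatrix:
    """K x N_total matrix of reduced potentials over pooled samples.

    ``counts[j]`` is the number of samples originating from state j (zero only
    for appended target states); ``origin_of_sample`` maps each pooled column
    back to its origin state.  Entries are finite or an explicit +inf sentinel
    (zero Boltzmann weight); NaN is rejected.
    """

    u: np.ndarray
    counts: np.ndarray
    origin_of_sample: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.origin_of_sample = np.asarray(self.origin_of_sample, dtype=np.int64)
        if self.u.ndim != 2:
            raise InputError("u must be a 2-D (K x N) matrix")
        if int(self.counts.sum()) != self.u.shape[1]:
            raise InputError(
                f"counts sum to {int(self.counts.sum())} but u has "
                f"{self.u.shape[1]} columns"
            )
        if self.origin_of_sample.shape != (self.u.shape[1],):
            raise InputError("origin_of_sample must have one entry per column")
        if np.isnan(self.u).any() or np.isneginf(self.u).any():
            raise InputError(
                "reduced potentials must be finite or +inf (never NaN/-inf)"
            )

    @property
    def n_states(self) -> int:
        return self.u.shape[0]

    @property
    def n_total(self) -> int:
        return self.u.shape[1]


def restraint_energy(
    spring_k,
    z,
    z_ref,
    periodic=None,
    *,
    half_spring: bool = False,
) -> np.ndarray:
    """Harmonic restraint energy sum_d k_d * (dz_d)^2 in kcal/mol.

    ``z`` is (N, d) or (N,); ``z_ref`` and ``spring_k`` broadcast over the d
    CV dimensions.  For periodic CVs, dz is the minimum-image displacement
    on the declared period.  ``half_spring=True`` converts inputs that use the
    (1/2) k dz^2 convention to the internal k dz^2 form.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    z_ref = np.atleast_1d(np.asarray(z_ref, dtype=float))
    if z_ref.shape[0] != z.shape[1]:
        raise InputError(
            f"z has {z.shape[1]} CV dimensions but z_ref has {z_ref.shape[0]}"
        )
    k = np.broadcast_to(np.atleast_1d(np.asarray(spring_k, dtype=float)), z_ref.shape)
    dz = z - z_ref[None, :]
    if periodic is not None:
        period = np.atleast_1d(np.asarray(periodic, dtype=float))
        if period.shape[0] != z.shape[1]:
            raise InputError(
                f"periodic has {period.shape[0]} entries for {z.shape[1]} CVs"
            )
        wrap = ~np.isnan(period)
        if wrap.any():
            p = np.where(wrap, period, 1.0)
            dz = np.where(wrap[None, :], dz - p * np.round(dz / p), dz)
    e = np.sum(k[None, :] * dz * dz, axis=1)
    return 0.5 * e if half_spring else e


def reduce_potential(
    state: ThermoState,
    samples: SampleSet,
    *,
    half_spring: bool = False,
) -> np.ndarray:
    """Dimensionless reduced potential of ``state`` on every sample.

    Returns beta_i * [U_i + p_i V + mu_i^T n] where the energy term U_i is
    mode-dependent: the restraint energy alone (restraint mode, the shared
    system potential having cancelled), the ``U_system`` column (scaling), or
    the state's named column plus its restraint when one is configured (full).
    Declared pressure or chemical potentials add their terms; omitted ones
    contribute zero.
    """
    mode = state.mode
    if mode is Mode.RESTRAINT:
        if samples.cv is None:
            raise InputError(
                "restraint mode needs collective-variable samples (cv)"
            )
        energy = restraint_energy(
            state.spring_k, samples.cv, state.z_ref, state.periodic,
            half_spring=half_spring,
        )
    elif mode is Mode.SCALING:
        energy = samples.energy_column("U_system")
    elif mode is Mode.FULL:
        energy = samples.energy_column(state.energy_column)
        if state.has_restraint:
            if samples.cv is None:
                raise InputError(
                    "full mode with a restraint needs cv samples"
                )
            energy = energy + restraint_energy(
                state.spring_k, samples.cv, state.z_ref, state.periodic,
                half_spring=half_spring,
            )
    else:
        raise ConfigError(
            "accumulation-mode states are estimated pairwise from neighbor "
            "energies (mbarkit.accumulate), not through reduce_potential"
        )
    total = np.array(energy, dtype=float, copy=True)
    if state.pressure is not None:
        if samples.volume is None:
            raise InputError("state declares pressure but samples have no volume")
        total += state.pressure * samples.volume
    if state.chem_potentials is not None:
        if samples.mol_counts is None:
            raise InputError(
                "state declares chemical potentials but samples have no mol_counts"
            )
        mu = state.chem_potentials
        if samples.mol_counts.shape[1] != mu.shape[0]:
            raise InputError(
                f"{mu.shape[0]} chemical potentials vs "
                f"{samples.mol_counts.shape[1]} molecule-count columns"
            )
        total += samples.mol_counts @ mu
    return state.beta * total


def build_reduced_matrix(
    states: Sequence[ThermoState],
    samplesets: Sequence[SampleSet],
    *,
    half_spring: bool = False,
) -> ReducedPotentialMatrix:
    """Assemble the K x N_total reduced-potential matrix.

    All states must share one mode.  Sampled states come first and must each
    have a sample set (in state order); trailing states without samples are
    permitted as appended zero-count targets, the mechanism by which unsampled
    states are estimated.
    """
    if not states:
        raise ConfigError("need at least one state")
    modes = {s.mode for s in states}
    if len(modes) > 1:
        raise ConfigError(
            f"all states must share one mode, got {sorted(m.value for m in modes)}"
        )
    if next(iter(modes)) is Mode.ACCUMULATION:
        raise ConfigError(
            "accumulation mode is handled pairwise by mbarkit.accumulate"
        )
    if len(samplesets) > len(states):
        raise ConfigError(
            f"{len(samplesets)} sample sets for {len(states)} states"
        )
    if len(samplesets) == 0:
        raise ConfigError("need at least one sampled state")

    counts = np.zeros(len(states), dtype=np.int64)
    origin = []
    for j, ss in enumerate(samplesets):
        if ss.n_samples == 0:
            raise ConfigError(
                f"sample set {j} is empty; zero-count states are permitted "
                "only as appended targets without a sample set"
            )
        counts[j] = ss.n_samples
        origin.append(np.full(ss.n_samples, ss.origin_state, dtype=np.int64))
    origin = np.concatenate(origin)

    rows = []
    for state in states:
        rows.append(
            np.concatenate(
                [reduce_potential(state, ss, half_spring=half_spring)
                 for ss in samplesets]
            )
        )
    return ReducedPotentialMatrix(np.vstack(rows), counts, origin)


def window_ladder(start: float, stop: float, spacing: float) -> np.ndarray:
    """Inclusive arithmetic ladder of window centers from start to stop.

    ``(0, 180, 3)`` yields 61 centers; ``(-1.0, 1.0, 0.1)`` yields 21.
    """
    if stop < start:
        raise InputError(f"stop ({stop}) must be >= start ({start})")
    if start == stop:
        return np.array([float(start)])
    if spacing <= 0:
        raise InputError(f"spacing must be positive, got {spacing}")
    n_steps = (stop - start) / spacing
    n = int(round(n_steps))
    if abs(n_steps - n) > 1e-9 * max(1.0, abs(n_steps)):
        raise InputError(
            f"spacing {spacing} does not evenly divide [{start}, {stop}]"
        )
    return np.linspace(start, stop, n + 1)
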