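"""Alchemical FEP by accumulation of neighbor-pair free-energy differences.

A lambda-stratified transformation mixes two endpoint potentials,
U(x; lambda) = (1 - lambda) U_start + lambda U_end.  Rather than filling the
full K x N reduced-energy matrix (non-neighbor differences are costly to
evaluate and can be infinite where configurations overlap cores), only the
reduced energies of each state at itself and at its immediate neighbors are
consumed.  Each neighbor pair is solved as the two-state case of the MBAR
equations — which is exactly Bennett's acceptance-ratio estimator — and the
endpoint difference is the accumulated sum of the pair differences.  The
one-sided exponential (Zwanzig) average is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._exceptions import InputError
from .solver import solve_mbar
from .uncertainty import ResamplingPlan, block_se, bootstrap_se

__all__ = [
    "NeighborEnergySet",
    "ChainResult",
    "bar_pair",
    "exp_average",
    "accumulate_chain",
    "estimate_chain",
]


@dataclass
class NeighborEnergySet:
    """Reduced energies of one lambda state's samples at itself and neighbors.

    ``u_self[n] = u_i(x_in)``; ``u_prev`` / ``u_next`` are the same samples
    re-evaluated under the neighboring states (absent at the chain ends).
    +inf entries are legal and carry zero Boltzmann weight.
    """

    state_index: int
    u_self: np.ndarray
    u_prev: np.ndarray | None = None
    u_next: np.ndarray | None = None

    def __post_init__(self):
        self.u_self = np.asarray(self.u_self, dtype=float)
        for name in ("u_prev", "u_next"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.u_self.shape:
                    raise InputError(
                        f"{name} length {v.shape} != u_self {self.u_self.shape} "
                        f"for state {self.state_index}"
                    )
                setattr(self, name, v)
        if self.u_prev is None and self.u_next is None:
            raise InputError(
                f"state {self.state_index} has no neighbor columns"
            )

    @property
    def n_samples(self) -> int:
        return len(self.u_self)


@dataclass
class ChainResult:
    """Accumulated free-energy profile along the lambda chain.

    ``cumulative[i]`` is the dimensionless difference f_i - f_0; the total is
    exactly the sum of the pair estimates.
    """

    pair_delta_f: np.ndarray
    pair_se: np.ndarray
    cumulative: np.ndarray
    total: float
    total_se: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": np.arange(len(self.pair_delta_f)),
                "delta_f": self.pair_delta_f,
                "se": self.pair_se,
                "cumulative": self.cumulative[1:],
            }
        )


def _pair_matrix(u_self_i, u_next_i, u_self_j, u_prev_j):
    """Two-state reduced matrix: state i samples first, then state j samples."""
    u = np.vstack(
        [
            np.concatenate([u_self_i, u_prev_j]),
            np.concatenate([u_next_i, u_self_j]),
        ]
    )
    counts = np.array([len(u_self_i), len(u_self_j)], dtype=np.int64)
    return u, counts


def _pair_delta_f(u_self_i, u_next_i, u_self_j, u_prev_j, initial=None):
    u, counts = _pair_matrix(u_self_i, u_next_i, u_self_j, u_prev_j)
    res = solve_mbar(
        u,
        counts,
        initial_f=None if initial is None else np.array([0.0, initial]),
        compute_ess=False,
    )
    return float(res.f_hat[1] - res.f_hat[0])


def bar_pair(fwd: NeighborEnergySet, rev: NeighborEnergySet, plan=None):
    """Free-energy difference of one neighbor pair by two-state MBAR (= BAR).

    ``fwd`` supplies u_i and u_{i+1} on state-i samples, ``rev`` supplies the
    same two states on state-(i+1) samples.  Returns (delta_f, se); the SE is
    computed per the plan (default: block averaging with 10 blocks).
    """
    if rev.state_index != fwd.state_index + 1:
        raise InputError(
            f"states {fwd.state_index} and {rev.state_index} are not neighbors"
        )
    if fwd.u_next is None:
        raise InputError(f"state {fwd.state_index} lacks a u_next column")
    if rev.u_prev is None:
        raise InputError(f"state {rev.state_index} lacks a u_prev column")
    if fwd.n_samples < 2 or rev.n_samples < 2:
        raise InputError("each side of a pair must contribute >= 2 samples")
    df = _pair_delta_f(fwd.u_self, fwd.u_next, rev.u_self, rev.u_prev)
    plan = plan or ResamplingPlan()
    se = _pair_se(fwd, rev, df, plan)
    return df, se


def _pair_se(fwd, rev, point, plan):
    ui = np.vstack([fwd.u_self, fwd.u_next])
    uj = np.vstack([rev.u_prev, rev.u_self])

    def estimator(idx, counts):
        ni = counts[0]
        ii, jj = idx[:ni], idx[ni:] - fwd.n_samples
        return _pair_delta_f(
            ui[0, ii], ui[1, ii], uj[1, jj], uj[0, jj], initial=point
        )

    counts = np.array([fwd.n_samples, rev.n_samples])
    if plan.method == "block":
        return float(block_se(estimator, counts, plan.n_blocks))
    se, _ = bootstrap_se(estimator, counts, plan.n_replicates, plan.seed)
    return float(se)


def exp_average(delta_u) -> float:
    """One-sided exponential (Zwanzig) estimate -ln < exp(-delta_u) >.

    ``delta_u`` holds u_target - u_origin evaluated on origin-state samples;
    evaluated with log-sum-exp so large differences cannot overflow.
    """
    delta_u = np.asarray(delta_u, dtype=float)
    if delta_u.size == 0:
        raise InputError("exp_average needs at least one sample")
    return float(-(logsumexp(-delta_u) - np.log(delta_u.size)))


def accumulate_chain(pairs, indices=None) -> ChainResult:
    """Combine per-pair (delta_f, se) estimates into the chain profile.

    ``indices``, when given, are the (i, i+1) pair positions and must be
    contiguous.  The total SE here is the root-sum-square of the pair SEs,
    which treats pairs as independent even though interior sample sets are
    shared by two pairs; :func:`estimate_chain` offers whole-chain block
    averaging instead.
    """
    pairs = list(pairs)
    if not pairs:
        raise InputError("empty pair list")
    if indices is not None:
        indices = list(indices)
        expect = list(range(indices[0], indices[0] + len(indices)))
        if indices != expect:
            raise InputError(f"gap in chain: pair indices {indices}")
    df = np.array([p[0] for p in pairs], dtype=float)
    se = np.array([p[1] for p in pairs], dtype=float)
    cumulative = np.concatenate([[0.0], np.cumsum(df)])
    return ChainResult(
        pair_delta_f=df,
        pair_se=se,
        cumulative=cumulative,
        total=float(df.sum()),
        total_se=float(np.sqrt(np.sum(se**2))),
    )


def estimate_chain(neighbor_sets, plan=None) -> ChainResult:
    """Full accumulation workflow from an ordered list of neighbor-energy sets.

    Solves every neighbor pair as two-state MBAR and accumulates.  The total
    SE comes from the configured plan applied to the whole chain: each block
    (or bootstrap replicate) re-estimates every pair on its own slice of
    every state's time series, so the correlation induced by interior states
    shared between adjacent pairs is carried through to the spread.
    """
    sets = list(neighbor_sets)
    if len(sets) < 2:
        raise InputError("a chain needs at least two states")
    for a, b in zip(sets[:-1], sets[1:]):
        if b.state_index != a.state_index + 1:
            raise InputError(
                f"gap in chain between states {a.state_index} and "
                f"{b.state_index}"
            )
    plan = plan or ResamplingPlan()

    def pair_on_slices(slices):
        out = []
        for a, b, sl_a, sl_b in zip(sets[:-1], sets[1:], slices[:-1], slices[1:]):
            out.append(
                _pair_delta_f(
                    a.u_self[sl_a], a.u_next[sl_a],
                    b.u_self[sl_b], b.u_prev[sl_b],
                )
            )
        return np.asarray(out)

    full = pair_on_slices([slice(None)] * len(sets))

    counts = np.array([s.n_samples for s in sets], dtype=np.int64)

    def estimator(idx, c):
        offsets = np.concatenate([[0], np.cumsum(counts)])
        local = [
            idx[(idx >= offsets[j]) & (idx < offsets[j + 1])] - offsets[j]
            for j in range(len(sets))
        ]
        return pair_on_slices(local)

    from .uncertainty import resample_estimates

    estimates = np.asarray(
        resample_estimates(estimator, counts, plan), dtype=float
    )
    spread = np.std(estimates, axis=0, ddof=1)
    totals = estimates.sum(axis=1)
    total_spread = np.std(totals, ddof=1)
    if plan.method == "block":
        spread = spread / np.sqrt(len(estimates))
        total_spread = total_spread / np.sqrt(len(estimates))
    return ChainResult(
        pair_delta_f=full,
        pair_se=spread,
        cumulative=np.concatenate([[0.0], np.cumsum(full)]),
        total=float(full.sum()),
        total_se=float(total_spread),
    )
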