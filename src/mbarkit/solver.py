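"""Self-consistent / Newton solver for the MBAR equations.

Given K states with reduced potentials u_k(x_jn) over the pooled samples and
origin counts N_k, the dimensionless free energies f_i solve

    f_i = -ln sum_jn  exp[-u_i(x_jn)] / sum_k N_k exp[f_k - u_k(x_jn)]

simultaneously for all i.  The solution is unique up to an additive constant;
we anchor f_1 = 0.  The fixed point is also the stationary point of the
standard convex MBAR objective

    kappa(f) = sum_n ln sum_k N_k exp(f_k - u_kn)  -  sum_k N_k f_k,

whose gradient and Hessian drive the Newton path.  The solver runs cheap
self-consistent sweeps until the residual is modest, then switches to damped
Newton steps with a self-consistent fallback whenever a step fails to reduce
the residual.  Every sum is evaluated in log space (log-sum-exp), so +inf
reduced potentials (zero-weight configurations, e.g. overlapping cores at
decoupled alchemical endpoints) are benign.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._exceptions import ConvergenceError, InputError
from .states import ReducedPotentialMatrix

__all__ = [
    "MBARResult",
    "solve_mbar",
    "self_consistent_step",
    "newton_step",
    "residual",
    "effective_sample_sizes",
]

#: Warn when a state's effective sample size falls below this.
ESS_WARN_THRESHOLD = 50.0


@dataclass
class MBARResult:
    """Solved dimensionless free energies and cached per-sample denominators.

    ``f_hat`` is anchored to ``f_hat[0] == 0``.  ``log_denominator[n]`` is
    ln sum_k N_k exp(f_hat_k - u_kn), the quantity every reweighting formula
    divides by; caching it makes target-state estimates O(N).
    """

    f_hat: np.ndarray
    log_denominator: np.ndarray
    counts: np.ndarray
    n_iterations: int
    final_residual: float
    converged: bool
    ess: np.ndarray | None = None

    def delta_f(self, i: int, j: int = 0) -> float:
        """Free-energy difference f_i - f_j (dimensionless)."""
        return float(self.f_hat[i] - self.f_hat[j])

    def to_report(self) -> dict:
        """JSON-serializable summary: f per state, deltas to state 1, ESS."""
        return {
            "f_hat": self.f_hat.tolist(),
            "delta_f_to_first": (self.f_hat - self.f_hat[0]).tolist(),
            "counts": self.counts.tolist(),
            "n_iterations": self.n_iterations,
            "final_residual": self.final_residual,
            "converged": self.converged,
            "ess": None if self.ess is None else self.ess.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_report(), **kwargs)


def _unpack(u, counts):
    if isinstance(u, ReducedPotentialMatrix):
        return u.u, u.counts
    if counts is None:
        raise InputError("counts required when u is a bare array")
    return np.asarray(u, dtype=float), np.asarray(counts, dtype=np.int64)


def _log_denominator(f, u, counts, active):
    # ln sum_k N_k exp(f_k - u_kn) over states with N_k > 0
    a = np.log(counts[active])[:, None] + f[active, None] - u[active, :]
    return logsumexp(a, axis=0)


def self_consistent_step(f, u, counts=None):
    """One evaluation of the MBAR right-hand side for all states, re-anchored.

    Computed entirely with log-sum-exp, so no intermediate exponential can
    overflow even for widely separated states.
    """
    u, counts = _unpack(u, counts)
    f = np.asarray(f, dtype=float)
    active = counts > 0
    log_denom = _log_denominator(f, u, counts, active)
    f_new = -logsumexp(-u - log_denom[None, :], axis=1)
    return f_new - f_new[0]


def residual(f, u, counts=None) -> float:
    """Max-norm gap between f and one re-anchored self-consistent update."""
    f = np.asarray(f, dtype=float)
    return float(np.max(np.abs(f - self_consistent_step(f, u, counts))))


def _gradient_hessian(f, u, counts, active):
    """Gradient and Hessian of the convex MBAR objective at f.

    W'_kn = exp(f_k - u_kn - L_n); at the solution sum_n W'_kn = 1 for every
    sampled state.  g_k = N_k (sum_n W'_kn - 1);
    H_kl = delta_kl N_k sum_n W'_kn - N_k N_l sum_n W'_kn W'_ln.
    """
    log_denom = _log_denominator(f, u, counts, active)
    with np.errstate(under="ignore"):
        w = np.exp(f[:, None] - u - log_denom[None, :])  # K x N, rows for all k
    row_sums = w.sum(axis=1)
    n = counts.astype(float)
    g = n * (row_sums - 1.0)
    h = np.diag(n * row_sums) - (n[:, None] * n[None, :]) * (w @ w.T)
    return g, h, log_denom


def newton_step(f, u, counts=None):
    """One damped Newton update on the K-1 free components (f_1 anchored).

    Derivatives come from the convex objective whose stationarity condition
    is the MBAR fixed point.  If the full or halved step fails to reduce the
    residual, or the Hessian is singular, falls back to a self-consistent
    step.
    """
    u, counts = _unpack(u, counts)
    f = np.asarray(f, dtype=float)
    k = len(f)
    if k == 1:
        return np.zeros(1)
    active = counts > 0
    g, h, _ = _gradient_hessian(f, u, counts, active)
    free = np.arange(1, k)
    h_ff = h[np.ix_(free, free)]
    g_f = g[free]
    base_res = residual(f, u, counts)
    try:
        delta = np.linalg.solve(h_ff, -g_f)
    except np.linalg.LinAlgError:
        return self_consistent_step(f, u, counts)
    if not np.all(np.isfinite(delta)):
        return self_consistent_step(f, u, counts)
    for damping in (1.0, 0.5, 0.25, 0.1):
        f_try = f.copy()
        f_try[free] = f[free] + damping * delta
        f_try -= f_try[0]
        if residual(f_try, u, counts) < base_res:
            return f_try
    return self_consistent_step(f, u, counts)


def effective_sample_sizes(f, u, counts=None) -> np.ndarray:
    """Per-state ESS_k = 1 / sum_n w_kn^2 of the normalized MBAR weights.

    Low ESS signals poor configuration-space overlap between that state and
    the pooled samples; its free energy may carry large uncertainty even when
    the equations converge.
    """
    u, counts = _unpack(u, counts)
    f = np.asarray(f, dtype=float)
    active = counts > 0
    log_denom = _log_denominator(f, u, counts, active)
    logw = -u - log_denom[None, :]
    logw = logw - logsumexp(logw, axis=1)[:, None]
    with np.errstate(under="ignore"):
        return 1.0 / np.exp(logsumexp(2.0 * logw, axis=1))


def solve_mbar(
    u,
    counts=None,
    *,
    tolerance: float = 1e-8,
    max_iterations: int = 100_000,
    initial_f=None,
    newton_switch: float = 1e-2,
    compute_ess: bool = True,
) -> MBARResult:
    """Solve the MBAR equations for the dimensionless free energies.

    Parameters
    ----------
    u
        ReducedPotentialMatrix, or a bare (K, N) array with ``counts`` given.
    counts
        Per-state origin sample counts N_k (zero only for appended targets).
    tolerance
        Convergence threshold on the max-norm self-consistency residual.
    max_iterations
        Iteration cap; exceeding it raises ConvergenceError with the trace.
    initial_f
        Optional warm start (anchored internally).
    newton_switch
        Residual below which the solver switches from plain self-consistent
        iteration to damped Newton steps.

    Returns
    -------
    MBARResult with f_hat (f_hat[0] = 0), cached per-sample log-denominators,
    iteration/residual diagnostics and per-state effective sample sizes.
    """
    u, counts = _unpack(u, counts)
    k, n_total = u.shape
    if counts.shape != (k,):
        raise InputError(f"counts must have length {k}, got {counts.shape}")
    if int(counts.sum()) != n_total:
        raise InputError("counts must sum to the number of pooled samples")
    if not np.any(counts > 0):
        raise InputError("at least one state must have samples")
    if np.isnan(u).any() or np.isneginf(u).any():
        raise InputError("u must be finite or +inf (never NaN/-inf)")
    active = counts > 0
    if np.any(np.all(np.isposinf(u[active, :]), axis=0)):
        raise InputError(
            "some pooled sample has infinite reduced potential in every "
            "sampled state (all-infinite column)"
        )

    if initial_f is not None:
        f = np.asarray(initial_f, dtype=float).copy()
        if f.shape != (k,):
            raise InputError(f"initial_f must have length {k}")
        f -= f[0]
    else:
        f = np.zeros(k)

    # res is always the exact self-consistency residual at the current f; in
    # the plain self-consistent phase the update it was computed from is
    # reused as the next iterate, so each sweep costs one matrix pass.
    trace = []
    it = 0
    f_next = self_consistent_step(f, u, counts)
    res = float(np.max(np.abs(f - f_next)))
    while res > tolerance and it < max_iterations:
        if res > newton_switch:
            f = f_next
        else:
            f = newton_step(f, u, counts)
        f_next = self_consistent_step(f, u, counts)
        res = float(np.max(np.abs(f - f_next)))
        trace.append(res)
        it += 1
    if res > tolerance:
        raise ConvergenceError(
            f"MBAR did not converge in {max_iterations} iterations "
            f"(residual {res:.3e} > tolerance {tolerance:.3e})",
            residual_trace=trace,
        )

    log_denom = _log_denominator(f, u, counts, active)
    ess = None
    if compute_ess:
        ess = effective_sample_sizes(f, u, counts)
        low = np.flatnonzero(ess < ESS_WARN_THRESHOLD)
        if low.size:
            warnings.warn(
                f"states {low.tolist()} have effective sample size below "
                f"{ESS_WARN_THRESHOLD:g}; poor overlap, estimates may carry "
                "large uncertainties",
                stacklevel=2,
            )
    return MBARResult(
        f_hat=f,
        log_denominator=log_denom,
        counts=counts.copy(),
        n_iterations=it,
        final_residual=res,
        converged=True,
        ess=ess,
    )
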