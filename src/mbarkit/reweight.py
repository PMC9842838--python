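"""Target-state reweighting: free energies, averages, and PMFs.

Once the MBAR equations are solved, any state — sampled or not — can be
queried by appending it as a zero-count (K+1)-th state.  Its free energy is

    f_target = -ln sum_n exp[-u_target(x_n) - L_n],

with L_n the cached pooled log-denominator, and the average of an observable
A under the target ensemble is the weighted sum  sum_n A(x_n) w_n  with
normalized weights  w_n ∝ exp[-u_target(x_n) - L_n].  Taking A to be the
indicator of a collective-variable bin yields the potential of mean force
without any histogram bias from the sampled (biased) ensembles.

Non-negative observables can equivalently be expressed through two free
energies, <A> = exp[f_target - f_target_A]; observables of general sign are
averaged directly, which is the form implemented here (the log form is kept
for tests of the equivalence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._exceptions import InputError, OverlapError
from .solver import MBARResult, solve_mbar
from .states import ReducedPotentialMatrix

__all__ = [
    "PMFProfile",
    "target_log_weights",
    "target_free_energy",
    "expectation",
    "compute_pmf",
    "reweighting_cost_fraction",
]


@dataclass
class PMFProfile:
    """A binned potential of mean force in units of kT.

    ``pmf`` is min-shifted so the lowest non-empty bin is zero; empty bins are
    flagged and carry NaN.  ``eff_count`` is the per-bin effective number of
    contributing samples (sum w)^2 / sum w^2.  For 2-D profiles ``bin_edges``
    is a tuple of two edge arrays and the value arrays are 2-D.
    """

    bin_edges: np.ndarray | tuple[np.ndarray, np.ndarray]
    pmf: np.ndarray
    se: np.ndarray | None
    eff_count: np.ndarray
    empty: np.ndarray

    @property
    def ndim(self) -> int:
        return 1 if isinstance(self.bin_edges, np.ndarray) else 2

    @property
    def bin_centers(self):
        if self.ndim == 1:
            return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.bin_edges)

    def in_kcal_mol(self, temperature_k: float) -> np.ndarray:
        """PMF converted from kT to kcal/mol at the given temperature."""
        from .constants import KB_KCAL_MOL_K

        return self.pmf * (KB_KCAL_MOL_K * temperature_k)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form (bin centers, pmf, se, eff_count, empty flag)."""
        if self.ndim == 1:
            data = {"bin_center": self.bin_centers}
        else:
            c0, c1 = self.bin_centers
            g0, g1 = np.meshgrid(c0, c1, indexing="ij")
            data = {"bin_center_0": g0.ravel(), "bin_center_1": g1.ravel()}
        data["pmf"] = self.pmf.ravel()
        data["se"] = (
            np.full(self.pmf.size, np.nan) if self.se is None else self.se.ravel()
        )
        data["eff_count"] = self.eff_count.ravel()
        data["empty"] = self.empty.ravel().astype(int)
        return pd.DataFrame(data)


def _target_log_numerators(result: MBARResult, u_target) -> np.ndarray:
    u_target = np.asarray(u_target, dtype=float)
    if u_target.shape != result.log_denominator.shape:
        raise InputError(
            f"u_target has {u_target.shape} entries, expected "
            f"{result.log_denominator.shape}"
        )
    if np.isnan(u_target).any() or np.isneginf(u_target).any():
        raise InputError("u_target must be finite or +inf")
    return -u_target - result.log_denominator


def target_log_weights(result: MBARResult, u_target) -> np.ndarray:
    """Normalized per-sample log weights of the target ensemble.

    log w_n = -u_target(x_n) - L_n, normalized so sum_n w_n = 1.  Invariant
    under any constant shift of u_target.
    """
    log_num = _target_log_numerators(result, u_target)
    norm = logsumexp(log_num)
    if not np.isfinite(norm):
        raise OverlapError(
            "target state has no overlap with samples (all weights vanish)"
        )
    return log_num - norm


def target_free_energy(result: MBARResult, u_target) -> float:
    """Dimensionless free energy of the target state on the pooled samples.

    Reduces exactly to f_hat_i when u_target equals a sampled state's row.
    """
    log_num = _target_log_numerators(result, u_target)
    f = -logsumexp(log_num)
    if not np.isfinite(f):
        raise OverlapError(
            "target state has no overlap with samples (all weights vanish)"
        )
    return float(f)


def expectation(result: MBARResult, u_target, a) -> float:
    """Estimate <A>_target as the weight-averaged sum over pooled samples.

    Supports observables of general sign; for A >= 0 this coincides with the
    two-free-energy form exp[f_target - f_target_A].
    """
    a = np.asarray(a, dtype=float)
    logw = target_log_weights(result, u_target)
    if a.shape != logw.shape:
        raise InputError(f"A has shape {a.shape}, expected {logw.shape}")
    with np.errstate(under="ignore"):
        return float(np.sum(a * np.exp(logw)))


def log_form_expectation(result: MBARResult, u_target, a) -> float:
    """<A>_target for A >= 0 via exp[f_target - f_target_A].

    The weighted-free-energy route; kept as an internally independent path
    for consistency checks against :func:`expectation`.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise InputError("log-form expectation requires A >= 0")
    log_num = _target_log_numerators(result, u_target)
    f_target = -logsumexp(log_num)
    with np.errstate(divide="ignore"):
        f_target_a = -logsumexp(log_num + np.log(a))
    return float(np.exp(f_target - f_target_a))


def _bin_index_1d(x, edges):
    """Half-open bins [e_i, e_{i+1}), last bin closed; -1 outside."""
    idx = np.searchsorted(edges, x, side="right") - 1
    idx[np.asarray(x) == edges[-1]] = len(edges) - 2
    idx[(idx < 0) | (idx > len(edges) - 2)] = -1
    return idx


def _pmf_raw(logw, cv, bin_edges):
    """Unshifted per-bin -ln sum w plus effective counts.

    Returns (neg_log_wsum, eff_count, empty) with 1-D or 2-D layouts.
    """
    cv = np.asarray(cv, dtype=float)
    if cv.ndim == 1:
        cv = cv[:, None]
    d = cv.shape[1]
    if d > 2:
        raise InputError(f"PMFs supported for 1 or 2 CV dimensions, got {d}")
    if d == 1:
        edges = np.asarray(bin_edges, dtype=float)
        nb = len(edges) - 1
        flat_idx = _bin_index_1d(cv[:, 0], edges)
        shape = (nb,)
    else:
        if not isinstance(bin_edges, (tuple, list)) or len(bin_edges) != 2:
            raise InputError("2-D PMF needs a pair of bin-edge arrays")
        e0 = np.asarray(bin_edges[0], dtype=float)
        e1 = np.asarray(bin_edges[1], dtype=float)
        i0 = _bin_index_1d(cv[:, 0], e0)
        i1 = _bin_index_1d(cv[:, 1], e1)
        nb0, nb1 = len(e0) - 1, len(e1) - 1
        flat_idx = np.where((i0 >= 0) & (i1 >= 0), i0 * nb1 + i1, -1)
        nb = nb0 * nb1
        shape = (nb0, nb1)
    with np.errstate(under="ignore"):
        w = np.exp(logw)
    inside = flat_idx >= 0
    wsum = np.bincount(flat_idx[inside], weights=w[inside], minlength=nb)
    w2sum = np.bincount(flat_idx[inside], weights=w[inside] ** 2, minlength=nb)
    empty = wsum <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log = np.where(empty, np.nan, -np.log(wsum))
        eff = np.where(empty, 0.0, wsum**2 / np.where(empty, 1.0, w2sum))
    return neg_log.reshape(shape), eff.reshape(shape), empty.reshape(shape)


def compute_pmf(
    result: MBARResult,
    u_target,
    cv,
    bin_edges,
    *,
    matrix: ReducedPotentialMatrix | None = None,
    plan=None,
) -> PMFProfile:
    """PMF over collective-variable bins under the target ensemble, in kT.

    Each bin's value is -ln of the total normalized target weight it holds
    (the indicator-observable route), min-shifted to zero over non-empty
    bins.  When a :class:`~mbarkit.uncertainty.ResamplingPlan` is supplied
    together with the reduced-potential ``matrix``, per-bin standard errors
    are estimated by re-solving the full chain (MBAR refit + reweighting) on
    each block or bootstrap replicate.
    """
    logw = target_log_weights(result, u_target)
    neg_log, eff, empty = _pmf_raw(logw, cv, bin_edges)
    if empty.all():
        raise InputError("all PMF bins are empty; check bin edges vs CV range")

    se = None
    if plan is not None:
        if matrix is None:
            raise InputError("per-bin standard errors need the reduced matrix")
        se = _pmf_se(result, matrix, u_target, cv, bin_edges, plan).reshape(
            neg_log.shape
        )

    shift = np.nanmin(neg_log)
    pmf = neg_log - shift
    return PMFProfile(
        bin_edges=(
            np.asarray(bin_edges, dtype=float)
            if not isinstance(bin_edges, (tuple, list))
            else tuple(np.asarray(e, dtype=float) for e in bin_edges)
        ),
        pmf=pmf,
        se=se,
        eff_count=eff,
        empty=empty,
    )


def _pmf_se(result, matrix, u_target, cv, bin_edges, plan):
    """Per-bin SE by resampling; each replicate refits MBAR warm-started.

    The replicate statistic is the difference of the unshifted per-bin value
    to its replicate mean over non-empty bins, which removes the arbitrary
    overall normalization before the spread is measured.
    """
    from .uncertainty import resample_estimates

    u_target = np.asarray(u_target, dtype=float)
    cv = np.asarray(cv, dtype=float)

    def estimator(idx, counts):
        sub = matrix.u[:, idx]
        res = solve_mbar(
            sub, counts, initial_f=result.f_hat, compute_ess=False
        )
        logw = target_log_weights(res, u_target[idx])
        neg_log, _, _ = _pmf_raw(logw, cv[idx], bin_edges)
        flat = neg_log.ravel()
        return flat - np.nanmean(flat)

    estimates = resample_estimates(estimator, matrix.counts, plan)
    stacked = np.vstack(estimates)
    n_rep = stacked.shape[0]
    finite = np.isfinite(stacked)
    enough = finite.sum(axis=0) >= max(2, n_rep // 2)
    with np.errstate(invalid="ignore"):
        spread = np.nanstd(np.where(finite, stacked, np.nan), axis=0, ddof=1)
    if plan.method == "block":
        spread = spread / np.sqrt(n_rep)
    return np.where(enough, spread, np.nan)


def reweighting_cost_fraction(n_reweighted: int, n_brute_force: int) -> float:
    """Cost of single-point reweighting relative to a brute-force run, in %.

    The dual-level workflow replaces ``n_brute_force`` high-level MD steps by
    high-level single-point energies on ``n_reweighted`` stored snapshots;
    the quotient (as a percentage) is the headline cost saving.
    """
    if n_reweighted < 0 or n_brute_force <= 0:
        raise InputError("counts must be positive")
    return 100.0 * n_reweighted / n_brute_force
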