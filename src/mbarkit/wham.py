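"""Binned WHAM for umbrella sampling, as a cross-validation reference.

The weighted histogram analysis method estimates the unbiased density rho_b
on collective-variable bins from biased window histograms h_ib via the
self-consistent pair

    rho_b        =  sum_i h_ib  /  sum_i N_i exp(f_i) c_ib
    exp(-f_i)    =  sum_b c_ib rho_b

with c_ib = exp(-beta k_i (z_b - z_i_ref)^2) the bias factor at the bin
center.  MBAR is the zero-bin-width limit of this scheme, so on a shared
grid the two PMFs should agree up to binning bias; that comparison is the
purpose of this module.  The restraint uses the same k (dz)^2 convention as
the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ._exceptions import ConvergenceError, InputError
from .states import restraint_energy

__all__ = ["WHAMResult", "wham_umbrella"]


@dataclass
class WHAMResult:
    """Converged WHAM output on a fixed bin grid.

    ``window_f`` are the dimensionless window free energies (first window
    anchored to 0); ``density`` is the unbiased probability per bin (sums to
    one over bins); ``pmf`` is -ln density, min-shifted to zero.
    """

    window_f: np.ndarray
    density: np.ndarray
    pmf: np.ndarray
    bin_edges: np.ndarray
    n_iterations: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def wham_umbrella(
    cv_trajectories,
    spring_ks,
    z_refs,
    beta: float,
    bin_edges,
    *,
    periodic=None,
    half_spring: bool = False,
    bias_offsets=None,
    tolerance: float = 1e-8,
    max_iterations: int = 100_000,
) -> WHAMResult:
    """Solve binned WHAM for one-dimensional umbrella-sampling data.

    Parameters
    ----------
    cv_trajectories
        One CV array per window (the window's biased samples).
    spring_ks, z_refs
        Per-window restraint constants (kcal/mol per squared CV unit, using
        k (dz)^2) and centers.
    beta
        Shared inverse temperature, 1/(kcal/mol).
    bin_edges
        Histogram edges; bins are half-open [e_i, e_{i+1}), last bin closed.
    periodic
        Optional CV period for minimum-image restraint displacement.
    bias_offsets
        Optional per-window constants (kcal/mol) added to the restraint
        energy; they shift the window free energies but leave the PMF
        invariant.

    The iteration runs in log space and stops when the max-norm change of the
    window free energies drops below ``tolerance``.
    """
    trajs = [np.asarray(t, dtype=float).ravel() for t in cv_trajectories]
    if not trajs:
        raise InputError("need at least one window")
    k_arr = np.broadcast_to(
        np.asarray(spring_ks, dtype=float).ravel(), (len(trajs),)
    )
    z_arr = np.asarray(z_refs, dtype=float).ravel()
    if len(z_arr) != len(trajs):
        raise InputError(
            f"{len(trajs)} trajectories but {len(z_arr)} window centers"
        )
    edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)

    # Per-window histograms on the shared grid.
    hist = np.zeros((len(trajs), nb))
    for i, t in enumerate(trajs):
        idx = np.searchsorted(edges, t, side="right") - 1
        idx[t == edges[-1]] = nb - 1
        inside = (idx >= 0) & (idx < nb)
        hist[i] = np.bincount(idx[inside], minlength=nb)
    n_i = hist.sum(axis=1)
    if np.any(n_i == 0):
        raise InputError(
            f"windows {np.flatnonzero(n_i == 0).tolist()} have no samples "
            "inside the bin range"
        )
    occupied = hist.sum(axis=0) > 0
    if not occupied.any():
        raise InputError("no occupied bins")

    # log bias factor at bin centers: -beta * k_i * (z_b - z_ref_i)^2
    log_c = np.empty((len(trajs), nb))
    for i in range(len(trajs)):
        log_c[i] = -beta * restraint_energy(
            k_arr[i], centers[:, None], [z_arr[i]],
            periodic=None if periodic is None else [periodic],
            half_spring=half_spring,
        )
    if bias_offsets is not None:
        offsets = np.asarray(bias_offsets, dtype=float).ravel()
        if len(offsets) != len(trajs):
            raise InputError("bias_offsets must have one entry per window")
        log_c -= beta * offsets[:, None]

    log_h_tot = np.where(occupied, np.log(np.where(occupied, hist.sum(axis=0), 1.0)), -np.inf)
    log_n = np.log(n_i)

    f = np.zeros(len(trajs))
    for it in range(1, max_iterations + 1):
        # density update then window normalization, both in log space
        log_rho = log_h_tot - logsumexp(
            log_n[:, None] + f[:, None] + log_c, axis=0
        )
        log_rho -= logsumexp(log_rho[occupied])
        f_new = -logsumexp(log_c[:, occupied] + log_rho[None, occupied], axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iterations} iterations "
            f"(last change {delta:.3e})",
        )

    log_rho = log_h_tot - logsumexp(log_n[:, None] + f[:, None] + log_c, axis=0)
    log_rho -= logsumexp(log_rho[occupied])
    with np.errstate(divide="ignore"):
        density = np.where(occupied, np.exp(log_rho), 0.0)
    pmf = np.where(occupied, -log_rho, np.nan)
    pmf = pmf - np.nanmin(pmf)
    return WHAMResult(
        window_f=f,
        density=density,
        pmf=pmf,
        bin_edges=edges,
        n_iterations=it,
    )
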