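"""Standard errors by block averaging and bootstrap resampling.

Both schemes re-run an arbitrary estimator on subsets of the pooled samples,
respecting the per-state origin structure: blocks are contiguous time slices
within each state (so slowly decaying correlations inflate the block spread,
as they should), while the bootstrap draws with replacement independently
within each state and therefore assumes decorrelated input.  A stride
subsampler is provided for thinning correlated series before bootstrapping.

Estimators receive (pooled_index_array, per_state_counts) and may return a
scalar or an array; failures inside bootstrap replicates are tolerated up to
half the replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._exceptions import InputError

__all__ = [
    "ResamplingPlan",
    "block_se",
    "bootstrap_se",
    "resample_estimates",
    "stride_subsample",
]


@dataclass(frozen=True)
class ResamplingPlan:
    """How to estimate a standard error.

    ``method`` is ``"block"`` (n_blocks contiguous per-state time slices,
    default 10) or ``"bootstrap"`` (n_replicates within-state resamples,
    default 50, seeded).
    """

    method: str = "block"
    n_blocks: int = 10
    n_replicates: int = 50
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("block", "bootstrap"):
            raise InputError(f"unknown resampling method {self.method!r}")
        if self.method == "block" and self.n_blocks < 2:
            raise InputError(f"n_blocks must be >= 2, got {self.n_blocks}")
        if self.method == "bootstrap" and self.n_replicates < 2:
            raise InputError(
                f"n_replicates must be >= 2, got {self.n_replicates}"
            )


def _state_offsets(counts):
    counts = np.asarray(counts, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return counts, offsets


def _block_indices(counts, n_blocks):
    """Pooled index array and counts for each of the B blocks.

    Block b holds the b-th contiguous time slice of every sampled state;
    slice boundaries come from an even split of each state's N.
    """
    counts, offsets = _state_offsets(counts)
    sampled = np.flatnonzero(counts > 0)
    small = counts[sampled][counts[sampled] < n_blocks]
    if small.size:
        raise InputError(
            f"n_blocks={n_blocks} exceeds the sample count of some state "
            f"(min N = {int(counts[sampled].min())})"
        )
    out = []
    for b in range(n_blocks):
        idx_parts = []
        block_counts = np.zeros_like(counts)
        for j in sampled:
            bounds = np.linspace(0, counts[j], n_blocks + 1).astype(np.int64)
            lo, hi = bounds[b], bounds[b + 1]
            idx_parts.append(np.arange(offsets[j] + lo, offsets[j] + hi))
            block_counts[j] = hi - lo
        out.append((np.concatenate(idx_parts), block_counts))
    return out


def _bootstrap_indices(counts, n_replicates, seed):
    counts, offsets = _state_offsets(counts)
    sampled = np.flatnonzero(counts > 0)
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx_parts = [
            offsets[j] + rng.integers(0, counts[j], size=counts[j])
            for j in sampled
        ]
        yield np.concatenate(idx_parts), counts.copy()


def resample_estimates(estimator, counts, plan: ResamplingPlan):
    """Run the estimator on every block / bootstrap replicate.

    Returns the list of replicate estimates.  Bootstrap replicates that raise
    are dropped with a warning; at least half must survive.
    """
    if plan.method == "block":
        return [
            estimator(idx, c) for idx, c in _block_indices(counts, plan.n_blocks)
        ]
    estimates = []
    n_failed = 0
    for idx, c in _bootstrap_indices(counts, plan.n_replicates, plan.seed):
        try:
            estimates.append(estimator(idx, c))
        except Exception as exc:  # noqa: BLE001 - replicate failure is data-driven
            n_failed += 1
            warnings.warn(
                f"bootstrap replicate failed and was dropped: {exc}",
                stacklevel=2,
            )
    if len(estimates) < max(2, plan.n_replicates // 2):
        raise InputError(
            f"only {len(estimates)}/{plan.n_replicates} bootstrap replicates "
            "survived; estimator too fragile for these data"
        )
    return estimates


def block_se(estimator, counts, n_blocks: int = 10):
    """Block-averaging standard error of an estimator.

    The estimator is evaluated on each of ``n_blocks`` contiguous per-state
    time slices; SE = std(block estimates, ddof=1) / sqrt(B).
    """
    plan = ResamplingPlan(method="block", n_blocks=n_blocks)
    estimates = np.asarray(resample_estimates(estimator, counts, plan), dtype=float)
    return np.std(estimates, axis=0, ddof=1) / np.sqrt(n_blocks)


def bootstrap_se(
    estimator,
    counts,
    n_replicates: int = 50,
    seed: int | None = None,
    *,
    ci: tuple[float, float] = (2.5, 97.5),
):
    """Bootstrap standard error and percentile confidence interval.

    Samples are redrawn with replacement independently within each state,
    the estimator re-run per replicate; SE is the replicate standard
    deviation.  Returns (se, (ci_low, ci_high)).
    """
    plan = ResamplingPlan(
        method="bootstrap", n_replicates=n_replicates, seed=seed
    )
    estimates = np.asarray(resample_estimates(estimator, counts, plan), dtype=float)
    se = np.std(estimates, axis=0, ddof=1)
    lo, hi = np.percentile(estimates, ci, axis=0)
    return se, (lo, hi)


def stride_subsample(counts, stride: int):
    """Pooled indices and per-state counts after keeping every stride-th row.

    A crude decorrelation step for correlated series ahead of bootstrapping;
    choosing the stride is up to the user.
    """
    if stride < 1:
        raise InputError(f"stride must be >= 1, got {stride}")
    counts, offsets = _state_offsets(counts)
    idx_parts, new_counts = [], np.zeros_like(counts)
    for j in range(len(counts)):
        kept = np.arange(offsets[j], offsets[j + 1], stride)
        idx_parts.append(kept)
        new_counts[j] = kept.size
    return np.concatenate(idx_parts), new_counts
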