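"""Shuffle-based nonparametric null for spectral significance.

The observed values are permuted over the fixed sample times (preserving the
inter-sample intervals), the model is refit with the same delta and
dictionaries, and the absolute coefficients are recorded. Repeating this
(default 100 times) yields a noise-floor distribution; a coefficient of the
real fit is significant when its amplitude is equal to or greater than the
chosen percentile (default 99th) of the noise floor for its period.

The noise floor at a period is estimated from the null amplitudes of all
grid bins within ``pool_halfwidth`` (default 10%) of that period, not from
the single bin alone: an L1 solver returns exactly sparse null fits, so a
single bin is often zero in every shuffle even though the local noise floor
is positive, and a per-bin percentile would then flag arbitrarily small
coefficients. The thresholds remain period-specific; ``pool_halfwidth = 0``
recovers the strict bin-by-bin comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import FrequencyGrid
from .design import build_design
from .sampling import SampledSeries, shuffle_values
from .solver import BPWPFit, Spectrum, residual_projector, solve_l1_constrained_multi

__all__ = ["NullDistribution", "build_shuffle_null", "flag_significant", "pooled_thresholds"]


@dataclass
class NullDistribution:
    """Coefficient amplitudes from shuffled refits, with thresholds."""

    amplitudes: np.ndarray  # n_iter x n
    percentile: float
    thresholds: np.ndarray  # per-period percentile of the pooled local null
    n_iter: int
    seed: int | None
    delta: float
    period_days: np.ndarray
    pool_halfwidth: float = 0.1
    global_floor: bool = True

    def threshold_at(self, percentile: float) -> np.ndarray:
        thr = pooled_thresholds(self.amplitudes, self.period_days,
                                percentile, self.pool_halfwidth)
        if self.global_floor:
            thr = np.maximum(thr, _global_floor(self.amplitudes, self.period_days, percentile))
        return thr


def _global_floor(amplitudes: np.ndarray, period_days: np.ndarray, percentile: float) -> float:
    """Percentile of the entire finite-period shuffle distribution.

    The envelope of the noise floor: a sparse solver leaves whole period
    regions inactive in every shuffle, where a local percentile is zero even
    though shuffled noise demonstrably produces amplitude elsewhere. A peak
    must at least clear what shuffling produces anywhere in the spectrum.
    """
    finite = np.isfinite(np.asarray(period_days, dtype=float))
    return float(np.percentile(amplitudes[:, finite], percentile))


def pooled_thresholds(
    amplitudes: np.ndarray,
    period_days: np.ndarray,
    percentile: float,
    pool_halfwidth: float = 0.1,
    min_pool: int = 25,
) -> np.ndarray:
    """Percentile of the null amplitudes pooled within a local period window.

    For each bin the pool is every bin whose period lies within
    ``pool_halfwidth`` (relative) of its own, widened to the ``min_pool``
    nearest bins in log-period when the window is sparser than that (the
    long-period end of the grid has isolated bins whose own null column is
    empty in almost every shuffle). Infinite-period (DC) bins pool only with
    themselves. ``pool_halfwidth = 0`` is the strict per-bin percentile.
    """
    periods = np.asarray(period_days, dtype=float)
    n = periods.size
    if pool_halfwidth == 0.0:
        return np.percentile(amplitudes, percentile, axis=0)
    finite = np.isfinite(periods)
    order = np.argsort(periods)
    sorted_p = periods[order]
    n_finite = int(finite.sum())
    logp = np.log(sorted_p[:n_finite])
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    thresholds = np.empty(n)
    lo_idx = np.searchsorted(sorted_p, periods * (1.0 - pool_halfwidth), side="left")
    hi_idx = np.searchsorted(sorted_p, periods * (1.0 + pool_halfwidth), side="right")
    for k in range(n):
        if not finite[k]:
            thresholds[k] = np.percentile(amplitudes[:, k], percentile)
            continue
        k_pos = pos[k]
        lo, hi = lo_idx[k], min(hi_idx[k], n_finite)
        while hi - lo < min(min_pool, n_finite):
            # grow toward the nearer neighbor in log-period
            left = logp[k_pos] - logp[lo - 1] if lo > 0 else np.inf
            right = logp[hi] - logp[k_pos] if hi < n_finite else np.inf
            if left <= right:
                lo -= 1
            else:
                hi += 1
        pool = order[lo:hi]
        thresholds[k] = np.percentile(amplitudes[:, pool], percentile)
    return thresholds


def build_shuffle_null(
    sampled: SampledSeries,
    grid: FrequencyGrid,
    max_degree: int = 1,
    delta: float = 0.0,
    n_iter: int = 100,
    seed: int | None = 0,
    percentile: float = 99.0,
    solver_tol: float = 1e-6,
    solver_max_iter: int = 5000,
    t0: float = 0.0,
    batch_size: int = 50,
    pool_halfwidth: float = 0.1,
    global_floor: bool = True,
) -> NullDistribution:
    """Fit the model to ``n_iter`` value-shuffled copies of the data.

    All shuffles share the projected design, so they are solved as batched
    columns of one proximal-gradient run (in chunks of ``batch_size``).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    A, B, _, _ = build_design(sampled, grid, max_degree=max_degree, t0=t0)
    P = residual_projector(B)
    A_t = P(A)
    rng = np.random.default_rng(seed)
    amplitudes = np.empty((n_iter, grid.n))
    done = 0
    while done < n_iter:
        k = min(batch_size, n_iter - done)
        Y = np.empty((sampled.m, k))
        for j in range(k):
            Y[:, j] = shuffle_values(sampled, seed=rng.integers(2**31)).values
        X, _, _ = solve_l1_constrained_multi(
            A_t, P(Y), np.full(k, delta),
            tol=solver_tol, max_iter=solver_max_iter, check=False,
        )
        amplitudes[done : done + k] = np.abs(X).T
        done += k
    thresholds = pooled_thresholds(amplitudes, grid.period_days, percentile, pool_halfwidth)
    if global_floor:
        thresholds = np.maximum(
            thresholds, _global_floor(amplitudes, grid.period_days, percentile)
        )
    return NullDistribution(
        amplitudes=amplitudes,
        percentile=percentile,
        thresholds=thresholds,
        n_iter=n_iter,
        seed=seed,
        delta=delta,
        period_days=grid.period_days,
        pool_halfwidth=pool_halfwidth,
        global_floor=global_floor,
    )


def flag_significant(
    fit: BPWPFit,
    null: NullDistribution,
    percentile: float | None = None,
) -> Spectrum:
    """Flag coefficients whose amplitude reaches the null percentile.

    The comparison is inclusive: amplitude equal to the threshold counts as
    significant.
    """
    if fit.x.size != null.amplitudes.shape[1]:
        raise ValueError("fit and null distribution use different frequency grids")
    thr = null.thresholds if percentile is None else null.threshold_at(percentile)
    amp = np.abs(fit.x)
    # inclusive comparison, but a zero coefficient is never a peak (null
    # columns that were inactive in every shuffle have threshold 0)
    return Spectrum(
        period_days=null.period_days,
        amplitude=amp,
        significant=(amp >= thr) & (amp > 0.0),
        threshold=thr,
    )
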