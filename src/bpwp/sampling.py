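"""Dense and sparse series containers, random sampling, drops, shuffles.

Time is in days throughout; values are event rates (events/hour).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DenseSeries",
    "SamplingMask",
    "SampledSeries",
    "EventSeries",
    "random_sample",
    "random_sample_excluding",
    "make_drop_mask",
    "shuffle_values",
    "interpolate_gaps",
]


@dataclass(frozen=True)
class DenseSeries:
    """Regularly spaced series: value ``i`` is observed at ``t0 + i*dt`` days."""

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def N(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.N)


@dataclass(frozen=True)
class SamplingMask:
    """Strictly increasing unique 0-based positions into a dense grid."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if idx.size and (np.any(np.diff(idx) <= 0) or idx.min() < 0):
            raise ValueError("indices must be nonnegative, strictly increasing, unique")
        object.__setattr__(self, "indices", idx)

    @property
    def m(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class SampledSeries:
    """Irregular observations ``(times, values)`` with optional source mask."""

    times: np.ndarray
    values: np.ndarray
    source_mask: SamplingMask | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class EventSeries:
    """Sorted nonnegative event times in days (e.g. seizure onsets)."""

    event_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.sort(np.asarray(self.event_times, dtype=float))
        if t.size and t[0] < 0:
            raise ValueError("event times must be nonnegative")
        object.__setattr__(self, "event_times", t)


def _window_indices(dense: DenseSeries, window_days: tuple[float, float]) -> np.ndarray:
    w0, w1 = window_days
    if w1 <= w0:
        raise ValueError("window must have positive length")
    t = dense.times
    return np.flatnonzero((t >= w0) & (t < w1))


def random_sample(
    dense: DenseSeries,
    rate_per_day: float,
    window_days: tuple[float, float] | None = None,
    seed: int | None = 0,
) -> SampledSeries:
    """Draw ``floor(rate * window length)`` grid points uniformly at random.

    The draw is a single global draw without replacement over the window, so
    the total sample count is exact (e.g. 5/day over 360 days gives exactly
    1800 samples), not binomial.
    """
    if rate_per_day <= 0:
        raise ValueError("rate_per_day must be positive")
    if window_days is None:
        window_days = (dense.t0, dense.t0 + dense.dt * dense.N)
    eligible = _window_indices(dense, window_days)
    count = int(np.floor(rate_per_day * (window_days[1] - window_days[0])))
    if count > eligible.size:
        raise ValueError(f"requested {count} samples but only {eligible.size} grid points in window")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(eligible, size=count, replace=False))
    mask = SamplingMask(chosen)
    return SampledSeries(times=dense.times[chosen], values=dense.values[chosen], source_mask=mask)


def make_drop_mask(
    window_days: tuple[float, float],
    block_length_days: float,
    total_drop_days: float,
    seed: int | None = 0,
) -> list[tuple[float, float]]:
    """Place non-overlapping contiguous drop intervals uniformly at random.

    ``total_drop_days`` must be an integer multiple of ``block_length_days``;
    e.g. 120 total days in 12-day blocks gives 10 intervals. Returns a list
    of ``(start, end)`` exclusion intervals in days.
    """
    if total_drop_days < 0 or block_length_days <= 0:
        raise ValueError("durations must be positive")
    if total_drop_days == 0:
        return []
    n_blocks_f = total_drop_days / block_length_days
    n_blocks = int(round(n_blocks_f))
    if abs(n_blocks_f - n_blocks) > 1e-9:
        raise ValueError("total_drop_days must be divisible by block_length_days")
    w0, w1 = window_days
    free = (w1 - w0) - n_blocks * block_length_days
    if free < 0:
        raise ValueError("drop blocks do not fit in the window")
    rng = np.random.default_rng(seed)
    gaps = np.sort(rng.uniform(0.0, free, size=n_blocks))
    starts = w0 + gaps + block_length_days * np.arange(n_blocks)
    return [(float(s), float(s + block_length_days)) for s in starts]


def random_sample_excluding(
    dense: DenseSeries,
    n_samples: int,
    window_days: tuple[float, float] | None = None,
    exclusions: Sequence[tuple[float, float]] = (),
    seed: int | None = 0,
) -> SampledSeries:
    """Draw a fixed number of samples from the window minus drop intervals.

    Used for the data-drop experiments, where the total sample count is held
    fixed across drop conditions (default 1307 in the evaluation sweeps).
    """
    if window_days is None:
        window_days = (dense.t0, dense.t0 + dense.dt * dense.N)
    eligible = _window_indices(dense, window_days)
    t = dense.times[eligible]
    keep = np.ones(t.size, dtype=bool)
    for s, e in exclusions:
        keep &= ~((t >= s) & (t < e))
    eligible = eligible[keep]
    if n_samples > eligible.size:
        raise ValueError(f"requested {n_samples} samples but only {eligible.size} available")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(eligible, size=n_samples, replace=False))
    mask = SamplingMask(chosen)
    return SampledSeries(times=dense.times[chosen], values=dense.values[chosen], source_mask=mask)


def shuffle_values(sampled: SampledSeries, seed: int | None = 0) -> SampledSeries:
    """Permute observed values over fixed sample times.

    This preserves the original inter-sample intervals while destroying the
    temporal ordering — the null model for spectral significance.
    """
    if sampled.m < 2:
        raise ValueError("need at least two samples to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sampled.m)
    return SampledSeries(
        times=sampled.times,
        values=sampled.values[perm],
        source_mask=sampled.source_mask,
    )


def interpolate_gaps(
    dense: DenseSeries,
    events: EventSeries | None = None,
    periictal_hours: float = 2.0,
) -> DenseSeries:
    """Fill missing values and excise peri-event windows by interpolation.

    Samples within ``periictal_hours`` of any event (before or after, plus
    the event instant itself) are marked invalid along with any NaN entries;
    invalid stretches are filled by linear interpolation between flanking
    valid points, and leading/trailing gaps by the nearest valid value.
    """
    values = dense.values.copy()
    valid = np.isfinite(values)
    if events is not None and events.event_times.size:
        t = dense.times
        half = periictal_hours / 24.0
        for ev in events.event_times:
            valid &= ~((t >= ev - half) & (t <= ev + half))
    if not np.any(valid):
        raise ValueError("no valid points remain to interpolate from")
    t = dense.times
    filled = np.interp(t, t[valid], values[valid])
    return DenseSeries(t0=dense.t0, dt=dense.dt, values=filled)
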