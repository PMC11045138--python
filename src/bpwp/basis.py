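"""Oscillation and trend dictionaries.

The oscillation dictionary is an orthonormal DCT-II synthesis matrix whose
frequency axis has been *remapped*: fractional frequency indices are inserted
so that slow cycles (days to months) are represented on a dense period grid,
and an equal number of columns is removed from the high-frequency end so the
dictionary stays square. The trend dictionary is a Vandermonde matrix in
affinely normalized time.

Frequency index convention: columns are indexed by a real-valued frequency
index ``f >= 1``. The column for index ``f`` sampled at (1-based) time index
``n`` is::

    sqrt(2/N) / sqrt(1 + [f == 1]) * cos(pi * (2n - 1) * (f - 1) / (2N))

For integer ``f = 1..N`` this is exactly the orthonormal DCT-II basis (the
``f == 1`` Kronecker-delta term is the DC scaling). The period in days of a
column is ``2*N*dt / (f - 1)`` (infinite at ``f = 1``), so a target period
``P`` maps to ``f = 1 + 2*N*dt/P``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FrequencyGrid",
    "OscillationBasis",
    "PolynomialBasis",
    "build_dct_basis",
    "build_frequency_mapping",
    "build_mapped_basis",
    "build_polynomial_basis",
    "subsample_rows",
    "DEFAULT_TARGET_PERIODS",
    "DEFAULT_REMOVAL_CEILING",
]

#: Default set of target periods (days) densified onto the frequency grid:
#: 2 to 150 days in half-day steps, covering circadian-adjacent through
#: multi-month cycles.
DEFAULT_TARGET_PERIODS: np.ndarray = np.arange(2.0, 150.0 + 0.25, 0.5)

#: Default period ceiling (days) below which high-frequency columns may be
#: sacrificed to make room for the inserted low-frequency columns.
DEFAULT_REMOVAL_CEILING: float = 0.25


def _period_of(f: np.ndarray, N: int, dt: float) -> np.ndarray:
    """Period in days of frequency index ``f`` on an ``N``-point grid."""
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(f > 1.0, 2.0 * N * dt / (f - 1.0), np.inf)


@dataclass(frozen=True)
class FrequencyGrid:
    """Remapped frequency-index grid for an N-point dense time base.

    Parameters
    ----------
    N : int
        Dense grid length (number of time samples).
    dt : float
        Dense sample spacing in days.
    f_values : ndarray
        Sorted real frequency indices, all in ``[1, N]``, length ``N``
        (remapping preserves the dictionary size).
    """

    N: int
    dt: float
    f_values: np.ndarray
    seed: int | None = None
    target_periods: np.ndarray = field(default_factory=lambda: np.array([]))
    removal_ceiling_days: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.f_values, dtype=float)
        if f.ndim != 1 or f.size != self.N:
            raise ValueError(f"f_values must have length N={self.N}, got {f.size}")
        if np.any(f < 1.0) or np.any(f > self.N):
            raise ValueError("frequency indices must lie in [1, N]")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency indices must be strictly increasing")
        object.__setattr__(self, "f_values", f)

    @property
    def n(self) -> int:
        return self.f_values.size

    @property
    def period_days(self) -> np.ndarray:
        """Per-column period in days (infinite for the DC column)."""
        return _period_of(self.f_values, self.N, self.dt)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "N": self.N,
            "dt_days": self.dt,
            "f_values": self.f_values.tolist(),
            "seed": self.seed,
            "target_periods": np.asarray(self.target_periods).tolist(),
            "removal_ceiling_days": self.removal_ceiling_days,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FrequencyGrid":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            N=int(d["N"]),
            dt=float(d["dt_days"]),
            f_values=np.asarray(d["f_values"], dtype=float),
            seed=d.get("seed"),
            target_periods=np.asarray(d.get("target_periods", [])),
            removal_ceiling_days=d.get("removal_ceiling_days"),
        )


@dataclass
class OscillationBasis:
    """Realization of a :class:`FrequencyGrid` as a cosine dictionary.

    The dense ``N x n`` matrix is built lazily; row subsets (the subsampled
    dictionary ``A``) are computed directly from the closed form without
    materializing the dense matrix.
    """

    grid: FrequencyGrid
    _matrix: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.grid.N

    @property
    def n(self) -> int:
        return self.grid.n

    def rows(self, row_indices: np.ndarray, columns: np.ndarray | None = None) -> np.ndarray:
        """Evaluate selected (0-based) rows of the dictionary.

        ``row_indices`` may be fractional, in which case the cosine is
        evaluated at the corresponding off-grid time; integer indices
        reproduce rows of :attr:`matrix` exactly.
        """
        r = np.atleast_1d(np.asarray(row_indices, dtype=float))
        f = self.grid.f_values if columns is None else self.grid.f_values[columns]
        N = self.N
        # 1-based time index n = r + 1  ->  (2n - 1) = 2r + 1
        phase = np.pi * np.outer(2.0 * r + 1.0, f - 1.0) / (2.0 * N)
        out = np.cos(phase)
        out *= np.sqrt(2.0 / N)
        dc = f == 1.0
        if np.any(dc):
            out[:, dc] /= np.sqrt(2.0)
        return out

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = self.rows(np.arange(self.N))
        return self._matrix

    def synthesize(self, x: np.ndarray, row_indices: np.ndarray | None = None) -> np.ndarray:
        """Compute ``Psi @ x`` touching only the columns where x is nonzero."""
        x = np.asarray(x, dtype=float)
        if x.shape[0] != self.n:
            raise ValueError("coefficient length does not match dictionary size")
        rows = np.arange(self.N) if row_indices is None else row_indices
        active = np.flatnonzero(x != 0.0)
        if active.size == 0:
            return np.zeros(np.atleast_1d(rows).size)
        return self.rows(rows, columns=active) @ x[active]


@dataclass
class PolynomialBasis:
    """Vandermonde trend dictionary in affinely normalized time.

    ``matrix[:, j] = t_norm ** j`` where ``t_norm = (t - offset) / scale``
    maps the raw time span onto ``[-1, 1]``; ``p = max_degree + 1`` columns.
    """

    matrix: np.ndarray
    p: int
    time_scale: tuple[float, float]  # (offset, scale)
    times: np.ndarray

    def rows_at(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the trend dictionary at arbitrary times (days)."""
        offset, scale = self.time_scale
        tn = (np.asarray(times, dtype=float) - offset) / scale
        return np.polynomial.polynomial.polyvander(tn, self.p - 1)


def build_dct_basis(N: int) -> OscillationBasis:
    """Orthonormal DCT-II synthesis matrix as an identity-mapped basis."""
    if N < 1 or int(N) != N:
        raise ValueError(f"N must be a positive integer, got {N!r}")
    grid = FrequencyGrid(N=int(N), dt=1.0, f_values=np.arange(1, N + 1, dtype=float))
    return OscillationBasis(grid=grid)


def build_frequency_mapping(
    N: int,
    dt: float,
    target_periods: Sequence[float] | np.ndarray | None = None,
    removal_period_ceiling: float | None = None,
    seed: int | None = 0,
) -> FrequencyGrid:
    """Densify the DCT frequency grid at target (long) periods.

    Each target period ``P`` (days) contributes a column at the possibly
    fractional index ``f = 1 + 2*N*dt/P``. Targets already present on the
    integer grid (or duplicated among themselves) are dropped; for each net
    inserted column one identity column with period below
    ``removal_period_ceiling`` is removed, chosen uniformly at random with
    ``seed``, so the dictionary stays square.
    """
    if N < 1 or dt <= 0:
        raise ValueError("need N >= 1 and dt > 0")
    if removal_period_ceiling is None:
        # keep the ceiling above the dense grid's Nyquist period so there is
        # always a removable high-frequency band
        removal_period_ceiling = max(DEFAULT_REMOVAL_CEILING, 3.0 * dt)
    if target_periods is None:
        # default targets capped at the record length; on small grids thin
        # the list evenly so it fits the removable high-frequency budget
        target_periods = DEFAULT_TARGET_PERIODS[DEFAULT_TARGET_PERIODS <= N * dt]
        budget = int(np.sum(_period_of(np.arange(1, N + 1), N, dt) < removal_period_ceiling))
        if target_periods.size > budget:
            step = int(np.ceil(target_periods.size / max(budget, 1)))
            target_periods = target_periods[::step]
    targets = np.asarray(target_periods, dtype=float)
    identity = np.arange(1, N + 1, dtype=float)

    if targets.size:
        if np.any(targets > N * dt) or np.any(targets <= 2.0 * dt):
            raise ValueError(
                "target periods must satisfy 2*dt < P <= N*dt "
                f"(record length {N * dt:g} d, Nyquist period {2 * dt:g} d)"
            )
        if removal_period_ceiling >= targets.min():
            raise ValueError("removal ceiling must be shorter than the shortest target period")

    f_new = 1.0 + 2.0 * N * dt / targets if targets.size else np.array([])
    # drop targets landing (numerically) on the integer identity grid, and
    # duplicates among the targets themselves
    f_new = f_new[np.abs(f_new - np.round(f_new)) > 1e-9]
    f_new = np.unique(np.round(f_new, 9))
    k = f_new.size

    if k:
        identity_periods = _period_of(identity, N, dt)
        removable = np.flatnonzero(identity_periods < removal_period_ceiling)
        if k > removable.size:
            raise ValueError(
                f"{k} inserted frequencies but only {removable.size} identity columns "
                f"with period below {removal_period_ceiling:g} d are removable"
            )
        rng = np.random.default_rng(seed)
        removed = rng.choice(removable, size=k, replace=False)
        keep = np.ones(N, dtype=bool)
        keep[removed] = False
        f_values = np.sort(np.concatenate([identity[keep], f_new]))
    else:
        f_values = identity

    return FrequencyGrid(
        N=int(N),
        dt=float(dt),
        f_values=f_values,
        seed=seed,
        target_periods=targets,
        removal_ceiling_days=float(removal_period_ceiling),
    )


def build_mapped_basis(grid: FrequencyGrid) -> OscillationBasis:
    """Realize a frequency grid as a cosine dictionary."""
    return OscillationBasis(grid=grid)


def build_polynomial_basis(times: np.ndarray, max_degree: int = 1) -> PolynomialBasis:
    """Vandermonde trend dictionary on the given times (days)."""
    if max_degree < 0 or int(max_degree) != max_degree:
        raise ValueError("max_degree must be a nonnegative integer")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or not np.all(np.isfinite(t)):
        raise ValueError("times must be a finite 1-D array")
    p = int(max_degree) + 1
    if np.unique(t).size < p:
        warnings.warn(
            f"only {np.unique(t).size} distinct times for p={p} columns: trend is rank-deficient",
            stacklevel=2,
        )
    lo, hi = t.min(), t.max()
    offset = 0.5 * (lo + hi)
    scale = 0.5 * (hi - lo) if hi > lo else 1.0
    basis = PolynomialBasis(matrix=np.empty(0), p=p, time_scale=(offset, scale), times=t)
    basis.matrix = basis.rows_at(t)
    return basis


def subsample_rows(basis, mask) -> np.ndarray:
    """Select rows of a dictionary at observed sample positions.

    ``basis`` may be a plain matrix, an :class:`OscillationBasis` (rows are
    then evaluated from the closed form, never materializing the dense
    matrix), or a :class:`PolynomialBasis`. ``mask`` holds 0-based row
    indices, strictly increasing and unique.
    """
    indices = np.asarray(getattr(mask, "indices", mask))
    if indices.ndim != 1:
        raise ValueError("mask must be a 1-D index array")
    if indices.size and (np.any(np.diff(indices) <= 0)):
        raise ValueError("mask indices must be strictly increasing and unique")
    if isinstance(basis, OscillationBasis):
        N = basis.N
    elif isinstance(basis, PolynomialBasis):
        N = basis.matrix.shape[0]
    else:
        basis = np.asarray(basis)
        N = basis.shape[0]
    if indices.size and (indices.min() < 0 or indices.max() >= N):
        raise ValueError(f"mask indices out of range [0, {N - 1}]")
    if isinstance(basis, OscillationBasis):
        return basis.rows(indices)
    if isinstance(basis, PolynomialBasis):
        return basis.matrix[indices, :]
    return basis[indices, :]
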