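"""Assemble the subsampled design matrices A and B for a sampled series."""

from __future__ import annotations

import numpy as np

from .basis import (
    FrequencyGrid,
    OscillationBasis,
    PolynomialBasis,
    build_mapped_basis,
    build_polynomial_basis,
)
from .sampling import SampledSeries

__all__ = ["build_design"]


def build_design(
    sampled: SampledSeries,
    grid: FrequencyGrid,
    max_degree: int = 1,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, OscillationBasis, PolynomialBasis]:
    """Dictionaries evaluated at the observation rows.

    The oscillation dictionary rows come from the sample positions on the
    dense grid (fractional positions are allowed when samples are off-grid);
    the trend dictionary is normalized over the *dense* record so that its
    coefficients transfer directly to dense reconstruction.

    Returns ``(A, B, oscillation_basis, polynomial_basis)`` where the bases
    are the dense-grid objects used later for reconstruction.
    """
    basis = build_mapped_basis(grid)
    dense_times = t0 + grid.dt * np.arange(grid.N)
    poly = build_polynomial_basis(dense_times, max_degree=max_degree)
    if sampled.source_mask is not None:
        rows = sampled.source_mask.indices.astype(float)
    else:
        rows = (sampled.times - t0) / grid.dt
    A = basis.rows(rows)
    B = poly.rows_at(sampled.times)
    return A, B, basis, poly
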