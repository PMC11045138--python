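"""Dictionary construction: orthonormal DCT-II, frequency remapping, trends."""

import numpy as np
import pytest
import scipy.fft

from bpwp.basis import (
    build_dct_basis,
    build_frequency_mapping,
    build_mapped_basis,
    build_polynomial_basis,
    subsample_rows,
)
from bpwp.sampling import SamplingMask


@pytest.mark.parametrize("N", list(range(1, 17)) + [32, 64])
def test_dct_is_orthonormal_and_matches_scipy(N):
    M = build_dct_basis(N).matrix
    assert np.allclose(M.T @ M, np.eye(N), atol=1e-8)
    ref = scipy.fft.idct(np.eye(N), type=2, norm="ortho", axis=0)
    assert np.allclose(M, ref, atol=1e-12)


def test_dct_entries():
    assert build_dct_basis(1).matrix[0, 0] == pytest.approx(1.0)
    # row 1, column 2 of the N=2 basis: cos(pi/4)
    assert build_dct_basis(2).matrix[0, 1] == pytest.approx(np.cos(np.pi / 4), abs=1e-12)
    with pytest.raises(ValueError):
        build_dct_basis(0)


class TestFrequencyMapping:
    def test_empty_targets_identity(self):
        g = build_frequency_mapping(16, 1.0, target_periods=[], seed=0)
        assert np.array_equal(g.f_values, np.arange(1, 17))

    def test_target_period_inserts_fractional_index(self):
        # 100-day target on a 26280-point 20-minute grid: f = 1 + 730/100
        g = build_frequency_mapping(26280, 1 / 72, target_periods=[100.0],
                                    removal_period_ceiling=0.25, seed=1)
        assert np.any(np.isclose(g.f_values, 8.3))
        assert g.n == 26280  # one added, one removed

    def test_added_equals_removed(self):
        g = build_frequency_mapping(2000, 0.25, target_periods=[33.3, 47.7, 121.0],
                                    removal_period_ceiling=0.6, seed=3)
        assert g.n == 2000
        # all three targets are fractional, hence inserted
        for P in (33.3, 47.7, 121.0):
            assert np.any(np.isclose(g.f_values, 1 + 2 * 2000 * 0.25 / P))

    def test_on_grid_target_deduplicated(self):
        # N*dt = 100 days; a 10-day target lands exactly on identity index 21
        g = build_frequency_mapping(400, 0.25, target_periods=[10.0],
                                    removal_period_ceiling=0.6, seed=0)
        assert g.n == 400
        assert np.array_equal(g.f_values, np.arange(1, 401))  # nothing removed

    def test_seed_determinism_and_difference(self):
        args = dict(target_periods=[33.3, 47.7], removal_period_ceiling=0.6)
        g1 = build_frequency_mapping(2000, 0.25, seed=7, **args)
        g2 = build_frequency_mapping(2000, 0.25, seed=7, **args)
        g3 = build_frequency_mapping(2000, 0.25, seed=8, **args)
        assert np.array_equal(g1.f_values, g2.f_values)
        assert not np.array_equal(g1.f_values, g3.f_values)

    def test_period_index_round_trip(self):
        g = build_frequency_mapping(2000, 0.25, target_periods=[33.3, 47.7],
                                    removal_period_ceiling=0.6, seed=3)
        f = g.f_values[g.f_values > 1]
        P = g.period_days[g.f_values > 1]
        assert np.allclose(1.0 + 2.0 * g.N * g.dt / P, f, atol=1e-10)

    def test_too_many_targets_rejected(self):
        with pytest.raises(ValueError):
            build_frequency_mapping(20, 1.0, target_periods=[3.3, 4.7, 6.1],
                                    removal_period_ceiling=2.05, seed=0)

    def test_json_round_trip(self, tmp_path):
        g = build_frequency_mapping(500, 0.5, target_periods=[41.5],
                                    removal_period_ceiling=1.5, seed=2)
        path = tmp_path / "grid.json"
        g.to_json(path)
        from bpwp.basis import FrequencyGrid

        g2 = FrequencyGrid.from_json(path)
        assert g2.N == g.N and g2.dt == g.dt
        assert np.array_equal(g2.f_values, g.f_values)


class TestMappedBasis:
    def test_identity_grid_equals_dct(self):
        g = build_frequency_mapping(12, 1.0, target_periods=[], seed=0)
        assert np.allclose(build_mapped_basis(g).matrix, build_dct_basis(12).matrix)

    def test_fractional_column_is_cosine_of_target_period(self):
        # the f=8.3 column on the 20-minute grid is a sampled 100-day cosine
        g = build_frequency_mapping(26280, 1 / 72, target_periods=[100.0],
                                    removal_period_ceiling=0.25, seed=1)
        basis = build_mapped_basis(g)
        col_idx = np.flatnonzero(np.isclose(g.f_values, 8.3))
        rows = np.arange(0, 26280, 5)
        col = basis.rows(rows, columns=col_idx)[:, 0]
        t = (rows + 0.5) / 72.0  # sample-center times in days
        D = np.column_stack([np.cos(2 * np.pi * t / 100.0), np.sin(2 * np.pi * t / 100.0)])
        resid = col - D @ np.linalg.lstsq(D, col, rcond=None)[0]
        assert np.max(np.abs(resid)) < 1e-8

    def test_remapped_gram_structure(self):
        # Remapping disrupts orthonormality only locally: the retained
        # integer-index (DCT) core stays exactly orthonormal, and coherence
        # is confined to near-degenerate period neighborhoods — columns
        # separated by a factor >= 1.5 in period stay below 0.2. (Columns a
        # half-day apart at 100+ day periods are near-duplicates over a
        # one-year record; no dictionary this dense can avoid that.)
        g = build_frequency_mapping(1460, 0.25, seed=0)  # 365 d at 4/day
        M = build_mapped_basis(g).matrix
        G = np.abs(M.T @ M)
        ident = np.isclose(g.f_values, np.round(g.f_values))
        core = G[np.ix_(ident, ident)] - np.eye(int(ident.sum()))
        assert np.max(np.abs(core)) < 1e-8
        np.fill_diagonal(G, 0.0)
        P = np.where(np.isfinite(g.period_days), g.period_days, 1e12)
        ratio = np.maximum.outer(P, P) / np.minimum.outer(P, P)
        assert G[ratio >= 1.5].max() < 0.2

    def test_column_amplitude_bound(self):
        g = build_frequency_mapping(1460, 0.25, seed=0)
        M = build_mapped_basis(g).matrix
        assert np.max(np.abs(M)) <= np.sqrt(2.0 / 1460) + 1e-12


class TestPolynomialBasis:
    def test_degree_zero_is_ones(self):
        b = build_polynomial_basis(np.linspace(0, 10, 5), max_degree=0)
        assert np.allclose(b.matrix, 1.0)

    def test_affine_normalization(self):
        b = build_polynomial_basis(np.array([0.0, 182.5, 365.0]), max_degree=1)
        assert np.allclose(b.matrix[:, 1], [-1.0, 0.0, 1.0])

    def test_p_is_degree_plus_one(self):
        for deg in (0, 1, 3):
            assert build_polynomial_basis(np.linspace(0, 1, 10), deg).p == deg + 1

    def test_rank_deficiency_warns(self):
        with pytest.warns(UserWarning, match="rank-deficient"):
            build_polynomial_basis(np.array([1.0, 1.0, 1.0]), max_degree=1)


class TestSubsampleRows:
    def test_full_mask_is_identity(self, rng):
        M = rng.standard_normal((8, 3))
        assert np.array_equal(subsample_rows(M, np.arange(8)), M)

    def test_single_row_and_shape(self, rng):
        M = rng.standard_normal((8, 3))
        assert subsample_rows(M, np.array([0])).shape == (1, 3)
        assert subsample_rows(M, np.array([1, 4, 6])).shape == (3, 3)

    def test_oscillation_basis_rows_match_dense(self):
        g = build_frequency_mapping(50, 0.5, target_periods=[7.3],
                                    removal_period_ceiling=1.1, seed=0)
        basis = build_mapped_basis(g)
        mask = SamplingMask(np.array([0, 7, 23, 49]))
        assert np.allclose(subsample_rows(basis, mask), basis.matrix[mask.indices])

    @pytest.mark.parametrize("bad", [[3, 3, 5], [5, 2], [-1, 2], [0, 99]])
    def test_invalid_masks_rejected(self, rng, bad):
        M = rng.standard_normal((8, 3))
        with pytest.raises(ValueError):
            subsample_rows(M, np.array(bad))
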