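"""PMF estimation, GaMD reweighting and minima/barrier extraction."""

import numpy as np
import pytest

from ternary import (
    KB,
    BoostedSamples,
    PMFGrid,
    minima_and_barrier,
    pmf_2d,
    pmf_reweighted,
    pmf_unbiased,
)
from ternary.synthetic import BoostSpec, make_opening_double_well, simulate_langevin

KT310 = KB * 310.0


def _grid_1d(values, mask=None, width=1.0):
    v = np.asarray(values, dtype=float)
    m = np.zeros(v.size, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    v = np.where(m, np.nan, v)
    return PMFGrid(bin_edges=(width * np.arange(v.size + 1),),
                   free_energy=v, count=np.full(v.size, 100), mask=m,
                   temperature=310.0)


class TestUnbiased:
    def test_single_bin_zero(self):
        grid = pmf_unbiased(np.full(50, 0.2), bin_width=0.5)
        assert grid.free_energy.shape == (1,)
        assert grid.free_energy[0] == 0.0

    def test_two_bin_log_ratio(self):
        samples = np.concatenate([np.full(1000, 0.25), np.full(368, 0.75)])
        grid = pmf_unbiased(samples, bin_width=0.5)
        expected = -KT310 * np.log(368 / 1000)
        assert grid.free_energy[1] - grid.free_energy[0] == pytest.approx(expected)
        assert expected == pytest.approx(0.616, abs=2e-3)

    def test_gaussian_sample_recovers_curvature(self):
        rng = np.random.default_rng(0)
        sigma, mu = 2.0, 50.0
        samples = rng.normal(mu, sigma, size=400_000)
        grid = pmf_unbiased(samples, bin_width=0.5, count_cutoff=500)
        centers = grid.bin_centers[0]
        keep = ~grid.mask
        # W(x) = kT (x-mu)^2 / (2 sigma^2) + const
        coeffs = np.polyfit(centers[keep], grid.free_energy[keep], 2)
        assert coeffs[0] == pytest.approx(KT310 / (2 * sigma**2), rel=0.05)

    def test_minimum_is_zero(self):
        rng = np.random.default_rng(1)
        grid = pmf_unbiased(rng.normal(size=10_000), bin_width=0.5)
        assert np.nanmin(grid.free_energy[~grid.mask]) == 0.0

    def test_all_bins_below_cutoff_rejected(self):
        with pytest.raises(ValueError):
            pmf_unbiased(np.asarray([1.0, 2.0]), bin_width=0.5, count_cutoff=10)


class TestReweighted:
    def test_zero_boost_bit_identical(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(50, 3, size=20_000)
        plain = pmf_unbiased(samples, bin_width=0.5, count_cutoff=2)
        rew = pmf_reweighted(BoostedSamples(cv=samples, deltaV=np.zeros(samples.size)),
                             bin_width=0.5, count_cutoff=2)
        np.testing.assert_array_equal(plain.free_energy, rew.free_energy)
        np.testing.assert_array_equal(plain.mask, rew.mask)

    def test_constant_boost_bit_identical(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(50, 3, size=20_000)
        plain = pmf_unbiased(samples, bin_width=0.5, count_cutoff=2)
        rew = pmf_reweighted(
            BoostedSamples(cv=samples, deltaV=np.full(samples.size, 4.2)),
            bin_width=0.5, count_cutoff=2)
        np.testing.assert_array_equal(plain.free_energy, rew.free_energy)

    def test_boosted_double_well_recovery(self, opening_well):
        """Cumulant-expansion reweighting recovers the analytic well-depth
        difference and barrier of the generating potential."""
        boost = BoostSpec.from_potential(opening_well)
        run = simulate_langevin(opening_well, n_steps=400_000, seed=4, x0=62.0,
                                boost=boost)
        grid = pmf_reweighted(BoostedSamples(run.series.values, run.deltaV),
                              bin_width=0.5, count_cutoff=100)
        res = minima_and_barrier(grid, min_prominence=0.5)
        assert len(res.minima) == 2
        (loc_open, w_open), (loc_closed, w_closed) = res.minima
        assert loc_open[0] == pytest.approx(62.0, abs=1.0)
        assert loc_closed[0] == pytest.approx(34.0, abs=1.0)
        assert w_closed - w_open == pytest.approx(opening_well.asymmetry(), abs=0.3)
        assert res.barrier == pytest.approx(opening_well.barrier(), abs=0.3)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            pmf_reweighted(BoostedSamples(cv=np.ones(5), deltaV=np.zeros(5)),
                           order=3)


class TestPMF2D:
    def test_independent_uniform_flat(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 5, size=200_000)
        y = rng.uniform(0, 5, size=200_000)
        grid = pmf_2d(x, y, bin_widths=(0.5, 0.5), count_cutoff=10)
        inner = grid.free_energy[1:-1, 1:-1]
        assert np.nanmax(inner) < 0.1

    def test_count_cutoff_boundary(self):
        # one bin with 10 samples (kept), one with 9 (masked)
        x = np.concatenate([np.full(10, 0.25), np.full(9, 0.75)])
        y = np.full(19, 0.25)
        grid = pmf_2d(x, y, bin_widths=(0.5, 0.5), count_cutoff=10)
        assert not grid.mask[0, 0]
        assert grid.mask[1, 0]

    def test_correlated_gaussian_orientation(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal((2, 300_000))
        rho = 0.7
        x = z[0]
        y = rho * z[0] + np.sqrt(1 - rho**2) * z[1]
        grid = pmf_2d(x, y, bin_widths=(0.5, 0.5), count_cutoff=50)
        cx, cy = grid.bin_centers

        def w_at(xv, yv):
            i = np.argmin(np.abs(cx - xv))
            j = np.argmin(np.abs(cy - yv))
            return grid.free_energy[i, j]

        # along the correlation diagonal the surface is lower than against it
        assert w_at(1.0, 1.0) < w_at(1.0, -1.0)
        assert w_at(-1.0, -1.0) < w_at(-1.0, 1.0)

    def test_marginalisation_consistency(self, opening_well):
        """Summing reweighted 2D probabilities over the second axis
        reproduces the 1D reweighted PMF of the first within binning error."""
        boost = BoostSpec.from_potential(opening_well)
        run = simulate_langevin(opening_well, n_steps=150_000, seed=7, x0=62.0,
                                boost=boost)
        rng = np.random.default_rng(8)
        y = rng.uniform(0, 2, size=len(run.series.values))
        g2 = pmf_2d(run.series.values, y, bin_widths=(0.5, 0.5), count_cutoff=10,
                    deltaV=run.deltaV)
        g1 = pmf_reweighted(BoostedSamples(run.series.values, run.deltaV),
                            bin_width=0.5, count_cutoff=20)
        beta = 1.0 / KT310
        p2 = np.where(np.isnan(g2.free_energy), 0.0, np.exp(-beta * np.nan_to_num(g2.free_energy)))
        marg = p2.sum(axis=1)
        with np.errstate(divide="ignore"):
            w_marg = -np.log(marg / marg.max()) / beta
        keep = (~g1.mask) & (marg > 0) & (g1.count > 500)
        np.testing.assert_allclose(w_marg[keep],
                                   g1.free_energy[keep] - g1.free_energy[keep].min(),
                                   atol=0.25)


class TestMinimaAndBarrier:
    def test_hand_built_double_well(self):
        grid = _grid_1d([1.0, 0.0, 1.5, 2.5, 1.2, 0.4, 3.0])
        res = minima_and_barrier(grid)
        depths = [d for _, d in res.minima]
        assert depths[:2] == [0.0, pytest.approx(0.4)]
        assert res.barrier == pytest.approx(2.5)  # max along the only segment

    def test_single_well_no_barrier(self):
        grid = _grid_1d([2.0, 1.0, 0.0, 1.0, 2.0])
        res = minima_and_barrier(grid)
        assert len(res.minima) == 1
        assert res.barrier is None

    def test_masked_bins_block_paths(self):
        grid = _grid_1d([0.0, 1.0, np.nan, 1.0, 0.5], mask=[0, 0, 1, 0, 0])
        res = minima_and_barrier(grid)
        assert len(res.minima) == 2
        assert res.barrier is None  # the mask disconnects the wells

    def test_2d_barrier_matches_exhaustive_path_oracle(self):
        rng = np.random.default_rng(9)
        shape = (4, 4)
        w = rng.uniform(0, 5, size=shape)
        w[0, 0] = 0.0
        w[3, 3] = 0.05
        # make both corners local minima
        w[0, 1] = max(w[0, 1], 1.0)
        w[1, 0] = max(w[1, 0], 1.0)
        w[2, 3] = max(w[2, 3], 1.0)
        w[3, 2] = max(w[3, 2], 1.0)
        grid = PMFGrid(bin_edges=(np.arange(5.0), np.arange(5.0)),
                       free_energy=w, count=np.full(shape, 100),
                       mask=np.zeros(shape, dtype=bool), temperature=310.0)
        res = minima_and_barrier(grid)

        # brute-force: minimax over every simple path from (0,0) to (3,3)
        best = [np.inf]

        def dfs(node, seen, high):
            if node == (3, 3):
                best[0] = min(best[0], high)
                return
            i, j = node
            for ni, nj in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)):
                if 0 <= ni < 4 and 0 <= nj < 4 and (ni, nj) not in seen:
                    dfs((ni, nj), seen | {(ni, nj)}, max(high, w[ni, nj]))

        dfs((0, 0), {(0, 0)}, w[0, 0])
        assert res.barrier == pytest.approx(best[0] - w[0, 0])
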