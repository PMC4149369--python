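"""Neutral-lattice and model-based data generators."""

import numpy as np
import pytest

from gsam import (GSAMSpec, LatticeCommunity, expected_nested_richness,
                  generate_gsam_data, nested_sar, populate_lattice,
                  simulate_metacommunity)
from gsam.terms import intercept, log_area_power


class TestMetacommunity:
    def test_sums_to_one_and_positive(self):
        p = simulate_metacommunity(80, 0.5, seed=1)
        assert p.size == 80
        assert np.all(p > 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        a = simulate_metacommunity(80, 0.5, seed=9)
        b = simulate_metacommunity(80, 0.5, seed=9)
        assert np.array_equal(a, b)

    def test_large_theta_tends_uniform(self):
        p = simulate_metacommunity(50, 1e6, seed=2)
        assert np.max(np.abs(p - 1 / 50)) < 1e-2

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_metacommunity(1, 0.5)
        with pytest.raises(ValueError):
            simulate_metacommunity(10, 0.0)


class TestLattice:
    def test_degenerate_pool_fills_single_species(self):
        p = np.full(5, 1e-300)
        p[0] = 1.0
        comm = populate_lattice(8, p / p.sum(), seed=3)
        assert np.all(comm.cells == 1)

    def test_cell_frequencies_approach_pool(self):
        p = simulate_metacommunity(40, 1.0, seed=4)
        comm = populate_lattice(256, p, seed=5)
        counts = np.bincount(comm.cells.ravel(), minlength=41)[1:]
        freq = counts / comm.cells.size
        big = p >= 0.01
        assert np.max(np.abs(freq[big] - p[big])) < 0.01

    def test_reproducible_grid(self):
        p = np.array([0.5, 0.5])
        a = populate_lattice(2, p, seed=11)
        b = populate_lattice(2, p, seed=11)
        assert np.array_equal(a.cells, b.cells)
        assert a.cells.shape == (2, 2)

    def test_community_validation(self):
        with pytest.raises(ValueError, match="square"):
            LatticeCommunity(np.ones((2, 3), int), np.array([1.0]))
        with pytest.raises(ValueError, match="sum"):
            LatticeCommunity(np.ones((2, 2), int), np.array([0.4, 0.4]))


class TestNestedSAR:
    def test_extreme_quadrats(self):
        p = simulate_metacommunity(30, 0.5, seed=6)
        comm = populate_lattice(32, p, seed=7)
        data = nested_sar(comm, [1, 32])
        assert data.species[0] == 1
        assert data.species[-1] == comm.richness()
        assert data.area[-1] == 32 ** 2

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_quadrat_side(self, seed):
        p = simulate_metacommunity(60, 0.5, seed=seed)
        comm = populate_lattice(48, p, seed=seed + 100)
        data = nested_sar(comm, [1, 2, 4, 8, 16, 32, 48])
        assert np.all(np.diff(data.species) >= 0)

    def test_quadrat_exceeding_lattice(self):
        comm = populate_lattice(8, np.array([0.5, 0.5]), seed=1)
        with pytest.raises(ValueError):
            nested_sar(comm, [4, 16])

    def test_mean_richness_matches_closed_form(self):
        """i.i.d. filling: mean richness over replicate lattices agrees
        with sum_i [1 - (1 - p_i)^a] within 3 SE."""
        pool = simulate_metacommunity(80, 0.5, seed=8)
        sides = [2, 4, 8, 16, 32]
        reps = 300
        rich = np.empty((reps, len(sides)))
        for r in range(reps):
            comm = populate_lattice(32, pool, seed=1000 + r)
            rich[r] = nested_sar(comm, sides).species
        mean = rich.mean(axis=0)
        se = rich.std(axis=0, ddof=1) / np.sqrt(reps)
        expected = expected_nested_richness(pool,
                                            np.asarray(sides, float) ** 2)
        # rounding to integer counts adds at most 0.5 of absolute slack
        assert np.all(np.abs(mean - expected) < 3 * se + 0.5)

    def test_average_anchor_option(self):
        p = simulate_metacommunity(30, 0.5, seed=12)
        comm = populate_lattice(16, p, seed=13)
        data = nested_sar(comm, [2, 8], anchor="average")
        assert len(data) == 2 and np.all(data.species >= 1)


@pytest.fixture(scope="module")
def spec():
    return GSAMSpec(terms=(intercept(), log_area_power(1)), lam=1.0)


class TestGSAMSampler:

    def test_zero_dispersion_is_deterministic_mean(self, spec):
        areas = np.array([1.0, 10.0, 100.0])
        data = generate_gsam_data(spec, [20.0, 10.0], lam=1.0, dispersion=0.0,
                                  areas=areas, seed=0)
        mu = 20.0 + 10.0 * np.log(areas)
        assert np.array_equal(data.species, np.rint(mu + 1).astype(int))

    def test_same_seed_same_data(self, spec):
        areas = np.geomspace(1, 50, 20)
        a = generate_gsam_data(spec, [20.0, 10.0], 1.0, 16.0, areas, seed=4)
        b = generate_gsam_data(spec, [20.0, 10.0], 1.0, 16.0, areas, seed=4)
        assert np.array_equal(a.species, b.species)

    def test_sampling_mean_at_one_area(self, spec):
        """Normal family, lambda = 1: the sample mean of richness at a fixed
        area approaches mu + 1."""
        n = 10 ** 4
        areas = np.full(n, 10.0)
        data = generate_gsam_data(spec, [20.0, 10.0], 1.0, 25.0, areas, seed=6)
        mu = 20.0 + 10.0 * np.log(10.0)
        se = data.species.std(ddof=1) / np.sqrt(n)
        assert abs(data.species.mean() - (mu + 1)) < 3 * se + 0.5

    def test_incompatible_parameters_raise(self, spec):
        areas = np.array([1.0])
        with pytest.raises((RuntimeError, ValueError)):
            generate_gsam_data(spec, [-50.0, 0.1], lam=1.0, dispersion=1.0,
                               areas=areas, seed=1, max_attempts=50)
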