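"""Living / thermal polymerization simulator: conservation, alternation,
closed-form limits, restart behavior."""

import numpy as np
import pytest
from scipy import stats

from dhtpoly import (
    ChainState,
    SimParams,
    chain_contour_lengths,
    extend_population,
    simulate_living,
    simulate_thermal,
)
from dhtpoly.chain_growth import tile_counts, unit_counts


class TestChainState:
    def test_alternation_from_sequence(self):
        c = ChainState.from_sequence(["A", "B", "A"])
        assert (c.n_A, c.n_B, c.n_tiles) == (2, 1, 3)
        with pytest.raises(ValueError):
            ChainState.from_sequence(["B", "A"])

    def test_living_chains_are_complete_repeats(self):
        pop = simulate_living(SimParams(ratio_MI=3, n_initiators=200, seed=0))
        for c in pop.chains:
            assert c.n_tiles % 2 == 0 and c.n_tiles > 0
            assert c.sequence[:2] == ["A", "B"]
            assert c.active_terminus == "expects_A"


class TestSimulateLiving:
    def test_determinism(self):
        p = SimParams(ratio_MI=5, n_initiators=500, seed=7)
        a = simulate_living(p)
        b = simulate_living(p)
        assert a.chains == b.chains and a.free_I == b.free_I

    def test_mass_conservation(self):
        for mode in ("ideal", "kinetic"):
            pop = simulate_living(
                SimParams(ratio_MI=4, n_initiators=300, mode=mode, seed=3)
            )
            pop.assert_mass_conserved()
            assert pop.total_A() == pop.meta["total_A"]
            assert pop.total_I() == pop.meta["n_initiators"]

    def test_no_monomers_leaves_bare_initiators(self):
        pop = simulate_living(SimParams(ratio_MI=0, n_initiators=50, seed=1))
        assert pop.chains == [] and pop.free_I == 50

    def test_zero_initiators_is_no_active_sites(self):
        with pytest.raises(ValueError, match="active sites"):
            simulate_living(SimParams(ratio_MI=1, n_initiators=0, seed=1))

    def test_unit_counts_are_poisson(self, pop_ratio10):
        """Fast-mixing limit: per-initiator repeat-unit counts are
        (multinomially) Poisson with mean [M]0/[I]0."""
        k = unit_counts(pop_ratio10, include_uninitiated=True)
        assert k.mean() == pytest.approx(10.0, abs=0.1)
        assert k.var() == pytest.approx(10.0, rel=0.05)
        # chi-squared goodness of fit against Poisson(10)
        lo, hi = 2, 20
        obs = np.array([(k == j).sum() for j in range(lo, hi)], dtype=float)
        obs = np.concatenate([[np.sum(k < lo)], obs, [np.sum(k >= hi)]])
        pmf = stats.poisson.pmf(np.arange(lo, hi), 10.0)
        exp = np.concatenate(
            [[stats.poisson.cdf(lo - 1, 10.0)], pmf, [stats.poisson.sf(hi - 1, 10.0)]]
        ) * k.size
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, df=obs.size - 1)
        assert p > 0.01

    def test_kinetic_equal_rates_matches_ideal_moments(self):
        """With the initiation segment kinetically identical to the
        propagation segment (the design's own sequence identity), the exact
        Gillespie run reproduces the fast-mixing moments."""
        n = 2000
        kin = simulate_living(
            SimParams(ratio_MI=5, n_initiators=n, mode="kinetic",
                      k_init=1.0, k_prop=1.0, seed=21)
        )
        ide = simulate_living(SimParams(ratio_MI=5, n_initiators=n, seed=22))
        uk = unit_counts(kin, include_uninitiated=True)
        ui = unit_counts(ide, include_uninitiated=True)
        assert uk.mean() == pytest.approx(ui.mean(), rel=1e-9)  # exact budget
        se_var = 5.0 * np.sqrt(2.0 / n) * 3
        assert abs(uk.var() - ui.var()) < 2 * se_var

    def test_slow_initiation_broadens_nothing_but_narrows_counts(self):
        # k_init << k_prop: few chains, each much longer (sanity direction)
        pop = simulate_living(
            SimParams(ratio_MI=5, n_initiators=1000, mode="kinetic",
                      k_init=0.01, k_prop=1.0, seed=4)
        )
        assert len(pop.chains) < 1000
        mean_len = np.mean([c.n_units for c in pop.chains])
        assert mean_len > 5.0


class TestSimulateThermal:
    def test_full_association_limit(self):
        pop = simulate_thermal(
            SimParams(mode="thermal", conversion_p=0.0, n_monomer_units=1000, seed=0)
        )
        assert all(c.n_tiles == 1 for c in pop.chains)
        assert all(c.active_terminus == "none" for c in pop.chains)

    def test_geometric_mean_length(self):
        pop = simulate_thermal(
            SimParams(mode="thermal", conversion_p=0.9, n_monomer_units=200_000,
                      seed=5)
        )
        t = tile_counts(pop)
        assert t.mean() == pytest.approx(10.0, rel=0.05)  # 1/(1-p)

    def test_p_out_of_range(self):
        with pytest.raises(ValueError):
            simulate_thermal(
                SimParams(mode="thermal", conversion_p=1.0, n_monomer_units=10)
            )


class TestExtendPopulation:
    def test_noop_extension(self):
        pop = simulate_living(SimParams(ratio_MI=2, n_initiators=400, seed=9))
        same = extend_population(pop, 0, 0)
        assert [c.n_tiles for c in same.chains] == [c.n_tiles for c in pop.chains]

    def test_chain_count_unchanged_and_mass_conserved(self):
        pop = simulate_living(SimParams(ratio_MI=1, n_initiators=2000, seed=9))
        n0 = len(pop.chains)
        new = extend_population(pop, 2000, 2000, seed=10)
        assert len(new.chains) == n0
        new.assert_mass_conserved()

    def test_mean_tile_count_doubles(self):
        n = 5000
        pop = simulate_living(SimParams(ratio_MI=1, n_initiators=n, seed=13))
        new = extend_population(pop, n, n, seed=14)
        m0 = tile_counts(pop).sum()
        m1 = tile_counts(new).sum()
        assert m1 == 2 * m0  # every added pair lands on a chain

    def test_thermal_population_has_no_active_termini(self):
        pop = simulate_thermal(
            SimParams(mode="thermal", conversion_p=0.5, n_monomer_units=100, seed=2)
        )
        with pytest.raises(ValueError, match="active termini"):
            extend_population(pop, 10, 10)


class TestContourLengths:
    def test_two_tile_chain(self):
        pop = simulate_living(SimParams(ratio_MI=1, n_initiators=1, seed=0))
        assert pop.chains[0].n_tiles == 2
        (length,) = chain_contour_lengths(pop, 16.0)
        assert length == pytest.approx(32.0)

    def test_initiator_contribution_configurable(self):
        pop = simulate_living(SimParams(ratio_MI=1, n_initiators=1, seed=0))
        (length,) = chain_contour_lengths(pop, 16.0, initiator_length_nm=5.0)
        assert length == pytest.approx(37.0)

    def test_bad_tile_length(self, pop_ratio1):
        with pytest.raises(ValueError):
            chain_contour_lengths(pop_ratio1, 0.0)
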