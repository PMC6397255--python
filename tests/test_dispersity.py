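"""Dispersity moments (Ln, Lw, sigma, PDI) and Poisson label-count fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhtpoly import (
    LabelHistogram,
    LengthSample,
    SimParams,
    dispersity_summary,
    fit_poisson,
    label_counts,
    simulate_living,
)


def brute_force_summary(values, multiplicities):
    """Expand multiplicities into a flat list and evaluate the moment
    definitions term by term."""
    flat = [v for v, m in zip(values, multiplicities) for _ in range(int(m))]
    N = len(flat)
    Ln = sum(flat) / N
    Lw = sum(v * v for v in flat) / sum(flat)
    sigma = math.sqrt(sum((v - Ln) ** 2 for v in flat) / N)
    return Ln, Lw, sigma, Lw / Ln


class TestDispersitySummary:
    def test_monodisperse(self):
        s = dispersity_summary(LengthSample([100.0] * 5))
        assert (s.Ln, s.Lw, s.sigma, s.PDI) == (100.0, 100.0, 0.0, 1.0)

    def test_hand_computed_case(self):
        s = dispersity_summary(LengthSample([100.0, 100.0, 200.0]))
        assert s.Ln == pytest.approx(133.3333, abs=1e-3)
        assert s.Lw == pytest.approx(150.0)
        assert s.sigma == pytest.approx(47.1405, abs=1e-3)
        assert s.PDI == pytest.approx(1.125)

    def test_multiplicities_match_expansion(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(1, 8)
            values = rng.uniform(1.0, 300.0, size=k)
            mult = rng.integers(1, 5, size=k)
            s = dispersity_summary(LengthSample(values, mult))
            Ln, Lw, sigma, pdi = brute_force_summary(values, mult)
            assert s.Ln == pytest.approx(Ln)
            assert s.Lw == pytest.approx(Lw)
            assert s.sigma == pytest.approx(sigma)
            assert s.PDI == pytest.approx(pdi)

    @given(
        st.lists(st.floats(min_value=0.5, max_value=1e4), min_size=1, max_size=60)
    )
    @settings(max_examples=150, derandomize=True)
    def test_lw_at_least_ln(self, values):
        s = dispersity_summary(LengthSample(values))
        assert s.Lw >= s.Ln * (1 - 1e-12)
        assert s.PDI >= 1 - 1e-12
        if len(set(values)) == 1:
            assert s.PDI == pytest.approx(1.0)

    def test_rejects_nonpositive_without_flag(self):
        with pytest.raises(ValueError):
            LengthSample([10.0, 0.0])
        LengthSample([10.0, 0.0], allow_zero=True)  # per-site bookkeeping
        with pytest.raises(ValueError):
            LengthSample([10.0, -1.0], allow_zero=True)

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            LengthSample([])


class TestFitPoisson:
    def test_untruncated_mle_is_weighted_mean(self):
        hist = LabelHistogram({0: 10, 1: 20, 2: 10, 3: 5})
        fit = fit_poisson(hist)
        assert fit.lambda_hat == pytest.approx(hist.mean())
        assert not fit.truncated and fit.converged

    def test_untruncated_recovery(self):
        rng = np.random.default_rng(12)
        draws = rng.poisson(2.0, size=10_000)
        fit = fit_poisson(LabelHistogram.from_counts(draws))
        assert fit.lambda_hat == pytest.approx(2.0, abs=0.05)

    def test_truncated_recovery(self):
        rng = np.random.default_rng(13)
        draws = rng.poisson(1.0, size=40_000)
        hist = LabelHistogram.from_counts(draws, truncated=True)
        fit = fit_poisson(hist)
        assert fit.truncated
        assert fit.lambda_hat == pytest.approx(1.0, abs=0.05)

    def test_degenerate_truncated_sample_is_flagged(self):
        fit = fit_poisson(LabelHistogram({1: 1000}, truncated=True))
        assert not fit.converged and fit.lambda_hat == 0.0

    def test_all_mass_at_zero_is_error(self):
        with pytest.raises(ValueError):
            fit_poisson(LabelHistogram({0: 100}))

    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_recovery_grid_bias_and_rmse(self, lam):
        """Bias < 2% at large n; RMSE decreasing with sample size."""
        rmse_by_n = []
        for n in (100, 1000, 10_000):
            errs = []
            for rep in range(8):
                rng = np.random.default_rng(1000 * rep + n)
                draws = rng.poisson(lam, size=n)
                hist = LabelHistogram.from_counts(draws, truncated=True)
                fit = fit_poisson(hist)
                if fit.converged:
                    errs.append(fit.lambda_hat - lam)
            rmse_by_n.append(np.sqrt(np.mean(np.square(errs))))
            if n == 10_000:
                assert abs(np.mean(errs)) / lam < 0.02
        assert rmse_by_n[-1] < rmse_by_n[0]

    def test_loglik_is_maximal_at_fit(self):
        rng = np.random.default_rng(5)
        hist = LabelHistogram.from_counts(rng.poisson(3.0, 2000), truncated=True)
        fit = fit_poisson(hist)
        from dhtpoly.dispersity import _loglik

        for lam in (fit.lambda_hat * 0.9, fit.lambda_hat * 1.1):
            assert _loglik(hist, lam) < fit.log_likelihood


class TestLabelCounts:
    def test_full_efficiency_counts_every_A(self, pop_ratio1):
        hist = label_counts(pop_ratio1, 1.0, truncated=False)
        expected = {}
        for c in pop_ratio1.chains:
            expected[c.n_A] = expected.get(c.n_A, 0) + 1
        assert hist.counts == expected

    def test_zero_efficiency_surfaces_downstream_error(self, pop_ratio1):
        hist = label_counts(pop_ratio1, 0.0, seed=1, truncated=True)
        assert hist.n == 0
        with pytest.raises(ValueError):
            fit_poisson(hist)

    def test_partial_labeling_thins_the_mean(self, pop_ratio10):
        hist = label_counts(pop_ratio10, 0.5, seed=2, truncated=False)
        assert hist.mean() == pytest.approx(5.0, rel=0.05)

    def test_pdi_decreases_with_ratio(self):
        """Tile-unit PDI over all initiator sites follows (1 + mu)/mu with mu
        the mean repeat-unit count, hence decreases with [M]0/[I]0."""
        from dhtpoly.chain_growth import tile_counts

        pdis = []
        for i, r in enumerate((1, 2, 5, 10)):
            pop = simulate_living(SimParams(ratio_MI=r, n_initiators=10_000,
                                            seed=40 + i))
            t = tile_counts(pop, include_uninitiated=True)
            s = dispersity_summary(LengthSample(t, allow_zero=True))
            assert s.PDI == pytest.approx((1 + r) / r, rel=0.03)
            pdis.append(s.PDI)
        assert all(a > b for a, b in zip(pdis, pdis[1:]))
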