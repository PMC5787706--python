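import numpy as np
import pytest
from scipy import stats

from galnet import (activation_lags, burn_in, default_time_grid,
                    predicted_inducibility, simulate_induction)
from galnet.simulate import TrajectoryEnsemble, ensemble_threshold


class TestBurnIn:
    def test_rejects_empty_population(self, params):
        with pytest.raises(ValueError):
            burn_in(params, 0, seed=1)

    def test_short_burn_in_warns(self, params):
        with pytest.warns(UserWarning, match="stationar"):
            burn_in(params, 5, seed=1, t_burn=10.0)

    def test_leaky_stationary_moments(self, no_feedback_params):
        """With feedback severed each gene is a two-stage birth-death process:
        stationary mean mRNA alpha/beta and mean protein alpha*gamma/(beta*mu),
        protein variance mean*(1 + gamma/(beta+mu))."""
        n = 1500
        pop = burn_in(no_feedback_params, n, seed=42, extrinsic_cv=0.0)
        for i, g in enumerate(no_feedback_params.genes):
            if g.name == "REPORTER":
                continue
            m_mean = g.alpha / g.beta
            se = np.sqrt(m_mean / n)  # Poisson variance
            assert pop.mrna[:, i].mean() == pytest.approx(m_mean, abs=3 * se)
            p_mean = g.alpha * g.gamma / (g.beta * g.mu)
            p_var = p_mean * (1 + g.gamma / (g.beta + g.mu))
            se_p = np.sqrt(p_var / n)
            assert pop.prot[:, i].mean() == pytest.approx(p_mean, abs=3 * se_p)

    def test_clamped_promoter_mrna_is_poisson(self, no_feedback_params):
        """Stationary mRNA of a constitutive gene is Poisson(alpha/beta)
        (chi-square goodness of fit, p > 0.01)."""
        n = 2000
        pop = burn_in(no_feedback_params, n, seed=7, extrinsic_cv=0.0)
        g = no_feedback_params["GAL80"]
        lam = g.alpha / g.beta
        counts = pop.mrna[:, 2]
        kmax = int(counts.max())
        observed = np.bincount(counts, minlength=kmax + 1).astype(float)
        expected = n * stats.poisson.pmf(np.arange(kmax + 1), lam)
        expected[-1] = n * stats.poisson.sf(kmax - 1, lam)
        # merge low-expectation tail bins
        keep = expected >= 5
        obs_m = np.append(observed[keep], observed[~keep].sum())
        exp_m = np.append(expected[keep], expected[~keep].sum())
        chi2 = np.sum((obs_m - exp_m) ** 2 / exp_m)
        p = stats.chi2.sf(chi2, df=len(obs_m) - 1)
        assert p > 0.01

    def test_reproducible(self, params):
        a = burn_in(params, 50, seed=9)
        b = burn_in(params, 50, seed=9)
        assert np.array_equal(a.prot, b.prot)
        assert np.array_equal(a.mrna, b.mrna)
        assert np.array_equal(a.efac, b.efac)


class TestInduction:
    def test_requires_valid_grid(self, params):
        pop = burn_in(params, 5, seed=1, t_burn=0.0)
        with pytest.raises(ValueError):
            simulate_induction(pop, 0.5, np.array([10.0, 20.0]), seed=1)
        with pytest.raises(ValueError):
            simulate_induction(pop, 0.5, np.array([0.0, 20.0, 20.0]), seed=1)

    def test_no_stimulus_leaves_distribution_stationary(self, gradual_params):
        """At gal = 0 the reporter distribution after 250 min is statistically
        indistinguishable from the t = 0 snapshot."""
        pop = burn_in(gradual_params, 500, seed=11)
        ens = simulate_induction(pop, 0.0, np.array([0.0, 250.0]), seed=12)
        _, p = stats.ks_2samp(ens.signals[:, 0], ens.signals[:, -1])
        assert p > 0.01

    def test_bit_reproducible(self, gradual_params):
        pop = burn_in(gradual_params, 60, seed=3)
        grid = np.array([0.0, 50.0, 100.0])
        a = simulate_induction(pop, 0.5, grid, seed=4)
        b = simulate_induction(pop, 0.5, grid, seed=4)
        assert np.array_equal(a.signals, b.signals)

    def test_population_not_mutated(self, gradual_params):
        pop = burn_in(gradual_params, 30, seed=3)
        before = pop.prot.copy()
        simulate_induction(pop, 0.5, np.array([0.0, 100.0]), seed=4)
        assert np.array_equal(pop.prot, before)


class TestActivationLags:
    def _ens(self, signals, grid, params):
        return TrajectoryEnsemble(time_grid=grid, signals=signals,
                                  initial_inducers=np.zeros(signals.shape[0]),
                                  seed=0, params=params, gal=0.5)

    def test_monotone_signal_crossing(self, params):
        grid = np.arange(0.0, 101.0, 10.0)
        sig = np.tile(np.linspace(0, 100, grid.size), (3, 1))  # crosses 35 at t=40
        lags, censored = activation_lags(self._ens(sig, grid, params), 35.0)
        assert np.all(lags == 40.0)
        assert not censored.any()

    def test_all_off_is_censored(self, params):
        grid = np.arange(0.0, 101.0, 10.0)
        sig = np.ones((4, grid.size))
        lags, censored = activation_lags(self._ens(sig, grid, params), 50.0)
        assert censored.all()

    def test_binary_regime_lag_anticorrelates_with_inducer_reserve(
            self, binary_params):
        """Cells holding fewer Gal1p+Gal3p molecules at induction lag longer."""
        pop = burn_in(binary_params, 500, seed=21)
        ens = simulate_induction(pop, 0.5, default_time_grid(), seed=22)
        thr = ensemble_threshold(ens)
        lags, _ = activation_lags(ens, thr)
        r, p = stats.spearmanr(lags, ens.initial_inducers)
        assert r < 0
        assert p < 0.01


class TestPredictedInducibility:
    def test_no_galactose_stays_off(self, gradual_params):
        ser = predicted_inducibility(gradual_params, 0.0, default_time_grid(),
                                     n_cells=400, seed=5)
        assert np.all(ser.fraction_on <= 0.02)

    def test_final_fraction_monotone_in_gal(self, gradual_params):
        pop = burn_in(gradual_params, 400, seed=6)
        finals = []
        for gal in (0.05, 0.1, 0.5):
            ser = predicted_inducibility(gradual_params, gal,
                                         default_time_grid(), 400, seed=6,
                                         population=pop)
            finals.append(ser.fraction_on[-1])
        assert finals[0] <= finals[1] + 0.02
        assert finals[1] <= finals[2] + 0.02

    def test_gradual_regime_saturates(self, gradual_params):
        ser = predicted_inducibility(gradual_params, 0.5, default_time_grid(),
                                     n_cells=500, seed=8)
        assert ser.fraction_on[-1] >= 0.95

    def test_sampling_error_shrinks_with_cells(self, gradual_params):
        small = predicted_inducibility(gradual_params, 0.5,
                                       default_time_grid(), 200, seed=9)
        large = predicted_inducibility(gradual_params, 0.5,
                                       default_time_grid(), 800, seed=9)
        transiting = (small.sem > 0) & (large.sem > 0)
        assert transiting.sum() >= 3
        assert np.all(large.sem[transiting] < small.sem[transiting])
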