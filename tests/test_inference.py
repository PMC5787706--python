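import numpy as np
import pytest

from galnet import default_time_grid, predicted_inducibility, study_inducibility
from galnet.inference import (FitGrid, FitResult, chi2_score, grid_fit,
                              predict_holdout, relative_summaries)
from galnet.series import InducibilitySeries, binomial_series


def make_series(times, fracs, sem, n=10_000, gal=0.5):
    fracs = np.asarray(fracs, float)
    return InducibilitySeries(times=np.asarray(times, float),
                              fraction_on=fracs,
                              sem=np.full(fracs.size, sem),
                              n_cells=np.full(fracs.size, n), gal=gal)


class TestChi2Score:
    def test_perfect_agreement_scores_zero(self):
        s = make_series([0, 10, 20], [0.1, 0.5, 0.9], sem=0.02)
        assert chi2_score({0.5: s}, {0.5: s}) == 0.0

    def test_single_point_value(self):
        obs = make_series([0.0], [0.5], sem=0.05)
        pred = make_series([0.0], [0.6], sem=0.0, n=10**9)  # negligible MC term
        assert chi2_score({0.5: obs}, {0.5: pred}) == pytest.approx(4.0, rel=1e-6)

    def test_additivity_over_concentrations(self):
        obs = make_series([0, 10], [0.2, 0.7], sem=0.03)
        pred = make_series([0, 10], [0.25, 0.65], sem=0.02)
        base = chi2_score({0.5: obs}, {0.5: pred})
        extra = make_series([0, 10], [0.3, 0.8], sem=0.03, gal=0.1)
        both = chi2_score({0.5: obs, 0.1: extra}, {0.5: pred, 0.1: extra})
        assert both == pytest.approx(base)

    def test_mismatched_keys_rejected(self):
        s = make_series([0.0], [0.5], sem=0.05)
        with pytest.raises(ValueError, match="concentration"):
            chi2_score({0.5: s}, {0.1: s})

    def test_mismatched_times_rejected(self):
        a = make_series([0.0, 10.0], [0.5, 0.6], sem=0.05)
        b = make_series([0.0, 20.0], [0.5, 0.6], sem=0.05)
        with pytest.raises(ValueError, match="time"):
            chi2_score({0.5: a}, {0.5: b})

    def test_sigma_floor_guards_saturated_points(self):
        obs = make_series([0.0], [0.0], sem=0.0)
        pred = make_series([0.0], [0.1], sem=0.0, n=100)
        # sigma floored at 1/n_pred = 0.01 -> chi2 = (0.1/0.01)^2
        assert chi2_score({0.5: obs}, {0.5: pred}) == pytest.approx(100.0)


class TestFitGrid:
    def test_default_spans_region_of_interest(self):
        grid = FitGrid.default()
        assert grid.rho_values[0] <= 10.0
        assert grid.rho_values[-1] >= 1000.0
        assert grid.kgal_values[0] == pytest.approx(0.005)
        assert grid.kgal_values[-1] >= 0.5
        # the reference coordinates are exactly representable
        assert np.min(np.abs(grid.rho_values - 40.0)) < 1e-9
        assert np.min(np.abs(grid.rho_values - 140.0)) < 1e-9
        assert np.min(np.abs(grid.kgal_values - 0.055)) < 1e-12

    def test_axes_must_increase(self):
        with pytest.raises(ValueError):
            FitGrid(rho_values=np.array([10.0, 5.0]),
                    kgal_values=np.array([0.01, 0.1]))


class TestGridFit:
    def test_local_recovery_of_generating_point(self, params):
        """Synthetic curves generated at a grid point are recovered at that
        grid point (narrow grid, seed-controlled)."""
        grid = FitGrid(rho_values=np.logspace(np.log10(40), np.log10(490), 5),
                       kgal_values=np.logspace(np.log10(0.014), np.log10(0.22), 5))
        rho_true = grid.rho_values[2]
        kgal_true = grid.kgal_values[2]
        gen = params.with_gal3(rho=rho_true, kgal=kgal_true)
        obs = study_inducibility(gen, (0.05, 0.5), default_time_grid(),
                                 n_cells=800, seed=31)
        fit = grid_fit(obs, grid, params, n_cells=150, seed=32)
        d_rho = abs(np.log10(fit.rho_hat / rho_true)) / grid.rho_spacing_log10
        d_kgal = abs(np.log10(fit.kgal_hat / kgal_true)) / grid.kgal_spacing_log10
        assert d_rho <= 1.0
        assert d_kgal <= 1.0
        assert not fit.unidentifiable
        assert fit.rho_err_log10 == pytest.approx(grid.rho_spacing_log10 / 2)

    def test_rescoring_is_bit_identical(self, params):
        gen = params.with_gal3(rho=140.0, kgal=0.055)
        obs = study_inducibility(gen, (0.5,), default_time_grid(), 300, seed=41)
        grid_a = FitGrid(np.array([60.0, 140.0, 320.0]),
                         np.array([0.03, 0.055, 0.1]))
        grid_b = FitGrid(np.array([60.0, 140.0, 320.0]),
                         np.array([0.03, 0.055, 0.1]))
        f1 = grid_fit(obs, grid_a, params, n_cells=120, seed=42)
        f2 = grid_fit(obs, grid_b, params, n_cells=120, seed=42)
        assert np.array_equal(f1.chi2_surface, f2.chi2_surface)

    def test_all_zero_observations_flagged_unidentifiable(self, params):
        times = default_time_grid()
        obs = {0.05: binomial_series(times, np.zeros(times.size),
                                     np.full(times.size, 500), gal=0.05)}
        obs[0.05].threshold = 50.0
        grid = FitGrid(np.logspace(1, 2, 4),
                       np.logspace(np.log10(0.05), np.log10(0.5), 4))
        fit = grid_fit(obs, grid, params, n_cells=100, seed=43)
        assert fit.unidentifiable

    def test_empty_observations_rejected(self, params):
        with pytest.raises(ValueError):
            grid_fit({}, FitGrid.default(), params, 100, 1)


class TestHoldout:
    def test_training_concentration_is_bit_exact(self, params):
        """Re-predicting a training concentration with the fit's own seed and
        cell count reproduces the training prediction exactly."""
        fit = FitResult(strain="s", rho_hat=140.0, kgal_hat=0.055,
                        rho_err_log10=0.05, kgal_err_log10=0.05, chi2_min=0.0,
                        chi2_surface=np.zeros((1, 1)),
                        grid=FitGrid(np.array([100.0, 140.0]),
                                     np.array([0.05, 0.055])),
                        seed=51, n_cells=300, threshold=40.0,
                        fixed_params=params)
        direct = predicted_inducibility(
            params.with_gal3(rho=140.0, kgal=0.055), 0.5, default_time_grid(),
            300, seed=51, threshold_rule=40.0)
        hold = predict_holdout(fit, 0.5, default_time_grid())
        assert np.array_equal(hold.fraction_on, direct.fraction_on)

    def test_missing_fixed_params_rejected(self):
        fit = FitResult("s", 140.0, 0.055, 0.05, 0.05, 0.0, np.zeros((1, 1)),
                        FitGrid(np.array([1.0, 2.0]), np.array([1.0, 2.0])))
        with pytest.raises(ValueError):
            predict_holdout(fit, 0.2, default_time_grid())


class TestRelativeSummaries:
    def _fit(self, strain, rho, kgal, unident=False):
        return FitResult(strain, rho, kgal, 0.05, 0.05, 0.0, np.zeros((1, 1)),
                         FitGrid(np.array([1.0, 2.0]), np.array([1.0, 2.0])),
                         unidentifiable=unident)

    def test_reference_is_unity(self):
        fits = {"REF": self._fit("REF", 140.0, 0.055)}
        rel = relative_summaries(fits, "REF")
        assert rel["REF"].rho_rel == 1.0
        assert rel["REF"].kgal_rel == 1.0

    def test_ratios(self):
        fits = {"REF": self._fit("REF", 100.0, 0.05),
                "VAR": self._fit("VAR", 300.0, 0.5)}
        rel = relative_summaries(fits, "REF")
        assert rel["VAR"].rho_rel == pytest.approx(3.0)
        assert rel["VAR"].kgal_rel == pytest.approx(10.0)

    def test_unidentifiable_reference_aborts(self):
        fits = {"REF": self._fit("REF", 100.0, 0.05, unident=True)}
        with pytest.raises(RuntimeError, match="unidentifiable"):
            relative_summaries(fits, "REF")
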