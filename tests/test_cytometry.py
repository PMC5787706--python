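import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from galnet.cytometry import (EventTable, NormalizationError, SchemaError,
                              fit_fl1_mixture, gate_events, inducibility,
                              normalize_samples, on_off_threshold,
                              response_amplitude)


def make_table(n, sample_id="s1", fsc_mean=480, ssc_mean=420, fl1=50.0,
               plate="P1", strain="A", time_min=60.0, seed=0, replicate=1):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "fsc": np.clip(rng.normal(fsc_mean, 50, n), 1, 1022).round(),
        "ssc": np.clip(rng.normal(ssc_mean, 55, n), 1, 1022).round(),
        "fl1": np.clip(rng.normal(fl1, 5, n), 1, 1022).round(),
        "strain": strain, "gal": 0.5, "time_min": time_min,
        "replicate": replicate, "plate": plate, "sample_id": sample_id,
    })


class TestGateEvents:
    def test_saturated_events_removed_before_gating(self):
        df = make_table(5000)
        df.loc[:199, "fl1"] = 1023
        gated, qc = gate_events(EventTable(df), min_cells=100)
        assert qc.loc[0, "n_unsaturated"] == 4800
        assert (gated.df["fl1"] < 1023).all()

    def test_retention_matches_keep_fraction(self):
        df = make_table(10_000)
        gated, qc = gate_events(EventTable(df), min_cells=100)
        retained = qc.loc[0, "n_gated"] / qc.loc[0, "n_unsaturated"]
        assert retained == pytest.approx(0.60, abs=0.02)

    def test_small_samples_dropped(self):
        # 4600 events -> ~2760 gated, below the default 3000-cell cutoff
        df = pd.concat([make_table(4600, "small"), make_table(10_000, "big")])
        gated, qc = gate_events(EventTable(df), min_cells=3000)
        qc = qc.set_index("sample_id")
        assert not qc.loc["small", "kept"]
        assert qc.loc["big", "kept"]
        assert set(gated.df["sample_id"]) == {"big"}

    def test_missing_column_rejected(self):
        df = make_table(100).drop(columns=["fl1"])
        with pytest.raises(SchemaError, match="fl1"):
            EventTable(df)


class TestNormalizeSamples:
    def _two_plate_tables(self, offset=10.0):
        parts, ctrl = [], []
        for plate, off in (("P1", 0.0), ("P2", offset)):
            for t in (0.0, 60.0):
                parts.append(make_table(
                    2000, f"A_{plate}_{t}", fl1=50 + off, plate=plate,
                    time_min=t, seed=int(t) + hash(plate) % 100))
            for rep in range(1, 25):
                ctrl.append(make_table(500, f"c_{plate}_{rep}", fl1=30 + off,
                                       plate=plate, strain="control",
                                       time_min=0.0, seed=rep, replicate=rep))
        return (EventTable(pd.concat(parts, ignore_index=True)),
                EventTable(pd.concat(ctrl, ignore_index=True)))

    def test_plate_offset_recovered(self):
        events, controls = self._two_plate_tables(offset=10.0)
        corrected, report = normalize_samples(events, controls, baseline=False)
        means = corrected.df.groupby("plate")["fl1"].mean()
        assert abs(means["P1"] - means["P2"]) < 0.5
        assert report["anova_p"] < 0.001

    def test_baseline_zeroes_t0(self):
        events, controls = self._two_plate_tables()
        corrected, _ = normalize_samples(events, controls)
        t0_mean = corrected.df.loc[corrected.df["time_min"] == 0, "fl1"].mean()
        assert t0_mean == pytest.approx(0.0, abs=1e-9)

    def test_single_plate_skips_plate_correction(self):
        df = pd.concat([make_table(1000, "a", fl1=40, time_min=0.0),
                        make_table(1000, "b", fl1=90, time_min=60.0)])
        corrected, report = normalize_samples(EventTable(df), controls=None)
        assert report["offsets"] == {}
        base = df.loc[df["time_min"] == 0, "fl1"].mean()
        expected = df.loc[df["time_min"] == 60, "fl1"].mean() - base
        got = corrected.df.loc[corrected.df["time_min"] == 60, "fl1"].mean()
        assert got == pytest.approx(expected, abs=1e-9)

    def test_multi_plate_without_controls_refused(self):
        events, _ = self._two_plate_tables()
        with pytest.raises(NormalizationError, match="control"):
            normalize_samples(events, controls=None)


class TestMixture:
    def test_unimodal_recovery(self):
        rng = np.random.default_rng(1)
        fit = fit_fl1_mixture(rng.normal(5.0, 1.0, 5000))
        assert fit.n_components == 1
        assert fit.mu_all == pytest.approx(5.0, abs=0.05)
        assert response_amplitude(fit) == fit.mu_all

    def test_bimodal_recovery(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(8, 1.5, 3000)])
        fit = fit_fl1_mixture(x)
        assert fit.n_components == 2
        assert fit.mu_off == pytest.approx(0.0, abs=0.1)
        assert fit.mu_on == pytest.approx(8.0, abs=0.15)
        assert fit.w_on == pytest.approx(0.6, abs=0.03)
        assert fit.sigma_on == pytest.approx(1.5, abs=0.1)
        assert response_amplitude(fit) == fit.mu_on

    def test_equal_components_collapse_to_one(self):
        rng = np.random.default_rng(3)
        fit = fit_fl1_mixture(rng.normal(4.0, 1.0, 4000))
        assert fit.n_components == 1

    def test_degenerate_input_uses_sigma_floor(self):
        fit = fit_fl1_mixture(np.full(100, 7.0))
        assert fit.n_components == 1
        assert fit.sigma_all > 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="50"):
            fit_fl1_mixture(np.arange(10.0))


class TestThreshold:
    @pytest.mark.parametrize("off,on,expected", [
        ((0.0, 1.0), (10.0, 1.0), 5.0),
        ((0.0, 2.0), (9.0, 1.0), 6.0),
    ])
    def test_closed_form(self, off, on, expected):
        assert on_off_threshold(off, on) == pytest.approx(expected, rel=1e-12)

    def test_defining_equation_holds(self):
        off, on = (1.3, 2.1), (17.9, 4.2)
        t = on_off_threshold(off, on)
        p_on_below = stats.norm.cdf(t, *on)
        p_off_above = stats.norm.sf(t, *off)
        assert abs(p_on_below - p_off_above) < 1e-12

    @given(st.floats(-50, 50))
    @settings(max_examples=25, derandomize=True)
    def test_translation_equivariance(self, c):
        t0 = on_off_threshold((0.0, 2.0), (9.0, 1.0))
        tc = on_off_threshold((c, 2.0), (9.0 + c, 1.0))
        assert tc == pytest.approx(t0 + c, abs=1e-9)

    def test_requires_separated_means(self):
        with pytest.raises(ValueError):
            on_off_threshold((5.0, 1.0), (5.0, 1.0))


class TestInducibility:
    @pytest.mark.parametrize("values,t,expected", [
        ([1, 2, 3, 4], 10.0, 0.0),
        ([1, 2, 3, 4], 2.5, 0.5),
        ([1, 2, 3, 4], 0.0, 1.0),
    ])
    def test_fractions(self, values, t, expected):
        frac, sem = inducibility(np.array(values, float), t)
        assert frac == expected
        assert sem == pytest.approx(np.sqrt(expected * (1 - expected) / 4))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            inducibility(np.array([]), 1.0)
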