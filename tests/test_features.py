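"""Biomarker battery: hand-checked oracles, closed forms, and recovery properties."""

import numpy as np
import pytest

from painecg.errors import ValidationError
from painecg.features import (
    RRSeries,
    build_feature_table,
    detect_r_peaks,
    derivative_statistics,
    ecg_statistics,
    hrv_frequency_domain,
    hrv_geometric,
    hrv_time_domain,
    FEATURE_COLUMNS,
    HRV_BIN_WIDTH_MS,
)
from painecg.synthdata import generate_rr_tachogram, synthesize_ecg


class TestECGStatistics:
    def test_hand_computed_example(self):
        out = ecg_statistics(np.array([3.0, -4.0, 3.0, -4.0]))
        assert out["ecg_rms"] == pytest.approx(3.5355, abs=1e-4)
        assert out["ecg_peak_to_peak"] == 7.0
        assert out["ecg_power"] == pytest.approx(12.5)

    def test_constant_signal_flags_moments_missing(self):
        out = ecg_statistics(np.full(10, -2.0))
        assert out["ecg_rms"] == 2.0
        assert out["ecg_peak_to_peak"] == 0.0
        assert np.isnan(out["ecg_kurtosis"]) and np.isnan(out["ecg_skewness"])

    def test_negation_flips_skewness_not_kurtosis(self):
        x = np.random.default_rng(1).gamma(2.0, size=500)
        a, b = ecg_statistics(x), ecg_statistics(-x)
        assert a["ecg_skewness"] == pytest.approx(-b["ecg_skewness"])
        assert a["ecg_kurtosis"] == pytest.approx(b["ecg_kurtosis"])

    def test_power_is_rms_squared(self, default_feature_table):
        tab = default_feature_table
        np.testing.assert_allclose(tab["ecg_power"], tab["ecg_rms"] ** 2, rtol=1e-12)


class TestDerivative:
    def test_constant_is_zero(self):
        assert derivative_statistics(np.full(100, 3.0), 250) == 0.0

    def test_unit_ramp(self):
        t = np.arange(1000) / 250.0
        assert derivative_statistics(t, 250) == pytest.approx(1.0)

    def test_sine_closed_form_limit(self):
        fs, f, A = 10000.0, 5.0, 2.0
        t = np.arange(int(fs)) / fs
        x = A * np.sin(2 * np.pi * f * t)
        expected = A * 2 * np.pi * f / np.sqrt(2)
        assert derivative_statistics(x, fs) == pytest.approx(expected, rel=1e-2)


class TestTimeDomainHRV:
    def test_hand_computed_quadruple(self):
        out = hrv_time_domain(np.array([800.0, 860.0, 870.0, 940.0]))
        assert out["rr_mean"] == pytest.approx(867.5)
        assert out["rr_std"] == pytest.approx(57.37, abs=0.01)
        assert out["rr_rmssd"] == pytest.approx(53.54, abs=0.01)
        assert out["pnn50"] == pytest.approx(66.67, abs=0.01)

    def test_equal_intervals_give_zero_variability(self):
        out = hrv_time_domain(np.full(10, 800.0))
        assert out["rr_std"] == out["rr_rmssd"] == out["pnn50"] == 0.0

    def test_pnn50_boundary_is_strict(self):
        out = hrv_time_domain(np.array([800.0, 850.0, 800.0]))  # |d| = 50 exactly
        assert out["pnn50"] == 0.0

    def test_insufficient_beats_flagged_missing(self):
        out = hrv_time_domain(np.array([800.0]))
        assert out["rr_mean"] == 800.0
        assert np.isnan(out["rr_std"])


class TestFrequencyDomainHRV:
    @staticmethod
    def _series_from_modulation(freq_hz: float, duration_s: float = 300.0) -> RRSeries:
        times = [0.0]
        while times[-1] < duration_s:
            t = times[-1]
            rr = 1.0 + 0.05 * np.sin(2 * np.pi * freq_hz * t)
            times.append(t + rr)
        return RRSeries.from_times(np.array(times))

    def test_hf_sinusoid_concentrates_in_hf(self):
        bands = hrv_frequency_domain(self._series_from_modulation(0.25))
        assert bands.hf_power >= 20 * bands.lf_power

    def test_lf_sinusoid_dominates_ratio(self):
        bands = hrv_frequency_domain(self._series_from_modulation(0.10))
        assert bands.lf_hf > 10

    def test_constant_tachogram_has_zero_power(self):
        times = np.arange(0, 300, 0.8)
        bands = hrv_frequency_domain(RRSeries.from_times(times))
        assert bands.vlf_power == bands.lf_power == bands.hf_power == 0.0


class TestGeometricHRV:
    def test_identical_intervals_single_bin(self):
        tri, tinn = hrv_geometric(np.full(100, 800.0))
        assert tri == 1.0
        assert tinn == pytest.approx(HRV_BIN_WIDTH_MS)

    def test_uniform_distribution_arithmetic(self):
        rr = np.random.default_rng(5).uniform(700, 900, size=50000)
        tri, _ = hrv_geometric(rr)
        # ideal n/(n*binwidth/200) = 25.6; modal-bin maximum bias pulls it low
        assert tri == pytest.approx(200.0 / HRV_BIN_WIDTH_MS, rel=0.12)

    def test_tinn_recovers_triangular_base_width(self):
        rr = np.random.default_rng(5).triangular(700, 800, 900, size=2000)
        _, tinn = hrv_geometric(rr)
        assert abs(tinn - 200.0) <= 2 * HRV_BIN_WIDTH_MS


class TestRPeakDetection:
    def test_sixty_bpm_minute_gives_sixty_peaks(self):
        ecg = synthesize_ecg(np.ones(60), 250)
        det = detect_r_peaks(ecg, 250)
        assert abs(det.n_peaks - 60) <= 1

    def test_timing_accuracy_on_noiseless_synthetic(self):
        rr = generate_rr_tachogram(60, 70, 40, 1.0, seed=2)
        ecg = synthesize_ecg(rr, 250)
        det = detect_r_peaks(ecg, 250)
        truth = 0.5 * rr[0] + np.concatenate([[0.0], np.cumsum(rr[1:])])
        for t in truth:
            assert np.min(np.abs(det.r_peak_times_s - t)) <= 0.020

    def test_flat_line_flagged_missing(self):
        det = detect_r_peaks(np.zeros(2500), 250)
        assert det.n_peaks == 0

    def test_constant_offset_invariance(self):
        ecg = synthesize_ecg(np.ones(30), 250)
        a = detect_r_peaks(ecg, 250)
        b = detect_r_peaks(ecg + 5.0, 250)
        np.testing.assert_array_equal(a.r_peak_times_s, b.r_peak_times_s)


class TestFeatureTable:
    def test_shape_and_column_contract(self, default_feature_table):
        tab = default_feature_table
        assert len(tab) == 80
        assert all(c in tab.columns for c in FEATURE_COLUMNS)
        assert {"covas_value", "covas_label"} <= set(tab.columns)
        assert len(FEATURE_COLUMNS) >= 18

    def test_hr_ibi_algebraic_identity(self, default_feature_table):
        tab = default_feature_table.dropna(subset=["hr_mean"])
        np.testing.assert_allclose(tab["hr_mean"] * tab["ibi_mean"], 60000.0, rtol=1e-12)

    def test_null_effect_features_carry_no_label_signal(self, null_study_table):
        """Pain vs no-pain groups are indistinguishable under the null.

        The battery is highly correlated (some columns are exact transforms
        of others), so family-wise control uses a min-p permutation test:
        the observed smallest Mann-Whitney p across features must not be
        extreme relative to its own label-permutation null.
        """
        from scipy.stats import mannwhitneyu

        tab = null_study_table
        usable = [
            c for c in FEATURE_COLUMNS
            if tab[c].dropna().nunique() > 1
        ]
        X = tab[usable].to_numpy()
        pain = (tab["covas_value"] > 0).to_numpy()

        def min_p(labels):
            ps = []
            for j in range(X.shape[1]):
                col = X[:, j]
                ok = ~np.isnan(col)
                ps.append(mannwhitneyu(col[ok & labels], col[ok & ~labels]).pvalue)
            return min(ps)

        observed = min_p(pain)
        rng = np.random.default_rng(99)
        n_perm = 200
        hits = sum(min_p(rng.permutation(pain)) <= observed for _ in range(n_perm))
        assert hits / n_perm > 0.01
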