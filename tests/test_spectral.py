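"""Windowed per-cell transforms, cohort averaging, peak detection and
waveform reconstruction."""

import numpy as np
import pytest

from holomass import spectral, synthetic
from holomass.drymass import DryMassTrace
from holomass.spectral import (OVERSAMPLING, average_spectra, cell_ft,
                               cohort_size_scan, compute_cell_spectra,
                               detrend_and_window, find_fundamental,
                               fundamental_amplitude, inverse_reconstruct,
                               measure_spikes, CellSpectrum, PeakReport)


def _trace(masses, dt=5.0, track_id=0):
    return DryMassTrace(track_id, np.arange(len(masses)) * dt,
                        np.asarray(masses, float))


class TestDetrendAndWindow:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(0, 500.0, 5.0)
        _, w, _ = detrend_and_window(_trace(200 + 0.3 * t))
        np.testing.assert_allclose(w, 0.0, atol=1e-9)

    def test_endpoints_vanish(self, rng):
        masses = 300 + rng.standard_normal(64)
        _, w, _ = detrend_and_window(_trace(masses))
        assert w[0] == 0.0
        assert abs(w[-1]) < 1e-12

    def test_sinusoid_windowed_pointwise(self):
        t = np.arange(0, 1000.0, 5.0)
        masses = 10 * np.sin(2 * np.pi * t / 125.0)
        times, w, T = detrend_and_window(_trace(masses))
        coef = np.polyfit(t, masses, 1)
        expected = (masses - np.polyval(coef, t)) * np.sin(np.pi * t / T)
        np.testing.assert_allclose(w, expected, atol=1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            detrend_and_window(_trace(np.ones(10)))


class TestCellFT:
    def test_zero_series_all_zero(self):
        t = np.arange(0, 500.0, 5.0)
        spec = cell_ft(t, np.zeros(t.size), 495.0)
        assert np.all(spec.amplitudes == 0)

    def test_frequency_grid_increment(self):
        t = np.arange(0, 500.0, 5.0)
        spec = cell_ft(t, np.zeros(t.size), 495.0)
        df = 1.0 / (495.0 * OVERSAMPLING)
        np.testing.assert_allclose(np.diff(spec.frequencies), df, rtol=1e-12)
        assert spec.frequencies[-1] <= 0.1 + df

    def test_on_grid_tone_peaks_at_its_frequency(self):
        f0 = 0.004
        trace = _trace(300 + np.cos(2 * np.pi * f0 * np.arange(0, 2000.0, 5.0)))
        t, w, T = detrend_and_window(trace)
        spec = cell_ft(t, w, T)
        peak = spec.frequencies[np.argmax(spec.amplitudes)]
        assert abs(peak - f0) <= spec.df / 2 + 1e-12

    def test_amplitude_normalization_matches_window_gain(self):
        # a cosine of amplitude a peaks at ~a: oracle by direct
        # evaluation of the windowed DFT at the tone frequency
        a, f0 = 7.0, 0.004
        t = np.arange(0, 2000.0, 5.0)
        trace = _trace(300 + a * np.cos(2 * np.pi * f0 * t))
        times, w, T = detrend_and_window(trace)
        spec = cell_ft(times, w, T)
        window = np.sin(np.pi * times / T)
        direct = 2 * abs(np.sum(w * np.exp(-2j * np.pi * f0 * times))) / window.sum()
        measured = spec.amplitudes[np.argmin(np.abs(spec.frequencies - f0))]
        assert measured == pytest.approx(direct, rel=1e-3)
        assert measured == pytest.approx(a, rel=0.05)

    def test_parseval_energy_identity(self, rng):
        # the zero-padded transform conserves windowed-signal energy:
        # sum |X_k|^2 over the full grid equals nfft * sum w^2
        for _ in range(3):
            masses = 300 + 20 * rng.standard_normal(200)
            t, w, T = detrend_and_window(_trace(masses))
            nfft = OVERSAMPLING * (t.size - 1)
            full = np.fft.fft(w, nfft)
            ratio = np.sum(np.abs(full) ** 2) / (nfft * np.sum(w ** 2))
            assert ratio == pytest.approx(1.0, rel=1e-12)


class TestAverageSpectra:
    def test_identical_spectra_mean_and_sd(self):
        t = np.arange(0, 1000.0, 5.0)
        trace = _trace(300 + np.cos(2 * np.pi * 0.004 * t))
        times, w, T = detrend_and_window(trace)
        spec = cell_ft(times, w, T)
        cohort = average_spectra([spec] * 5)
        # bins fed by a single grid frequency (count == 5 copies) have
        # zero spread; bins collecting two neighbouring grid points may
        # legitimately mix two amplitudes
        sel = cohort.count == 5
        assert np.nanmax(cohort.sd[sel]) == pytest.approx(0.0, abs=1e-6)
        sel = cohort.count > 0
        # the peak bin may pool two adjacent grid points of the
        # (identical) spectra, so compare at per-mille accuracy
        assert np.nanmax(cohort.mean[sel]) == pytest.approx(
            spec.amplitudes.max(), rel=1e-3)

    def test_every_frequency_in_exactly_one_bin(self):
        specs = []
        for T, cid in ((1000.0, 0), (1500.0, 1)):
            t = np.arange(0, T + 1e-9, 5.0)
            tr = _trace(300 + np.sin(0.01 * t), track_id=cid)
            times, w, Tj = detrend_and_window(tr)
            specs.append(cell_ft(times, w, Tj, cell_id=cid))
        cohort = average_spectra(specs, n_f=1)
        expected = sum(int((s.frequencies > 0).sum()) for s in specs)
        assert int(cohort.count.sum()) == expected

    def test_nf2_doubles_bin_width(self):
        t = np.arange(0, 1000.0, 5.0)
        tr = _trace(300 + np.sin(0.01 * t))
        times, w, T = detrend_and_window(tr)
        spec = cell_ft(times, w, T)
        c1 = average_spectra([spec], n_f=1)
        c2 = average_spectra([spec], n_f=2)
        assert c2.df == pytest.approx(2 * c1.df)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_spectra([])


class TestFindFundamental:
    def test_default_cohort_recovers_injected_frequency(self, default_cohort_report):
        cohort, report = default_cohort_report
        assert report.detected
        assert abs(report.f0 - 0.004) <= cohort.df

    def test_background_is_roughly_one_over_f(self, default_cohort_report):
        _, report = default_cohort_report
        assert 0.3 < report.background_exponent < 1.5

    def test_rhythm_free_cohort_not_detected(self):
        rhythm = synthetic.RhythmParams(pulse_amplitude=0.0)
        traces, _ = synthetic.generate_cohort(
            synthetic.CohortConfig(n_cells=150, seed=9), rhythm=rhythm)
        cohort = average_spectra(compute_cell_spectra(traces))
        report = find_fundamental(cohort)
        assert not report.detected
        assert report.message == "no significant peak"

    @pytest.mark.parametrize("period", [180.0, 250.0, 360.0])
    def test_period_sweep_recovered(self, period):
        rhythm = synthetic.RhythmParams(period=period)
        traces, _ = synthetic.generate_cohort(
            synthetic.CohortConfig(n_cells=300, seed=21), rhythm=rhythm)
        cohort = average_spectra(compute_cell_spectra(traces))
        report = find_fundamental(cohort)
        assert abs(report.f0 - 1.0 / period) / (1.0 / period) < 0.02

    def test_f0_estimate_unbiased_over_replicates(self):
        errors = []
        for seed in range(15):
            traces, _ = synthetic.generate_cohort(
                synthetic.CohortConfig(n_cells=150, seed=100 + seed))
            cohort = average_spectra(compute_cell_spectra(traces))
            report = find_fundamental(cohort)
            errors.append(report.f0 - 0.004)
        assert abs(np.mean(errors)) < 1.0 / (2000.0 * OVERSAMPLING)

    def test_fixed_frequency_amplitude_vanishes_without_rhythm(self):
        rhythm = synthetic.RhythmParams(pulse_amplitude=0.0)
        traces, _ = synthetic.generate_cohort(
            synthetic.CohortConfig(n_cells=150, seed=3), rhythm=rhythm)
        cohort = average_spectra(compute_cell_spectra(traces))
        af = fundamental_amplitude(cohort, 0.004)
        assert af < 5.0


class TestInverseReconstruct:
    def test_single_harmonic_is_pure_cosine(self):
        peak = PeakReport(f0=0.004, af=10.0, af_corrected=10.0,
                          significance=5.0, detected=True,
                          harmonics=np.array([10.0, 5.0, 2.0]),
                          background_coeff=1.0, background_exponent=0.5)
        rec = inverse_reconstruct(peak, duration=1000.0, n_harmonics=1)
        expected = 10.0 * np.cos(2 * np.pi * 0.004 * rec.times)
        np.testing.assert_allclose(rec.solution_plus, expected, atol=1e-9)

    def test_sign_pair_sums_to_zero(self, default_cohort_report):
        _, report = default_cohort_report
        rec = inverse_reconstruct(report)
        np.testing.assert_allclose(rec.solution_plus + rec.solution_minus, 0.0)

    def test_excess_harmonics_warn(self):
        peak = PeakReport(f0=0.004, af=1.0, af_corrected=1.0, significance=5.0,
                          detected=True, harmonics=np.array([1.0]),
                          background_coeff=1.0, background_exponent=0.5)
        with pytest.warns(UserWarning):
            inverse_reconstruct(peak, n_harmonics=4)

    def test_spike_metrics_on_known_comb(self):
        # six harmonics of an ideal FWHM-30 pulse train: spikes every
        # 250 min, measured width near 31 min
        a = np.array([23.1, 20.6, 17.0, 12.7, 8.5, 4.9])
        peak = PeakReport(f0=1 / 250.0, af=a[0], af_corrected=a[0],
                          significance=10.0, detected=True, harmonics=a,
                          background_coeff=1.0, background_exponent=0.5)
        rec = inverse_reconstruct(peak)
        metrics = measure_spikes(rec)
        assert metrics["interspike_min"] == pytest.approx(250.0, abs=1.5)
        assert 28.0 <= metrics["fwhm_min"] <= 34.0
        assert metrics["amplitude_pg"] == pytest.approx(102.7, rel=0.02)


class TestCohortSizeScan:
    def test_full_cohort_single_rep_reproduces_report(self, default_cohort,
                                                      default_cohort_report):
        traces, _ = default_cohort
        _, report = default_cohort_report
        rows = cohort_size_scan(traces, [300], n_rep=1)
        assert rows[0]["mean_significance"] == pytest.approx(report.significance)

    def test_oversized_request_rejected(self, default_cohort):
        traces, _ = default_cohort
        with pytest.raises(ValueError):
            cohort_size_scan(traces, [10 ** 6])
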