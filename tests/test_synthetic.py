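"""Generator tests: trace composition, cohort statistics, phantoms, holograms."""

import numpy as np
import pytest

from holomass import synthetic
from holomass.drymass import ALPHA
from holomass.synthetic import (CellPhantom, CohortConfig, GrowthNoiseParams,
                                RhythmParams, generate_cohort, generate_trace,
                                negative_control, phantom_opd, pink_noise,
                                pulse_train, render_hologram)

NOISE_OFF = GrowthNoiseParams(initial_mass=300.0, growth_rate=0.1,
                              pink_noise_rms=0.0, measurement_noise_sd=0.0)


class TestTraceComposition:
    def test_pulse_centers_spaced_by_period(self):
        rhythm = RhythmParams()
        t = np.arange(0, 2000.0, 1.0)
        p = pulse_train(t, rhythm, phase_offset=50.0)
        peaks = np.where((p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:])
                         & (p[1:-1] == rhythm.pulse_amplitude))[0] + 1
        assert np.all(np.diff(t[peaks]) == rhythm.period)

    @pytest.mark.parametrize("shape", ["raised-cosine", "triangular"])
    def test_pulse_shapes_peak_and_support(self, shape):
        rhythm = RhythmParams(pulse_shape=shape)
        t = np.arange(-200.0, 200.0, 0.5)
        p = pulse_train(t, rhythm, phase_offset=0.0)
        assert p.max() == pytest.approx(rhythm.pulse_amplitude)
        assert np.all(p[np.abs(t) >= rhythm.pulse_width / 2] == 0)

    def test_zero_amplitude_noise_off_is_exact_line(self):
        rhythm = RhythmParams(pulse_amplitude=0.0)
        trace, clean = generate_trace(rhythm, NOISE_OFF, T=1000.0, dt=5.0, seed=0)
        expected = 300.0 + 0.1 * trace.times
        np.testing.assert_array_equal(trace.masses, expected)
        np.testing.assert_array_equal(clean.masses, expected)

    def test_clean_minus_background_is_pulse_train(self):
        rhythm = RhythmParams()
        gn = GrowthNoiseParams()
        _, clean = generate_trace(rhythm, gn, T=1500.0, dt=5.0, seed=3,
                                  phase_offset=77.0)
        background = gn.initial_mass + gn.growth_rate * clean.times
        np.testing.assert_allclose(clean.masses - background,
                                   pulse_train(clean.times, rhythm, 77.0),
                                   atol=1e-9)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError, match="two rhythm periods"):
            generate_trace(RhythmParams(), NOISE_OFF, T=400.0, dt=5.0)

    def test_nondividing_dt_rejected(self):
        with pytest.raises(ValueError, match="dt must divide"):
            generate_trace(RhythmParams(), NOISE_OFF, T=1001.0, dt=5.0)

    def test_noise_sd_matches_generator_oracle(self):
        # Monte-Carlo oracle: rebuild the expected deviation directly
        # from the noise generators (birth-anchored pink + white) and
        # check the trace deviations reproduce it
        gn = GrowthNoiseParams()
        n = 201
        oracle_rng = np.random.default_rng(12345)
        oracle_sq = []
        for _ in range(150):
            p = synthetic.pink_noise(n, 5.0, gn.pink_noise_rms, oracle_rng,
                                     gn.pink_noise_exponent)
            p = p - p[0]
            w = gn.measurement_noise_sd * oracle_rng.standard_normal(n)
            oracle_sq.append(np.mean((p + w) ** 2))
        expected = np.sqrt(np.mean(oracle_sq))
        devs = []
        for seed in range(100):
            trace, clean = generate_trace(RhythmParams(), gn, T=1000.0,
                                          dt=5.0, seed=seed)
            devs.append(trace.masses - clean.masses)
        sd = np.sqrt(np.mean(np.concatenate(devs) ** 2))
        assert abs(sd - expected) / expected < 0.15


class TestPinkNoise:
    def test_zero_mean(self, rng):
        x = pink_noise(512, 5.0, 100.0, rng, exponent=2.0)
        se = x.std() / np.sqrt(np.sum(np.abs(np.fft.rfft(x)) > 0) + 1)
        assert abs(x.mean()) < 1e-9  # mean removed exactly by construction
        assert se >= 0

    @pytest.mark.parametrize("exponent", [1.0, 2.0])
    def test_amplitude_spectrum_slope(self, exponent, rng):
        # mean amplitude spectrum over >= 50 realizations falls as
        # f**(-exponent/2) within +-0.15 over a decade
        n, dt = 1024, 5.0
        freqs = np.fft.rfftfreq(n, dt)
        acc = np.zeros(freqs.size)
        for _ in range(60):
            acc += np.abs(np.fft.rfft(pink_noise(n, dt, 50.0, rng, exponent)))
        f_lo, f_hi = 0.002, 0.02
        sel = (freqs >= f_lo) & (freqs <= f_hi)
        slope = np.polyfit(np.log(freqs[sel]), np.log(acc[sel]), 1)[0]
        assert abs(slope + exponent / 2.0) < 0.15

    def test_ensemble_scale(self, rng):
        sds = [pink_noise(241, 5.0, 100.0, rng, 2.0).std() ** 2
               for _ in range(200)]
        assert abs(np.sqrt(np.mean(sds)) - 100.0) / 100.0 < 0.1


class TestCohort:
    def test_trace_count_and_recorded_durations(self, default_cohort):
        traces, truth = default_cohort
        assert len(traces) == 300
        assert len(truth.cells) == 300
        for tr, cell in zip(traces, truth.cells):
            assert tr.times[-1] - tr.times[0] == pytest.approx(cell.duration)
            assert cell.duration <= 4320.0

    def test_cycle_median_matches_distribution(self):
        cfg = CohortConfig(n_cells=1000, seed=5)
        _, truth = generate_cohort(cfg)
        med = np.median(truth.durations)
        assert abs(med - cfg.cycle_median) / cfg.cycle_median < 0.10

    def test_phase_offsets_circularly_uniform(self, default_cohort):
        # Rayleigh test against the uniform null, brute-force statistic
        _, truth = default_cohort
        theta = 2 * np.pi * truth.phase_offsets / truth.rhythm.period
        n = theta.size
        rbar = np.hypot(np.cos(theta).sum(), np.sin(theta).sum()) / n
        z = n * rbar ** 2
        p = np.exp(-z) * (1 + (2 * z - z ** 2) / (4 * n))
        assert p > 0.01

    def test_bitwise_reproducible(self):
        cfg = CohortConfig(n_cells=20, seed=42)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.masses, tb.masses)


class TestNegativeControls:
    def test_shuffle_preserves_residual_multiset(self, rng):
        trace, _ = generate_trace(RhythmParams(), GrowthNoiseParams(),
                                  T=1000.0, dt=5.0, seed=1)
        shuffled = negative_control(trace, "shuffle", rng)
        t = trace.times
        coef = np.polyfit(t, trace.masses, 1)
        trend = np.polyval(coef, t)
        res_orig = np.sort(trace.masses - trend)
        res_shuf = np.sort(shuffled.masses - trend)
        np.testing.assert_allclose(res_orig, res_shuf, atol=1e-8)

    def test_constant_mode_has_no_trend(self, rng):
        trace, _ = generate_trace(RhythmParams(), GrowthNoiseParams(),
                                  T=2000.0, dt=5.0, seed=2)
        const = negative_control(trace, "constant", rng)
        slope = np.polyfit(const.times, const.masses, 1)[0]
        # slope consistent with zero given 35 pg white noise
        se = 35.0 / (const.times.std() * np.sqrt(const.times.size))
        assert abs(slope) < 4 * se

    def test_unknown_mode_rejected(self, rng):
        trace, _ = generate_trace(RhythmParams(), GrowthNoiseParams(),
                                  T=1000.0, dt=5.0, seed=1)
        with pytest.raises(ValueError):
            negative_control(trace, "bogus", rng)


class TestPhantomsAndHolograms:
    @pytest.mark.parametrize("profile", ["cosine-dome", "uniform-disc"])
    def test_integrated_opd_encodes_mass(self, profile):
        mass, radius, pitch = 400.0, 20.0, 1.67
        peak = synthetic.peak_opd_for_mass(mass, radius, profile)
        opd = phantom_opd((256, 256), [CellPhantom((128, 128), radius, peak,
                                                   profile)], pitch)
        recovered = opd.sum() * pitch ** 2 / ALPHA
        assert abs(recovered - mass) / mass < 0.01

    def test_empty_scene_gives_unit_intensity(self):
        holo = render_hologram([], shape=(64, 64))
        np.testing.assert_allclose(holo.values, 1.0, atol=1e-10)

    def test_hologram_power_conserved(self):
        ph = CellPhantom((128, 128), 15.0, 0.05)
        holo = render_hologram([ph], shape=(256, 256))
        # pure-phase object: object-plane power equals the pixel count
        assert abs(holo.values.sum() / (256 * 256) - 1.0) < 0.005

    def test_hologram_is_shift_invariant(self):
        # the same disc at two positions produces the same local
        # pattern (periodic convolution commutes with shifts)
        a = render_hologram([CellPhantom((64, 64), 10.0, 0.05,
                                         "uniform-disc")],
                            shape=(256, 256)).values
        b = render_hologram([CellPhantom((192, 160), 10.0, 0.05,
                                         "uniform-disc")],
                            shape=(256, 256)).values
        pa = a[64 - 16:64 + 16, 64 - 16:64 + 16]
        pb = b[192 - 16:192 + 16, 160 - 16:160 + 16]
        assert np.max(np.abs(pa - pb)) < 1e-6


class TestScene:
    def test_division_mass_continuity(self, default_scene):
        truth, _ = default_scene
        by_id = {c.cell_id: c for c in truth.cells}
        n_div = 0
        for c in truth.cells:
            if c.parent is None or getattr(c, "is_continuation", False):
                continue
            mother = by_id[c.parent]
            cont = [x for x in truth.cells if x.parent == mother.cell_id
                    and getattr(x, "is_continuation", False)]
            if not cont:
                continue
            n_div += 1
            total = c.initial_mass + cont[0].initial_mass
            m_div = mother.clean_masses[-1]
            assert total == pytest.approx(m_div, rel=1e-9)
            frac = cont[0].initial_mass / m_div
            assert 0.45 <= frac <= 0.55
        assert n_div >= 2

    def test_daughter_appears_within_15_px(self, default_scene):
        truth, _ = default_scene
        by_id = {c.cell_id: c for c in truth.cells}
        for c in truth.cells:
            if c.parent is None or getattr(c, "is_continuation", False):
                continue
            mother = by_id[c.parent]
            d = np.hypot(*(c.positions[0] - mother.positions[-1]))
            assert d <= 15.0 + 1e-9

    def test_trajectories_merge_continuations(self, default_scene):
        truth, _ = default_scene
        pos, frames = synthetic.truth_trajectories(truth)
        for cid in pos:
            assert np.all(np.diff(frames[cid]) == 1)
        n_cont = sum(getattr(c, "is_continuation", False) for c in truth.cells)
        assert len(pos) == len(truth.cells) - n_cont
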