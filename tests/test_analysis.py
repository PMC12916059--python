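"""Spectral and synchronization statistics against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from bgdbs.analysis import (
    FS_HZ, RateSeries, beta_phase, binomial_baseline, corrected_band_power,
    mean_band_frequency, mean_band_power, plv, population_rate, psd_welch,
    spectrogram,
)
from bgdbs.engine import SpikeData


def _series(counts, n_neurons=100, start=0.0):
    return RateSeries(counts=np.asarray(counts), start=start,
                      n_neurons=n_neurons)


def _spikes(times, n=10, duration=6000.0):
    times = np.asarray(times, dtype=float)
    return SpikeData(neuron=np.zeros(times.size, dtype=np.int64),
                     time=times, pop_slices={"X": slice(0, n)},
                     duration=duration)


class TestPopulationRate:
    def test_no_spikes_all_zero(self):
        rs = population_rate(_spikes([]), "X", (2000, 6000))
        assert rs.counts.sum() == 0
        assert rs.counts.size == 4000

    def test_single_spike_lands_in_its_bin(self):
        rs = population_rate(_spikes([2500.3]), "X", (2000, 6000))
        assert rs.counts[500] == 1
        assert rs.counts.sum() == 1

    def test_counts_conserve_spikes(self, rng):
        times = rng.uniform(2000, 6000, size=500)
        rs = population_rate(_spikes(times), "X", (2000, 6000))
        assert rs.counts.sum() == 500

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            population_rate(_spikes([]), "X", (3000, 3000))


class TestWelch:
    def test_peak_at_injected_frequency(self):
        t = np.arange(4000) / FS_HZ
        x = 50 + 10 * np.sin(2 * np.pi * 20 * t)
        psd = psd_welch(_series(x))
        assert psd.frequencies[np.argmax(psd.power[1:]) + 1] == pytest.approx(
            20.0, abs=0.5)

    def test_frequency_grid(self):
        psd = psd_welch(_series(np.random.default_rng(0).poisson(5, 4000)))
        assert psd.frequencies[0] == 0.0
        assert psd.frequencies[-1] == 500.0
        assert np.allclose(np.diff(psd.frequencies), 0.5)

    def test_white_noise_flat_across_bands(self, rng):
        x = rng.poisson(40, size=60000)
        psd = psd_welch(_series(x))
        low = mean_band_power(psd, 10, 100)
        high = mean_band_power(psd, 200, 400)
        assert low == pytest.approx(high, rel=0.1)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            psd_welch(_series(np.zeros(1000)))


class TestBandPower:
    def test_constant_psd_mean_is_constant(self):
        from bgdbs.analysis import PSD
        f = np.arange(0, 501, 0.5)
        psd = PSD(frequencies=f, power=np.full(f.size, 3.0))
        assert mean_band_power(psd, 12, 30) == pytest.approx(3.0)

    def test_linearity(self, rng):
        x = rng.poisson(20, 4000).astype(float)
        p1 = psd_welch(_series(x))
        from bgdbs.analysis import PSD
        p2 = PSD(frequencies=p1.frequencies, power=2 * p1.power)
        assert mean_band_power(p2, 12, 30) == pytest.approx(
            2 * mean_band_power(p1, 12, 30))

    def test_invalid_band_rejected(self):
        psd = psd_welch(_series(np.random.default_rng(1).poisson(5, 4000)))
        with pytest.raises(ValueError):
            mean_band_power(psd, 30, 12)


class TestBinomialBaseline:
    def test_zero_rate_zero_baseline(self, rng):
        assert binomial_baseline(100, 0.0, 4000, rng) == 0.0

    def test_matches_analytic_white_level(self, rng):
        # i.i.d. binomial counts: one-sided PSD level 2 N v0 (1-v0) / fs
        n, v0 = 200, 0.02
        q = binomial_baseline(n, v0, 4000, rng, reps=40)
        analytic = 2 * n * v0 * (1 - v0) / FS_HZ
        assert q == pytest.approx(analytic, rel=0.05)

    def test_probability_above_one_rejected(self, rng):
        with pytest.raises(ValueError):
            binomial_baseline(10, 1.5, 4000, rng)

    def test_self_correction_near_zero(self, rng):
        # 60 s of signal: the single-draw band-power estimate then has a
        # ~1.5% relative SD, well below the 5% check
        counts = rng.binomial(200, 0.02, size=60000)
        bp = corrected_band_power(_series(counts, n_neurons=200), rng=rng)
        assert abs(bp.corrected) < 0.05 * bp.mean_power

    def test_corrected_grows_with_modulation_depth(self, rng):
        t = np.arange(4000) / FS_HZ
        vals = []
        for depth in (0.0, 0.3, 0.6):
            p = 0.02 * (1 + depth * np.sin(2 * np.pi * 20 * t))
            counts = rng.binomial(200, p)
            bp = corrected_band_power(_series(counts, n_neurons=200),
                                      rng=rng)
            vals.append(bp.corrected)
        assert vals[0] < vals[1] < vals[2]


class TestCentroid:
    def test_flat_spectrum_centroid_is_midband(self):
        from bgdbs.analysis import PSD
        f = np.arange(0, 501, 0.5)
        psd = PSD(frequencies=f, power=np.ones(f.size))
        assert mean_band_frequency(psd, 12, 30) == pytest.approx(21.0)

    def test_narrow_peak_centroid(self):
        from bgdbs.analysis import PSD
        f = np.arange(0, 501, 0.5)
        power = np.zeros(f.size)
        power[f == 18.0] = 5.0
        psd = PSD(frequencies=f, power=power)
        assert mean_band_frequency(psd, 12, 30) == pytest.approx(18.0,
                                                                 abs=0.3)

    def test_symmetric_double_peak(self):
        from bgdbs.analysis import PSD
        f = np.arange(0, 501, 0.5)
        power = np.zeros(f.size)
        power[f == 15.0] = 4.0
        power[f == 27.0] = 4.0
        psd = PSD(frequencies=f, power=power)
        assert mean_band_frequency(psd, 12, 30) == pytest.approx(21.0,
                                                                 abs=0.2)

    def test_zero_band_power_rejected(self):
        from bgdbs.analysis import PSD
        f = np.arange(0, 501, 0.5)
        psd = PSD(frequencies=f, power=np.zeros(f.size))
        with pytest.raises(ValueError):
            mean_band_frequency(psd, 12, 30)


class TestPhaseAndPLV:
    def test_phase_advances_at_signal_frequency(self):
        t = np.arange(4000) / FS_HZ
        x = np.sin(2 * np.pi * 20 * t)
        ph = np.unwrap(beta_phase(x))
        slope = np.polyfit(t[500:-500], ph[500:-500], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 20, rel=0.01)

    def test_identical_series_lock_perfectly(self):
        t = np.arange(4000) / FS_HZ
        x = np.sin(2 * np.pi * 19 * t)
        assert plv(beta_phase(x), beta_phase(x)) == pytest.approx(1.0)

    def test_fixed_lag_gives_constant_offset(self):
        t = np.arange(4000) / FS_HZ
        lag = 0.005
        a = beta_phase(np.sin(2 * np.pi * 20 * t))
        b = beta_phase(np.sin(2 * np.pi * 20 * (t - lag)))
        diff = np.angle(np.exp(1j * (a - b)))[500:-500]
        assert np.std(diff) < 0.05
        assert np.abs(diff.mean()) == pytest.approx(2 * np.pi * 20 * lag,
                                                    abs=0.05)

    def test_independent_phases_decay_as_root_n(self, rng):
        # Rayleigh: E|mean resultant| ~ sqrt(pi)/(2 sqrt(n))
        for n in (1000, 16000):
            vals = [plv(rng.uniform(0, 2 * np.pi, n),
                        rng.uniform(0, 2 * np.pi, n)) for _ in range(30)]
            assert np.mean(vals) == pytest.approx(
                np.sqrt(np.pi) / 2 / np.sqrt(n), rel=0.4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(10), np.zeros(11))

    @settings(max_examples=30, deadline=None)
    @given(phases=hnp.arrays(np.float64, st.integers(2, 300),
                             elements=st.floats(0, 2 * np.pi)),
           shift=st.floats(-10, 10))
    def test_plv_bounded_and_shift_invariant(self, phases, shift):
        other = phases[::-1].copy()
        v = plv(phases, other)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert plv(phases + shift, other + shift) == pytest.approx(v,
                                                                   abs=1e-9)


class TestSpectrogram:
    def test_stationary_ridge(self):
        t = np.arange(6000) / FS_HZ
        x = 20 + 5 * np.sin(2 * np.pi * 20 * t)
        f, times, p = spectrogram(_series(x))
        ridge = f[np.argmax(p, axis=0)]
        assert np.allclose(ridge, 20.0, atol=1.0)

    def test_chirp_ridge_is_monotone(self):
        from scipy.signal import chirp
        t = np.arange(8000) / FS_HZ
        x = 20 + 5 * chirp(t, f0=15, f1=25, t1=t[-1])
        f, times, p = spectrogram(_series(x))
        ridge = f[np.argmax(p, axis=0)]
        assert ridge[-1] > ridge[0]
        assert np.all(np.diff(ridge) > -2.0)
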