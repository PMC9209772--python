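import numpy as np
import pytest
from scipy.signal import periodogram

from semgnet.io import Recording
from semgnet.preprocessing import (
    ButterworthSpec,
    NotchSpec,
    apply_exact_highpass,
    apply_filters,
    design_highpass,
    design_notch,
    highpass_magnitude,
    normalize_channels,
    rectify,
    segment_windows,
)


def tone(freq, fs=1000.0, seconds=5.0):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def band_power(x, fs, freq, half_width=2.0):
    f, p = periodogram(x, fs=fs)
    sel = np.abs(f - freq) <= half_width
    return p[sel].sum()


class TestNotch:
    def test_minimum_at_line_frequency(self):
        design = design_notch(NotchSpec(omega0=50.0, q=30.0, fs=1000.0))
        grid = np.arange(0.1, 500.0, 0.1)
        mag = design.magnitude(grid)
        assert grid[np.argmin(mag)] == pytest.approx(50.0, abs=0.1)

    def test_unity_gain_at_dc(self):
        design = design_notch(NotchSpec())
        assert design.magnitude(np.array([0.0]))[0] == pytest.approx(1.0, rel=0.01)

    def test_tone_attenuation(self):
        """A 50 Hz tone loses >=99% of its power; a 150 Hz tone <5%."""
        design = design_notch(NotchSpec())
        fs = 1000.0
        for freq, check in ((50.0, lambda r: r <= 0.01), (150.0, lambda r: r >= 0.95)):
            x = tone(freq, fs)
            y = design.apply(x)[2000:]  # discard the settling transient
            ratio = band_power(y, fs, freq) / band_power(x[2000:], fs, freq)
            assert check(ratio), f"{freq} Hz power ratio {ratio}"

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            design_notch(NotchSpec(omega0=600.0, fs=1000.0))


class TestHighpass:
    spec = ButterworthSpec(order_n=3, cutoff_hz=20.0, epsilon=1.0, fs=1000.0)

    def test_cutoff_gain_is_minus_3dB(self):
        design = design_highpass(self.spec)
        g = design.magnitude(np.array([20.0]))[0]
        assert 20 * np.log10(g) == pytest.approx(-3.0103, abs=0.02)

    def test_dc_null(self):
        design = design_highpass(self.spec)
        assert design.magnitude(np.array([1e-9]))[0] < 1e-10
        assert highpass_magnitude(self.spec, np.array([0.0]))[0] == 0.0

    def test_stopband_slope_18dB_per_octave(self):
        """Deep-stopband roll-off of the causal filter: 6N = 18 dB/octave."""
        design = design_highpass(self.spec)
        g5, g10 = design.magnitude(np.array([5.0, 10.0]))
        slope = 20 * np.log10(g10 / g5)
        assert slope == pytest.approx(18.0, abs=0.5)

    def test_exact_realization_matches_closed_form(self):
        """Measured response of the exact-magnitude filter reproduces
        |H|² = 1/(1+ε²(Ωc/Ω)^2N) within 1% over 1-400 Hz."""
        n = 8192
        imp = np.zeros(n)
        imp[0] = 1.0
        h = np.abs(np.fft.rfft(apply_exact_highpass(imp, self.spec)))
        freqs = np.fft.rfftfreq(n, d=1.0 / self.spec.fs)
        sel = (freqs >= 1.0) & (freqs <= 400.0)
        ideal = highpass_magnitude(self.spec, freqs[sel])
        rel = np.abs(h[sel] - ideal) / ideal
        assert rel.max() < 0.01

    def test_epsilon_scales_cutoff_gain(self):
        spec = ButterworthSpec(order_n=3, cutoff_hz=20.0, epsilon=0.5, fs=1000.0)
        design = design_highpass(spec)
        expected = 1.0 / np.sqrt(1 + 0.5**2)
        assert design.magnitude(np.array([20.0]))[0] == pytest.approx(expected, rel=1e-3)


def make_rec(semg, fs=1000.0):
    semg = np.atleast_2d(semg).T if semg.ndim == 1 else semg
    return Recording(semg=semg, acc=np.zeros((semg.shape[0], 3)), fs=fs)


class TestApplyFilters:
    def test_zero_in_zero_out(self):
        rec = make_rec(np.zeros((1000, 2)))
        out = apply_filters(rec)
        assert np.all(out.semg == 0)

    def test_dc_offset_removed(self):
        rec = make_rec(np.full((3000, 1), 5.0))
        out = apply_filters(rec)
        assert np.abs(out.semg[2000:]).max() < 1e-3

    def test_mixture_keeps_120Hz_removes_50Hz(self):
        fs = 1000.0
        x = tone(50, fs) + tone(120, fs)
        rec = make_rec(x)
        out = apply_filters(rec)
        y = out.semg[:, 0][2000:]
        x_late = x[2000:]
        assert band_power(y, fs, 50) / band_power(x_late, fs, 50) <= 0.01
        assert band_power(y, fs, 120) / band_power(x_late, fs, 120) == pytest.approx(
            1.0, abs=0.05
        )

    def test_linearity(self, rng):
        a = rng.standard_normal((800, 2))
        b = rng.standard_normal((800, 2))
        lhs = apply_filters(make_rec(2.0 * a - 3.0 * b)).semg
        rhs = 2.0 * apply_filters(make_rec(a)).semg - 3.0 * apply_filters(make_rec(b)).semg
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_acc_untouched(self, rng):
        rec = Recording(semg=rng.standard_normal((500, 2)),
                        acc=rng.standard_normal((500, 3)), fs=1000.0)
        out = apply_filters(rec)
        np.testing.assert_array_equal(out.acc, rec.acc)
        assert out.n_samples == rec.n_samples


class TestRectify:
    def test_absolute_value_and_idempotence(self, rng):
        rec = make_rec(np.array([[1.0], [-1.0], [2.0]]))
        out = rectify(rec)
        np.testing.assert_array_equal(out.semg[:, 0], [1.0, 1.0, 2.0])
        r = make_rec(rng.standard_normal((100, 3)))
        once = rectify(r)
        twice = rectify(once)
        np.testing.assert_array_equal(once.semg, twice.semg)
        assert once.semg.min() >= 0
        np.testing.assert_array_equal(once.acc, r.acc)


class TestNormalize:
    def test_train_statistics(self, rng):
        segs = [rng.standard_normal((200, 3)) + [1.0, -2.0, 0.5] for _ in range(5)]
        normed, stats = normalize_channels(segs)
        pooled = np.concatenate(normed)
        np.testing.assert_allclose(pooled.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(pooled.std(axis=0), 1.0, atol=1e-12)

    def test_constant_channel_warns_and_zeroes(self):
        segs = [np.full((50, 2), 3.0)]
        with pytest.warns(RuntimeWarning):
            normed, stats = normalize_channels(segs)
        assert np.all(normed[0] == 0.0)
        assert np.all(stats.std == 1.0)

    def test_test_set_uses_train_statistics(self, rng):
        train = [rng.standard_normal((300, 2))]
        shifted = [rng.standard_normal((300, 2)) + 10.0]
        normed, _ = normalize_channels(train, apply_to=shifted)
        # a mean-shifted test set keeps its shift: no leakage of its own stats
        assert np.abs(normed[0].mean(axis=0)).min() > 5.0


class TestWindows:
    def test_window_counts(self):
        x = np.zeros((10_000, 2))
        wins = segment_windows(x, window_ms=200, step_ms=100, fs=1000.0)
        assert len(wins) == 99
        assert all(w.shape == (200, 2) for w in wins)

    def test_single_window_when_exact(self):
        x = np.zeros((200, 1))
        assert len(segment_windows(x, 200, 100, 1000.0)) == 1

    def test_window_longer_than_segment(self):
        with pytest.warns(RuntimeWarning):
            assert segment_windows(np.zeros((50, 1)), 200, 100, 1000.0) == []

    def test_windows_match_source_offsets(self, rng):
        x = rng.standard_normal((1000, 2))
        wins = segment_windows(x, 150, 60, 1000.0)
        for i, w in enumerate(wins):
            np.testing.assert_array_equal(w, x[i * 60 : i * 60 + 150])
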