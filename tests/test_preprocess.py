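import numpy as np
import pytest

from mesomap import (
    ImagingStack,
    bandpass,
    deconvolve,
    dff_event,
    dff_global,
    hemodynamic_correct,
    regress_global_signal,
    roi_power_spectrum,
)
from mesomap.preprocess import estimate_ar_coeffs


def brute_force_dff(stack_data, triggers, fs, window=(-3.0, 3.0), base=(-3.0, 0.0)):
    """Independent per-event loop over pixels (oracle)."""
    pre, post = int(round(window[0] * fs)), int(round(window[1] * fs))
    blo, bhi = int(round(base[0] * fs)), int(round(base[1] * fs))
    out = []
    for f in triggers:
        win = np.empty((post - pre,) + stack_data.shape[1:])
        for r in range(stack_data.shape[1]):
            for c in range(stack_data.shape[2]):
                f0 = stack_data[f + blo:f + bhi, r, c].mean()
                win[:, r, c] = (stack_data[f + pre:f + post, r, c] - f0) / f0
        out.append(win)
    return np.stack(out)


class TestDffEvent:
    def test_constant_stack_zero(self, constant_stack):
        ev = dff_event(constant_stack, np.array([35, 40]), window_s=(-3, 3))
        assert np.allclose(ev.values, 0.0)
        assert ev.n_events == 2

    def test_pixel_doubling_gives_one(self):
        data = np.full((80, 4, 4), 50.0)
        data[40:, 1, 2] = 100.0  # doubles exactly at the trigger frame
        stack = ImagingStack(data, 10.0)
        ev = dff_event(stack, np.array([40]))
        t = ev.window_times
        assert ev.values[0, t >= 0, 1, 2] == pytest.approx(1.0)
        assert np.allclose(ev.values[0, t < 0, 1, 2], 0.0)

    def test_matches_brute_force(self, rng):
        data = 100.0 + rng.random((120, 4, 4)) * 10
        stack = ImagingStack(data, 10.0)
        triggers = np.array([35, 60, 80])
        ev = dff_event(stack, triggers)
        oracle = brute_force_dff(stack.data, triggers, 10.0)
        assert np.allclose(ev.values, oracle, atol=1e-6)

    def test_edge_events_dropped(self, constant_stack):
        ev = dff_event(constant_stack, np.array([0, 35]))
        assert ev.n_events == 1 and ev.n_dropped == 1
        with pytest.raises(ValueError, match="no surviving"):
            dff_event(constant_stack, np.array([0]))

    def test_zero_baseline_named(self):
        data = np.full((80, 2, 2), 10.0)
        data[:, 0, 1] = 0.0
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            dff_event(ImagingStack(data, 10.0), np.array([40]))

    def test_scale_invariance(self, rng):
        data = 100.0 + rng.random((120, 3, 3))
        s1 = ImagingStack(data, 10.0)
        s2 = ImagingStack(data * 7.5, 10.0)
        t = np.array([40, 70])
        assert np.allclose(dff_event(s1, t).values, dff_event(s2, t).values, atol=1e-6)


class TestDffGlobal:
    def test_constant_zero_and_zero_mean(self, constant_stack, rng):
        assert np.allclose(dff_global(constant_stack).data, 0.0)
        stack = ImagingStack(100 + rng.random((50, 3, 3)), 10.0)
        out = dff_global(stack)
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-6)

    def test_equals_event_dff_when_baselines_coincide(self):
        # periodic stack whose mean over any whole number of 10-frame
        # cycles equals the global mean, so the -3..0 s event baseline
        # (30 frames) coincides with the whole-recording baseline
        n = 100
        osc = 20.0 * np.sin(2 * np.pi * np.arange(n) / 10.0)
        data = np.tile((200.0 + osc)[:, None, None], (1, 2, 2))
        stack = ImagingStack(data, 10.0)
        ev = dff_event(stack, np.array([40]))
        glob = dff_global(stack)
        assert np.allclose(ev.values[0], glob.data[10:70], atol=1e-5)


class TestBandpass:
    def test_passband_preserves_1hz(self):
        fs, t = 30.0, np.arange(3000) / 30.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = bandpass(x, 0.3, 3.0, fs=fs)
        mid = slice(500, 2500)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_dc_rejected(self):
        y = bandpass(np.full(1000, 5.0), 0.3, 3.0, fs=30.0)
        assert np.abs(y).max() < 5.0 * 1e-2  # > 40 dB down

    def test_stopband_attenuates_10hz(self):
        fs, t = 30.0, np.arange(3000) / 30.0
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, 0.3, 3.0, fs=fs)
        assert np.abs(y[500:2500]).max() < 0.1

    def test_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 0.3, 20.0, fs=30.0)


class TestGlobalSignalRegression:
    def test_identical_traces_removed(self, rng):
        trace = rng.standard_normal(200)
        data = np.tile(trace[:, None, None], (1, 4, 4))
        out = regress_global_signal(ImagingStack(data, 10.0))
        assert np.abs(out.data - out.data.mean()).max() < 1e-4

    def test_orthogonal_pixel_unchanged(self):
        t = np.arange(400) / 10.0
        g = np.sin(2 * np.pi * 0.5 * t)
        orth = np.cos(2 * np.pi * 0.5 * t)  # orthogonal to g over whole cycles
        # four pixels constructed so the global mean trace is exactly g
        # while one pixel carries only the orthogonal component
        data = np.stack([g + orth, g - orth, orth, 2 * g - orth], axis=1).reshape(400, 2, 2)
        out = regress_global_signal(ImagingStack(data, 10.0))
        assert np.allclose(out.data.reshape(400, 4)[:, 2], orth, atol=1e-4)

    def test_two_pixel_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        data = np.stack([np.stack([x, 2 * x], axis=1)[:, :, None]])[0]  # 4x2x1
        stack = ImagingStack(data.reshape(4, 2, 1), 10.0)
        out = regress_global_signal(stack)
        g = data.reshape(4, 2).mean(axis=1)
        gc = g - g.mean()
        for j, px in enumerate([x, 2 * x]):
            beta = (gc @ px) / (gc @ gc)
            assert np.allclose(out.data[:, j, 0], px - beta * gc, atol=1e-5)


class TestHemodynamicCorrect:
    def test_common_mode_cancels_exactly(self, rng):
        common = 1.0 + 0.05 * np.sin(np.arange(100) / 5.0)
        green = ImagingStack(200.0 * common[:, None, None] * np.ones((1, 4, 4)), 10.0)
        blue = ImagingStack(90.0 * common[:, None, None] * np.ones((1, 4, 4)), 10.0,
                            channel="blue_reflectance")
        out = hemodynamic_correct(green, blue)
        assert np.abs(out.data).max() < 1e-6

    def test_constant_blue_neutral(self, rng):
        gdata = 100.0 + rng.random((50, 3, 3))
        green = ImagingStack(gdata, 10.0)
        blue = ImagingStack(np.full((50, 3, 3), 80.0), 10.0, channel="blue_reflectance")
        out = hemodynamic_correct(green, blue)
        f0 = gdata.mean(axis=0)
        assert np.allclose(out.data, (gdata - f0) / f0, atol=1e-6)

    def test_artifact_power_removed(self, small_session):
        green, blue = small_session["green"], small_session["blue"]
        h = small_session["truth"].hemo_trace
        corrected = hemodynamic_correct(green, blue)
        dff = dff_global(green)

        def artifact_power(stack):
            x = stack.data.reshape(stack.n_frames, -1).mean(axis=1)
            hc = (h - h.mean()) / np.linalg.norm(h - h.mean())
            return float((x @ hc) ** 2)

        assert artifact_power(corrected) < 0.1 * artifact_power(dff)


class TestDeconvolve:
    def test_exact_ar1_impulse_inversion(self):
        g = 0.9
        n = 200
        c = np.zeros(n)
        c[50] = 1.0
        for i in range(51, n):
            c[i] = g * c[i - 1]
        s, resid = deconvolve(c, np.array([g]))
        assert np.argmax(s) == 50
        nonzero = np.where(s > 1e-12)[0]
        assert nonzero.tolist() == [50]
        assert resid < 1e-12

    def test_zero_trace(self):
        s, resid = deconvolve(np.zeros(100), np.array([0.8]))
        assert np.all(s == 0) and resid == 0

    def test_two_events_recovered(self):
        g = 0.85
        n = 300
        c = np.zeros(n)
        for start, amp in [(60, 1.0), (200, 0.5)]:
            imp = amp * g ** np.arange(n - start)
            c[start:] += imp
        s, _ = deconvolve(c, np.array([g]))
        peaks = np.where(s > 1e-6)[0]
        assert peaks.tolist() == [60, 200]

    def test_unstable_coeffs_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            deconvolve(np.ones(50), np.array([1.01]))

    def test_auto_ar_estimate_close(self, rng):
        g = 0.9
        n = 5000
        s_true = (rng.random(n) < 0.02).astype(float)
        from scipy.signal import lfilter

        c = lfilter([1.0], [1.0, -g], s_true)
        ghat = estimate_ar_coeffs(c, order=1)[0]
        assert ghat == pytest.approx(g, abs=0.05)


class TestPowerSpectrum:
    def test_sinusoid_peak_bin(self):
        fs, n = 20.0, 400
        t = np.arange(n) / fs
        out = roi_power_spectrum(np.sin(2 * np.pi * 2.0 * t), fs)
        peak_freq = out["frequency_hz"][np.argmax(out["amplitude"])]
        assert peak_freq == pytest.approx(2.0, abs=0.1)
        assert out["amplitude"].max() == pytest.approx(1.0, rel=0.05)

    def test_parseval(self, rng):
        fs, n = 30.0, 512
        x = rng.standard_normal(n)
        out = roi_power_spectrum(x, fs)
        amp = out["amplitude"]
        # one-sided amplitudes: power = A0^2 + sum A_k^2/2 (+ Nyquist fix)
        power = amp[0] ** 2 + (amp[1:-1] ** 2).sum() / 2 + amp[-1] ** 2
        assert power == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_sem_across_traces(self, rng):
        x = rng.standard_normal((5, 256))
        out = roi_power_spectrum(x, 30.0)
        assert out["sem"].shape == out["amplitude"].shape
        assert np.all(out["sem"] >= 0) and out["sem"].max() > 0
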