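"""Preprocessing-chain oracles: optical-density conversion against a literal
double loop, Beer-Lambert round trips, Butterworth response, epoching,
baseline correction, the 256-sample analysis window and ROI selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from fnirsda import preprocess as pp


def make_raw(rng, n_ch=2, n_samp=400, fs=10.0, events=()):
    intensity = rng.uniform(0.5, 2.0, size=(2, n_ch, n_samp))
    return pp.RawRecording(intensity=intensity, wavelengths=(760.0, 850.0),
                           fs=fs, events=list(events), subject_id="S01")


class TestIntensityToOd:
    def test_constant_intensity_gives_zero(self, rng):
        raw = make_raw(rng)
        raw.intensity[:] = 1.7
        od = pp.intensity_to_od(raw)
        assert np.allclose(od.dOD, 0.0, atol=1e-15)

    def test_halved_intensity_gives_log10_two(self, rng):
        raw = make_raw(rng, n_samp=4)
        raw.intensity[:] = 1.0
        raw.intensity[:, :, 2] = 0.5
        od = pp.intensity_to_od(raw, reference="first_sample")
        assert np.allclose(od.dOD[:, :, 2], np.log10(2.0), rtol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        raw = make_raw(rng, n_ch=3, n_samp=20)
        od = pp.intensity_to_od(raw, reference="mean")
        for w in range(2):
            for c in range(3):
                ref_i = raw.intensity[w, c].mean()
                for t in range(20):
                    expected = -np.log10(raw.intensity[w, c, t] / ref_i)
                    assert od.dOD[w, c, t] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_intensity_rejected_with_location(self, rng):
        raw = make_raw(rng)
        bad = raw.intensity.copy()
        bad[1, 0, 7] = -0.1
        with pytest.raises(ValueError, match=r"wavelength 1, channel 0, sample 7"):
            pp.RawRecording(intensity=bad, wavelengths=(760.0, 850.0), fs=10.0,
                            events=[], subject_id="S01")


class TestMbll:
    def test_zero_od_gives_zero_concentration(self):
        od = pp.OpticalDensityChange(dOD=np.zeros((2, 3, 10)), fs=10.0, events=[])
        hemo = pp.mbll(od)
        assert np.allclose(hemo.dHbO, 0.0) and np.allclose(hemo.dHbR, 0.0)

    def test_forward_round_trip(self):
        cfg = pp.MbllConfig(d=3.0, dpf=(6.0, 6.0),
                            eps=np.array([[1486.6, 3843.7], [2526.4, 1798.6]]))
        dhbo = np.full((2, 5), 1e-6)
        dhbr = np.full((2, 5), -5e-7)
        dod = pp.mbll_forward(dhbo, dhbr, cfg)
        hemo = pp.mbll(pp.OpticalDensityChange(dOD=dod, fs=10.0, events=[]), cfg)
        assert np.allclose(hemo.dHbO, dhbo, rtol=1e-12)
        assert np.allclose(hemo.dHbR, dhbr, rtol=1e-12)

    @given(st.floats(0.5, 5.0), st.floats(3.0, 8.0), st.floats(3.0, 8.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_round_trip_property(self, d, dpf1, dpf2):
        cfg = pp.MbllConfig(d=d, dpf=(dpf1, dpf2))
        r = np.random.default_rng(0)
        dhbo = r.standard_normal((3, 7)) * 1e-6
        dhbr = r.standard_normal((3, 7)) * 1e-6
        dod = pp.mbll_forward(dhbo, dhbr, cfg)
        hemo = pp.mbll(pp.OpticalDensityChange(dOD=dod, fs=10.0, events=[]), cfg)
        assert np.allclose(hemo.dHbO, dhbo, rtol=1e-10, atol=1e-18)
        assert np.allclose(hemo.dHbR, dhbr, rtol=1e-10, atol=1e-18)

    def test_doubling_distance_halves_output(self, rng):
        dod = rng.standard_normal((2, 2, 6)) * 0.01
        od = pp.OpticalDensityChange(dOD=dod, fs=10.0, events=[])
        h1 = pp.mbll(od, pp.MbllConfig(d=3.0))
        h2 = pp.mbll(od, pp.MbllConfig(d=6.0))
        assert np.allclose(h2.dHbO, h1.dHbO / 2, rtol=1e-12)

    def test_singular_eps_rejected(self):
        with pytest.raises(ValueError, match="eps"):
            pp.MbllConfig(eps=np.array([[1.0, 2.0], [2.0, 4.0]]))


class TestBandpass:
    def test_zero_in_zero_out(self):
        sig = pp.HemoSignal(dHbO=np.zeros((2, 500)), dHbR=np.zeros((2, 500)),
                            fs=10.0, events=[])
        out = pp.bandpass(sig)
        assert np.allclose(out.dHbO, 0.0)

    def test_midband_sinusoid_preserved(self):
        fs, dur = 10.0, 1000.0
        t = np.arange(0, dur, 1 / fs)
        x = np.sin(2 * np.pi * 0.05 * t)
        sig = pp.HemoSignal(dHbO=x[None, :], dHbR=x[None, :], fs=fs, events=[])
        out = pp.bandpass(sig).dHbO[0]
        steady = out[len(out) // 4: -len(out) // 4]
        assert np.abs(steady).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_sinusoid_attenuated(self):
        # amplitude of the 1 Hz component measured by demodulation over the
        # steady-state middle (a raw max would be dominated by the slowly
        # decaying 0.01 Hz edge transients, not the probe)
        fs = 10.0
        t = np.arange(0, 600, 1 / fs)
        x = np.sin(2 * np.pi * 1.0 * t)
        sig = pp.HemoSignal(dHbO=x[None, :], dHbR=x[None, :], fs=fs, events=[])
        out = pp.bandpass(sig).dHbO[0]
        n = len(out)
        mid = slice(n // 4, -n // 4)
        phasor = np.exp(-2j * np.pi * 1.0 * t[mid])
        amp = 2.0 * np.abs((out[mid] * phasor).mean())
        assert amp < 1e-3

    def test_linearity(self, rng):
        x = rng.standard_normal((2, 300))
        y = rng.standard_normal((2, 300))
        mk = lambda d: pp.HemoSignal(dHbO=d, dHbR=d, fs=10.0, events=[])
        f = lambda d: pp.bandpass(mk(d)).dHbO
        assert np.allclose(f(2.0 * x + 0.5 * y), 2.0 * f(x) + 0.5 * f(y),
                           rtol=1e-9, atol=1e-12)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            pp.FilterConfig(band=(0.01, 6.0)).sos(10.0)

    def test_minus_3db_points_near_band_edges(self):
        sos = pp.FilterConfig().sos(10.0)
        w, h = sps.sosfreqz(sos, worN=2 ** 18, fs=10.0)
        mag = np.abs(h)
        above = mag >= 1 / np.sqrt(2)
        lo, hi = w[above][0], w[above][-1]
        assert lo == pytest.approx(0.01, rel=0.05)
        assert hi == pytest.approx(0.1, rel=0.05)


def make_hemo(rng, n_ch=20, n_samp=2000, fs=10.0, events=None):
    events = events if events is not None else [(500, "left"), (900, "right"),
                                                (1300, "feet")]
    return pp.HemoSignal(dHbO=rng.standard_normal((n_ch, n_samp)),
                         dHbR=rng.standard_normal((n_ch, n_samp)), fs=fs,
                         events=events, subject_id="S01")


class TestEpoch:
    def test_counts_and_length(self, rng):
        sig = make_hemo(rng)
        trials = pp.epoch(sig)
        assert len(trials) == 3
        assert all(t.data.shape == (40, 300) for t in trials)
        assert all(t.t0_offset == 2.0 for t in trials)

    def test_truncated_event_dropped_and_counted(self, rng):
        report = pp.EpochReport()
        sig = make_hemo(rng, events=[(500, "left"), (1990, "right")])
        trials = pp.epoch(sig, report=report)
        assert len(trials) == 1
        assert report.n_dropped == 1
        assert report.n_epochs + report.n_dropped == report.n_events == 2

    def test_balanced_session(self, rng):
        events = []
        pos = 100
        labels = ["left", "right", "feet"] * 25
        for lab in labels:
            events.append((pos, lab))
            pos += 300
        sig = make_hemo(rng, n_samp=pos + 400, events=events)
        trials = pp.epoch(sig)
        assert len(trials) == 75
        counts = {c: sum(t.class_label == c for t in trials) for c in ("left", "right", "feet")}
        assert counts == {"left": 25, "right": 25, "feet": 25}


class TestBaselineCorrect:
    def test_constant_baseline_subtracted(self, rng):
        data = rng.standard_normal((4, 300))
        data[0] += 5.0
        trial = pp.TrialEpoch(data=data, fs=10.0, t0_offset=2.0, class_label="left")
        base = trial.data[:, 10:20].mean(axis=1, keepdims=True)
        out = pp.baseline_correct(trial)
        assert np.allclose(out.data, trial.data - base, rtol=1e-12)

    def test_zero_mean_baseline_is_identity(self, rng):
        data = rng.standard_normal((2, 300))
        data -= data[:, 10:20].mean(axis=1, keepdims=True)
        trial = pp.TrialEpoch(data=data, fs=10.0, t0_offset=2.0, class_label="left")
        assert np.allclose(pp.baseline_correct(trial).data, data, atol=1e-12)

    def test_output_baseline_mean_is_zero(self, rng):
        trial = pp.TrialEpoch(data=rng.standard_normal((6, 300)), fs=10.0,
                              t0_offset=2.0, class_label="feet")
        out = pp.baseline_correct(trial)
        assert np.allclose(out.data[:, 10:20].mean(axis=1), 0.0, atol=1e-12)

    def test_empty_window_rejected(self, rng):
        trial = pp.TrialEpoch(data=rng.standard_normal((2, 300)), fs=10.0,
                              t0_offset=2.0, class_label="left")
        with pytest.raises(ValueError):
            pp.baseline_correct(trial, window=(-5.0, -4.0))


class TestCropWindow:
    def test_default_window_length_256(self, rng):
        trial = pp.TrialEpoch(data=rng.standard_normal((4, 300)), fs=10.0,
                              t0_offset=2.0, class_label="left")
        out = pp.crop_window(trial)
        assert out.data.shape == (4, 256)
        assert np.array_equal(out.data[:, 0], trial.data[:, 20])

    def test_full_range_is_identity(self, rng):
        trial = pp.TrialEpoch(data=rng.standard_normal((4, 300)), fs=10.0,
                              t0_offset=2.0, class_label="left")
        assert np.array_equal(pp.crop_window(trial, 0, 300).data, trial.data)

    def test_short_epoch_rejected(self, rng):
        trial = pp.TrialEpoch(data=rng.standard_normal((4, 100)), fs=10.0,
                              t0_offset=2.0, class_label="left")
        with pytest.raises(ValueError, match="100"):
            pp.crop_window(trial)


class TestSelectRoi:
    @pytest.mark.parametrize("name,channels,count", [
        ("A", (1, 2, 3, 4, 11, 12, 13, 14), 8),
        ("B", (5, 6, 15, 16), 4),
        ("C", (4, 5, 6, 7, 14, 15, 16, 17), 8),
        ("D", (8, 9, 18, 19), 4),
        ("E", (7, 8, 9, 10, 17, 18, 19, 20), 8),
    ])
    def test_roi_channel_sets(self, rng, name, channels, count):
        spec = pp.RoiSpec.from_name(name)
        assert spec.channels == channels and len(spec.channels) == count
        trial = pp.TrialEpoch(data=rng.standard_normal((40, 30)), fs=10.0,
                              t0_offset=2.0, class_label="left")
        out = pp.select_roi(trial, name)
        assert out.data.shape == (2 * count, 30)
        idx = np.array(channels) - 1
        assert np.array_equal(out.data, trial.data[np.concatenate([idx, idx + 20])])

    def test_full_roi_is_identity(self, rng):
        trial = pp.TrialEpoch(data=rng.standard_normal((40, 30)), fs=10.0,
                              t0_offset=2.0, class_label="left")
        assert np.array_equal(pp.select_roi(trial, "FULL").data, trial.data)

    def test_unknown_roi_lists_valid_names(self):
        with pytest.raises(ValueError, match="A"):
            pp.RoiSpec.from_name("Z")

    def test_roi_commutes_with_crop(self, rng):
        trial = pp.TrialEpoch(data=rng.standard_normal((40, 300)), fs=10.0,
                              t0_offset=2.0, class_label="left")
        a = pp.crop_window(pp.select_roi(trial, "C"))
        b = pp.select_roi(pp.crop_window(trial), "C")
        assert np.array_equal(a.data, b.data)


def test_full_chain_shape_contract(rng):
    """Every trial emerging from the raw-intensity chain is 40 x 256."""
    events = [(400, "left"), (800, "right"), (1200, "feet")]
    intensity = rng.uniform(0.9, 1.1, size=(2, 20, 1600))
    raw = pp.RawRecording(intensity=intensity, wavelengths=(760.0, 850.0),
                          fs=10.0, events=events, subject_id="S01")
    trials = pp.preprocess_recording(raw)
    assert len(trials) == 3
    assert all(t.data.shape == (40, 256) for t in trials)
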