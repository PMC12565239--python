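"""Filter contracts (pass-band fidelity, stop-band attenuation), framing."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from readeog import (FilterSpec, TextSpec, bandpass, baseline_correct, notch,
                     segment_frames, simulate_recording, tdc_preset)
from readeog.preprocess import BandpassFilter


def tone(freq, fs, duration):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestBandpass:
    def test_zero_vector_maps_to_zero(self):
        assert np.allclose(bandpass(np.zeros(500), 100.0), 0.0)

    def test_inband_tone_preserved(self):
        """A 2 Hz tone sits well inside 0.1-10 Hz; central amplitude is
        preserved within 5%, as predicted by the design's response."""
        x = tone(2.0, 100.0, 60.0)
        y = bandpass(x, 100.0)
        core = slice(1000, -1000)  # skip edge transients
        assert rms(y[core]) == pytest.approx(rms(x[core]), rel=0.05)
        # frequency-response oracle for the same design
        sos = sps.butter(4, [0.1, 10.0], btype="bandpass", fs=100.0, output="sos")
        w, h = sps.sosfreqz(sos, worN=[2.0], fs=100.0)
        assert abs(h[0]) ** 2 == pytest.approx(1.0, abs=0.05)  # filtfilt doubles response

    def test_subband_drift_removed(self):
        """0.01 Hz drift of amplitude 10 over 100 s leaves residual < 1."""
        x = 10.0 * tone(0.01, 100.0, 100.0)
        y = bandpass(x, 100.0)
        assert np.max(np.abs(y[500:-500])) < 1.0

    def test_mains_attenuation_at_least_40_db(self):
        """Stop-band oracle: the default design attenuates 50 Hz by >= 40 dB
        (evaluated on the response; 50 Hz must be below Nyquist)."""
        sos = sps.butter(4, [0.1, 10.0], btype="bandpass", fs=256.0, output="sos")
        w, h = sps.sosfreqz(sos, worN=[50.0], fs=256.0)
        atten_db = -20 * np.log10(abs(h[0]) ** 2)  # squared: forward-backward
        assert atten_db >= 40.0

    def test_passband_idempotence(self):
        """Double application changes in-band RMS of a 2 Hz tone by < 5%."""
        x = tone(2.0, 100.0, 60.0)
        once = bandpass(x, 100.0)
        twice = bandpass(once, 100.0)
        core = slice(1000, -1000)
        assert rms(twice[core]) == pytest.approx(rms(once[core]), rel=0.05)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass(np.zeros(10), 100.0)

    def test_transformer_matches_function(self):
        x = tone(1.0, 100.0, 30.0)
        est = BandpassFilter(fs=100.0).fit(x[None])
        np.testing.assert_allclose(est.transform(x[None])[0], bandpass(x, 100.0))


class TestNotch:
    def test_zero_vector(self):
        assert np.allclose(notch(np.zeros(500), 256.0), 0.0)

    def test_passband_unchanged(self):
        x = tone(2.0, 256.0, 30.0)
        y = notch(x, 256.0)
        core = slice(1000, -1000)
        assert rms(y[core]) == pytest.approx(rms(x[core]), rel=0.02)

    def test_mains_suppressed(self):
        x = tone(50.0, 256.0, 30.0)
        y = notch(x, 256.0)
        assert rms(y[1000:-1000]) <= 0.10 * rms(x[1000:-1000])

    def test_notch_at_nyquist_rejected_with_skip_hint(self):
        with pytest.raises(ValueError, match="skip"):
            notch(np.zeros(500), 100.0, notch_hz=50.0)


class TestBaselineCorrect:
    def test_constant_vector(self):
        assert np.allclose(baseline_correct(np.full(10, 3.7)), 0.0)

    def test_small_example(self):
        np.testing.assert_allclose(baseline_correct([1, 2, 3]), [-1, 0, 1])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(-100, 100, allow_nan=False),
           seed=st.integers(0, 2**16))
    def test_shift_invariance(self, offset, seed):
        x = np.random.default_rng(seed).normal(size=64)
        np.testing.assert_allclose(baseline_correct(x + offset),
                                   baseline_correct(x), atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct([])


class TestSegmentFrames:
    @pytest.mark.parametrize("n_samples,n_frames", [(6000, 6), (1234, 1), (999, 0)])
    def test_floor_rule(self, n_samples, n_frames, dys_recording):
        rec = _with_length(dys_recording, n_samples)
        if n_frames == 0:
            with pytest.warns(UserWarning, match="no frames"):
                frames = segment_frames(rec, "horizontal")
        else:
            frames = segment_frames(rec, "horizontal")
        assert len(frames) == n_frames
        if n_frames:
            np.testing.assert_array_equal(frames[0].samples, rec.horizontal[:1000])
            assert frames[0].label == rec.group_label
            assert frames[0].frame_index == 0

    def test_partition_property(self, dys_recording):
        rec = _with_length(dys_recording, 2750)
        frames = segment_frames(rec, "vertical", frame_len=1000)
        cat = np.concatenate([f.samples for f in frames])
        np.testing.assert_array_equal(cat, rec.vertical[:2000])


def _with_length(rec, n):
    """Tile/crop a recording's channels to exactly n samples."""
    from dataclasses import replace

    reps = int(np.ceil(n / len(rec.horizontal)))
    h = np.tile(rec.horizontal, reps)[:n]
    v = np.tile(rec.vertical, reps)[:n]
    return replace(rec, horizontal=h, vertical=v, markers=[0, n])
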