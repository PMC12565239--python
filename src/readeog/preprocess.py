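"""Filtering, baseline correction and fixed-length framing for EOG.

The analysis chain is: a 4th-order Butterworth band-pass (0.1–10 Hz,
the band that contains saccades, fixationd drift and blinks) on both
channels; for blink detection on the vertical channel additionally a
50 Hz notch (only meaningful when the sampling rate puts 50 Hz strictly
below Nyquist) and median baseline correction.  All filters are applied
forward–backward (zero phase) so that event latencies — on which the
blink acceptance window operates — are not shifted.

Frames for scalogram imaging are half-open tiles of 1000 samples
(10 s at 100 Hz); the trailing remainder is dropped rather than padded,
because padding would fabricate signal content in the images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import EogRecording

__all__ = [
    "FilterSpec",
    "SignalFrame",
    "bandpass",
    "notch",
    "baseline_correct",
    "segment_frames",
    "preprocess_recording",
    "BandpassFilter",
    "NotchFilter",
]

DEFAULT_FRAME_LEN = 1000


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one filtering stage."""

    kind: str = "bandpass_butterworth"  # or "notch"
    order: int = 4
    low_hz: float = 0.1
    high_hz: float = 10.0
    notch_hz: float = 50.0
    quality: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass_butterworth", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.kind == "bandpass_butterworth" and not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


@dataclass
class SignalFrame:
    """A fixed-length window of one channel, carrying provenance."""

    samples: np.ndarray
    channel: str
    source_recording: str
    frame_index: int
    label: str


def _as_signal(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample vector")
    return x


def bandpass(x, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass; default 4th order, 0.1–10 Hz."""
    x = _as_signal(x)
    if spec is None:
        spec = FilterSpec()
    if spec.kind != "bandpass_butterworth":
        raise ValueError("bandpass() requires a bandpass_butterworth FilterSpec")
    if fs <= 2 * spec.high_hz:
        raise ValueError(f"sampling rate {fs} Hz too low for high edge {spec.high_hz} Hz")
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=fs, output="sos")
    # sosfiltfilt needs signals longer than its padding length.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= padlen:
        raise ValueError(f"signal of {len(x)} samples shorter than filter warm-up ({padlen})")
    return sps.sosfiltfilt(sos, x)


def notch(x, fs: float, notch_hz: float = 50.0, quality: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch; rejects a narrow band around ``notch_hz``."""
    x = _as_signal(x)
    if notch_hz >= fs / 2:
        raise ValueError(
            f"notch at {notch_hz} Hz is at/above Nyquist for fs={fs} Hz; "
            "skip the notch stage (the mains band is already outside the sampled band)"
        )
    b, a = sps.iirnotch(notch_hz, quality, fs=fs)
    padlen = 3 * max(len(b), len(a))
    if len(x) <= padlen:
        raise ValueError(f"signal of {len(x)} samples shorter than filter warm-up ({padlen})")
    return sps.filtfilt(b, a, x)


def baseline_correct(x) -> np.ndarray:
    """Subtract the signal median so the resting level sits at zero."""
    x = _as_signal(x)
    if len(x) == 0:
        raise ValueError("cannot baseline-correct an empty signal")
    return x - np.median(x)


def segment_frames(
    recording: EogRecording,
    channel: str = "horizontal",
    frame_len: int = DEFAULT_FRAME_LEN,
) -> list[SignalFrame]:
    """Tile one channel into half-open frames of ``frame_len`` samples.

    Frame *i* covers samples ``[i*frame_len, (i+1)*frame_len)``; the
    remainder is dropped.  A signal shorter than one frame yields an
    empty list and a warning.
    """
    if frame_len < 1:
        raise ValueError("frame_len must be >= 1")
    x = recording.channel(channel)
    n_frames = len(x) // frame_len
    if n_frames == 0:
        warnings.warn(
            f"recording {recording.recording_id}: {len(x)} samples < frame_len "
            f"{frame_len}; no frames produced",
            stacklevel=2,
        )
        return []
    return [
        SignalFrame(
            samples=np.asarray(x[i * frame_len:(i + 1) * frame_len], dtype=float),
            channel=channel,
            source_recording=recording.recording_id,
            frame_index=i,
            label=recording.group_label,
        )
        for i in range(n_frames)
    ]


def preprocess_recording(
    rec: EogRecording,
    band: FilterSpec | None = None,
    apply_notch: bool = True,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> EogRecording:
    """Standard chain: band-pass both channels; notch (if representable)
    + baseline-correct the vertical channel for blink detection."""
    h = bandpass(rec.horizontal, rec.sampling_rate, band)
    v = np.asarray(rec.vertical, dtype=float)
    if apply_notch:
        if notch_hz < rec.sampling_rate / 2:
            v = notch(v, rec.sampling_rate, notch_hz, notch_q)
        else:
            warnings.warn(
                f"skipping {notch_hz} Hz notch at fs={rec.sampling_rate} Hz "
                "(at/above Nyquist)",
                stacklevel=2,
            )
    v = baseline_correct(v)
    return replace(rec, horizontal=h, vertical=v)


class BandpassFilter(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying the Butterworth band-pass row-wise."""

    def __init__(self, fs: float = 100.0, order: int = 4,
                 low_hz: float = 0.1, high_hz: float = 10.0):
        self.fs = fs
        self.order = order
        self.low_hz = low_hz
        self.high_hz = high_hz

    def fit(self, X, y=None):
        self.spec_ = FilterSpec(order=self.order, low_hz=self.low_hz, high_hz=self.high_hz)
        return self

    def transform(self, X):
        if not hasattr(self, "spec_"):
            self.fit(X)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([bandpass(row, self.fs, self.spec_) for row in X])


class NotchFilter(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying the mains notch row-wise."""

    def __init__(self, fs: float = 256.0, notch_hz: float = 50.0, quality: float = 30.0):
        self.fs = fs
        self.notch_hz = notch_hz
        self.quality = quality

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([notch(row, self.fs, self.notch_hz, self.quality) for row in X])
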