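"""Continuous wavelet transform energy scalograms and their images.

A 1000-sample EOG frame is mapped to the time–frequency plane with an
analytic Morlet wavelet,

    W(a, b) = a^{-1/2} ∫ x(t) ψ*((t − b)/a) dt,

evaluated in the Fourier domain (the wavelet's spectrum is a Gaussian
centred on ω0/a, ω0 = 6), and the *energy scalogram* is the squared
magnitude |W(a, b)|².  Scales follow a geometric grid with a configurable
number of voices per octave over the analysis band (default 0.1–10 Hz);
the frequency attached to a scale is the wavelet's centre frequency
ω0 / (2π a).

Images: log-power, per-image min–max normalisation, a jet-like 256-entry
colour lookup table, bilinear resize to the consuming network's input
size (28×28 for the lightweight CNN).  The normalisation constant is
relative to the frame's own maximum, so a frame and any positive
rescaling of it render to identical pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .preprocess import DEFAULT_FRAME_LEN, SignalFrame, segment_frames

__all__ = [
    "WaveletSpec",
    "Scalogram",
    "ScalogramImage",
    "ImageSet",
    "cwt",
    "render_image",
    "build_image_dataset",
    "jet_lut",
    "write_images",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Analytic wavelet configuration for the CWT."""

    family: str = "morlet"
    voices_per_octave: int = 12
    freq_range: tuple[float, float] = (0.1, 10.0)
    omega0: float = 6.0

    def __post_init__(self) -> None:
        if self.family != "morlet":
            raise ValueError(f"unsupported wavelet family {self.family!r}")
        if self.voices_per_octave < 4:
            raise ValueError("voices_per_octave must be >= 4")
        lo, hi = self.freq_range
        if not 0 < lo < hi:
            raise ValueError("freq_range must satisfy 0 < low < high")


@dataclass
class Scalogram:
    """|CWT|² power, rows ordered coarse (low f) → fine (high f)."""

    power: np.ndarray       # [n_scales, n_samples]
    scales: np.ndarray      # seconds
    frequencies: np.ndarray  # Hz, ascending
    frame_ref: str = ""


@dataclass
class ScalogramImage:
    """Rendered fixed-size 8-bit RGB image of one scalogram."""

    pixels: np.ndarray  # [H, W, 3] uint8
    size: tuple[int, int]
    colormap_name: str = "jet"
    frame_ref: str = ""


def _wavelet_frequencies(spec: WaveletSpec, fs: float) -> np.ndarray:
    lo, hi = spec.freq_range
    hi = min(hi, fs / 2)
    if hi <= lo:
        raise ValueError("freq_range collapses below the sampling rate's Nyquist")
    n_octaves = np.log2(hi / lo)
    n = int(np.floor(n_octaves * spec.voices_per_octave)) + 1
    return lo * 2.0 ** (np.arange(n) / spec.voices_per_octave)


def cwt(frame, fs: float, spec: WaveletSpec | None = None) -> Scalogram:
    """Analytic-Morlet CWT of one frame; returns the energy scalogram.

    Accepts a :class:`SignalFrame` or a bare sample vector.  Uses the
    FFT algorithm with L2 scale normalisation so a unit-amplitude tone
    produces a ridge at its own frequency independent of scale.
    """
    if spec is None:
        spec = WaveletSpec()
    if isinstance(frame, SignalFrame):
        x = frame.samples
        ref = f"{frame.source_recording}/{frame.channel}/{frame.frame_index}"
    else:
        x = np.asarray(frame, dtype=float)
        ref = ""
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("frame must be a non-empty 1-D sample vector")

    n = len(x)
    dt = 1.0 / fs
    freqs = _wavelet_frequencies(spec, fs)
    scales = spec.omega0 / (2 * np.pi * freqs)  # seconds
    omega = 2 * np.pi * np.fft.fftfreq(n, d=dt)
    X = np.fft.fft(x)
    W = np.empty((len(scales), n), dtype=complex)
    positive = omega > 0
    for i, s in enumerate(scales):
        psi_hat = np.zeros(n)
        psi_hat[positive] = (
            np.pi ** -0.25
            * np.sqrt(2 * np.pi * s / dt)
            * np.exp(-0.5 * (s * omega[positive] - spec.omega0) ** 2)
        )
        W[i] = np.fft.ifft(X * psi_hat)
    power = np.abs(W) ** 2
    return Scalogram(power=power, scales=scales, frequencies=freqs, frame_ref=ref)


def jet_lut(n: int = 256) -> np.ndarray:
    """A jet-like rainbow lookup table (blue→cyan→yellow→red), uint8 [n,3]."""
    x = np.linspace(0.0, 1.0, n)

    def channel(center: float) -> np.ndarray:
        return np.clip(1.5 - 4.0 * np.abs(x - center), 0.0, 1.0)

    rgb = np.stack([channel(0.75), channel(0.5), channel(0.25)], axis=1)
    return np.round(rgb * 255).astype(np.uint8)


def render_image(
    scal: Scalogram,
    size: tuple[int, int] = (28, 28),
    lut: np.ndarray | None = None,
    colormap_name: str = "jet",
) -> ScalogramImage:
    """Render a scalogram to a fixed-size RGB image (deterministic).

    Log-power is min–max normalised per image (a constant scalogram maps
    to the mid colour), passed through the colour LUT, and bilinearly
    resized.  High frequencies are drawn at the top of the image.
    """
    if lut is None:
        lut = jet_lut()
    p = np.asarray(scal.power, dtype=float)
    if p.size == 0:
        raise ValueError("empty scalogram")
    pmax = p.max()
    if pmax <= 0 or p.min() == pmax:
        norm = np.full_like(p, 0.5)
    else:
        logp = np.log10(p + pmax * 1e-12)
        norm = (logp - logp.min()) / (logp.max() - logp.min())
    norm = norm[::-1]  # fine frequencies on top
    resized = _sk_resize(norm, size, order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    idx = np.clip(np.round(resized * (len(lut) - 1)).astype(int), 0, len(lut) - 1)
    return ScalogramImage(pixels=lut[idx], size=tuple(size),
                          colormap_name=colormap_name, frame_ref=scal.frame_ref)


@dataclass
class ImageSet:
    """A labelled scalogram-image dataset with per-image provenance."""

    images: np.ndarray   # [n, H, W, 3] uint8
    labels: np.ndarray   # [n] str group labels
    provenance: "pd.DataFrame"  # recording, frame_index, channel per image  # noqa: F821


def build_image_dataset(
    recordings,
    channel: str = "horizontal",
    spec: WaveletSpec | None = None,
    size: tuple[int, int] = (28, 28),
    frame_len: int = DEFAULT_FRAME_LEN,
    limit_per_class: int | None = None,
) -> ImageSet:
    """Frames → scalogram images for one channel across recordings.

    When ``limit_per_class`` is set the dataset is balanced by taking the
    first N frames per class in deterministic recording order.  A class
    with zero frames is an error.
    """
    import pandas as pd

    by_class: dict[str, list] = {}
    for rec in recordings:
        for frame in segment_frames(rec, channel=channel, frame_len=frame_len):
            by_class.setdefault(frame.label, []).append(frame)
    if not by_class:
        raise ValueError("no frames produced from any recording")
    for label, frames in by_class.items():
        if not frames:
            raise ValueError(f"class {label!r} contributed zero frames")
        if limit_per_class is not None and len(frames) < limit_per_class:
            raise ValueError(
                f"class {label!r} has {len(frames)} frames < limit_per_class={limit_per_class}"
            )

    fs_by_id = {rec.recording_id: rec.sampling_rate for rec in recordings}
    images, labels, prov = [], [], []
    for label in sorted(by_class):
        frames = by_class[label]
        if limit_per_class is not None:
            frames = frames[:limit_per_class]
        for frame in frames:
            img = render_image(cwt(frame, fs_by_id[frame.source_recording], spec), size=size)
            images.append(img.pixels)
            labels.append(label)
            prov.append({
                "recording": frame.source_recording,
                "frame_index": frame.frame_index,
                "channel": frame.channel,
                "label": label,
            })
    return ImageSet(
        images=np.stack(images),
        labels=np.asarray(labels),
        provenance=pd.DataFrame(prov),
    )


def write_images(imgset: ImageSet, out_dir: str | Path) -> Path:
    """Write PNGs plus a JSON manifest; returns the manifest path."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (img, label) in enumerate(zip(imgset.images, imgset.labels)):
        row = imgset.provenance.iloc[i]
        name = f"{i:05d}_{label}.png"
        Image.fromarray(img).save(out_dir / name)
        entries.append({
            "file": name,
            "label": str(label),
            "recording": str(row["recording"]),
            "frame_index": int(row["frame_index"]),
            "channel": str(row["channel"]),
        })
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(entries, indent=1))
    return manifest
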