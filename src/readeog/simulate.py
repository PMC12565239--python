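"""Synthetic reading-EOG generator with ground-truth event annotations.

Two-channel electrooculography (EOG) during silent text reading has a
highly stereotyped structure which this module emulates:

* **Horizontal channel** — a staircase of rightward word-to-word saccade
  steps separated by fixation plateaus, occasionally interrupted by a
  *regression* (a leftward return to earlier words, i.e. a sudden negative
  amplitude step), and terminated at each line end by a large leftward
  *line-return sweep* back to the left margin.
* **Vertical channel** — near-baseline activity punctuated by large
  biphasic blink pulses arriving roughly as a Poisson process with a
  physiological refractory gap.

Both channels carry additive white Gaussian noise and an optional 50 Hz
power-line component.  Every injected blink and regression is recorded in
a :class:`GroundTruth` object so that the event detectors can be scored
against a known answer.

Amplitudes are in arbitrary units (a.u.): EOG gain depends on the
acquisition chain and no calibration to microvolts is claimed.

Randomness is organised into four independent streams spawned from the
single seed, in this fixed order: ``fixation``, ``regression``, ``blink``,
``noise``.  The regression stream draws exactly one Bernoulli variate per
word (``uniform < regression_prob``), which makes the injected regression
schedule replayable by an external oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TextSpec",
    "SimParams",
    "GroundTruth",
    "EogRecording",
    "tdc_preset",
    "dyslexia_preset",
    "default_texts",
    "simulate_recording",
    "make_dataset",
    "write_recording",
    "read_recording",
]

_FONT_SIZES = (14, 16, 18, 20, 22)
_GRADES = (2, 3, 4)

# Minimum plausible fixation; truncates the Gaussian duration draw.
_MIN_FIXATION_S = 0.08
# Physiological refractory gap between successive blinks (s).
_BLINK_REFRACTORY_S = 0.8
# Quiet padding before/after the marked reading interval (s).
_LEAD_S = 0.5


@dataclass(frozen=True)
class TextSpec:
    """Metadata for one reading task (text)."""

    text_id: int
    typeface: str = "BonvenoCF"
    font_size: int = 16
    word_count: int = 40
    grade: int = 3

    def __post_init__(self) -> None:
        if self.word_count <= 0:
            raise ValueError(f"word_count must be positive, got {self.word_count}")
        if self.font_size not in _FONT_SIZES:
            raise ValueError(f"font_size must be one of {_FONT_SIZES}, got {self.font_size}")
        if self.grade not in _GRADES:
            raise ValueError(f"grade must be one of {_GRADES}, got {self.grade}")


@dataclass
class SimParams:
    """Generative parameters for one subject's reading behaviour.

    The group presets (:func:`tdc_preset`, :func:`dyslexia_preset`) encode
    the qualitative group differences reported for dyslexic readers —
    longer fixations, more regressions, higher blink rate — as generative
    quantities; the magnitudes are synthetic choices, not measurements.
    """

    group_label: str = "tdc"
    sampling_rate: float = 100.0
    words_per_line: int = 8
    n_lines: int = 5
    fixation_duration_mean: float = 0.25
    fixation_duration_sd: float = 0.05
    saccade_amplitude: float = 1.0
    saccade_duration: float = 0.03
    regression_prob: float = 0.05
    regression_amplitude_frac: float = 1.5
    blink_rate: float = 12.0
    blink_peak_amplitude: float = 4.0
    blink_rise_time: float = 0.15
    line_return_amplitude: float | None = None
    noise_sd: float = 0.05
    powerline_amp: float = 0.05
    seed: int | None = None

    def validate(self) -> None:
        numeric = {
            "sampling_rate": self.sampling_rate,
            "fixation_duration_mean": self.fixation_duration_mean,
            "fixation_duration_sd": self.fixation_duration_sd,
            "saccade_amplitude": self.saccade_amplitude,
            "saccade_duration": self.saccade_duration,
            "regression_prob": self.regression_prob,
            "regression_amplitude_frac": self.regression_amplitude_frac,
            "blink_rate": self.blink_rate,
            "blink_peak_amplitude": self.blink_peak_amplitude,
            "blink_rise_time": self.blink_rise_time,
            "noise_sd": self.noise_sd,
            "powerline_amp": self.powerline_amp,
        }
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise ValueError(f"SimParams.{name} must be finite, got {value!r}")
        if self.group_label not in ("tdc", "dyslexia"):
            raise ValueError(f"group_label must be 'tdc' or 'dyslexia', got {self.group_label!r}")
        for name in ("fixation_duration_mean", "saccade_duration", "blink_rise_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimParams.{name} must be > 0")
        if not 0.0 <= self.regression_prob <= 1.0:
            raise ValueError("regression_prob must lie in [0, 1]")
        # The analysis band extends to 10 Hz; anything slower undersamples it.
        if self.sampling_rate <= 20.0:
            raise ValueError("sampling_rate must exceed 20 Hz (2 x 10 Hz band edge)")
        if self.words_per_line < 1 or self.n_lines < 1:
            raise ValueError("words_per_line and n_lines must be >= 1")
        if self.noise_sd < 0 or self.blink_rate < 0 or self.powerline_amp < 0:
            raise ValueError("noise_sd, blink_rate, powerline_amp must be >= 0")

    @property
    def line_return(self) -> float:
        if self.line_return_amplitude is not None:
            return self.line_return_amplitude
        return self.words_per_line * self.saccade_amplitude


def tdc_preset(**overrides) -> SimParams:
    """Typically developing control preset."""
    return replace(SimParams(group_label="tdc"), **overrides)


def dyslexia_preset(**overrides) -> SimParams:
    """Dyslexia preset: longer fixations, more regressions, more blinks."""
    params = SimParams(
        group_label="dyslexia",
        fixation_duration_mean=0.40,
        fixation_duration_sd=0.08,
        regression_prob=0.20,
        blink_rate=20.0,
    )
    return replace(params, **overrides)


@dataclass
class GroundTruth:
    """Simulator-side event annotations, in seconds from reading onset."""

    blink_times: list[float] = field(default_factory=list)
    regression_times: list[float] = field(default_factory=list)
    reading_time: float = 0.0
    word_count: int = 0

    def validate(self) -> None:
        for name in ("blink_times", "regression_times"):
            times = getattr(self, name)
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            if any(t < 0 or t > self.reading_time for t in times):
                raise ValueError(f"{name} must lie within [0, reading_time]")


@dataclass
class EogRecording:
    """One subject x text two-channel EOG signal with markers and metadata."""

    subject_id: str
    group_label: str
    grade: int
    text_meta: TextSpec
    horizontal: np.ndarray
    vertical: np.ndarray
    sampling_rate: float
    markers: list[int]
    ground_truth: GroundTruth | None = None

    def validate(self) -> None:
        if len(self.horizontal) != len(self.vertical):
            raise ValueError("horizontal and vertical channels must have equal length")
        m = list(self.markers)
        if m != sorted(m):
            raise ValueError("markers must be sorted")
        if len(m) % 2 != 0:
            raise ValueError("markers must come in start/end pairs (even count)")
        if m and (m[0] < 0 or m[-1] > len(self.horizontal)):
            raise ValueError("markers must lie within the signal")

    @property
    def recording_id(self) -> str:
        return f"{self.subject_id}_t{self.text_meta.text_id:02d}"

    def channel(self, name: str) -> np.ndarray:
        if name == "horizontal":
            return self.horizontal
        if name == "vertical":
            return self.vertical
        raise KeyError(f"unknown channel {name!r}")


def _spawn_streams(seed) -> tuple[np.random.Generator, ...]:
    """Fixed stream order: fixation, regression, blink, noise."""
    children = np.random.SeedSequence(seed).spawn(4)
    return tuple(np.random.default_rng(c) for c in children)


def _blink_template(fs: float, rise: float, amplitude: float) -> np.ndarray:
    """Biphasic blink pulse: raised-cosine lobe with a small undershoot.

    The positive lobe has half-width ``rise`` so the latency from any
    sub-peak threshold crossing to the crest is at most ``rise`` seconds.
    """
    w = max(2, int(round(rise * fs)))
    u = 2 * w  # undershoot width (samples)
    t_main = np.arange(-w, w + 1)
    main = 0.5 * amplitude * (1.0 + np.cos(np.pi * t_main / w))
    t_under = np.arange(1, u + 1)
    under = -0.2 * amplitude * np.sin(np.pi * t_under / u) ** 2
    return np.concatenate([main, under])


def _ramp(start: float, stop: float, n: int) -> np.ndarray:
    """Linear ramp of n samples ending at `stop` (excludes the start value)."""
    if n <= 0:
        return np.empty(0)
    return start + (stop - start) * np.arange(1, n + 1) / n


def simulate_recording(
    params: SimParams,
    text: TextSpec | None = None,
    subject_id: str = "sim",
) -> EogRecording:
    """Generate one reading recording with ground-truth annotations.

    The horizontal channel is built word by word: a fixation plateau whose
    duration is drawn from a truncated Gaussian, then a 1-word rightward
    saccade ramp.  With probability ``regression_prob`` (one Bernoulli
    draw per word, in word order, from the dedicated regression stream) a
    regression is inserted after the word's fixation: a fast leftward step
    of ``regression_amplitude_frac`` word-steps, a short re-reading
    fixation, and a compensating rightward return.  Each line ends with a
    line-return sweep back to the left margin.
    """
    params.validate()
    if text is None:
        text = TextSpec(text_id=0, word_count=params.words_per_line * params.n_lines)
    if text.word_count < params.words_per_line:
        raise ValueError("text.word_count must be at least words_per_line")

    fs = params.sampling_rate
    fix_rng, reg_rng, blink_rng, noise_rng = _spawn_streams(params.seed)

    n_words = text.word_count
    words_per_line = params.words_per_line
    sacc_n = max(1, int(round(params.saccade_duration * fs)))
    sweep_n = max(2, int(round(0.08 * fs)))  # line-return sweep duration
    step = params.saccade_amplitude
    reg_amp = params.regression_amplitude_frac * step

    # One replayable Bernoulli per word, drawn up front in word order.
    reg_draws = reg_rng.random(n_words) < params.regression_prob

    segments: list[np.ndarray] = []
    regression_samples: list[int] = []
    pos = 0.0
    t = 0  # samples since reading onset
    for w in range(n_words):
        fix_dur = max(_MIN_FIXATION_S, fix_rng.normal(params.fixation_duration_mean,
                                                      params.fixation_duration_sd))
        fix_n = max(1, int(round(fix_dur * fs)))
        segments.append(np.full(fix_n, pos))
        t += fix_n

        if reg_draws[w]:
            # Leftward return of ~1.5 words, brief re-read, rightward return.
            regression_samples.append(t)
            segments.append(_ramp(pos, pos - reg_amp, sacc_n))
            t += sacc_n
            refix_n = max(1, int(round(0.7 * fix_n)))
            segments.append(np.full(refix_n, pos - reg_amp))
            t += refix_n
            segments.append(_ramp(pos - reg_amp, pos, sacc_n))
            t += sacc_n

        end_of_line = (w + 1) % words_per_line == 0
        last_word = w == n_words - 1
        if last_word:
            break
        if end_of_line:
            segments.append(_ramp(pos, 0.0, sweep_n))
            t += sweep_n
            pos = 0.0
        else:
            segments.append(_ramp(pos, pos + step, sacc_n))
            t += sacc_n
            pos += step

    horizontal_read = np.concatenate(segments)
    n_read = len(horizontal_read)
    reading_time = n_read / fs

    # Vertical channel: blink arrivals with a refractory gap, only within
    # the reading interval, at an effective rate ~= blink_rate per minute.
    vertical_read = np.zeros(n_read)
    blink_times: list[float] = []
    if params.blink_rate > 0:
        mean_gap = 60.0 / params.blink_rate
        exp_mean = max(1e-6, mean_gap - _BLINK_REFRACTORY_S)
        template = _blink_template(fs, params.blink_rise_time, params.blink_peak_amplitude)
        half = int(round(params.blink_rise_time * fs))
        t_blink = _BLINK_REFRACTORY_S + blink_rng.exponential(exp_mean)
        margin = params.blink_rise_time + 0.05
        while t_blink < reading_time - margin:
            if t_blink > margin:
                peak = int(round(t_blink * fs))
                lo = peak - half
                hi = lo + len(template)
                if 0 <= lo and hi <= n_read:
                    vertical_read[lo:hi] += template
                    blink_times.append(t_blink)
            t_blink += _BLINK_REFRACTORY_S + blink_rng.exponential(exp_mean)

    lead_n = int(round(_LEAD_S * fs))
    # After the marked reading interval the gaze sweeps back to the left
    # margin; without this the signal would end in an unphysical step.
    trail = np.concatenate([_ramp(pos, 0.0, sweep_n), np.zeros(max(0, lead_n - sweep_n))])
    horizontal = np.concatenate([np.zeros(lead_n), horizontal_read, trail])
    vertical = np.concatenate([np.zeros(lead_n), vertical_read, np.zeros(len(trail))])
    n_total = len(horizontal)

    if params.noise_sd > 0:
        horizontal = horizontal + noise_rng.normal(0.0, params.noise_sd, n_total)
        vertical = vertical + noise_rng.normal(0.0, params.noise_sd, n_total)
    if params.powerline_amp > 0:
        tt = np.arange(n_total) / fs
        mains = params.powerline_amp * np.sin(2 * np.pi * 50.0 * tt + np.pi / 2)
        horizontal = horizontal + mains
        vertical = vertical + mains

    gt = GroundTruth(
        blink_times=blink_times,
        regression_times=[s / fs for s in regression_samples],
        reading_time=reading_time,
        word_count=n_words,
    )
    gt.validate()
    rec = EogRecording(
        subject_id=subject_id,
        group_label=params.group_label,
        grade=text.grade,
        text_meta=text,
        horizontal=horizontal,
        vertical=vertical,
        sampling_rate=fs,
        markers=[lead_n, lead_n + n_read],
        ground_truth=gt,
    )
    rec.validate()
    return rec


def default_texts(n: int = 28, word_count: int = 40) -> list[TextSpec]:
    """A bank of reading tasks cycling typefaces/font sizes over 3 grades."""
    typefaces = ["BonvenoCF", "Times New Roman", "Arial", "TTKB Dik Temel ABC",
                 "SofiaPro", "OpenDyslexic", "Calibri"]
    sizes = [14, 16, 18, 20]
    texts = []
    for i in range(n):
        texts.append(TextSpec(
            text_id=i + 1,
            typeface=typefaces[i % len(typefaces)],
            font_size=sizes[(i // len(typefaces)) % len(sizes)],
            word_count=word_count,
            grade=_GRADES[i % 3],
        ))
    return texts


def _jitter_params(base: SimParams, rng: np.random.Generator, sd: float = 0.10) -> SimParams:
    """Per-subject multiplicative log-normal jitter on behavioural rates."""
    j = lambda: float(rng.lognormal(0.0, sd))  # noqa: E731
    return replace(
        base,
        fixation_duration_mean=base.fixation_duration_mean * j(),
        blink_rate=base.blink_rate * j(),
        regression_prob=min(1.0, base.regression_prob * j()),
    )


def make_dataset(
    n_subjects_per_group: int,
    texts: Sequence[TextSpec],
    group_presets: tuple[SimParams, SimParams] | None = None,
    seed: int | None = None,
) -> list[EogRecording]:
    """Simulate a cohort: one recording per subject x text.

    Each subject gets a jittered copy of their group preset (log-normal,
    10% sd on fixation duration, blink rate and regression probability)
    and an independent per-recording noise seed, all derived
    deterministically from ``seed``.
    """
    if n_subjects_per_group < 1:
        raise ValueError("n_subjects_per_group must be >= 1")
    if not texts:
        raise ValueError("texts must be non-empty")
    if group_presets is None:
        group_presets = (dyslexia_preset(), tdc_preset())
    root = np.random.SeedSequence(seed)
    recordings: list[EogRecording] = []
    for preset in group_presets:
        preset.validate()
        group_ss = root.spawn(1)[0]
        for s in range(n_subjects_per_group):
            subj_ss = group_ss.spawn(1)[0]
            subj_rng = np.random.default_rng(subj_ss)
            subj_params = _jitter_params(preset, subj_rng)
            subject_id = f"{preset.group_label}_{s:02d}"
            for text in texts:
                rec_seed = int(subj_rng.integers(0, 2**31 - 1))
                rec = simulate_recording(
                    replace(subj_params, seed=rec_seed), text, subject_id=subject_id
                )
                recordings.append(rec)
    return recordings


# ---------------------------------------------------------------------------
# Plain-text I/O: two-column CSV + JSON sidecar
# ---------------------------------------------------------------------------

def write_recording(rec: EogRecording, out_dir: str | Path) -> tuple[Path, Path]:
    """Write one recording as ``<id>.csv`` (horizontal,vertical) + ``<id>.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{rec.recording_id}.csv"
    data = np.column_stack([rec.horizontal, rec.vertical])
    np.savetxt(csv_path, data, delimiter=",", header="horizontal,vertical", comments="")
    meta = {
        "subject_id": rec.subject_id,
        "group_label": rec.group_label,
        "grade": rec.grade,
        "sampling_rate": rec.sampling_rate,
        "markers": list(map(int, rec.markers)),
        "text_meta": asdict(rec.text_meta),
        "ground_truth": asdict(rec.ground_truth) if rec.ground_truth else None,
    }
    json_path = out_dir / f"{rec.recording_id}.json"
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path


def read_recording(csv_path: str | Path) -> EogRecording:
    """Load a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    gt = GroundTruth(**meta["ground_truth"]) if meta.get("ground_truth") else None
    rec = EogRecording(
        subject_id=meta["subject_id"],
        group_label=meta["group_label"],
        grade=meta["grade"],
        text_meta=TextSpec(**meta["text_meta"]),
        horizontal=data[:, 0],
        vertical=data[:, 1],
        sampling_rate=meta["sampling_rate"],
        markers=meta["markers"],
        ground_truth=gt,
    )
    rec.validate()
    return rec
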