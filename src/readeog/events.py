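"""Oculomotor event detection and reading-performance features.

Four features characterise one reading of one text:

* **reading time** — difference between the start/end markers, s;
* **blink count / rate** — blinks on the vertical channel per minute of
  reading time;
* **regression count / rate** — leftward re-reading saccades on the
  horizontal channel per word of text;
* **signal energy** — the discrete energy ``sum(x[n]**2)`` of the
  horizontal channel over the reading interval (unit sample spacing
  convention; arbitrary-units² · samples).

Blink rule: a vertical-channel excursion counts as a blink when its crest
exceeds a per-signal amplitude threshold ``T = median + k·MAD`` (k=4,
normal-consistent MAD) and the latency from the up-crossing of T to the
crest lies within a 50–400 ms acceptance window.

Regression rule: a fast negative amplitude step — first difference over a
50 ms window — of magnitude at least ``min_drop`` (default 0.6 median
word-steps), but smaller than half the per-line signal range so that
line-return sweeps are never counted; consecutive detections closer than
``min_separation`` collapse onto the most negative step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .simulate import EogRecording

__all__ = [
    "BlinkConfig",
    "RegressionConfig",
    "OcularEvent",
    "FeatureSet",
    "reading_time",
    "detect_blinks",
    "detect_regressions",
    "signal_energy",
    "features",
    "features_table",
    "group_report",
    "event_match_stats",
]


@dataclass(frozen=True)
class BlinkConfig:
    """Blink acceptance rule parameters.

    The 50–400 ms up-crossing→crest window is the study rule; the wider
    literature window (100–800 ms) can be configured instead.
    """

    min_rise: float = 0.05
    max_rise: float = 0.40
    threshold_k: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.min_rise < self.max_rise:
            raise ValueError("need 0 < min_rise < max_rise")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")


@dataclass(frozen=True)
class RegressionConfig:
    """Regression step-detector parameters (see module docstring)."""

    diff_window: float = 0.05        # s; first-difference span
    min_drop_frac: float = 0.6       # of the median word-step
    line_exclusion_frac: float = 0.5  # of the per-line signal range
    min_separation: float = 0.15     # s between consecutive events
    min_drop: float | None = None    # absolute override, signal units
    sweep_guard: float = 0.15        # s; suppression radius around sweeps


@dataclass(frozen=True)
class OcularEvent:
    """A detected blink or regression."""

    kind: str  # "blink" | "regression"
    onset: float  # s
    peak: float   # s
    amplitude: float

    def __post_init__(self) -> None:
        if self.onset > self.peak:
            raise ValueError("onset must not follow peak")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass
class FeatureSet:
    """The per-recording feature vector."""

    reading_time: float
    n_blinks: int
    blink_rate: float        # blinks / minute
    n_regressions: int
    regression_rate: float   # regressions / word
    energy: float            # a.u.² · samples

    def validate(self) -> None:
        vals = [self.reading_time, self.n_blinks, self.blink_rate,
                self.n_regressions, self.regression_rate, self.energy]
        if any(v < 0 for v in vals):
            raise ValueError("features must be non-negative")


def reading_time(recording: EogRecording, text_index: int = 0) -> float:
    """Reading time from the ``text_index``-th start/end marker pair, s."""
    m = recording.markers
    if len(m) < 2 * (text_index + 1):
        raise ValueError(
            f"no marker pair for text index {text_index} "
            f"(text id {recording.text_meta.text_id})"
        )
    start, end = m[2 * text_index], m[2 * text_index + 1]
    if end <= start:
        raise ValueError(
            f"marker pair ({start}, {end}) has non-positive duration "
            f"(text id {recording.text_meta.text_id})"
        )
    return (end - start) / recording.sampling_rate


def detect_blinks(vertical, fs: float, cfg: BlinkConfig | None = None) -> list[OcularEvent]:
    """Detect blinks on a notch-filtered, baseline-corrected vertical channel."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if cfg is None:
        cfg = BlinkConfig()
    x = np.asarray(vertical, dtype=float)
    if len(x) == 0:
        return []
    med = np.median(x)
    mad = spstats.median_abs_deviation(x, scale="normal")
    if mad == 0:
        mad = np.std(x)
    threshold = med + cfg.threshold_k * mad
    above = x > threshold
    if not above.any():
        return []
    # Contiguous supra-threshold excursions; crest = max within excursion.
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(x))
    events = []
    for s, e in zip(starts, ends):
        crest = s + int(np.argmax(x[s:e]))
        latency = (crest - s) / fs
        if cfg.min_rise <= latency <= cfg.max_rise:
            events.append(OcularEvent("blink", onset=s / fs, peak=crest / fs,
                                      amplitude=float(x[crest])))
    return events


def _run_centers(d: np.ndarray, mask: np.ndarray, window: int) -> np.ndarray:
    """Centre sample of each contiguous run in ``mask`` (at the run's
    most negative difference, shifted by half the difference window)."""
    if not mask.any():
        return np.empty(0, dtype=np.int64)
    run_idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(run_idx) > 1) + 1
    return np.asarray(
        [run[int(np.argmin(d[run]))] + window // 2 for run in np.split(run_idx, breaks)],
        dtype=np.int64,
    )


def _estimate_word_step(d: np.ndarray) -> float:
    """Median forward-saccade step from the windowed difference series."""
    pos = d[d > 0]
    if len(pos) == 0:
        return 0.0
    big = pos[pos > 0.25 * np.percentile(pos, 99)]
    if len(big) == 0:
        return 0.0
    return float(np.median(big))


def detect_regressions(
    horizontal,
    fs: float,
    cfg: RegressionConfig | None = None,
) -> list[OcularEvent]:
    """Detect regressive (leftward) saccades on a band-passed horizontal channel."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if cfg is None:
        cfg = RegressionConfig()
    x = np.asarray(horizontal, dtype=float)
    w = max(1, int(round(cfg.diff_window * fs)))
    if len(x) <= w:
        return []
    d = x[w:] - x[:-w]  # amplitude change over the 50 ms window

    if cfg.min_drop is not None:
        min_drop = cfg.min_drop
    else:
        step = _estimate_word_step(d)
        if step == 0.0:
            return []
        min_drop = cfg.min_drop_frac * step
    # Upper bound excludes the much larger line-return sweeps.  The
    # staircase resets every line, so the per-line range is well
    # approximated by the overall signal range.
    line_range = float(np.max(x) - np.min(x))
    max_drop = cfg.line_exclusion_frac * line_range

    candidate = (d <= -min_drop) & (-d < max_drop)
    if not candidate.any():
        return []
    idx = np.flatnonzero(candidate)
    # Line-return sweeps are both larger and longer than regressions: a
    # 50 ms window may straddle only part of one, leaving its magnitude
    # between min_drop and the exclusion bound.  Locate sweeps with an
    # additional long-window difference that captures the full drop, and
    # suppress every candidate within sweep_guard of a sweep centre.
    wl = max(w + 1, int(round(3 * cfg.diff_window * fs)))
    d_long = x[wl:] - x[:-wl] if len(x) > wl else np.empty(0)
    centers = np.concatenate([
        _run_centers(d, -d >= max_drop, w),
        _run_centers(d_long, -d_long >= max_drop, wl),
    ])
    if len(centers):
        centers.sort()
        guard = int(round(cfg.sweep_guard * fs))
        cand_centers = idx + w // 2
        pos = np.searchsorted(centers, cand_centers)
        big = np.iinfo(np.int64).max
        dist_r = np.where(pos < len(centers),
                          np.abs(centers[np.minimum(pos, len(centers) - 1)] - cand_centers),
                          big)
        dist_l = np.where(pos > 0,
                          np.abs(cand_centers - centers[np.maximum(pos - 1, 0)]),
                          big)
        idx = idx[np.minimum(dist_r, dist_l) > guard]
        if len(idx) == 0:
            return []
    # Split candidate runs, take the most negative step within each run,
    # then enforce the minimum separation keeping the earlier event.
    min_sep = int(round(cfg.min_separation * fs))
    run_breaks = np.flatnonzero(np.diff(idx) > w) + 1
    events: list[OcularEvent] = []
    last_kept = -np.inf
    for run in np.split(idx, run_breaks):
        i = run[int(np.argmin(d[run]))]
        if i - last_kept < min_sep:
            continue
        last_kept = i
        events.append(OcularEvent(
            "regression",
            onset=i / fs,
            peak=(i + w) / fs,
            amplitude=float(d[i]),
        ))
    return events


def signal_energy(x) -> float:
    """Discrete signal energy ``sum(x[n]**2)``, unit sample spacing."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return float(np.sum(x * x))


def features(
    recording: EogRecording,
    blink_cfg: BlinkConfig | None = None,
    regression_cfg: RegressionConfig | None = None,
    text_index: int = 0,
) -> FeatureSet:
    """Extract the full feature vector from a preprocessed recording.

    Detection and the energy integral are restricted to the marked
    reading interval; energy is computed on the horizontal channel.
    """
    rt = reading_time(recording, text_index)
    m = recording.markers
    start, end = m[2 * text_index], m[2 * text_index + 1]
    fs = recording.sampling_rate
    v = recording.vertical[start:end]
    # Give the regression detector ~0.3 s of context past the end marker
    # so the post-reading return sweep is recognised (and excluded) as a
    # sweep rather than leaking shoulder artifacts into the interval.
    context = int(round(0.3 * fs))
    h_ext = recording.horizontal[start:min(end + context, len(recording.horizontal))]
    h = recording.horizontal[start:end]
    blinks = detect_blinks(v, fs, blink_cfg)
    regressions = [ev for ev in detect_regressions(h_ext, fs, regression_cfg)
                   if ev.onset <= rt]
    word_count = recording.text_meta.word_count
    fset = FeatureSet(
        reading_time=rt,
        n_blinks=len(blinks),
        blink_rate=len(blinks) / (rt / 60.0),
        n_regressions=len(regressions),
        regression_rate=len(regressions) / word_count,
        energy=signal_energy(h),
    )
    fset.validate()
    return fset


def features_table(
    recordings,
    blink_cfg: BlinkConfig | None = None,
    regression_cfg: RegressionConfig | None = None,
) -> pd.DataFrame:
    """Feature rows (one per recording) for a list of recordings."""
    rows = []
    for rec in recordings:
        f = features(rec, blink_cfg, regression_cfg)
        rows.append({
            "subject_id": rec.subject_id,
            "group": rec.group_label,
            "grade": rec.grade,
            "text_id": rec.text_meta.text_id,
            "typeface": rec.text_meta.typeface,
            "font_size": rec.text_meta.font_size,
            "reading_time": f.reading_time,
            "n_blinks": f.n_blinks,
            "blink_rate": f.blink_rate,
            "n_regressions": f.n_regressions,
            "regression_rate": f.regression_rate,
            "energy": f.energy,
        })
    return pd.DataFrame(rows)


FEATURE_COLUMNS = ("reading_time", "blink_rate", "regression_rate", "energy")


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.0001:
        return "****"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupReport:
    """Per-text group means and pooled two-sample t-tests."""

    per_text: pd.DataFrame
    tests: pd.DataFrame
    flags: list[str] = field(default_factory=list)


def group_report(table: pd.DataFrame) -> GroupReport:
    """Group comparison in the style of the per-text figures.

    ``table`` is the output of :func:`features_table`.  Produces per-text
    group means for each feature and, per grade, independent two-sample
    t-tests (Welch) for each feature under two units of analysis:
    ``subject`` (per-subject means across texts; the conservative choice)
    and ``text`` (all recordings pooled).  Groups with fewer than two
    subjects are flagged and not tested.
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    per_text = (
        table.groupby(["grade", "text_id", "group"])[list(FEATURE_COLUMNS)]
        .mean()
        .reset_index()
    )

    rows = []
    flags: list[str] = []
    for grade, sub in table.groupby("grade"):
        for unit in ("subject", "text"):
            if unit == "subject":
                data = sub.groupby(["group", "subject_id"])[list(FEATURE_COLUMNS)].mean()
                samples = {g: data.loc[g] for g in groups if g in data.index.get_level_values(0)}
            else:
                samples = {g: sub[sub["group"] == g][list(FEATURE_COLUMNS)] for g in groups}
            for feat in FEATURE_COLUMNS:
                a = samples.get(groups[0], pd.DataFrame()).get(feat, pd.Series(dtype=float))
                b = samples.get(groups[1], pd.DataFrame()).get(feat, pd.Series(dtype=float))
                row = {
                    "grade": grade, "unit": unit, "feature": feat,
                    f"mean_{groups[0]}": float(np.mean(a)) if len(a) else np.nan,
                    f"mean_{groups[1]}": float(np.mean(b)) if len(b) else np.nan,
                }
                if len(a) < 2 or len(b) < 2:
                    row.update(t=np.nan, p=np.nan, stars="")
                    flags.append(f"grade {grade}/{unit}/{feat}: group with <2 samples, no test")
                else:
                    import warnings
                    with warnings.catch_warnings():
                        # near-identical samples (e.g. all-zero counts) are
                        # legitimate here and simply yield t ~ 0
                        warnings.simplefilter("ignore", RuntimeWarning)
                        t, p = spstats.ttest_ind(a, b, equal_var=False)
                    row.update(t=float(t), p=float(p), stars=_stars(float(p)))
                rows.append(row)
    return GroupReport(per_text=per_text, tests=pd.DataFrame(rows), flags=flags)


def event_match_stats(
    detected_times,
    true_times,
    tol: float = 0.15,
) -> dict[str, float]:
    """Greedy one-to-one matching of detected vs ground-truth event times.

    Returns precision, recall and counts; used to score the detectors
    against the simulator's annotations.
    """
    detected = sorted(detected_times)
    truth = sorted(true_times)
    used = [False] * len(truth)
    tp = 0
    for t_det in detected:
        best, best_dt = None, tol
        for j, t_true in enumerate(truth):
            if used[j]:
                continue
            dt = abs(t_det - t_true)
            if dt <= best_dt:
                best, best_dt = j, dt
        if best is not None:
            used[best] = True
            tp += 1
    fp = len(detected) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}
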