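"""Event detectors, feature arithmetic and group statistics."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import prep
from readeog import (BlinkConfig, TextSpec, detect_blinks, detect_regressions,
                     dyslexia_preset, event_match_stats, features, features_table,
                     group_report, make_dataset, reading_time, signal_energy,
                     simulate_recording, tdc_preset)


class TestReadingTime:
    def test_marker_difference(self, dys_recording):
        rec = replace(dys_recording, markers=[0, 3000])
        assert reading_time(rec) == pytest.approx(30.0)

    def test_zero_duration_rejected(self, dys_recording):
        rec = replace(dys_recording, markers=[500, 500])
        with pytest.raises(ValueError, match="non-positive"):
            reading_time(rec)

    def test_missing_pair_rejected(self, dys_recording):
        with pytest.raises(ValueError, match="text"):
            reading_time(dys_recording, text_index=1)

    def test_matches_simulator_ground_truth(self, dys_recording):
        gt = dys_recording.ground_truth.reading_time
        assert reading_time(dys_recording) == pytest.approx(gt, abs=0.02)


def synthetic_pulse(rise_s, fs=100.0, amplitude=3.0, noise_sd=0.1, seed=0):
    """Noise floor plus one triangular pulse with the given ramp time."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise_sd, int(20 * fs))
    n = int(rise_s * fs)
    ramp = np.linspace(0, amplitude, n, endpoint=True)
    peak = len(x) // 2
    x[peak - n:peak] += ramp
    x[peak:peak + n] += ramp[::-1]
    return x


class TestDetectBlinks:
    def test_zero_signal_empty(self):
        assert detect_blinks(np.zeros(1000), 100.0) == []

    def test_pulse_inside_window_detected(self):
        """200 ms rise, amplitude far above threshold: exactly one blink."""
        x = synthetic_pulse(0.2)
        events = detect_blinks(x, 100.0)
        assert len(events) == 1
        assert events[0].kind == "blink"
        assert events[0].peak == pytest.approx(10.0, abs=0.05)

    def test_pulse_outside_window_rejected(self):
        """600 ms rise: the up-crossing→crest latency exceeds 400 ms."""
        x = synthetic_pulse(0.6)
        assert detect_blinks(x, 100.0) == []

    def test_wider_literature_window_accepts_slow_pulse(self):
        x = synthetic_pulse(0.6)
        cfg = BlinkConfig(min_rise=0.10, max_rise=0.80)
        assert len(detect_blinks(x, 100.0, cfg)) == 1

    def test_subthreshold_peaks_never_returned(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.1, 2000)  # noise only: nothing above median+4*MAD window rule
        events = detect_blinks(x, 100.0)
        assert all(e.amplitude > 0.1 for e in events)

    def test_invalid_fs_rejected(self):
        with pytest.raises(ValueError):
            detect_blinks(np.zeros(10), 0.0)

    def test_recovers_simulated_blinks(self, dys_preprocessed, dys_recording):
        s, e = dys_preprocessed.markers
        det = [ev.peak for ev in
               detect_blinks(dys_preprocessed.vertical[s:e], 100.0)]
        stats = event_match_stats(det, dys_recording.ground_truth.blink_times)
        assert stats["precision"] == 1.0 and stats["recall"] == 1.0


class TestDetectRegressions:
    def test_monotone_staircase_empty(self):
        x = np.repeat(np.arange(20, dtype=float), 30)  # rising staircase only
        assert detect_regressions(x, 100.0) == []

    def test_recovers_injected_regressions(self, dys_preprocessed, dys_recording):
        """Count matches the simulator ground truth within ±1."""
        s, e = dys_preprocessed.markers
        gt = dys_recording.ground_truth.regression_times
        det = detect_regressions(dys_preprocessed.horizontal[s:e + 30], 100.0)
        det = [ev.onset for ev in det if ev.onset <= (e - s) / 100.0]
        assert abs(len(det) - len(gt)) <= 1

    def test_sweeps_alone_yield_nothing(self, text40):
        """regression_prob=0 at zero noise: line-return sweeps are excluded."""
        params = tdc_preset(regression_prob=0.0, noise_sd=0.0, powerline_amp=0.0,
                            blink_rate=0.0, seed=2)
        rec = prep(simulate_recording(params, text40))
        s, e = rec.markers
        events = detect_regressions(rec.horizontal[s:e + 30], 100.0)
        assert [ev for ev in events if ev.onset <= (e - s) / 100.0] == []

    def test_events_sorted_and_separated(self, dys_preprocessed):
        s, e = dys_preprocessed.markers
        events = detect_regressions(dys_preprocessed.horizontal[s:e], 100.0)
        onsets = [ev.onset for ev in events]
        assert onsets == sorted(onsets)
        assert all(b - a >= 0.15 for a, b in zip(onsets, onsets[1:]))


class TestSignalEnergy:
    def test_zero_vector(self):
        assert signal_energy(np.zeros(100)) == 0.0

    def test_direct_sum(self):
        assert signal_energy([1, 2, 3]) == 14.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), split=st.integers(1, 63))
    def test_additive_and_symmetric(self, seed, split):
        x = np.random.default_rng(seed).normal(size=64)
        total = signal_energy(x)
        assert signal_energy(x[:split]) + signal_energy(x[split:]) == pytest.approx(total)
        assert signal_energy(x[::-1]) == pytest.approx(total)
        assert signal_energy(-x) == pytest.approx(total)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            signal_energy([1.0, np.inf])


class TestFeatures:
    def test_rate_identities(self, dys_preprocessed):
        f = features(dys_preprocessed)
        assert f.blink_rate == pytest.approx(f.n_blinks / (f.reading_time / 60.0))
        assert f.regression_rate == pytest.approx(
            f.n_regressions / dys_preprocessed.text_meta.word_count)
        assert f.energy >= 0 and f.reading_time > 0

    def test_dyslexia_group_reads_slower(self, small_cohort):
        tab = features_table(small_cohort)
        means = tab.groupby("group")["reading_time"].mean()
        assert means["dyslexia"] > means["tdc"]


class TestGroupReport:
    @staticmethod
    def _table(values_a, values_b, feature="reading_time"):
        rows = []
        for g, vals in (("dyslexia", values_a), ("tdc", values_b)):
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"{g}{i}", "group": g, "grade": 3,
                             "text_id": 1, "reading_time": v, "blink_rate": v,
                             "regression_rate": v, "energy": v})
        return pd.DataFrame(rows)

    def test_identical_groups_give_t_zero(self):
        rep = group_report(self._table([1, 2, 3, 4], [1, 2, 3, 4]))
        row = rep.tests[(rep.tests.unit == "subject")
                        & (rep.tests.feature == "reading_time")].iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_single_subject_group_flagged_not_tested(self):
        rep = group_report(self._table([1.0], [1, 2, 3]))
        sub = rep.tests[rep.tests.unit == "subject"]
        assert sub["p"].isna().all()
        assert any("no test" in f for f in rep.flags)

    def test_default_presets_significant_direction(self, small_cohort):
        tab = features_table(small_cohort)
        rep = group_report(tab)
        row = rep.tests[(rep.tests.unit == "subject")
                        & (rep.tests.feature == "reading_time")].iloc[0]
        assert row["mean_dyslexia"] > row["mean_tdc"]
        assert row["p"] < 0.05

    def test_type_one_error_rate_controlled(self):
        """Equal presets for both groups: pooled rejection rate at α=0.05
        over 50 seeds x 4 features stays near nominal."""
        text = [TextSpec(text_id=1, word_count=30, grade=3)]
        fp = total = 0
        for seed in range(50):
            null = replace(tdc_preset(), group_label="dyslexia")
            recs = make_dataset(4, text, (null, tdc_preset()), seed=seed)
            tab = features_table([prep(r) for r in recs])
            ps = group_report(tab).tests.query("unit == 'subject'")["p"].to_numpy()
            fp += int(np.sum(ps < 0.05))
            total += len(ps)
        assert 0.01 <= fp / total <= 0.12


def test_event_match_stats_greedy_matching():
    stats = event_match_stats([1.0, 2.0, 9.0], [1.05, 2.1, 5.0], tol=0.15)
    assert (stats["tp"], stats["fp"], stats["fn"]) == (2, 1, 1)
    assert stats["precision"] == pytest.approx(2 / 3)
    assert stats["recall"] == pytest.approx(2 / 3)
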