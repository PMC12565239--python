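"""Shared fixtures: small simulated cohorts, preprocessed recordings."""

import warnings

import numpy as np
import pytest

from readeog import (TextSpec, dyslexia_preset, make_dataset, preprocess_recording,
                     simulate_recording, tdc_preset)


def prep(rec):
    """Standard preprocessing, silencing the expected Nyquist-notch skip."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return preprocess_recording(rec)


@pytest.fixture(scope="session")
def text40():
    return TextSpec(text_id=1, word_count=40, grade=3)


@pytest.fixture(scope="session")
def dys_recording(text40):
    return simulate_recording(dyslexia_preset(seed=11), text40)


@pytest.fixture(scope="session")
def dys_preprocessed(dys_recording):
    return prep(dys_recording)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects/group x 2 texts, preprocessed; deterministic."""
    texts = [TextSpec(text_id=i + 1, word_count=60, grade=3) for i in range(2)]
    recs = make_dataset(4, texts, (dyslexia_preset(), tdc_preset()), seed=42)
    return [prep(r) for r in recs]


@pytest.fixture(scope="session")
def tone_images():
    """Two separable synthetic classes: tones in disjoint frequency bands."""
    from readeog import cwt, render_image

    fs = 100.0
    t = np.arange(1000) / fs
    rng = np.random.default_rng(0)
    imgs, labels = [], []
    for cls, (flo, fhi) in enumerate([(0.3, 0.8), (2.0, 5.0)]):
        for _ in range(50):
            f0 = rng.uniform(flo, fhi)
            x = (np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
                 + 0.2 * rng.normal(size=len(t)))
            imgs.append(render_image(cwt(x, fs)).pixels)
            labels.append(f"class{cls}")
    return np.stack(imgs), np.asarray(labels)
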