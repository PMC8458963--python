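"""Shared fixtures: small synthetic recordings and a scaled cohort.

Expensive cohort-level fixtures are session-scoped so the feature matrices
are computed once per test session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neurofuse import CohortSpec, EEGRecording, generate_cohort
from neurofuse.pipeline import eeg_feature_matrix, mri_feature_matrix

FS = 125.0
CHANNELS = ("F3", "Fz", "F4", "Cz", "P3", "Pz", "P4")


def sine_recording(freq_hz: float, duration_s: float = 20.0, fs: float = FS,
                   channels: tuple[str, ...] = CHANNELS,
                   amplitude: float = 10.0) -> EEGRecording:
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return EEGRecording(np.tile(x, (len(channels), 1)), fs, channels)


def noise_recording(duration_s: float = 20.0, fs: float = FS,
                    channels: tuple[str, ...] = CHANNELS, seed: int = 0,
                    amplitude: float = 10.0) -> EEGRecording:
    rng = np.random.default_rng(seed)
    data = amplitude * rng.standard_normal((len(channels), int(duration_s * fs)))
    return EEGRecording(data, fs, channels)


def am_tone_epoch(carrier_hz: float, mod_hz: float, depth: float = 0.5,
                  duration_s: float = 8.0, fs: float = FS,
                  channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """Sinusoidal-AM tone epoch, identical on every channel."""
    t = np.arange(int(duration_s * fs)) / fs
    x = (1.0 + depth * np.cos(2 * np.pi * mod_hz * t)) * np.cos(2 * np.pi * carrier_hz * t)
    return np.tile(10.0 * x, (len(channels), 1))


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects at reduced duration: exercises all pipeline mechanics."""
    spec = CohortSpec(n_subjects=6, duration=20.0, seed=123)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_cohort_features():
    """A scaled planted-signal cohort with its feature matrices and labels.

    40 subjects at 60 s keep the statistical structure of the full benchmark
    (planted EEG modulation drifts and MRI slopes) at a fraction of the cost.
    """
    spec = CohortSpec(n_subjects=40, duration=60.0, seed=77)
    cohort = generate_cohort(spec)
    eeg = eeg_feature_matrix(cohort)
    mri = mri_feature_matrix(cohort)
    fused = pd.concat([eeg, mri], axis=1)
    y = pd.Series({r.subject_id: r.mmse for r in cohort})[fused.index]
    return spec, eeg, mri, fused, y
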