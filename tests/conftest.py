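"""Shared fixtures: deterministic signals and a session-scoped cohort."""

import numpy as np
import pytest

import tremorkit as tk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sinusoid(freq, rate=100.0, duration=4.0, amp=1.0, phase=0.0):
    t = np.arange(int(round(rate * duration))) / rate
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def sinusoid_segment():
    def _make(freq, rate=100.0, duration=4.0, amp=1.0, phase=0.0,
              noise_sd=0.0, seed=0):
        x = make_sinusoid(freq, rate, duration, amp, phase)
        if noise_sd:
            x = x + noise_sd * np.random.default_rng(seed).standard_normal(x.size)
        return tk.Segment(x, rate, "fixture", 0)
    return _make


def ar2_coeffs(freq_hz, radius, rate=100.0):
    """Predictor coefficients of an AR(2) with a pole pair at ``freq_hz``."""
    w = 2 * np.pi * freq_hz / rate
    return np.array([2 * radius * np.cos(w), -radius ** 2])


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study conditions: 14 patients x 100 segments, seed 0.

    Session-scoped so its cached dominant-frequency tables are shared by
    every test that evaluates the cohort.
    """
    return tk.gen_cohort(tk.default_cohort_spec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A light separable cohort for fast pipeline tests."""
    return tk.gen_cohort(tk.CohortSpec(
        n_patients=4, n_segments=30,
        prevalences=(0.2, 0.4, 0.6, 0.8), seed=7,
    ))
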