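"""Shared fixtures: kernels, raised-cosine drivers, synthetic recordings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from scdecomp import BatemanParams, Signal, discretize_unit_area

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

FS = 32.0


def raised_cosine(t: np.ndarray, onset: float, duration: float, amplitude: float) -> np.ndarray:
    """Compact driver bump with exact support [onset, onset + duration]."""
    phase = (t - onset) / duration
    bump = 0.5 * amplitude * (1.0 - np.cos(2.0 * np.pi * np.clip(phase, 0.0, 1.0)))
    bump[(phase <= 0) | (phase >= 1)] = 0.0
    return bump


def scr_signal(
    onsets_amps: list[tuple[float, float]],
    kernel,
    duration_s: float = 60.0,
    bump_width: float = 1.0,
    baseline: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[Signal, np.ndarray]:
    """Sum of Bateman SCRs from compact driver bumps; returns (signal, driver)."""
    n = int(duration_s * FS)
    t = np.arange(n) / FS
    driver = np.zeros(n)
    for onset, amp in onsets_amps:
        driver += raised_cosine(t, onset, bump_width, amp)
    values = np.convolve(driver, kernel.samples * kernel.dt)[:n] + baseline
    if noise_sigma > 0:
        values = values + np.random.default_rng(seed).normal(0, noise_sigma, n)
    return Signal(values, fs=FS), driver


@pytest.fixture(scope="session")
def slow_kernel():
    """The paradigmatic slow-recovery kernel (tau2 = 20 s) at 32 Hz."""
    return discretize_unit_area(BatemanParams(0.75, 20.0), FS)


@pytest.fixture(scope="session")
def short_kernel():
    """A short kernel for oracle comparisons (kernel length 240 samples)."""
    return discretize_unit_area(BatemanParams(0.3, 1.5), 16.0)
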