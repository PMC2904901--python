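"""Convolution algebra: standard and nonnegative division, smoothing, fade-in."""

import numpy as np
import pytest

from scdecomp import (
    SamplingRateError,
    Signal,
    convolve,
    fade_in_extend,
    gaussian_smooth,
    nonnegative_deconvolve,
    standard_deconvolve,
)
from scdecomp.deconv import nonnegative_deconvolve_reference

from conftest import FS, raised_cosine, scr_signal


def _random_sparse_driver(rng, n):
    """Nonnegative driver with a few compact bumps on a zero baseline."""
    q = np.zeros(n)
    for _ in range(rng.integers(1, 4)):
        start = int(rng.integers(0, n - 20))
        width = int(rng.integers(4, 16))
        q[start : start + width] += rng.uniform(0.1, 2.0, width)
    return q


class TestConvolve:
    def test_zero_driver(self, slow_kernel):
        out = convolve(Signal(np.zeros(100), fs=FS), slow_kernel)
        assert np.all(out.values == 0)

    def test_impulse_sifting(self, slow_kernel):
        """A unit impulse of height 1/dt reproduces the kernel one index later."""
        n = 400
        q = np.zeros(n)
        j = 7
        q[j] = FS  # height 1/dt
        out = convolve(Signal(q, fs=FS), slow_kernel)
        assert np.allclose(out.values[:j], 0, atol=1e-14)
        m = n - j
        assert np.allclose(out.values[j : j + m], slow_kernel.samples[:m], atol=1e-12)

    def test_linearity_superposition(self, slow_kernel):
        n = 800
        q1, q2 = np.zeros(n), np.zeros(n)
        q1[100] = 3.0
        q2[100 + int(4 * FS)] = 1.5
        both = convolve(Signal(q1 + q2, fs=FS), slow_kernel).values
        sep = (
            convolve(Signal(q1, fs=FS), slow_kernel).values
            + convolve(Signal(q2, fs=FS), slow_kernel).values
        )
        assert np.allclose(both, sep, atol=1e-12)

    def test_dt_mismatch_rejected(self, slow_kernel):
        with pytest.raises(SamplingRateError):
            convolve(Signal(np.ones(10), fs=64.0), slow_kernel)


class TestStandardDeconvolve:
    def test_round_trip_arbitrary_driver(self, short_kernel):
        rng = np.random.default_rng(0)
        q = rng.normal(0, 1, 512)  # includes negative values
        s = convolve(Signal(q, fs=1 / short_kernel.dt), short_kernel)
        back = standard_deconvolve(s, short_kernel)
        assert np.allclose(back.values, q, atol=1e-6)

    def test_kernel_deconvolves_to_impulse(self, short_kernel):
        fs = 1 / short_kernel.dt
        s = Signal(short_kernel.samples.copy(), fs=fs)
        q = standard_deconvolve(s, short_kernel)
        assert q.values[0] == pytest.approx(fs, rel=1e-9)
        assert np.allclose(q.values[1:], 0, atol=1e-6)

    def test_peaked_scr_goes_negative(self, slow_kernel):
        """With a slow-recovery kernel, a peaked SCR forces negative driver values."""
        n = int(60 * FS)
        t = np.arange(n) / FS
        flat = np.convolve(
            raised_cosine(t, 5, 1.0, 3.0), slow_kernel.samples * slow_kernel.dt
        )[:n]
        peaked = flat + raised_cosine(t, 6.0, 3.0, 0.08)
        q = standard_deconvolve(Signal(peaked, fs=FS), slow_kernel)
        assert q.values.min() < 0


class TestNonnegativeDeconvolve:
    def test_exact_driver_recovery(self, slow_kernel):
        """Well-separated compact impulses are recovered with ~zero remainder."""
        sig, q0 = scr_signal([(5.0, 2.0), (30.0, 1.0)], slow_kernel)
        res = nonnegative_deconvolve(sig, slow_kernel)
        assert np.allclose(res.driver.values, q0, atol=1e-6)
        assert np.allclose(res.remainder.values, 0, atol=1e-8)

    def test_kernel_input_yields_impulse(self, short_kernel):
        fs = 1 / short_kernel.dt
        res = nonnegative_deconvolve(Signal(short_kernel.samples.copy(), fs=fs), short_kernel)
        assert res.driver.values[0] == pytest.approx(fs, rel=1e-9)
        assert np.allclose(res.remainder.values, 0, atol=1e-9)

    def test_peaked_scr_splits_into_impulse_and_remainder(self, slow_kernel):
        n = int(60 * FS)
        t = np.arange(n) / FS
        flat = np.convolve(
            raised_cosine(t, 5, 1.0, 3.0), slow_kernel.samples * slow_kernel.dt
        )[:n]
        peaked = flat + raised_cosine(t, 6.0, 3.0, 0.08)
        res = nonnegative_deconvolve(Signal(peaked, fs=FS), slow_kernel)
        assert np.all(res.driver.values >= 0)
        assert res.remainder.values.min() >= -1e-9
        assert res.remainder.values.max() > 0.01  # distinct positive deflection

    def test_additive_reconstruction_identity(self, short_kernel):
        """driver * kernel + remainder reproduces any input sample by sample."""
        rng = np.random.default_rng(1)
        fs = 1 / short_kernel.dt
        for _ in range(10):
            s = Signal(rng.uniform(0, 1, 300), fs=fs)
            res = nonnegative_deconvolve(s, short_kernel)
            rec = convolve(res.driver, short_kernel).values + res.remainder.values
            assert np.allclose(rec, s.values, atol=1e-8)
            assert np.all(res.driver.values >= 0)

    def test_area_conservation(self, short_kernel):
        """Unit-area division is area-neutral: driver + remainder mass equals
        the signal mass (driver supported away from the right edge)."""
        rng = np.random.default_rng(2)
        fs = 1 / short_kernel.dt
        n = 700
        k = len(short_kernel.samples)
        q = np.zeros(n)
        q[: n - k - 50] = _random_sparse_driver(rng, n - k - 50)
        extra = np.zeros(n)
        extra[60:90] = 0.05
        s = convolve(Signal(q, fs=fs), short_kernel).with_values(
            convolve(Signal(q, fs=fs), short_kernel).values + extra
        )
        res = nonnegative_deconvolve(s, short_kernel)
        total = (res.driver.values.sum() + res.remainder.values.sum()) / fs
        assert total == pytest.approx(s.values.sum() / fs, rel=1e-6)

    def test_monotone_nesting_under_standard(self, short_kernel):
        """On exactly generated inputs the nonnegative driver never exceeds
        the standard quotient."""
        rng = np.random.default_rng(3)
        fs = 1 / short_kernel.dt
        q = _random_sparse_driver(rng, 350)
        s = convolve(Signal(q, fs=fs), short_kernel)
        nn = nonnegative_deconvolve(s, short_kernel).driver.values
        std = standard_deconvolve(s, short_kernel).values
        assert np.all(nn <= std + 1e-9)

    def test_oracle_equivalence(self, short_kernel):
        """Optimised division matches the literal per-sample simulation."""
        rng = np.random.default_rng(4)
        fs = 1 / short_kernel.dt
        for _ in range(15):
            n = int(rng.integers(64, 512))
            s = Signal(rng.uniform(0, 1, n), fs=fs)
            fast = nonnegative_deconvolve(s, short_kernel)
            slow = nonnegative_deconvolve_reference(s, short_kernel)
            assert np.allclose(fast.driver.values, slow.driver.values, atol=1e-10)
            assert np.allclose(fast.remainder.values, slow.remainder.values, atol=1e-10)

    def test_noise_floor_oracle_equivalence(self, short_kernel):
        rng = np.random.default_rng(5)
        fs = 1 / short_kernel.dt
        s = Signal(rng.uniform(-0.1, 1, 300), fs=fs)
        fast = nonnegative_deconvolve(s, short_kernel, noise_floor=0.05)
        slow = nonnegative_deconvolve_reference(s, short_kernel, noise_floor=0.05)
        assert np.allclose(fast.driver.values, slow.driver.values, atol=1e-10)
        assert np.allclose(fast.remainder.values, slow.remainder.values, atol=1e-10)


class TestGaussianSmooth:
    def test_constant_preserved(self):
        s = Signal(np.full(500, 3.3), fs=FS)
        out = gaussian_smooth(s, 0.2)
        assert np.allclose(out.values, 3.3, atol=1e-12)

    def test_mass_preserved_for_interior_support(self):
        n = 600
        v = np.zeros(n)
        v[250:280] = 1.7
        out = gaussian_smooth(Signal(v, fs=FS), 0.2)
        assert out.values.sum() == pytest.approx(v.sum(), abs=1e-6)

    def test_impulse_response_is_renormalized_gaussian(self):
        sigma_s = 0.2
        sigma = sigma_s * FS
        radius = int(4 * sigma + 0.5)
        n = 2 * radius + 41
        v = np.zeros(n)
        v[n // 2] = 1.0
        out = gaussian_smooth(Signal(v, fs=FS), sigma_s).values
        x = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (x / sigma) ** 2)
        w /= w.sum()
        assert np.allclose(out[n // 2 - radius : n // 2 + radius + 1], w, atol=1e-12)

    def test_sigma_zero_is_identity(self):
        s = Signal(np.random.default_rng(0).normal(size=64), fs=FS)
        assert gaussian_smooth(s, 0.0) is s


class TestFadeIn:
    def test_zero_start_gives_zero_prefix(self, slow_kernel):
        phasic = Signal(np.zeros(50), fs=FS)
        ext, plen = fade_in_extend(phasic, slow_kernel)
        assert plen == slow_kernel.rising_length
        assert np.all(ext.values[:plen] == 0)

    def test_prefix_matches_first_sample(self, slow_kernel):
        phasic = Signal(np.full(50, 1.0), fs=FS)
        ext, plen = fade_in_extend(phasic, slow_kernel)
        assert ext.values[plen - 1] == pytest.approx(1.0, abs=1e-12)
        assert len(ext) == plen + 50

    def test_junction_continuity(self, slow_kernel):
        phasic = Signal(np.linspace(0.8, 1.2, 50), fs=FS)
        ext, plen = fade_in_extend(phasic, slow_kernel)
        rise = ext.values[:plen]
        max_step = np.max(np.abs(np.diff(rise))) if plen > 1 else 1.0
        assert abs(ext.values[plen] - ext.values[plen - 1]) <= max_step + 1e-9
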