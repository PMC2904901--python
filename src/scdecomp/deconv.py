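"""Signal container and the deconvolution algebra at the heart of the method.

Skin conductance is modelled as the convolution of a nonnegative, compactly
supported driver (sudomotor burst activity) with the Bateman impulse response,
on top of a slow tonic level.  Standard deconvolution inverts the convolution
exactly but produces negative driver excursions whenever an SCR deviates from
the kernel shape.  Nonnegative deconvolution — long division that considers
the entire divisor and takes the overall minimum of the per-digit quotients —
yields a nonnegative driver plus a nonnegative remainder that captures shape
deviations (attributed to pore opening).

All convolutions carry an explicit ``dt`` factor and kernels are unit-area in
the ``dt`` sense, so signals, drivers and remainders all live in microsiemens
and the method's amplitude thresholds apply at any sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve, lfilter

from .errors import KernelDomainError, SamplingRateError
from .kernel import DiscreteKernel

__all__ = [
    "Signal",
    "NonnegDeconvResult",
    "convolve",
    "standard_deconvolve",
    "biexponential_inverse",
    "nonnegative_deconvolve",
    "nonnegative_deconvolve_reference",
    "estimate_noise_floor",
    "gaussian_smooth",
    "fade_in_extend",
]

# Above this operation count np.convolve's direct O(N*K) loop is replaced by
# an FFT product; below it, direct evaluation keeps bitwise-reproducible sums.
_FFT_THRESHOLD = 2_000_000


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled time series (conductance or driver, microsiemens).

    ``t0`` is the time of the first sample, so sample ``i`` sits at
    ``t0 + i / fs``.
    """

    values: np.ndarray = field(repr=False)
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) < 1:
            raise ValueError("signal must be a non-empty 1-d array")
        if not np.all(np.isfinite(values)):
            raise ValueError("signal contains non-finite values")
        if self.fs <= 0:
            raise SamplingRateError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    def with_values(self, values: np.ndarray) -> "Signal":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class NonnegDeconvResult:
    """Nonnegative driver and remainder; driver * kernel + remainder = input."""

    driver: Signal
    remainder: Signal


def _check_dt(signal: Signal, kernel: DiscreteKernel) -> None:
    if abs(signal.dt - kernel.dt) > 1e-12 * kernel.dt:
        raise SamplingRateError(
            f"signal dt {signal.dt} does not match kernel dt {kernel.dt}"
        )


def convolve(driver: Signal, kernel: DiscreteKernel) -> Signal:
    """Discrete convolution with the kernel, truncated to the driver length.

    ``out[t] = sum_k kernel[k] * driver[t - k] * dt``.  With a unit-area
    kernel this has DC gain 1: a constant driver maps to the same constant
    (away from the start-up transient).
    """
    _check_dt(driver, kernel)
    h = kernel.samples * kernel.dt
    n = len(driver)
    if n * len(h) > _FFT_THRESHOLD:
        out = fftconvolve(driver.values, h)[:n]
    else:
        out = np.convolve(driver.values, h)[:n]
    return driver.with_values(out)


def standard_deconvolve(signal: Signal, kernel: DiscreteKernel) -> Signal:
    """Exact inverse of :func:`convolve` by recursive long division.

    Computes the unique q with ``convolve(q, kernel) == signal`` on the
    signal's support:

        q[t] = (s[t] - sum_{k>=1} h[k] * q[t-k] * dt) / (h[0] * dt)

    which is an all-pole filter, evaluated with :func:`scipy.signal.lfilter`.
    The quotient may contain negative values; for an SCR shape deviating from
    the kernel it generally does.
    """
    _check_dt(signal, kernel)
    h = kernel.samples * kernel.dt
    if h[0] <= 0:
        raise KernelDomainError("kernel leading sample must be positive")
    q = lfilter([1.0], h, signal.values)
    return signal.with_values(q)


def biexponential_inverse(signal: Signal, kernel: DiscreteKernel) -> Signal:
    """Stable closed-form deconvolution for the biexponential kernel.

    The sampled Bateman kernel is an AR(2) process; its exact inverse is the
    three-tap whitening filter

        q[t] = (s[t] - (a1 + a2) s[t-1] + a1 a2 s[t-2]) / (h[0] dt),

    with ``a_i = exp(-dt / tau_i)``.  Unlike the long-division recursion of
    :func:`standard_deconvolve` — whose truncated-kernel inverse is
    marginally unstable and diverges on recordings of many thousands of
    samples — this form is unconditionally stable, at the price of a
    relative round-trip error of order of the truncated tail area (~1e-4).
    Used where a driver *estimate* is needed on long data (tonic stage).
    """
    _check_dt(signal, kernel)
    a1 = np.exp(-kernel.dt / kernel.params.tau1)
    a2 = np.exp(-kernel.dt / kernel.params.tau2)
    taps = np.array([1.0, -(a1 + a2), a1 * a2]) / (kernel.samples[0] * kernel.dt)
    q = np.convolve(signal.values, taps)[: len(signal)]
    return signal.with_values(q)


def nonnegative_deconvolve(
    signal: Signal, kernel: DiscreteKernel, noise_floor: float = 0.0
) -> NonnegDeconvResult:
    """Long division with a nonnegativity constraint and a remainder.

    Walking left to right through the signal, the quotient digit at t is the
    overall minimum over the whole divisor of the residual-to-divisor ratios,

        q[t] = max(0, min_k r[t+k] / (h[k] * dt)),

    after which ``q[t] * h * dt`` is subtracted from the residual.  The final
    residual is the remainder.  The driver is nonnegative by construction; for
    inputs generated from a nonnegative driver plus a nonnegative extra the
    remainder is nonnegative too, and the additive reconstruction
    ``convolve(driver, kernel) + remainder == signal`` holds exactly.  Near
    the right edge the minimum ranges only over kernel indices that stay
    inside the signal, so no data beyond the recording is fabricated.

    ``noise_floor`` makes the division robust on noisy recordings: the
    minimum stops at the first residual sample at or below the floor (but
    always covers at least the kernel's rising limb), so measurement noise
    deep in the kernel tail — where the divisor is tiny and ratios explode —
    cannot clamp the driver.  With the default floor of 0 this is exactly
    the unrestricted minimum: the first nonpositive residual already forces
    the digit to zero, so stopping there changes nothing.
    """
    _check_dt(signal, kernel)
    hd = kernel.samples * kernel.dt
    if np.any(hd <= 0):
        raise KernelDomainError("all kernel samples must be strictly positive")
    if noise_floor < 0:
        raise ValueError(f"noise_floor must be nonnegative, got {noise_floor}")
    n = len(signal)
    k = len(hd)
    rising = kernel.rising_length
    r = signal.values.copy()
    q = np.zeros(n)
    for t in range(n):
        m = k if t + k <= n else n - t
        window = r[t : t + m]
        below = np.flatnonzero(window <= noise_floor)
        # include the first at-or-below-floor sample: it is the binding digit
        end = min(below[0] + 1, m) if below.size else m
        end = min(max(end, rising), m)
        v = np.min(window[:end] / hd[:end])
        if v > 0:
            q[t] = v
            window -= v * hd[:m]
    return NonnegDeconvResult(
        driver=signal.with_values(q),
        remainder=signal.with_values(r),
    )


def nonnegative_deconvolve_reference(
    signal: Signal, kernel: DiscreteKernel, noise_floor: float = 0.0
) -> NonnegDeconvResult:
    """Literal per-sample transcription of the division, one scalar at a time.

    O(N*K) with explicit Python loops; serves as an independent oracle for the
    vectorised implementation in tests and is far too slow for real use.
    """
    _check_dt(signal, kernel)
    hd = [h * kernel.dt for h in kernel.samples.tolist()]
    if any(h <= 0 for h in hd):
        raise KernelDomainError("all kernel samples must be strictly positive")
    rising = kernel.rising_length
    r = signal.values.tolist()
    n = len(r)
    q = [0.0] * n
    for t in range(n):
        best = None
        seen_below = False
        for j, h in enumerate(hd):
            if t + j >= n:
                break
            ratio = r[t + j] / h
            if best is None or ratio < best:
                best = ratio
            if r[t + j] <= noise_floor:
                seen_below = True
            if seen_below and j + 1 >= rising:
                break
        if best is not None and best > 0:
            q[t] = best
            for j, h in enumerate(hd):
                if t + j >= n:
                    break
                r[t + j] -= best * h
    return NonnegDeconvResult(
        driver=signal.with_values(np.array(q)),
        remainder=signal.with_values(np.array(r)),
    )


def estimate_noise_floor(signal: Signal, k_sigma: float = 4.0) -> float:
    """Robust noise-amplitude estimate from second differences.

    The median absolute second difference ignores both level and slope of
    the smooth SCR content and scales with the white-noise sigma as
    sqrt(6)/1.4826; the returned floor is ``k_sigma`` of those sigmas
    (effectively 0 for noise-free data).
    """
    if len(signal) < 3:
        return 0.0
    d2 = np.abs(np.diff(signal.values, n=2))
    return float(k_sigma * 1.4826 * np.median(d2) / np.sqrt(6.0))


def gaussian_smooth(signal: Signal, sigma: float) -> Signal:
    """Convolve with a unit-sum Gaussian window truncated at +/- 4 sigma.

    ``sigma`` is in seconds; edges are handled by reflection.  Deconvolution
    amplifies noise, so the driver and remainder are smoothed before peak
    detection; sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma}")
    if sigma == 0:
        return signal
    out = gaussian_filter1d(signal.values, sigma * signal.fs, mode="reflect", truncate=4.0)
    return signal.with_values(out)


def fade_in_extend(phasic: Signal, kernel: DiscreteKernel) -> tuple[Signal, int]:
    """Prefix the phasic data with a smooth fade-in to avoid onset artifacts.

    The rising limb of the kernel (samples up to and including its maximum)
    is rescaled so its last sample equals the first phasic sample, and
    prepended to the data.  If the first sample is not positive, a zero
    prefix of the same length is used.  Returns the extended signal and the
    prefix length so downstream indices can be restored.
    """
    rise = kernel.samples[: kernel.rising_length]
    first = phasic.values[0]
    if first > 0:
        prefix = rise * (first / rise[-1])
    else:
        prefix = np.zeros_like(rise)
    extended = Signal(
        values=np.concatenate([prefix, phasic.values]),
        fs=phasic.fs,
        t0=phasic.t0 - len(prefix) * phasic.dt,
    )
    return extended, len(prefix)
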