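"""Bateman impulse response: the standard skin-conductance-response shape.

The sweat-diffusion part of a skin conductance response (SCR) is modelled as a
two-compartment process: sweat enters the duct, diffuses forward into the
corneum and is eliminated from there, both steps first order.  The resulting
impulse response is the biexponential Bateman function

    b(t) = exp(-t / tau2) - exp(-t / tau1),   t >= 0,

with a steep rise governed by ``tau1`` and a slow recovery governed by
``tau2``.  This module evaluates the kernel, characterises it (peak time,
half-recovery time) and samples it as a discrete unit-area kernel suitable for
convolution and deconvolution of sampled recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterDomainError, TruncationError

__all__ = [
    "BatemanParams",
    "DiscreteKernel",
    "bateman",
    "peak_time",
    "half_recovery_time",
    "discretize_unit_area",
]

#: Relative tail-area bound enforced by requiring duration >= 10 * tau2.
_MIN_DURATION_TAU2 = 10.0


@dataclass(frozen=True)
class BatemanParams:
    """Time constants of the Bateman kernel, in seconds.

    ``tau1`` (rise) must be strictly smaller than ``tau2`` (recovery); the
    degenerate equal-constant limit is rejected rather than replaced by its
    limiting form, because the optimiser enforces a minimum ratio anyway.
    """

    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ParameterDomainError(
                f"time constants must be positive, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if not self.tau1 < self.tau2:
            raise ParameterDomainError(
                f"tau1 must be strictly smaller than tau2, got tau1={self.tau1}, tau2={self.tau2}"
            )


@dataclass(frozen=True)
class DiscreteKernel:
    """Unit-area sampling of the Bateman kernel.

    ``samples[k]`` holds ``b((k + 1) * dt)`` rescaled so that
    ``sum(samples) * dt == 1``.  The t = 0 sample is excluded: b(0) = 0 would
    make the leading coefficient of the deconvolution's long division zero.
    As a consequence the discrete response to an impulse at index j begins at
    index j, one sample early in time; latency reporting corrects this offset.
    """

    samples: np.ndarray = field(repr=False)
    dt: float
    params: BatemanParams

    @property
    def duration(self) -> float:
        """Temporal support of the sampled kernel, in seconds."""
        return len(self.samples) * self.dt

    @property
    def rising_length(self) -> int:
        """Number of samples up to and including the kernel maximum."""
        return int(np.argmax(self.samples)) + 1


def bateman(t, params: BatemanParams):
    """Evaluate b(t) = exp(-t/tau2) - exp(-t/tau1); zero for t <= 0.

    Accepts scalars or arrays; the return type follows numpy broadcasting.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(
        t > 0,
        np.exp(-t / params.tau2) - np.exp(-t / params.tau1),
        0.0,
    )
    if out.ndim == 0:
        return float(out)
    return out


def peak_time(params: BatemanParams) -> float:
    """Time of the kernel maximum: tau1*tau2/(tau2 - tau1) * ln(tau2/tau1)."""
    t1, t2 = params.tau1, params.tau2
    return t1 * t2 / (t2 - t1) * np.log(t2 / t1)


def half_recovery_time(params: BatemanParams, reference: str = "from_onset") -> float:
    """Time at which the recovery limb falls to 50% of the kernel peak.

    Parameters
    ----------
    params
        Kernel time constants.
    reference
        ``"from_onset"`` measures from t = 0 (response onset);
        ``"from_peak"`` subtracts the peak time, matching the classical
        "time from SCR peak to 50% recovery" definition.
    """
    if reference not in ("from_onset", "from_peak"):
        raise ValueError(f"unknown reference {reference!r}")
    tp = peak_time(params)
    half = 0.5 * bateman(tp, params)
    # Bracket the root on the recovery limb: expand until b drops below half.
    hi = tp + params.tau2
    while bateman(hi, params) > half:
        hi += params.tau2
    t_half = brentq(lambda t: bateman(t, params) - half, tp, hi, xtol=1e-9)
    if reference == "from_peak":
        return t_half - tp
    return t_half


def discretize_unit_area(
    params: BatemanParams, fs: float, duration: float | None = None
) -> DiscreteKernel:
    """Sample the kernel at t = dt, 2*dt, ... and rescale to unit area.

    ``duration`` must be at least ``10 * tau2`` so the omitted tail carries
    less than 1e-4 of the total area; when omitted it defaults to exactly
    that bound.  Unit area (``sum * dt == 1``) makes convolution with the
    kernel a unit-DC-gain operation, so driver amplitudes and thresholds
    remain in microsiemens at any sampling rate.
    """
    if fs <= 0:
        raise ParameterDomainError(f"sampling rate must be positive, got {fs}")
    if duration is None:
        duration = _MIN_DURATION_TAU2 * params.tau2
    if duration < _MIN_DURATION_TAU2 * params.tau2:
        raise TruncationError(
            f"kernel duration {duration} s too short; need >= {_MIN_DURATION_TAU2 * params.tau2} s "
            f"(10 * tau2) to bound the truncated tail area"
        )
    dt = 1.0 / fs
    n = int(round(duration * fs))
    t = np.arange(1, n + 1) * dt
    samples = np.exp(-t / params.tau2) - np.exp(-t / params.tau1)
    samples /= samples.sum() * dt
    return DiscreteKernel(samples=samples, dt=dt, params=params)
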