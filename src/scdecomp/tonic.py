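"""Tonic (baseline) estimation from inter-impulse sections of the driver.

The slowly varying skin conductance level is estimated in driver space: the
recording is standard-deconvolved with the Bateman kernel (unit DC gain keeps
the driver in microsiemens), smoothed, and segmented by peak detection.  All
samples that belong to no impulse section reflect non-overlapped tonic
activity; they are averaged on a 100-s grid and interpolated with a cubic
spline.  Subtracting the interpolated tonic from the raw data yields phasic
data, a pure superposition of SCRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .deconv import Signal, biexponential_inverse, gaussian_smooth
from .errors import InsufficientDataError
from .kernel import DiscreteKernel

__all__ = [
    "PeakSection",
    "TonicModel",
    "detect_peaks",
    "estimate_tonic",
    "subtract_tonic",
    "tonic_variability",
]


@dataclass(frozen=True)
class PeakSection:
    """A significant peak and the flanking local minima that delimit it."""

    onset_index: int
    peak_index: int
    offset_index: int
    prominence: float

    def __post_init__(self) -> None:
        if not self.onset_index <= self.peak_index <= self.offset_index:
            raise ValueError("section indices must be ordered onset <= peak <= offset")


def _local_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior maxima and minima, plateaus collapsed to their first sample."""
    run_starts = np.flatnonzero(np.concatenate([[True], np.diff(values) != 0]))
    w = values[run_starts]
    if len(w) < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.sign(np.diff(w))
    interior = np.arange(1, len(w) - 1)
    maxima = run_starts[interior[(d[:-1] > 0) & (d[1:] < 0)]]
    minima = run_starts[interior[(d[:-1] < 0) & (d[1:] > 0)]]
    return maxima, minima


def detect_peaks(signal: Signal, delta: float) -> list[PeakSection]:
    """Segment a (pre-smoothed) signal into significant peak sections.

    Local extrema are found through sign changes of the first difference.  A
    maximum is significant if it rises by at least ``delta`` above its
    preceding or its following local minimum; its section spans those two
    minima.  Signal boundaries act as local minima, so sections never extend
    past the recording.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    v = signal.values
    n = len(v)
    maxima, _ = _local_extrema(v)
    sections: list[PeakSection] = []
    for p in maxima:
        # Walk down each limb to the flanking local minima.  The strict
        # comparison stops at the near edge of any plateau, so a flat valley
        # contributes its closest sample and stays inter-impulse otherwise.
        i = p
        while i > 0 and v[i - 1] < v[i]:
            i -= 1
        j = p
        while j < n - 1 and v[j + 1] < v[j]:
            j += 1
        prominence = max(v[p] - v[i], v[p] - v[j])
        if prominence >= delta:
            sections.append(PeakSection(int(i), int(p), int(j), float(prominence)))
    return sections


@dataclass(frozen=True)
class TonicModel:
    """Tonic level on a coarse time grid plus a cubic-spline interpolant.

    Natural boundary conditions (zero second derivative) are used and the
    tonic is held constant beyond the outermost grid points, which prevents
    cubic blow-up at the recording edges.
    """

    grid_times: np.ndarray = field(repr=False)
    grid_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        gt = np.asarray(self.grid_times, dtype=float)
        gv = np.asarray(self.grid_values, dtype=float)
        if gt.ndim != 1 or gt.shape != gv.shape or len(gt) < 1:
            raise ValueError("grid_times and grid_values must be matching 1-d arrays")
        if len(gt) > 1 and not np.all(np.diff(gt) > 0):
            raise ValueError("grid_times must be strictly increasing")
        object.__setattr__(self, "grid_times", gt)
        object.__setattr__(self, "grid_values", gv)
        spline = None
        if len(gt) > 1:
            spline = CubicSpline(gt, gv, bc_type="natural")
        object.__setattr__(self, "_spline", spline)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self._spline is None:
            out = np.full_like(t, self.grid_values[0])
        else:
            out = self._spline(np.clip(t, self.grid_times[0], self.grid_times[-1]))
        return out if out.ndim else float(out)


def estimate_tonic(
    sc: Signal,
    kernel: DiscreteKernel,
    grid_spacing: float = 100.0,
    smooth_sigma: float = 0.2,
    delta: float = 0.2,
) -> TonicModel:
    """Estimate the tonic component of a raw recording (decomposition step 1).

    Pipeline: standard deconvolution, Gaussian smoothing, peak detection
    with threshold ``delta``; the complement of all peak sections supplies
    inter-impulse driver samples, which are averaged within half a grid
    spacing of each grid point.  Grid points are placed at the start of the
    recording, every ``grid_spacing`` seconds, and at the final sample;
    points with no inter-impulse samples in range are omitted and bridged by
    the spline.

    A recording that starts at its tonic level would deconvolve to a huge
    one-off onset impulse whose truncated-kernel tail leaves artifacts far
    into the driver.  Since the unit-DC-gain kernel maps a constant onto
    itself, the initial level is subtracted before the division and added
    back to the driver afterwards, which removes the artifact exactly for a
    constant start; the first smoothing-window of samples is excluded from
    the averaging as well.
    """
    if len(sc) < 2:
        raise InsufficientDataError("recording must contain at least 2 samples")
    # Deconvolution and Gaussian smoothing are both LTI, so smoothing the
    # data first is the same operator as smoothing the driver afterwards —
    # but vastly better conditioned, since the whitening inverse amplifies
    # raw sample noise by 1/(h[0] dt).
    smoothed = gaussian_smooth(sc, smooth_sigma)
    level = float(smoothed.values[0])
    q = biexponential_inverse(smoothed.with_values(smoothed.values - level), kernel)
    qs = q.with_values(q.values + level)
    # The outermost 4-sigma margins of the smoothed driver carry reflection
    # and onset artifacts: peaks are detected on the interior only and the
    # margins are excluded from the inter-impulse averaging.
    n = len(qs)
    edge = int(np.ceil(4 * smooth_sigma * sc.fs)) + 8
    inter = np.ones(n, dtype=bool)
    if n > 2 * edge + 16:
        interior = Signal(qs.values[edge : n - edge], fs=qs.fs, t0=qs.t0 + edge * qs.dt)
        # Impulses appear as peaks; sharp deviations from the assumed kernel
        # shape whiten into oscillations with equally phasic troughs, so both
        # polarities are excluded from the tonic estimate.
        sections = [
            PeakSection(
                s.onset_index + edge, s.peak_index + edge, s.offset_index + edge, s.prominence
            )
            for flipped in (interior, interior.with_values(-interior.values))
            for s in detect_peaks(flipped, delta)
        ]
        inter[:edge] = False
        inter[n - edge :] = False
    else:
        sections = detect_peaks(qs, delta) + detect_peaks(
            qs.with_values(-qs.values), delta
        )
    for s in sections:
        inter[s.onset_index : s.offset_index + 1] = False

    times = sc.times
    t_end = times[-1]
    grid = list(np.arange(sc.t0, t_end, grid_spacing))
    if not grid or t_end - grid[-1] > 1e-9:
        grid.append(t_end)
    grid_t, grid_v = [], []
    half = grid_spacing / 2.0
    for g in grid:
        sel = inter & (np.abs(times - g) <= half)
        if np.any(sel):
            grid_t.append(g)
            grid_v.append(float(np.mean(qs.values[sel])))
    if not grid_t:
        # Every sample sits inside an impulse section: fall back to the lowest
        # smoothed driver value as a conservative baseline.
        grid_t, grid_v = [sc.t0], [float(np.min(qs.values))]
    return TonicModel(np.array(grid_t), np.array(grid_v))


def subtract_tonic(sc: Signal, tonic: TonicModel) -> Signal:
    """Raw minus tonic: phasic data (may carry small negative noise values)."""
    return sc.with_values(sc.values - tonic(sc.times))


def tonic_variability(tonic_series: Signal, window: float = 10.0) -> float:
    """Mean absolute difference of successive window means, in uS per window.

    The standard comparison statistic for baseline stability: the series is
    cut into consecutive full windows (default 10 s), each window is
    averaged, and the absolute differences of succeeding window means are
    averaged.
    """
    samples_per_window = int(round(window * tonic_series.fs))
    n_windows = len(tonic_series) // samples_per_window
    if n_windows < 2:
        raise InsufficientDataError(
            f"series spans {n_windows} full window(s); need at least 2"
        )
    v = tonic_series.values[: n_windows * samples_per_window]
    means = v.reshape(n_windows, samples_per_window).mean(axis=1)
    return float(np.mean(np.abs(np.diff(means))))
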