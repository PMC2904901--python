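"""Phasic decomposition: segmentation, SCR reconstruction and scoring.

Once the tonic level is subtracted, the phasic data are nonnegatively
deconvolved into a driver (sudomotor impulses) and a remainder (deviations
from the standard SCR shape, interpreted as pore-opening components).  Both
are smoothed and segmented by peak detection; remainder deflections are
allotted to the impulse whose epoch contains their onset.  Each SCR is then
reconstructed as the convolution of its impulse with the kernel plus its
pore-opening (PO) segment, so amplitudes, areas and latencies are measured on
single, non-overlapped responses.  The classical trough-to-peak scoring is
provided as a baseline for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .deconv import (
    Signal,
    estimate_noise_floor,
    fade_in_extend,
    gaussian_smooth,
    nonnegative_deconvolve,
)
from .kernel import DiscreteKernel
from .tonic import detect_peaks

__all__ = [
    "Impulse",
    "POComponent",
    "ScrRecord",
    "EventMarker",
    "DriverDecomposition",
    "decompose_phasic",
    "reconstruct_scr",
    "filter_significant",
    "attribute_to_events",
    "trough_to_peak",
    "log_amplitude",
]


@dataclass(frozen=True)
class Impulse:
    """One compact driver impulse (one sudomotor burst).

    Times are in seconds and already corrected for the one-sample offset
    introduced by sampling the kernel from t = dt.  ``amplitude`` is the
    smoothed driver peak height; ``area`` the trapezoidal driver integral
    over the section (uS*s).
    """

    onset_time: float
    peak_time: float
    offset_time: float
    amplitude: float
    area: float
    onset_index: int
    peak_index: int
    offset_index: int

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time


@dataclass(frozen=True)
class POComponent:
    """A remainder deflection allotted to an impulse (pore opening).

    ``values`` carries the smoothed remainder over the deflection section so
    the component can be re-applied or detached without recomputation.
    ``merged`` flags epochs in which several remainder deflections were
    combined (summed area, maximum amplitude).
    """

    onset_time: float
    peak_time: float
    offset_time: float
    amplitude: float
    area: float
    parent: int
    onset_index: int
    peak_index: int
    offset_index: int
    values: np.ndarray = field(repr=False)
    merged: bool = False

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time


@dataclass(frozen=True)
class EventMarker:
    """A stimulus onset: time in seconds plus a label."""

    time: float
    label: str


@dataclass(frozen=True)
class DriverDecomposition:
    """Driver and remainder (raw and smoothed) with their segmentation.

    The driver's time origin sits one sample before the phasic data's: the
    kernel is sampled from t = dt, so deconvolved driver content runs one
    sample late and the shifted origin restores physical time.  The
    remainder lives on the signal's own grid.  ``po_components`` each carry
    the index of their parent impulse; ``prefix_len`` records the fade-in
    length used for the deconvolution (already stripped here).
    """

    driver: Signal
    remainder: Signal
    raw_driver: Signal
    raw_remainder: Signal
    impulses: list[Impulse]
    po_components: list[POComponent]
    prefix_len: int
    noise_floor: float

    def po_for(self, impulse_index: int) -> POComponent | None:
        for po in self.po_components:
            if po.parent == impulse_index:
                return po
        return None


@dataclass(frozen=True)
class ScrRecord:
    """One reconstructed, non-overlapped skin conductance response.

    ``waveform`` is local: it starts at the impulse onset and covers the
    impulse section convolved with the kernel plus the allotted PO segment.
    ``area`` is impulse area plus PO area — the unit-area kernel makes the
    deconvolution area-neutral, so this equals the SCR's own area.
    """

    impulse: Impulse
    po: POComponent | None
    waveform: Signal = field(repr=False)
    amplitude: float
    log_amplitude: float
    area: float
    event_label: str | None = None
    latency: float | None = None

    @property
    def onset_time(self) -> float:
        return self.impulse.onset_time


def log_amplitude(a: float) -> float:
    """log(1 + a): the standard transform for skewed SCR amplitudes."""
    if a < 0:
        raise ValueError(f"amplitude must be nonnegative, got {a}")
    return float(np.log1p(a))


#: Fraction of the raw-driver section maximum used to refine impulse support.
_SUPPORT_FRACTION = 0.001


def decompose_phasic(
    phasic: Signal,
    kernel: DiscreteKernel,
    smooth_sigma: float = 0.2,
    delta: float = 0.01,
    po_delta: float = 0.005,
    noise_floor: float | None = None,
) -> DriverDecomposition:
    """Decomposition steps 2 and 3: deconvolve, smooth, segment, allot.

    The phasic data are prefixed with the kernel-rise fade-in, nonnegatively
    deconvolved, and driver and remainder are Gaussian-smoothed before the
    prefix is stripped.  Impulses come from peak detection on the smoothed
    driver with threshold ``delta`` (0.01 uS, less conservative than the
    tonic stage); because smoothing advances every deflection onset by up to
    its window width, impulse onset and offset are then refined to the raw
    driver's support inside each section, which is exact for noise-free
    data.  Remainder deflections come from peak detection with ``po_delta``
    (0.005 uS), each allotted to the impulse whose epoch [onset, next onset)
    contains the deflection onset.  Deflections preceding the first
    impulse have no parent epoch and are discarded; several deflections in
    one epoch are merged (summed area, maximum amplitude).

    ``noise_floor`` is handed to the division; the default estimates it from
    the phasic data (see :func:`scdecomp.deconv.estimate_noise_floor`).
    """
    dt = phasic.dt
    if len(phasic) == 0 or not np.any(phasic.values != 0):
        empty = phasic.with_values(np.zeros(len(phasic)))
        shifted = Signal(empty.values, fs=phasic.fs, t0=phasic.t0 - dt)
        return DriverDecomposition(shifted, empty, shifted, empty, [], [], 0, 0.0)
    if noise_floor is None:
        noise_floor = estimate_noise_floor(phasic)
    extended, prefix_len = fade_in_extend(phasic, kernel)
    result = nonnegative_deconvolve(extended, kernel, noise_floor=noise_floor)
    driver_s = gaussian_smooth(result.driver, smooth_sigma)
    remainder_s = gaussian_smooth(result.remainder, smooth_sigma)
    # The driver grid runs one sample late (kernel sampled from t = dt);
    # shifting its origin restores physical time for all reported latencies.
    driver = Signal(driver_s.values[prefix_len:], fs=phasic.fs, t0=phasic.t0 - dt)
    raw_driver = Signal(result.driver.values[prefix_len:], fs=phasic.fs, t0=phasic.t0 - dt)
    remainder = Signal(remainder_s.values[prefix_len:], fs=phasic.fs, t0=phasic.t0)
    raw_remainder = Signal(result.remainder.values[prefix_len:], fs=phasic.fs, t0=phasic.t0)

    impulses: list[Impulse] = []
    for sec in detect_peaks(driver, delta):
        seg = driver.values[sec.onset_index : sec.offset_index + 1]
        raw_seg = raw_driver.values[sec.onset_index : sec.offset_index + 1]
        onset, offset = sec.onset_index, sec.offset_index
        support = np.flatnonzero(raw_seg > _SUPPORT_FRACTION * raw_seg.max())
        if support.size:
            onset = min(sec.onset_index + int(support[0]), sec.peak_index - 1)
            offset = max(sec.onset_index + int(support[-1]), sec.peak_index + 1)
        impulses.append(
            Impulse(
                onset_time=driver.t0 + onset * dt,
                peak_time=driver.t0 + sec.peak_index * dt,
                offset_time=driver.t0 + offset * dt,
                amplitude=float(driver.values[sec.peak_index]),
                area=float(np.trapezoid(seg, dx=dt)),
                onset_index=sec.onset_index,
                peak_index=sec.peak_index,
                offset_index=sec.offset_index,
            )
        )

    po_components: list[POComponent] = []
    if impulses:
        impulse_onsets = np.array([imp.onset_time for imp in impulses])
        per_epoch: dict[int, list[POComponent]] = {}
        for sec in detect_peaks(remainder, po_delta):
            onset_time = remainder.t0 + sec.onset_index * dt
            pos = int(np.searchsorted(impulse_onsets, onset_time, side="right")) - 1
            if pos < 0:
                continue  # precedes the first impulse: no parent epoch
            seg = remainder.values[sec.onset_index : sec.offset_index + 1]
            comp = POComponent(
                onset_time=onset_time,
                peak_time=remainder.t0 + sec.peak_index * dt,
                offset_time=remainder.t0 + sec.offset_index * dt,
                amplitude=float(remainder.values[sec.peak_index]),
                area=float(np.trapezoid(seg, dx=dt)),
                parent=pos,
                onset_index=sec.onset_index,
                peak_index=sec.peak_index,
                offset_index=sec.offset_index,
                values=seg.copy(),
            )
            per_epoch.setdefault(pos, []).append(comp)
        for pos in sorted(per_epoch):
            comps = per_epoch[pos]
            if len(comps) == 1:
                po_components.append(comps[0])
                continue
            first, last = comps[0], comps[-1]
            biggest = max(comps, key=lambda c: c.amplitude)
            seg = remainder.values[first.onset_index : last.offset_index + 1]
            po_components.append(
                POComponent(
                    onset_time=first.onset_time,
                    peak_time=biggest.peak_time,
                    offset_time=last.offset_time,
                    amplitude=biggest.amplitude,
                    area=float(sum(c.area for c in comps)),
                    parent=pos,
                    onset_index=first.onset_index,
                    peak_index=biggest.peak_index,
                    offset_index=last.offset_index,
                    values=seg.copy(),
                    merged=True,
                )
            )

    return DriverDecomposition(
        driver,
        remainder,
        raw_driver,
        raw_remainder,
        impulses,
        po_components,
        prefix_len,
        noise_floor,
    )


def _overlay(wave: np.ndarray, start: int, values: np.ndarray, sign: float) -> np.ndarray:
    """Add/subtract a segment at ``start``, clamping at the waveform edges.

    A pore-opening segment can begin one sample before its impulse section
    (epoch times carry the one-sample latency correction, remainder times do
    not); the clipped boundary sample is immaterial.
    """
    if start < 0:
        values = values[-start:]
        start = 0
    stop = start + len(values)
    if stop > len(wave):
        wave = np.concatenate([wave, np.zeros(stop - len(wave))])
    wave[start:stop] += sign * values
    return wave


def reconstruct_scr(
    impulse: Impulse,
    po: POComponent | None,
    decomposition: DriverDecomposition,
    kernel: DiscreteKernel,
) -> ScrRecord:
    """Decomposition step 4 for one response.

    The impulse section of the driver is convolved with the kernel and the
    allotted PO remainder segment is added in place, yielding the SCR as it
    would appear without any overlap.  By definition the SCR onset latency
    equals the impulse onset latency.
    """
    # The raw driver keeps the additive division identity exact, so a single
    # noise-free SCR reconstructs to the original phasic data; amplitudes and
    # areas are still quantified on the smoothed driver.
    driver = decomposition.raw_driver
    dt = driver.dt
    # The driver grid is index-aligned with the signal grid (its shifted t0
    # only serves latency reporting), so the waveform starts at the section
    # index on the signal's own time base.
    t0_wave = driver.t0 + dt + impulse.onset_index * dt
    seg = driver.values[impulse.onset_index : impulse.offset_index + 1]
    wave_len = len(seg) + len(kernel.samples)
    wave = np.zeros(wave_len)
    wave[: wave_len - 1] = np.convolve(seg, kernel.samples * dt)
    if po is not None:
        wave = _overlay(wave, int(round((po.onset_time - t0_wave) * driver.fs)), po.values, +1.0)
    waveform = Signal(wave, fs=driver.fs, t0=t0_wave)
    amplitude = float(wave.max())
    area = impulse.area + (po.area if po is not None else 0.0)
    return ScrRecord(
        impulse=impulse,
        po=po,
        waveform=waveform,
        amplitude=amplitude,
        log_amplitude=log_amplitude(max(amplitude, 0.0)),
        area=area,
    )


def filter_significant(
    scrs: list[ScrRecord],
    min_scr_amp: float = 0.01,
    min_po_amp: float = 0.005,
) -> list[ScrRecord]:
    """Apply the minimum-amplitude criteria.

    SCRs with amplitude below ``min_scr_amp`` are removed; PO components with
    amplitude below ``min_po_amp`` are detached from their SCR (the impulse
    is retained and the record is rebuilt without the PO overlay).  Both
    thresholds are inclusive: a component exactly at threshold is kept.
    """
    out: list[ScrRecord] = []
    for scr in scrs:
        if scr.po is not None and scr.po.amplitude < min_po_amp:
            start = int(round((scr.po.onset_time - scr.waveform.t0) * scr.waveform.fs))
            wave = _overlay(scr.waveform.values.copy(), start, scr.po.values, -1.0)
            amplitude = float(wave.max())
            scr = replace(
                scr,
                po=None,
                waveform=scr.waveform.with_values(wave),
                amplitude=amplitude,
                log_amplitude=log_amplitude(max(amplitude, 0.0)),
                area=scr.impulse.area,
            )
        if scr.amplitude >= min_scr_amp:
            out.append(scr)
    return out


def attribute_to_events(
    scrs: list[ScrRecord],
    events: list[EventMarker],
    window: tuple[float, float] = (1.0, 4.0),
) -> list[ScrRecord]:
    """Assign SCRs to stimulus events by onset latency within a window.

    An SCR qualifies for an event if its onset falls ``window[0]`` to
    ``window[1]`` seconds after the event.  Events are processed in temporal
    order; each takes the earliest qualifying unattributed SCR, so when event
    windows overlap the earlier event wins.  Returns new records; each SCR is
    attributed to at most one event.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window start must precede end, got {window}")
    scrs = sorted(scrs, key=lambda s: s.onset_time)
    taken = [False] * len(scrs)
    out = list(scrs)
    for ev in sorted(events, key=lambda e: e.time):
        for i, scr in enumerate(scrs):
            if taken[i]:
                continue
            latency = scr.onset_time - ev.time
            if lo <= latency <= hi:
                out[i] = replace(scr, event_label=ev.label, latency=latency)
                taken[i] = True
                break
    return out


def trough_to_peak(
    sc: Signal, min_amp: float = 0.01, smooth_sigma: float = 0.2
) -> list[tuple[float, float, float]]:
    """Classical SCR scoring: local minimum to following local maximum.

    Works on lightly smoothed raw data; amplitude is SC(peak) - SC(trough).
    Superposed SCRs riding on a recovery limb get systematically
    underestimated amplitudes and late onsets — the bias the decomposition
    avoids.  Returns (onset_time, peak_time, amplitude) triples at or above
    ``min_amp``.
    """
    smoothed = gaussian_smooth(sc, smooth_sigma)
    v = smoothed.values
    from .tonic import _local_extrema

    maxima, minima = _local_extrema(v)
    mins = np.unique(np.concatenate([[0], minima, [len(v) - 1]]))
    out = []
    for p in maxima:
        trough = mins[np.searchsorted(mins, p) - 1]
        amplitude = float(v[p] - v[trough])
        if amplitude >= min_amp:
            out.append(
                (
                    float(sc.t0 + trough * sc.dt),
                    float(sc.t0 + p * sc.dt),
                    amplitude,
                )
            )
    return out
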