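"""The full four-step decomposition for one recording at fixed kernel params.

Steps: (1) estimate and subtract the tonic component, (2) nonnegatively
deconvolve the phasic data, (3) segment driver and remainder into impulses
and pore-opening components, (4) reconstruct every SCR and recompose the
recording as tonic + sum of reconstructed SCRs.  The optimiser re-runs this
whole pipeline for each candidate (tau1, tau2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .deconv import Signal
from .kernel import BatemanParams, DiscreteKernel, discretize_unit_area
from .phasic import (
    DriverDecomposition,
    ScrRecord,
    decompose_phasic,
    filter_significant,
    reconstruct_scr,
)
from .tonic import TonicModel, estimate_tonic, subtract_tonic

__all__ = ["DecompositionResult", "run_decomposition"]


@dataclass(frozen=True)
class DecompositionResult:
    """Everything produced by one pass of the four decomposition steps.

    ``scrs`` holds the significant responses (minimum-amplitude criteria
    applied); ``all_scrs`` every reconstructed response.  ``recomposed`` is
    tonic plus the superposition of all reconstructed SCRs, aligned with the
    input; its residual against the raw data defines the model RMSE.
    """

    params: BatemanParams
    kernel: DiscreteKernel = field(repr=False)
    tonic: TonicModel
    phasic: Signal = field(repr=False)
    decomposition: DriverDecomposition
    scrs: list[ScrRecord]
    all_scrs: list[ScrRecord]
    recomposed: Signal = field(repr=False)
    rmse: float


def run_decomposition(
    sc: Signal, params: BatemanParams, config: RunConfig | None = None
) -> DecompositionResult:
    """Run the four decomposition steps on a raw recording."""
    config = config or RunConfig()
    kernel = discretize_unit_area(params, sc.fs)
    tonic = estimate_tonic(
        sc,
        kernel,
        grid_spacing=config.grid_spacing,
        smooth_sigma=config.tonic_smooth_sigma,
        delta=config.tonic_delta,
    )
    phasic = subtract_tonic(sc, tonic)
    decomposition = decompose_phasic(
        phasic,
        kernel,
        smooth_sigma=config.smooth_sigma,
        delta=config.segmentation_delta,
        po_delta=config.po_delta,
    )
    all_scrs = [
        reconstruct_scr(imp, decomposition.po_for(i), decomposition, kernel)
        for i, imp in enumerate(decomposition.impulses)
    ]
    scrs = filter_significant(
        all_scrs, min_scr_amp=config.min_scr_amp, min_po_amp=config.min_po_amp
    )
    recomposed = _recompose(sc, tonic, all_scrs)
    rmse = float(np.sqrt(np.mean((sc.values - recomposed.values) ** 2)))
    return DecompositionResult(
        params=params,
        kernel=kernel,
        tonic=tonic,
        phasic=phasic,
        decomposition=decomposition,
        scrs=scrs,
        all_scrs=all_scrs,
        recomposed=recomposed,
        rmse=rmse,
    )


def _recompose(sc: Signal, tonic: TonicModel, scrs: list[ScrRecord]) -> Signal:
    """Superpose tonic and all reconstructed SCR waveforms on the raw grid."""
    out = np.asarray(tonic(sc.times), dtype=float).copy()
    n = len(out)
    for scr in scrs:
        start = int(round((scr.waveform.t0 - sc.t0) * sc.fs))
        wave = scr.waveform.values
        lo = max(start, 0)
        hi = min(start + len(wave), n)
        if hi > lo:
            out[lo:hi] += wave[lo - start : hi - start]
    return sc.with_values(out)
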