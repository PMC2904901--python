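"""Reading recordings and writing decomposition results as columnar text.

Signals travel as one- or two-column CSV/TSV (time + conductance, or
conductance with an explicit sampling rate); events as (time, label) CSV.
Results are written as a time-series table, an SCR table mirroring the
standard response measures (onset/peak latency, duration, amplitude, area,
for impulse, pore-opening part and reconstructed SCR), and a JSON metadata
file echoing the configuration.  Times are in seconds in files; the CLI
summary prints milliseconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .deconv import Signal
from .errors import FormatError
from .phasic import EventMarker, ScrRecord
from .pipeline import DecompositionResult

__all__ = ["SCRecording", "read_recording", "write_results"]

#: Relative timestamp jitter above which a two-column file is rejected.
_JITTER_TOL = 0.01


@dataclass(frozen=True)
class SCRecording:
    """A raw conductance recording plus optional stimulus events."""

    signal: Signal
    events: list[EventMarker] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t_end = self.signal.t0 + (len(self.signal) - 1) / self.signal.fs
        for ev in self.events:
            if not self.signal.t0 <= ev.time <= t_end:
                raise ValueError(
                    f"event {ev.label!r} at {ev.time} s outside recording span "
                    f"[{self.signal.t0}, {t_end}] s"
                )


def _read_table(path: str | Path) -> pd.DataFrame:
    # Delimiter sniffing trips over scientific notation in one-column files,
    # so try the common delimiters explicitly.
    last_error: Exception | None = None
    for sep in (",", "\t", r"\s+"):
        try:
            df = pd.read_csv(path, sep=sep, header=None, comment="#", skip_blank_lines=True)
        except Exception as exc:  # malformed under this delimiter
            last_error = exc
            continue
        # Tolerate a header row of column names.
        try:
            df.iloc[0].astype(float)
        except (ValueError, TypeError):
            df = df.iloc[1:].reset_index(drop=True)
        try:
            return df.astype(float)
        except (ValueError, TypeError) as exc:
            last_error = exc
    raise FormatError(f"{path}: could not parse a numeric table ({last_error})")


def read_recording(
    signal_path: str | Path,
    events_path: str | Path | None = None,
    fs: float | None = None,
) -> SCRecording:
    """Load a recording from columnar text.

    Two columns are interpreted as (time s, conductance uS); the sampling
    rate is inferred from the median time step and the file is rejected if
    the timestamps jitter by more than 1% or are non-monotone.  A single
    column requires an explicit ``fs``.
    """
    df = _read_table(signal_path)
    if df.shape[1] == 2:
        times = df.iloc[:, 0].to_numpy()
        values = df.iloc[:, 1].to_numpy()
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise FormatError(f"{signal_path}: timestamps are not strictly increasing")
        dt = float(np.median(steps))
        if np.max(np.abs(steps - dt)) > _JITTER_TOL * dt:
            raise FormatError(
                f"{signal_path}: timestamp jitter exceeds {_JITTER_TOL:.0%} of the median step"
            )
        signal = Signal(values, fs=1.0 / dt, t0=float(times[0]))
    elif df.shape[1] == 1:
        if fs is None:
            raise FormatError(
                f"{signal_path}: single-column file needs an explicit sampling rate"
            )
        signal = Signal(df.iloc[:, 0].to_numpy(), fs=fs, t0=0.0)
    else:
        raise FormatError(f"{signal_path}: expected 1 or 2 columns, found {df.shape[1]}")

    events: list[EventMarker] = []
    if events_path is not None:
        edf = pd.read_csv(events_path, sep=None, engine="python", header=None, comment="#")
        try:
            edf.iloc[0, 0] = float(edf.iloc[0, 0])
        except (ValueError, TypeError):
            edf = edf.iloc[1:].reset_index(drop=True)
        for _, row in edf.iterrows():
            label = str(row.iloc[1]) if edf.shape[1] > 1 else ""
            events.append(EventMarker(time=float(row.iloc[0]), label=label))
    return SCRecording(signal=signal, events=events, metadata={"source": str(signal_path)})


def write_signal(signal: Signal, path: str | Path) -> None:
    """Write a (time, value) CSV readable by :func:`read_recording`."""
    pd.DataFrame({"time_s": signal.times, "sc_uS": signal.values}).to_csv(
        path, index=False, float_format="%.9g"
    )


def write_events(events: list[EventMarker], path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": [e.time for e in events], "label": [e.label for e in events]}
    ).to_csv(path, index=False)


def _scr_row(scr: ScrRecord) -> dict:
    imp, po = scr.impulse, scr.po
    row = {
        "impulse_onset_s": imp.onset_time,
        "impulse_peak_s": imp.peak_time,
        "impulse_duration_s": imp.duration,
        "impulse_amplitude_uS": imp.amplitude,
        "impulse_area_uSs": imp.area,
        "po_onset_s": po.onset_time if po else np.nan,
        "po_peak_s": po.peak_time if po else np.nan,
        "po_duration_s": po.duration if po else np.nan,
        "po_amplitude_uS": po.amplitude if po else np.nan,
        "po_area_uSs": po.area if po else np.nan,
        "scr_amplitude_uS": scr.amplitude,
        "scr_amplitude_log_uS": scr.log_amplitude,
        "scr_area_uSs": scr.area,
        "event_label": scr.event_label if scr.event_label is not None else "",
        "event_latency_s": scr.latency if scr.latency is not None else np.nan,
    }
    return row


def write_results(
    result: DecompositionResult,
    raw: Signal,
    config: RunConfig,
    out_dir: str | Path,
    criterion=None,
    optimization=None,
) -> dict[str, Path]:
    """Write timeseries.csv, scrs.csv and run_metadata.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "timeseries": out / "timeseries.csv",
        "scrs": out / "scrs.csv",
        "metadata": out / "run_metadata.json",
    }
    pd.DataFrame(
        {
            "time_s": raw.times,
            "raw_uS": raw.values,
            "tonic_uS": np.asarray(result.tonic(raw.times), dtype=float),
            "driver_uS": result.decomposition.driver.values,
            "remainder_uS": result.decomposition.remainder.values,
            "reconstructed_uS": result.recomposed.values,
        }
    ).to_csv(paths["timeseries"], index=False, float_format="%.10g")

    pd.DataFrame([_scr_row(s) for s in result.scrs]).to_csv(
        paths["scrs"], index=False, float_format="%.10g"
    )

    meta = {
        "software_version": __version__,
        "tau1": result.params.tau1,
        "tau2": result.params.tau2,
        "rmse_uS": result.rmse,
        "n_significant_scrs": len(result.scrs),
        "config": config.to_dict(),
    }
    if criterion is not None:
        meta["criterion"] = {
            "d_driver": criterion.d_driver,
            "d_remainder": criterion.d_remainder,
            "n": criterion.n,
            "rmse": criterion.rmse,
            "c": criterion.c,
        }
    if optimization is not None:
        meta["optimization"] = {
            "best_tau1": optimization.best.tau1,
            "best_tau2": optimization.best.tau2,
            "best_c": optimization.best_c,
            "improved": optimization.improved,
            "per_start": [
                {
                    "initial": [s.tau1, s.tau2],
                    "final": [f.tau1, f.tau2],
                    "final_c": c,
                }
                for s, f, c in optimization.per_start
            ],
            "iterations": optimization.iterations,
        }
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2)
    return paths
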