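"""Pipeline configuration with the method's published defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of the decomposition, with standard defaults.

    Amplitude thresholds are in microsiemens, times in seconds.  The driver
    and remainder discreteness thresholds feed the compound model criterion;
    the four initial tau sets span slow to fast recovery and the optimiser
    keeps the start with the lowest final criterion.
    """

    smooth_sigma: float = 0.2
    tonic_smooth_sigma: float = 1.0
    tonic_delta: float = 0.2
    segmentation_delta: float = 0.01
    po_delta: float = 0.005
    driver_discreteness_threshold: float = 0.2
    remainder_discreteness_threshold: float = 0.005
    min_scr_amp: float = 0.01
    min_po_amp: float = 0.005
    grid_spacing: float = 100.0
    response_window: tuple[float, float] = (1.0, 4.0)
    initial_tau_sets: tuple[tuple[float, float], ...] = (
        (0.75, 2.0),
        (0.75, 20.0),
        (0.75, 40.0),
        (0.75, 60.0),
    )
    max_iter: int = 50
    tol: float = 1e-4
    fd_rel_step: float = 0.05
    w_n: float = 0.05
    w_e: float = 10.0
    tau1_min: float = 0.05
    tau2_max: float = 300.0
    tau_ratio_min: float = 1.5
    log_base: str = "e"  # base of log(1+SC); recorded so outputs stay comparable

    def __post_init__(self) -> None:
        for name in (
            "smooth_sigma",
            "tonic_smooth_sigma",
            "tonic_delta",
            "segmentation_delta",
            "po_delta",
            "driver_discreteness_threshold",
            "remainder_discreteness_threshold",
            "min_scr_amp",
            "min_po_amp",
            "grid_spacing",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.response_window
        if not lo < hi:
            raise ValueError(f"response window start must precede end, got {self.response_window}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["response_window"] = list(self.response_window)
        d["initial_tau_sets"] = [list(t) for t in self.initial_tau_sets]
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a YAML mapping of field names to values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "response_window" in raw:
            raw["response_window"] = tuple(raw["response_window"])
        if "initial_tau_sets" in raw:
            raw["initial_tau_sets"] = tuple(tuple(t) for t in raw["initial_tau_sets"])
        return cls(**raw)
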