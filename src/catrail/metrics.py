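"""Closed-form assay metrics: Yoda1 sensitization, FRET efficiency, calcium ratio.

Three small formulas used around the simulations:

* Yoda1 sensitization — percent decrease in viability caused by adding Yoda1,
  100 × (V_DMSO − V_Yoda1) / V_DMSO.
* Donor-quenching FRET efficiency — E = 1 − (FI_double − FI_bg)/(FI_donor − FI_bg),
  from mean donor-channel intensities of the double-stained, donor-only and
  unstained samples.
* Ratiometric calcium — the median per-event Fluo-4/Fura Red ratio over an
  acquisition window (default the first 200 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensitizationInput",
    "FretInput",
    "RatioTrace",
    "FretResult",
    "RatioSummary",
    "yoda1_sensitization",
    "fret_efficiency",
    "ratiometric_median",
]


@dataclass(frozen=True)
class SensitizationInput:
    dmso_viability: float
    yoda_viability: float

    def __post_init__(self) -> None:
        for v in (self.dmso_viability, self.yoda_viability):
            if not 0 <= v <= 100:
                raise ValueError("viabilities must be percentages in [0, 100]")
        if self.dmso_viability == 0:
            raise ValueError("DMSO (vehicle) viability must be positive")


def yoda1_sensitization(inp: SensitizationInput) -> float:
    """Percent viability decrease from Yoda1; negative if Yoda1 helped."""
    return 100.0 * (inp.dmso_viability - inp.yoda_viability) / inp.dmso_viability


@dataclass(frozen=True)
class FretInput:
    fi_double: float  # donor channel, acceptor + donor double stain
    fi_donor: float   # donor-only stain
    fi_background: float  # unstained

    def __post_init__(self) -> None:
        if min(self.fi_double, self.fi_donor, self.fi_background) < 0:
            raise ValueError("fluorescence intensities must be non-negative")
        if self.fi_donor == self.fi_background:
            raise ValueError("donor-only and background intensities coincide (zero denominator)")


@dataclass(frozen=True)
class FretResult:
    efficiency: float
    in_range: bool  # efficiency within [0, 1]


def fret_efficiency(inp: FretInput) -> FretResult:
    """Donor-quenching FRET efficiency with a quality flag for out-of-range values."""
    e = 1.0 - (inp.fi_double - inp.fi_background) / (inp.fi_donor - inp.fi_background)
    return FretResult(efficiency=float(e), in_range=bool(0.0 <= e <= 1.0))


@dataclass
class RatioTrace:
    """Per-event Fluo-4 and Fura Red intensities with acquisition timestamps (s)."""

    time_s: np.ndarray
    fluo4: np.ndarray
    furared: np.ndarray
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluo4 = np.asarray(self.fluo4, dtype=float)
        self.furared = np.asarray(self.furared, dtype=float)
        if not (len(self.time_s) == len(self.fluo4) == len(self.furared)):
            raise ValueError("time, Fluo-4 and Fura Red arrays must have equal length")
        if (self.fluo4 < 0).any() or (self.furared < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class RatioSummary:
    median_ratio: float
    n_events: int
    n_excluded: int  # events with zero Fura Red, excluded from the ratio


def ratiometric_median(trace: RatioTrace, window_s: float = 200.0) -> RatioSummary:
    """Median per-event Fluo-4/Fura Red over [0, window_s]."""
    mask = (trace.time_s >= 0) & (trace.time_s <= window_s)
    if not mask.any():
        raise ValueError(f"no events within the first {window_s} s")
    fluo = trace.fluo4[mask]
    fura = trace.furared[mask]
    ok = fura > 0
    if not ok.any():
        raise ValueError("all events in the window have zero Fura Red signal")
    return RatioSummary(
        median_ratio=float(np.median(fluo[ok] / fura[ok])),
        n_events=int(ok.sum()),
        n_excluded=int((~ok).sum()),
    )
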