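"""Condition mapping: ratiometric calcium fluorescence → model calcium (µM).

Flow-cytometry calcium readout is the per-event Fluo-4/Fura Red ratio; the
model consumes absolute cytosolic calcium.  The bridge is a normalization that
pins a reference condition (Yoda1 treatment) to 1 µM and scales every other
condition by its median ratio relative to the reference.  A designated blank
condition (calcium-free medium) maps to 0 µM by definition regardless of its
measured median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .model import CellCondition, make_condition

__all__ = [
    "CalciumPanel",
    "DEFAULT_PANEL",
    "normalize_calcium",
    "panel_to_conditions",
    "load_panel",
]


@dataclass(frozen=True)
class CalciumPanel:
    """Per-condition median ratiometric fluorescence plus the reference anchor."""

    medians: dict[str, float]
    reference: str = "yoda1"
    reference_um: float = 1.0
    blank: str | None = "calcium-free"
    # conditions whose calcium is given directly in µM (bypassing the ratio)
    direct_um: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, med in self.medians.items():
            if med < 0:
                raise ValueError(f"negative median for condition {name!r}")
        if self.reference not in self.medians and self.reference not in self.direct_um:
            raise ValueError(f"reference condition {self.reference!r} absent from panel")


#: Default panel.  Only the anchors printed as concentrations are encoded
#: directly (control ≈ 0.105 µM, Yoda1 = 1.0 µM, Yoda1+RSV = 1.7 µM,
#: calcium-free = 0); the resveratrol-only value is a synthetic default
#: (0.2 µM) standing between control and Yoda1, not a measured number.
DEFAULT_PANEL = CalciumPanel(
    medians={},
    direct_um={
        "calcium-free": 0.0,
        "control": 0.105,
        "resveratrol": 0.2,  # synthetic default, not from measurements
        "yoda1": 1.0,
        "yoda1+resveratrol": 1.7,
    },
)

CONDITION_ORDER = ["calcium-free", "control", "resveratrol", "yoda1", "yoda1+resveratrol"]


def normalize_calcium(panel: CalciumPanel) -> dict[str, float]:
    """Map every condition to µM: 1 µM × median/median(reference).

    Conditions listed in ``direct_um`` pass through unchanged; the blank
    condition is forced to 0.
    """
    out = dict(panel.direct_um)
    if panel.medians:
        ref = panel.medians.get(panel.reference)
        if ref is None and panel.reference not in panel.direct_um:
            raise ValueError("reference median missing")
        if ref is not None:
            if ref <= 0:
                raise ValueError("reference median must be positive")
            for name, med in panel.medians.items():
                out[name] = panel.reference_um * med / ref
    if panel.blank is not None and panel.blank in out:
        out[panel.blank] = 0.0
    if panel.reference in panel.medians:
        out[panel.reference] = panel.reference_um  # exact fixed point
    return out


def panel_to_conditions(
    calcium_map: dict[str, float], trail_ng_per_ml: float
) -> list[CellCondition]:
    """One CellCondition per panel entry at a common TRAIL dose."""
    if not calcium_map:
        raise ValueError("empty calcium map")
    ordered = sorted(
        calcium_map.items(),
        key=lambda kv: (CONDITION_ORDER.index(kv[0]) if kv[0] in CONDITION_ORDER else len(CONDITION_ORDER), kv[0]),
    )
    return [make_condition(trail_ng_per_ml, um, label=name) for name, um in ordered]


def load_panel(path: str | Path, reference: str = "yoda1", blank: str | None = "calcium-free") -> CalciumPanel:
    """Read a panel CSV with columns (condition, median_ratio) or (condition, calcium_um)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"condition", "median_ratio"} <= cols:
        return CalciumPanel(
            medians=dict(zip(df["condition"], df["median_ratio"].astype(float))),
            reference=reference,
            blank=blank,
        )
    if {"condition", "calcium_um"} <= cols:
        return CalciumPanel(
            medians={},
            reference=reference,
            blank=blank,
            direct_um=dict(zip(df["condition"], df["calcium_um"].astype(float))),
        )
    raise ValueError(
        f"{path}: expected columns (condition, median_ratio) or (condition, calcium_um)"
    )
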