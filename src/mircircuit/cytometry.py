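"""Flow-cytometry quantification: percentile gating, relative/absolute
reporter units, and viability.

Event tables are plain DataFrames with one row per event and one column per
channel; a boolean ``scatter_live`` column marks events inside the
forward/side-scatter live gate.  Compensation and scatter gating are
assumed to be applied upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GateSet",
    "gate_threshold",
    "positive_mask",
    "positive_fraction",
    "relative_units",
    "absolute_units",
    "viability",
    "validate_events",
]

#: Fraction of a negative-control sample required to fall outside the gate.
CONTROL_EXCLUSION = 0.999


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    if len(events) == 0:
        raise ValueError("event table is empty")
    if events.columns.duplicated().any():
        raise ValueError("duplicate channel names")
    numeric = events.select_dtypes(include=[np.number])
    if not np.isfinite(numeric.to_numpy(dtype=float)).all():
        raise ValueError("non-finite intensities in event table")
    return events


@dataclass
class GateSet:
    """Per-channel positivity thresholds with their provenance."""

    thresholds: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def threshold(self, channel: str) -> float:
        if channel not in self.thresholds:
            raise KeyError(f"no gate set for channel {channel!r}")
        return self.thresholds[channel]

    def set(self, channel: str, threshold: float, source: str = "") -> None:
        if not np.isfinite(threshold):
            raise ValueError("threshold must be finite")
        self.thresholds[channel] = float(threshold)
        self.provenance[channel] = source


def gate_threshold(
    control: pd.DataFrame, channel: str, min_events: int = 1000
) -> float:
    """Positivity threshold from a fluorophore-negative control.

    The threshold is the 99.9th percentile of the control's channel
    intensities, so 99.9% of control events fall at or below it; an event is
    called positive only when strictly above the threshold.
    """
    validate_events(control)
    if channel not in control.columns:
        raise KeyError(f"channel {channel!r} not in control table")
    if len(control) < min_events:
        warnings.warn(
            f"control has only {len(control)} events (< {min_events}); "
            "the 99.9th percentile will be noisy",
            stacklevel=2,
        )
    return float(np.quantile(control[channel].to_numpy(dtype=float), CONTROL_EXCLUSION))


def positive_mask(events: pd.DataFrame, channel: str, gates: GateSet) -> pd.Series:
    """Boolean mask of events strictly above the channel's gate."""
    if channel not in events.columns:
        raise KeyError(f"channel {channel!r} not in event table")
    return events[channel] > gates.threshold(channel)


def positive_fraction(events: pd.DataFrame, channel: str, gates: GateSet) -> float:
    return float(positive_mask(events, channel, gates).mean())


def _total_signal(events: pd.DataFrame, channel: str, gates: GateSet) -> float:
    """mean(channel | positive) x frequency(positive); 0 when nothing is
    positive."""
    mask = positive_mask(events, channel, gates)
    if not mask.any():
        return 0.0
    mean_pos = float(events.loc[mask, channel].mean())
    return mean_pos * float(mask.mean())


def relative_units(
    sample: pd.DataFrame,
    gates: GateSet,
    reporter: str,
    marker: str,
) -> float:
    """Reporter signal in relative units (rel.U.).

    rel.U. = [mean(reporter | reporter+) x freq(reporter+)] /
    [mean(marker | marker+) x freq(marker+)], with positivity defined by the
    per-channel gates.  The sample is expected to be pre-gated to live
    single cells.
    """
    validate_events(sample)
    denominator = _total_signal(sample, marker, gates)
    if denominator == 0.0:
        raise ValueError(
            f"no events positive for transfection marker {marker!r}; "
            "rel.U. normalization is undefined"
        )
    return _total_signal(sample, reporter, gates) / denominator


def absolute_units(sample: pd.DataFrame, gates: GateSet, reporter: str) -> float:
    """Reporter signal in absolute units: mean(reporter | reporter+) x
    freq(reporter+)."""
    validate_events(sample)
    return _total_signal(sample, reporter, gates)


def viability(
    sample: pd.DataFrame,
    dead_threshold: float | None = None,
    scatter_col: str = "scatter_live",
    dead_col: str = "dead_stain",
) -> float:
    """Fraction scatter-live x fraction dead-stain-negative.

    Both fractions are computed over the full event table.  The dead stain
    is negative when the intensity is at or below ``dead_threshold``; for a
    boolean ``dead_col`` the threshold is ignored and ``False`` means
    negative.
    """
    validate_events(sample)
    for col in (scatter_col, dead_col):
        if col not in sample.columns:
            raise KeyError(f"column {col!r} not in event table")
    frac_scatter = float(sample[scatter_col].astype(bool).mean())
    dead = sample[dead_col]
    if dead.dtype == bool:
        frac_negative = float((~dead).mean())
    else:
        if dead_threshold is None:
            raise ValueError(
                "dead_threshold required for a non-boolean dead-stain channel"
            )
        frac_negative = float((dead <= dead_threshold).mean())
    return frac_scatter * frac_negative


def sample_metrics(
    sample: pd.DataFrame,
    gates: GateSet,
    reporter: str,
    marker: str,
    dead_threshold: float | None = None,
) -> dict[str, float]:
    """Convenience bundle of the per-sample readouts."""
    metrics = {
        "relative_units": relative_units(sample, gates, reporter, marker),
        "absolute_units": absolute_units(sample, gates, reporter),
        f"frac_{reporter}_positive": positive_fraction(sample, reporter, gates),
        f"frac_{marker}_positive": positive_fraction(sample, marker, gates),
    }
    if "scatter_live" in sample.columns and "dead_stain" in sample.columns:
        metrics["viability"] = viability(sample, dead_threshold)
    return metrics


def build_gates(controls: Mapping[str, pd.DataFrame]) -> GateSet:
    """Derive one gate per channel from its negative-control table."""
    gates = GateSet()
    for channel, control in controls.items():
        gates.set(channel, gate_threshold(control, channel), source=f"control:{channel}")
    return gates
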