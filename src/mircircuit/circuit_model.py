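"""Steady-state bow-tie circuit model and parameter screens.

The circuit is a four-step transcriptional cascade with no feedback, so its
steady state is obtained by sequential closed-form substitution:

1. endogenous miRNA input represses Act1 (non-cooperative Hill),
2. Act1 activates production of the synthetic miRNA FF4,
3. FF4 represses Act2 (and optional miR_low inputs repress Act2 directly,
   composing multiplicatively),
4. Act2 activates the output.

All concentrations are molecules/cell.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "InputLevels",
    "SteadyState",
    "ScreenResult",
    "CombinatorialScreenResult",
    "DEFAULT_PARAMETERS",
    "DEFAULT_M_ON",
    "DEFAULT_M_OFF",
    "steady_state",
    "circuit_output",
    "on_off_ratio",
    "parameter_screen",
    "combinatorial_screen",
    "misfit_attenuate",
    "load_misfit_table",
]

#: Default On / Off input levels used throughout the screens.
DEFAULT_M_ON = 3000.0
DEFAULT_M_OFF = 0.0


@dataclass(frozen=True)
class ModelParameters:
    """The eight constants of the steady-state cascade (molecules/cell).

    Defaults are the optimized set used for all simulations.
    """

    IC50miR: float = 20.0
    IC50FF4: float = 20.0
    KD1: float = 10_251.0
    KD2: float = 10_251.0
    Act1MAX: float = 9_755.0
    Act2MAX: float = 9_755.0
    FF4MAX: float = 3_000.0
    OutMAX: float = 30_000.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v >= 0.0):
                raise ValueError(f"parameter {f.name} must be finite and >= 0")
            if f.name != "FF4MAX" and v <= 0.0:
                # FF4MAX = 0 (disconnected cascade) is a legal degenerate case
                raise ValueError(f"parameter {f.name} must be > 0")

    def with_value(self, name: str, value: float) -> "ModelParameters":
        if name not in PARAMETER_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        return replace(self, **{name: float(value)})

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Load parameters from a JSON or YAML mapping; missing keys keep
        their defaults."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        unknown = set(data) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"unknown parameters in {path}: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


PARAMETER_NAMES = tuple(f.name for f in fields(ModelParameters))
DEFAULT_PARAMETERS = ModelParameters()


@dataclass(frozen=True)
class InputLevels:
    """miRNA input concentrations seen by the circuit.

    ``miR_high_total`` is the combined concentration at the miR_high OR-gate
    (contributing miRNAs summed); ``miR_low_levels`` maps each miR_low input
    to its concentration.
    """

    miR_high_total: float = 0.0
    miR_low_levels: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.miR_high_total < 0:
            raise ValueError("miR_high_total must be >= 0")
        for name, level in self.miR_low_levels.items():
            if level < 0:
                raise ValueError(f"negative miR_low level for {name!r}")


@dataclass(frozen=True)
class SteadyState:
    Act1: float
    FF4: float
    Act2: float
    Out: float


def _repression(m, ic50):
    """Survival fraction 1 - m/(ic50 + m) of a non-cooperative repression."""
    m = np.asarray(m, dtype=float)
    return ic50 / (ic50 + m)


def _activation(a, kd):
    a = np.asarray(a, dtype=float)
    return a / (kd + a)


def steady_state(inputs: InputLevels, params: ModelParameters) -> SteadyState:
    """Evaluate the cascade's steady state by sequential substitution."""
    m = inputs.miR_high_total
    act1 = params.Act1MAX * _repression(m, params.IC50miR)
    ff4 = params.FF4MAX * _activation(act1, params.KD1)
    low_survival = 1.0
    for level in inputs.miR_low_levels.values():
        low_survival *= _repression(level, params.IC50miR)
    act2 = params.Act2MAX * _repression(ff4, params.IC50FF4) * low_survival
    out = params.OutMAX * _activation(act2, params.KD2)
    return SteadyState(Act1=float(act1), FF4=float(ff4), Act2=float(act2), Out=float(out))


def circuit_output(
    m_high: float | np.ndarray | None,
    low_levels: Sequence[np.ndarray] | Sequence[float] = (),
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> np.ndarray:
    """Vectorized output of the full classifier circuit.

    ``m_high=None`` means the circuit has no miR_high sensor at all: the
    FF4 arm is absent (FF4 = 0) and Act2 is only shaped by the miR_low
    inputs.  Broadcasts over arrays of per-sample levels.
    """
    if m_high is None:
        ff4 = np.asarray(0.0)
    else:
        m = np.asarray(m_high, dtype=float)
        if (m < 0).any():
            raise ValueError("negative miR_high input")
        act1 = params.Act1MAX * _repression(m, params.IC50miR)
        ff4 = params.FF4MAX * _activation(act1, params.KD1)
    survival = np.asarray(1.0)
    for levels in low_levels:
        lv = np.asarray(levels, dtype=float)
        if (lv < 0).any():
            raise ValueError("negative miR_low input")
        survival = survival * _repression(lv, params.IC50miR)
    act2 = params.Act2MAX * _repression(ff4, params.IC50FF4) * survival
    return params.OutMAX * _activation(act2, params.KD2)


def on_off_ratio(
    params: ModelParameters,
    m_on: float = DEFAULT_M_ON,
    m_off: float = DEFAULT_M_OFF,
) -> float:
    """Dynamic range Out(m_on) / Out(m_off) of the miR_high sensor alone."""
    if m_on == m_off:
        return 1.0
    on = steady_state(InputLevels(miR_high_total=m_on), params).Out
    off = steady_state(InputLevels(miR_high_total=m_off), params).Out
    if off == 0.0:
        warnings.warn("Off-state output is zero; On/Off ratio is +inf", stacklevel=2)
        return float("inf")
    return on / off


@dataclass
class ScreenResult:
    """Dose-response of the On/Off ratio along one parameter grid."""

    varied: str
    grid: np.ndarray
    on_values: np.ndarray
    off_values: np.ndarray
    ratio: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                self.varied: self.grid,
                "on": self.on_values,
                "off": self.off_values,
                "ratio": self.ratio,
            }
        )


def parameter_screen(
    params: ModelParameters,
    name: str,
    grid: Sequence[float],
    m_on: float = DEFAULT_M_ON,
    m_off: float = DEFAULT_M_OFF,
) -> ScreenResult:
    """Sweep one parameter over ``grid`` with the others fixed at ``params``."""
    if name not in PARAMETER_NAMES:
        raise KeyError(f"unknown parameter {name!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if (grid <= 0).any() and name != "FF4MAX":
        raise ValueError("grid values must be strictly positive")
    if not (np.diff(grid) >= 0).all():
        raise ValueError("grid must be sorted ascending")
    on = np.empty_like(grid)
    off = np.empty_like(grid)
    for i, v in enumerate(grid):
        p = params.with_value(name, v)
        on[i] = steady_state(InputLevels(miR_high_total=m_on), p).Out
        off[i] = steady_state(InputLevels(miR_high_total=m_off), p).Out
    with np.errstate(divide="ignore"):
        ratio = np.where(off > 0, on / np.where(off > 0, off, 1.0), np.inf)
    return ScreenResult(varied=name, grid=grid, on_values=on, off_values=off, ratio=ratio)


@dataclass
class CombinatorialScreenResult:
    """FF4 and Out levels over an Act1MAX x Act2MAX grid.

    All arrays are shaped (len(act1_grid), len(act2_grid)); FF4 does not
    depend on Act2MAX, so its rows are constant along axis 1.
    """

    act1_grid: np.ndarray
    act2_grid: np.ndarray
    ff4_on: np.ndarray
    ff4_off: np.ndarray
    out_on: np.ndarray
    out_off: np.ndarray

    @property
    def ff4_off_on_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.ff4_off / self.ff4_on

    @property
    def out_on_off_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.out_on / self.out_off

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, a1 in enumerate(self.act1_grid):
            for j, a2 in enumerate(self.act2_grid):
                rows.append(
                    {
                        "Act1MAX": a1,
                        "Act2MAX": a2,
                        "ff4_on": self.ff4_on[i, j],
                        "ff4_off": self.ff4_off[i, j],
                        "out_on": self.out_on[i, j],
                        "out_off": self.out_off[i, j],
                        "ff4_off_on": self.ff4_off_on_ratio[i, j],
                        "out_on_off": self.out_on_off_ratio[i, j],
                    }
                )
        return pd.DataFrame(rows)


def combinatorial_screen(
    act1_grid: Sequence[float],
    act2_grid: Sequence[float],
    params: ModelParameters = DEFAULT_PARAMETERS,
    m_on: float = DEFAULT_M_ON,
    m_off: float = DEFAULT_M_OFF,
) -> CombinatorialScreenResult:
    """Evaluate FF4 and Out at every (Act1MAX, Act2MAX) pair, On and Off."""
    a1 = np.asarray(act1_grid, dtype=float)
    a2 = np.asarray(act2_grid, dtype=float)
    if (a1 <= 0).any() or (a2 <= 0).any():
        raise ValueError("grids must be strictly positive")
    shape = (a1.size, a2.size)
    ff4_on = np.empty(shape)
    ff4_off = np.empty(shape)
    out_on = np.empty(shape)
    out_off = np.empty(shape)
    for (i, v1), (j, v2) in itertools.product(enumerate(a1), enumerate(a2)):
        p = replace(params, Act1MAX=float(v1), Act2MAX=float(v2))
        ss_on = steady_state(InputLevels(miR_high_total=m_on), p)
        ss_off = steady_state(InputLevels(miR_high_total=m_off), p)
        ff4_on[i, j], out_on[i, j] = ss_on.FF4, ss_on.Out
        ff4_off[i, j], out_off[i, j] = ss_off.FF4, ss_off.Out
    return CombinatorialScreenResult(
        act1_grid=a1, act2_grid=a2,
        ff4_on=ff4_on, ff4_off=ff4_off, out_on=out_on, out_off=out_off,
    )


def misfit_attenuate(out: float | np.ndarray, repression_factor: float) -> np.ndarray:
    """Attenuate an output level by a target-site-variant repression factor."""
    if not 0.0 <= repression_factor <= 1.0:
        raise ValueError("repression_factor must lie in [0, 1]")
    return np.asarray(out, dtype=float) * repression_factor


def load_misfit_table(path: str | Path) -> dict[str, float]:
    """Load a variant -> repression-factor table from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    table = {str(k): float(v) for k, v in data.items()}
    for k, v in table.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"variant {k!r} has factor {v} outside [0, 1]")
    return table


def attenuate_by_variant(
    out: float | np.ndarray, variant: str, table: Mapping[str, float]
) -> np.ndarray:
    if variant not in table:
        raise KeyError(f"unknown miSFIT variant {variant!r}")
    return misfit_attenuate(out, table[variant])
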