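"""Deterministic generators for every input the pipeline consumes.

Each generator is a pure function of its spec (explicit seed, one private
RNG stream) and returns the generated object together with a ground-truth
manifest, so downstream results can be checked against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mircircuit.circuit_model import DEFAULT_PARAMETERS, ModelParameters
from mircircuit.classifier_search import CircuitTopology, score_circuit
from mircircuit.colony_metrics import ColonyPointCloud
from mircircuit.expression_data import ExpressionMatrix, MiRNARecord

__all__ = [
    "PlantedMarker",
    "GeneratorSpec",
    "CytometryFixtureSpec",
    "ColonyFixtureSpec",
    "generate_expression",
    "generate_cytometry",
    "generate_colony",
    "RADIAL_FUNCTIONS",
]


@dataclass(frozen=True)
class PlantedMarker:
    """One planted miRNA: its level in positive and in negative samples
    (copies/cell)."""

    mirna_id: str
    positive_level: float
    negative_level: float

    def __post_init__(self) -> None:
        if self.positive_level < 0 or self.negative_level < 0:
            raise ValueError("planted levels must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """Spec for a labelled expression matrix with planted structure.

    ``planted_high`` markers are meant to be high in positives (classifier
    miR_high inputs); ``planted_low`` markers high in (some) negatives.
    ``low_active_fraction`` controls in how many negative samples each
    planted_low marker is switched on.  Background miRNAs follow a
    log-normal whose median sits well below the 1% binarization threshold.
    """

    seed: int
    n_positive: int = 4
    n_negative: int = 8
    n_background_mirnas: int = 30
    planted_high: tuple[PlantedMarker, ...] = ()
    planted_low: tuple[PlantedMarker, ...] = ()
    background_log_mu: float = np.log(10.0)
    background_log_sigma: float = 1.0
    noise_cv: float = 0.0
    n_replicates: int = 1
    low_active_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("need at least one sample per class")
        if self.n_background_mirnas < 0:
            raise ValueError("n_background_mirnas must be >= 0")
        if not 0.0 < self.low_active_fraction <= 1.0:
            raise ValueError("low_active_fraction must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _unique_sequences(rng: np.random.Generator, n: int, length: int = 22) -> list[str]:
    alphabet = list("ACGU")
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        s = "".join(alphabet[i] for i in rng.integers(0, 4, size=length))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def generate_expression(
    spec: GeneratorSpec,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> tuple[ExpressionMatrix, dict]:
    """Generate a labelled copies/cell matrix with planted classifier
    structure.

    The manifest records the planted topology and its cMargin under
    ``params`` (scored on the generated matrix), plus the spec echo.
    """
    rng = np.random.default_rng(spec.seed)
    bg_ids = [f"bg-{i:03d}" for i in range(spec.n_background_mirnas)]
    planted = list(spec.planted_high) + list(spec.planted_low)
    planted_ids = [m.mirna_id for m in planted]
    if len(set(planted_ids)) != len(planted_ids):
        raise ValueError("duplicate planted miRNA ids")
    collisions = set(planted_ids) & set(bg_ids)
    if collisions:
        raise ValueError(f"planted ids collide with background ids: {sorted(collisions)}")

    pos_samples = [f"pos-{i:02d}" for i in range(spec.n_positive)]
    neg_samples = [f"neg-{i:02d}" for i in range(spec.n_negative)]
    samples = pos_samples + neg_samples
    n_samples = len(samples)

    columns = planted_ids + bg_ids
    values = np.empty((n_samples, len(columns)))
    values[:, len(planted_ids):] = rng.lognormal(
        mean=spec.background_log_mu,
        sigma=spec.background_log_sigma,
        size=(n_samples, len(bg_ids)),
    )
    n_pos = spec.n_positive
    for j, marker in enumerate(spec.planted_high):
        values[:n_pos, j] = marker.positive_level
        values[n_pos:, j] = marker.negative_level
    offset = len(spec.planted_high)
    for j, marker in enumerate(spec.planted_low):
        col = offset + j
        values[:n_pos, col] = marker.positive_level
        active = max(1, round(spec.low_active_fraction * spec.n_negative))
        # deterministic subset of negatives carries the marker
        active_rows = rng.choice(spec.n_negative, size=active, replace=False)
        values[n_pos:, col] = 0.0
        values[n_pos + active_rows, col] = marker.negative_level

    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=values.shape)
        values = values * noise

    frame = pd.DataFrame(values, index=samples, columns=columns)
    if spec.n_replicates > 1:
        reps, rep_group = [], {}
        sigma = np.sqrt(np.log1p(max(spec.noise_cv, 1e-9) ** 2))
        for s in samples:
            for r in range(spec.n_replicates):
                rid = f"{s}.r{r}"
                jitter = rng.lognormal(-sigma**2 / 2, sigma, size=len(columns))
                reps.append(pd.Series(frame.loc[s] * jitter, name=rid))
                rep_group[rid] = s
        frame = pd.DataFrame(reps)
        replicate_group = pd.Series(rep_group)
        labels = pd.Series(
            {
                rid: "positive" if base in pos_samples else "negative"
                for rid, base in rep_group.items()
            }
        )
    else:
        replicate_group = None
        labels = pd.Series(
            {s: "positive" if s in pos_samples else "negative" for s in samples}
        )

    sequences = _unique_sequences(rng, len(columns))
    records = [
        MiRNARecord(name=name, mature_sequence=seq, source_dataset="synthetic")
        for name, seq in zip(columns, sequences)
    ]
    matrix = ExpressionMatrix(
        values=frame,
        labels=labels,
        mirnas=records,
        replicate_group=replicate_group,
        units="copies_per_cell",
        name="synthetic",
    )

    manifest: dict = {
        "seed": spec.seed,
        "planted_high": [m.mirna_id for m in spec.planted_high],
        "planted_low": [m.mirna_id for m in spec.planted_low],
        "n_positive": spec.n_positive,
        "n_negative": spec.n_negative,
    }
    if planted:
        topology = CircuitTopology(
            high_gate=frozenset(m.mirna_id for m in spec.planted_high),
            low_sensors=frozenset(m.mirna_id for m in spec.planted_low),
        )
        scored = score_circuit(topology, matrix, params)
        manifest["planted_topology"] = {
            "high_gate": sorted(topology.high_gate),
            "low_sensors": sorted(topology.low_sensors),
        }
        manifest["planted_cmargin"] = scored.cmargin
        manifest["planted_auc"] = scored.auc
    return matrix, manifest


# ---------------------------------------------------------------------------
# cytometry fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelMixture:
    """Log-normal intensity parameters for the transfected (positive) and
    untransfected (negative) subpopulations of one channel."""

    mu_positive: float
    sigma_positive: float
    mu_negative: float
    sigma_negative: float


@dataclass(frozen=True)
class CytometryFixtureSpec:
    seed: int
    n_events: int = 10_000
    transfected_fraction: float = 0.5
    channels: dict[str, ChannelMixture] = field(
        default_factory=lambda: {
            "reporter": ChannelMixture(4.0, 0.5, 0.0, 0.3),
            "marker": ChannelMixture(4.5, 0.5, 0.0, 0.3),
        }
    )
    dead_fraction: float = 0.05
    scatter_live_fraction: float = 0.9

    def __post_init__(self) -> None:
        for name, frac in (
            ("transfected_fraction", self.transfected_fraction),
            ("dead_fraction", self.dead_fraction),
            ("scatter_live_fraction", self.scatter_live_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def generate_cytometry(spec: CytometryFixtureSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a per-event channel-intensity table plus ground truth.

    The manifest records which events are transfected and the realized
    per-channel subpopulation means/fractions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    transfected = rng.random(n) < spec.transfected_fraction
    data: dict[str, np.ndarray] = {}
    for channel, mix in spec.channels.items():
        pos = rng.lognormal(mix.mu_positive, mix.sigma_positive, size=n)
        neg = rng.lognormal(mix.mu_negative, mix.sigma_negative, size=n)
        data[channel] = np.where(transfected, pos, neg)
    data["dead_stain"] = np.where(
        rng.random(n) < spec.dead_fraction,
        rng.lognormal(3.0, 0.3, size=n),
        rng.lognormal(0.0, 0.3, size=n),
    )
    data["scatter_live"] = rng.random(n) < spec.scatter_live_fraction
    events = pd.DataFrame(data)
    manifest = {
        "seed": spec.seed,
        "transfected": transfected,
        "transfected_fraction_realized": float(transfected.mean()),
        "channel_means_transfected": {
            c: float(events.loc[transfected, c].mean()) for c in spec.channels
        },
    }
    return events, manifest


# ---------------------------------------------------------------------------
# colony fixtures
# ---------------------------------------------------------------------------

def _ring(r: np.ndarray) -> np.ndarray:
    return np.exp(-((r - 0.5) ** 2) / (2 * 0.15**2))


RADIAL_FUNCTIONS = {
    "flat": lambda r: np.ones_like(r),
    "edge_high": lambda r: r,
    "center_high": lambda r: 1.0 - r,
    "ring": _ring,
}


@dataclass(frozen=True)
class MarkerField:
    function: str
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.function not in RADIAL_FUNCTIONS:
            raise ValueError(
                f"unknown radial function {self.function!r}; "
                f"choose from {sorted(RADIAL_FUNCTIONS)}"
            )


@dataclass(frozen=True)
class ColonyFixtureSpec:
    seed: int
    n_cells: int = 500
    colony_radius: float = 500.0
    markers: dict[str, MarkerField] = field(
        default_factory=lambda: {
            "Sox2": MarkerField("center_high"),
            "TBXT": MarkerField("ring"),
            "Sox17": MarkerField("edge_high"),
        }
    )
    noise_sigma: float = 0.0
    colony_id: str = "colony-0"

    def __post_init__(self) -> None:
        if self.n_cells < 10:
            raise ValueError("n_cells must be >= 10")
        if self.colony_radius <= 0:
            raise ValueError("colony_radius must be > 0")


def generate_colony(spec: ColonyFixtureSpec) -> tuple[ColonyPointCloud, dict]:
    """Cells uniform over the disc; intensity = f(r/R) * amplitude + noise."""
    rng = np.random.default_rng(spec.seed)
    r = spec.colony_radius * np.sqrt(rng.random(spec.n_cells))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_cells)
    cells = pd.DataFrame({"x": r * np.cos(theta), "y": r * np.sin(theta)})
    rnorm = r / spec.colony_radius
    for marker, fieldspec in spec.markers.items():
        signal = fieldspec.amplitude * RADIAL_FUNCTIONS[fieldspec.function](rnorm)
        if spec.noise_sigma > 0:
            signal = signal + rng.normal(0.0, spec.noise_sigma, size=spec.n_cells)
        cells[marker] = signal
    cloud = ColonyPointCloud(
        cells=cells, colony_id=spec.colony_id, colony_radius=spec.colony_radius
    )
    manifest = {
        "seed": spec.seed,
        "markers": {m: (f.function, f.amplitude) for m, f in spec.markers.items()},
        "noise_sigma": spec.noise_sigma,
    }
    return cloud, manifest
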