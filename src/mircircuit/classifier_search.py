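"""Exhaustive search for classifier circuits over miRNA input sets.

A candidate circuit is a :class:`CircuitTopology`: a set of miRNAs wired
into the miR_high OR-gate (output requires them HIGH) plus a set of miR_low
sensors (output requires them LOW).  Each topology is scored by predicting
the mechanistic circuit output for every sample and summarizing the
separation between positive and negative samples as a classification
margin (cMargin, log10 scale), an ROC AUC, and per-sample truth calls.

The search enumerates every admissible topology within the input-count
constraints after a role-based prefilter on the binarized matrix, and can
optionally prune inputs whose contribution is not supported by a stratified
bootstrap.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from mircircuit.circuit_model import (
    DEFAULT_PARAMETERS,
    ModelParameters,
    circuit_output,
)
from mircircuit.expression_data import (
    NEGATIVE,
    POSITIVE,
    BinarizedMatrix,
    ExpressionMatrix,
    binarize,
)

__all__ = [
    "CircuitTopology",
    "ScoredCircuit",
    "SearchConfig",
    "predict_outputs",
    "score_circuit",
    "candidate_pool",
    "enumerate_topologies",
    "enumerate_and_search",
    "prune_circuit",
]

#: Floor applied to predicted outputs before taking ratios (molecules/cell).
OUTPUT_EPSILON = 1e-6


@dataclass(frozen=True)
class CircuitTopology:
    """Which miRNAs feed the miR_high OR-gate and the miR_low sensors."""

    high_gate: frozenset[str] = frozenset()
    low_sensors: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "high_gate", frozenset(self.high_gate))
        object.__setattr__(self, "low_sensors", frozenset(self.low_sensors))
        overlap = self.high_gate & self.low_sensors
        if overlap:
            raise ValueError(
                f"miRNA(s) {sorted(overlap)} appear in both gate roles"
            )

    @property
    def inputs(self) -> frozenset[str]:
        return self.high_gate | self.low_sensors

    @property
    def n_inputs(self) -> int:
        return len(self.high_gate) + len(self.low_sensors)

    def without(self, mirna: str) -> "CircuitTopology":
        if mirna not in self.inputs:
            raise KeyError(mirna)
        return CircuitTopology(
            high_gate=self.high_gate - {mirna},
            low_sensors=self.low_sensors - {mirna},
        )

    def describe(self) -> str:
        high = " | ".join(sorted(self.high_gate)) or "-"
        low = " & ".join(f"NOT {m}" for m in sorted(self.low_sensors)) or "-"
        return f"({high}) AND {low}" if self.low_sensors else f"({high})"


@dataclass
class ScoredCircuit:
    topology: CircuitTopology
    per_sample_output: pd.Series
    avg_margin: float
    worst_margin: float
    cmargin: float
    auc: float
    truth: pd.Series

    def to_dict(self) -> dict:
        return {
            "high_gate": sorted(self.topology.high_gate),
            "low_sensors": sorted(self.topology.low_sensors),
            "avg_margin": self.avg_margin,
            "worst_margin": self.worst_margin,
            "cmargin": self.cmargin,
            "auc": self.auc,
        }


@dataclass
class SearchConfig:
    """Knobs of the exhaustive search.

    ``max_total_inputs`` caps |high_gate| + |low_sensors| and
    ``max_inputs_per_gate`` caps |high_gate| alone.  Prefilter softness:
    a miR_high candidate must exceed threshold in at least
    ``high_min_pos_frac`` of positives (and in fewer than all negatives); a
    miR_low candidate must exceed threshold in at most ``low_max_pos_frac``
    of positives and in at least one negative.
    """

    max_total_inputs: int = 3
    max_inputs_per_gate: int = 2
    t_fraction: float = 0.01
    prune: bool = False
    bootstrap_reps: int = 200
    prune_alpha: float = 0.05
    seed: int | None = None
    aggregation: str = "geometric"
    epsilon: float = OUTPUT_EPSILON
    high_min_pos_frac: float = 1.0
    low_max_pos_frac: float = 0.0
    max_topologies: int = 200_000

    def __post_init__(self) -> None:
        if self.max_total_inputs < 1:
            raise ValueError("max_total_inputs must be >= 1")
        if self.max_inputs_per_gate < 0:
            raise ValueError("max_inputs_per_gate must be >= 0")
        if self.aggregation not in {"geometric", "arithmetic"}:
            raise ValueError("aggregation must be 'geometric' or 'arithmetic'")
        if self.prune:
            if self.bootstrap_reps < 1:
                raise ValueError("bootstrap_reps must be >= 1 when pruning")
            if not 0.0 < self.prune_alpha < 1.0:
                raise ValueError("prune_alpha must lie in (0, 1)")
            if self.seed is None:
                raise ValueError("pruning requires an explicit seed")


def _levels(matrix: ExpressionMatrix, names: Iterable[str]) -> list[np.ndarray]:
    missing = [n for n in names if n not in matrix.values.columns]
    if missing:
        raise KeyError(f"topology references unknown miRNA(s): {missing}")
    return [matrix.values[n].to_numpy(dtype=float) for n in names]


def predict_outputs(
    topology: CircuitTopology,
    matrix: ExpressionMatrix,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> pd.Series:
    """Predicted steady-state output (molecules/cell) for every sample.

    high_gate abundances are summed into the OR-gate input; each miR_low
    sensor acts independently.  An empty high_gate removes the FF4 arm
    entirely (pure miR_low circuit).
    """
    if matrix.units != "copies_per_cell":
        raise ValueError(
            f"predict_outputs requires copies_per_cell, got {matrix.units!r}"
        )
    if topology.high_gate:
        m_high = np.sum(_levels(matrix, sorted(topology.high_gate)), axis=0)
    else:
        m_high = None
    low = _levels(matrix, sorted(topology.low_sensors))
    out = circuit_output(m_high, low, params)
    out = np.broadcast_to(np.asarray(out, dtype=float), (len(matrix.samples),))
    return pd.Series(out, index=matrix.values.index, name="out")


def _aggregate(values: np.ndarray, how: str) -> float:
    if how == "geometric":
        return float(np.exp(np.mean(np.log(values))))
    return float(np.mean(values))


def _margins(
    outputs: np.ndarray,
    is_positive: np.ndarray,
    aggregation: str = "geometric",
    epsilon: float = OUTPUT_EPSILON,
) -> tuple[float, float, float, float]:
    """(avg_margin, worst_margin, cmargin, threshold) on floored outputs."""
    if epsilon > 0 and (outputs < epsilon).any():
        outputs = np.maximum(outputs, epsilon)
    pos = outputs[is_positive]
    neg = outputs[~is_positive]
    agg_pos = _aggregate(pos, aggregation)
    agg_neg = _aggregate(neg, aggregation)
    avg_margin = math.log10(agg_pos / agg_neg)
    worst_margin = math.log10(pos.min() / neg.max())
    cmargin = 0.5 * (avg_margin + worst_margin)
    gm_pos = _aggregate(pos, "geometric")
    gm_neg = _aggregate(neg, "geometric")
    threshold = math.sqrt(gm_pos * gm_neg)
    return avg_margin, worst_margin, cmargin, threshold


def score_circuit(
    topology: CircuitTopology,
    matrix: ExpressionMatrix,
    params: ModelParameters = DEFAULT_PARAMETERS,
    aggregation: str = "geometric",
    epsilon: float = OUTPUT_EPSILON,
) -> ScoredCircuit:
    """Score a topology on a labelled matrix.

    * ``avg_margin`` — log10 ratio of the aggregated (default geometric
      mean) positive vs negative outputs;
    * ``worst_margin`` — log10 of the smallest output ratio over all
      (positive, negative) sample pairs;
    * ``cmargin`` — their mean;
    * ``auc`` — ROC area using the outputs as positive-class scores;
    * ``truth`` — 1 where the output clears the geometric midpoint of the
      two group geometric means.
    """
    pos_samples = matrix.positive_samples
    neg_samples = matrix.negative_samples
    if not pos_samples or not neg_samples:
        raise ValueError("need at least one positive and one negative sample")
    outputs = predict_outputs(topology, matrix, params)
    raw = outputs.to_numpy()
    if (raw < epsilon).any():
        warnings.warn(
            f"{int((raw < epsilon).sum())} output(s) floored at {epsilon}",
            stacklevel=2,
        )
    is_positive = (matrix.labels == POSITIVE).to_numpy()
    avg_m, worst_m, cmargin, thr = _margins(
        raw, is_positive, aggregation=aggregation, epsilon=epsilon
    )
    y_true = is_positive.astype(int)
    if raw.std() == 0.0:
        auc = 0.5
    else:
        auc = float(roc_auc_score(y_true, raw))
    truth = pd.Series(
        (np.maximum(raw, epsilon) >= thr).astype(int), index=outputs.index
    )
    return ScoredCircuit(
        topology=topology,
        per_sample_output=outputs,
        avg_margin=avg_m,
        worst_margin=worst_m,
        cmargin=cmargin,
        auc=auc,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def candidate_pool(
    binarized: BinarizedMatrix,
    high_min_pos_frac: float = 1.0,
    low_max_pos_frac: float = 0.0,
) -> tuple[list[str], list[str]]:
    """Role-based prefilter on the binarized matrix.

    miR_high candidates must exceed threshold in >= ``high_min_pos_frac``
    of positive samples and in fewer than all negative samples; miR_low
    candidates must exceed threshold in <= ``low_max_pos_frac`` of positive
    samples and in at least one negative sample.
    """
    above = binarized.above_threshold()
    pos = (binarized.labels == POSITIVE).to_numpy()
    neg = ~pos
    pos_frac = above.loc[above.index[pos]].mean(axis=0)
    neg_any = above.loc[above.index[neg]].any(axis=0)
    neg_all = above.loc[above.index[neg]].all(axis=0)
    high = sorted(above.columns[(pos_frac >= high_min_pos_frac) & ~neg_all])
    low = sorted(above.columns[(pos_frac <= low_max_pos_frac) & neg_any])
    return high, low


def enumerate_topologies(
    high_candidates: Sequence[str],
    low_candidates: Sequence[str],
    max_total_inputs: int,
    max_inputs_per_gate: int,
) -> list[CircuitTopology]:
    """All non-empty topologies within the input-count constraints."""
    topologies = []
    max_high = min(max_inputs_per_gate, max_total_inputs, len(high_candidates))
    for k_high in range(max_high + 1):
        for high in itertools.combinations(sorted(high_candidates), k_high):
            remaining = max_total_inputs - k_high
            max_low = min(remaining, len(low_candidates))
            low_pool = sorted(set(low_candidates) - set(high))
            for k_low in range(max_low + 1):
                if k_high + k_low == 0:
                    continue
                for low in itertools.combinations(low_pool, k_low):
                    topologies.append(
                        CircuitTopology(
                            high_gate=frozenset(high),
                            low_sensors=frozenset(low),
                        )
                    )
    return topologies


def _rank_key(sc: ScoredCircuit):
    return (
        -sc.cmargin,
        sc.topology.n_inputs,
        len(sc.topology.high_gate),
        tuple(sorted(sc.topology.high_gate)),
        tuple(sorted(sc.topology.low_sensors)),
    )


def enumerate_and_search(
    matrix: ExpressionMatrix,
    params: ModelParameters = DEFAULT_PARAMETERS,
    config: SearchConfig = SearchConfig(),
) -> list[ScoredCircuit]:
    """Exhaustively score all admissible topologies, best first.

    Ties are broken toward fewer total inputs, then toward smaller
    high_gates (miR_low-only designs preferred), then lexicographically.
    """
    binarized = binarize(matrix, config.t_fraction)
    high_cands, low_cands = candidate_pool(
        binarized, config.high_min_pos_frac, config.low_max_pos_frac
    )
    if not high_cands and not low_cands:
        raise ValueError("candidate pool is empty after prefiltering")
    topologies = enumerate_topologies(
        high_cands, low_cands, config.max_total_inputs, config.max_inputs_per_gate
    )
    if len(topologies) > config.max_topologies:
        raise ValueError(
            f"{len(topologies)} topologies exceed the cap "
            f"({config.max_topologies}); tighten the prefilter or constraints"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scored = [
            score_circuit(
                t, matrix, params,
                aggregation=config.aggregation, epsilon=config.epsilon,
            )
            for t in topologies
        ]
    scored.sort(key=_rank_key)
    if config.prune and scored:
        best = prune_circuit(scored[0], matrix, params, config)
        scored[0] = best
    return scored


# ---------------------------------------------------------------------------
# bootstrap pruning
# ---------------------------------------------------------------------------

def _cmargin_on_subset(
    topology: CircuitTopology,
    matrix: ExpressionMatrix,
    params: ModelParameters,
    idx_pos: np.ndarray,
    idx_neg: np.ndarray,
    config: SearchConfig,
    output_cache: dict,
) -> float:
    """cMargin of ``topology`` on a bootstrap resample given by row indices."""
    if topology not in output_cache:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            output_cache[topology] = predict_outputs(
                topology, matrix, params
            ).to_numpy()
    out = output_cache[topology]
    values = np.concatenate([out[idx_pos], out[idx_neg]])
    is_pos = np.zeros(values.size, dtype=bool)
    is_pos[: idx_pos.size] = True
    _, _, cm, _ = _margins(
        values, is_pos, aggregation=config.aggregation, epsilon=config.epsilon
    )
    return cm


def prune_circuit(
    scored: ScoredCircuit,
    matrix: ExpressionMatrix,
    params: ModelParameters = DEFAULT_PARAMETERS,
    config: SearchConfig = SearchConfig(prune=True, seed=0),
) -> ScoredCircuit:
    """Iteratively drop inputs whose cMargin contribution is insignificant.

    For each input miRNA, class-stratified bootstrap resamples give a
    distribution of ΔcMargin = cMargin(with) - cMargin(without).  The input
    whose fraction of replicates with Δ <= 0 is largest is removed when that
    fraction exceeds ``prune_alpha``; the loop repeats until no input
    qualifies.  Removal never empties the topology.
    """
    if not config.prune:
        raise ValueError("config.prune must be true")
    rng = np.random.default_rng(config.seed)
    pos_rows = np.flatnonzero((matrix.labels == POSITIVE).to_numpy())
    neg_rows = np.flatnonzero((matrix.labels == NEGATIVE).to_numpy())
    topology = scored.topology
    cache: dict = {}

    while topology.n_inputs > 1:
        frac_nonpositive: dict[str, float] = {}
        # one shared set of resamples per round keeps comparisons paired
        resamples = [
            (
                rng.choice(pos_rows, size=pos_rows.size, replace=True),
                rng.choice(neg_rows, size=neg_rows.size, replace=True),
            )
            for _ in range(config.bootstrap_reps)
        ]
        for mirna in sorted(topology.inputs):
            reduced = topology.without(mirna)
            n_nonpos = 0
            for idx_pos, idx_neg in resamples:
                full = _cmargin_on_subset(
                    topology, matrix, params, idx_pos, idx_neg, config, cache
                )
                part = _cmargin_on_subset(
                    reduced, matrix, params, idx_pos, idx_neg, config, cache
                )
                if full - part <= 0.0:
                    n_nonpos += 1
            frac_nonpositive[mirna] = n_nonpos / config.bootstrap_reps
        worst = max(sorted(frac_nonpositive), key=frac_nonpositive.get)
        if frac_nonpositive[worst] > config.prune_alpha:
            topology = topology.without(worst)
        else:
            break
    if topology.n_inputs == 0:  # defensive; loop keeps >= 1 input
        warnings.warn("pruning would empty the topology; keeping last input")
        topology = scored.topology
    return score_circuit(
        topology, matrix, params,
        aggregation=config.aggregation, epsilon=config.epsilon,
    )


def results_to_frame(scored: Sequence[ScoredCircuit]) -> pd.DataFrame:
    """Tabulate ranked results (one row per circuit)."""
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "high_gate": "|".join(sorted(sc.topology.high_gate)),
                "low_sensors": "|".join(sorted(sc.topology.low_sensors)),
                "cmargin": sc.cmargin,
                "avg_margin": sc.avg_margin,
                "worst_margin": sc.worst_margin,
                "auc": sc.auc,
            }
            for i, sc in enumerate(scored)
        ]
    )
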