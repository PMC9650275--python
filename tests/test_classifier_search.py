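import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircircuit.circuit_model import DEFAULT_PARAMETERS, InputLevels, steady_state
from mircircuit.classifier_search import (
    CircuitTopology,
    SearchConfig,
    candidate_pool,
    enumerate_and_search,
    enumerate_topologies,
    predict_outputs,
    prune_circuit,
    score_circuit,
    _margins,
)
from mircircuit.expression_data import binarize
from mircircuit.synthetic_data import GeneratorSpec, PlantedMarker, generate_expression

from conftest import make_matrix


def brute_force_margins(pos, neg):
    """Independent oracle: explicit geomeans and full pairwise minimum."""
    gm = lambda xs: math.exp(sum(math.log(x) for x in xs) / len(xs))
    avg = math.log10(gm(pos) / gm(neg))
    worst = math.log10(min(p / n for p in pos for n in neg))
    return avg, worst, (avg + worst) / 2


def brute_force_auc(pos, neg):
    """Mann-Whitney pairwise-comparison count."""
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def _matrix_from_outputs_oracle(topology, matrix, params=DEFAULT_PARAMETERS):
    """Per-sample output via the scalar steady-state path (oracle for the
    vectorized predictor)."""
    outs = {}
    for s in matrix.samples:
        row = matrix.values.loc[s]
        low = {m: float(row[m]) for m in topology.low_sensors}
        if topology.high_gate:
            m_high = float(sum(row[m] for m in topology.high_gate))
            outs[s] = steady_state(InputLevels(m_high, low), params).Out
        else:
            # no FF4 arm: Act2 shaped by miR_low survival only
            survival = 1.0
            for v in low.values():
                survival *= params.IC50miR / (params.IC50miR + v)
            act2 = params.Act2MAX * survival
            outs[s] = params.OutMAX * act2 / (params.KD2 + act2)
    return pd.Series(outs)


class TestCircuitTopology:
    def test_roles_must_be_disjoint(self):
        with pytest.raises(ValueError):
            CircuitTopology(high_gate={"a"}, low_sensors={"a"})

    def test_without(self):
        t = CircuitTopology(high_gate={"a"}, low_sensors={"b"})
        assert t.without("b").low_sensors == frozenset()
        with pytest.raises(KeyError):
            t.without("zzz")


class TestPredictOutputs:
    def test_empty_topology_gives_uniform_unrepressed_output(self, four_sample_matrix):
        outs = predict_outputs(CircuitTopology(), four_sample_matrix)
        p = DEFAULT_PARAMETERS
        expected = p.OutMAX * p.Act2MAX / (p.KD2 + p.Act2MAX)
        np.testing.assert_allclose(outs.to_numpy(), expected, rtol=1e-12)

    def test_zero_high_input_equals_fully_repressed_output(self, four_sample_matrix):
        outs = predict_outputs(
            CircuitTopology(high_gate={"miR-high"}), four_sample_matrix
        )
        off = steady_state(InputLevels(0.0), DEFAULT_PARAMETERS).Out
        assert outs["n1"] == pytest.approx(off, rel=1e-12)

    def test_matches_scalar_oracle_per_sample(self, four_sample_matrix):
        for high, low in [
            ({"miR-high"}, {"miR-low"}),
            (set(), {"miR-low", "miR-bg"}),
            ({"miR-high", "miR-bg"}, set()),
        ]:
            t = CircuitTopology(high_gate=high, low_sensors=low)
            outs = predict_outputs(t, four_sample_matrix)
            oracle = _matrix_from_outputs_oracle(t, four_sample_matrix)
            for s in four_sample_matrix.samples:
                assert outs[s] == pytest.approx(oracle[s], rel=1e-12)

    def test_unknown_mirna_errors(self, four_sample_matrix):
        with pytest.raises(KeyError, match="unknown miRNA"):
            predict_outputs(
                CircuitTopology(high_gate={"ghost"}), four_sample_matrix
            )

    def test_requires_copies_per_cell(self, four_sample_matrix):
        four_sample_matrix.units = "counts"
        with pytest.raises(ValueError, match="copies_per_cell"):
            predict_outputs(CircuitTopology(), four_sample_matrix)


class TestScoreCircuit:
    def test_worked_example(self):
        # positives {100,100}, negatives {10,5}; brute-force oracle values
        avg, worst, cm = brute_force_margins([100, 100], [10, 5])
        assert avg == pytest.approx(1.1505149978319906)
        assert worst == pytest.approx(1.0)
        assert cm == pytest.approx(1.0752574989159953)
        got = _margins(
            np.array([100.0, 100.0, 10.0, 5.0]),
            np.array([True, True, False, False]),
        )
        assert got[0] == pytest.approx(avg, rel=1e-12)
        assert got[1] == pytest.approx(worst, rel=1e-12)
        assert got[2] == pytest.approx(cm, rel=1e-12)

    def test_perfect_separation_auc_one(self, four_sample_matrix):
        sc = score_circuit(
            CircuitTopology(high_gate={"miR-high"}, low_sensors={"miR-low"}),
            four_sample_matrix,
        )
        assert sc.auc == 1.0
        assert sc.truth.tolist() == [1, 1, 0, 0]

    def test_identical_outputs_no_information(self, four_sample_matrix):
        sc = score_circuit(CircuitTopology(), four_sample_matrix)
        assert sc.avg_margin == 0.0
        assert sc.worst_margin == 0.0
        assert sc.cmargin == 0.0
        assert sc.auc == 0.5

    def test_cmargin_consistency_invariant(self, four_sample_matrix):
        sc = score_circuit(
            CircuitTopology(high_gate={"miR-high"}), four_sample_matrix
        )
        lo, hi = sorted([sc.avg_margin, sc.worst_margin])
        assert lo <= sc.cmargin <= hi
        assert sc.cmargin == pytest.approx(
            (sc.avg_margin + sc.worst_margin) / 2
        )

    def test_scale_invariance_of_margins(self):
        rng = np.random.default_rng(0)
        outs = rng.lognormal(2.0, 1.0, size=8)
        is_pos = np.array([True] * 3 + [False] * 5)
        base = _margins(outs, is_pos)
        scaled = _margins(outs * 1e4, is_pos)
        assert scaled[0] == pytest.approx(base[0], rel=1e-9)
        assert scaled[1] == pytest.approx(base[1], rel=1e-9)
        assert scaled[2] == pytest.approx(base[2], rel=1e-9)

    def test_log10_convention_reproduces_reported_fold_change(self):
        # the published margin arithmetic only holds on log10 scale
        assert 10 ** 1.16 == pytest.approx(14.45, abs=0.01)
        assert round(10 ** 1.16, 1) == 14.5 or round(10 ** 1.16, 1) == 14.4

    def test_arithmetic_aggregation_variant(self):
        outs = np.array([100.0, 100.0, 10.0, 5.0])
        is_pos = np.array([True, True, False, False])
        avg, _, _, _ = _margins(outs, is_pos, aggregation="arithmetic")
        assert avg == pytest.approx(math.log10(100 / 7.5))

    def test_needs_both_classes(self):
        matrix = make_matrix(
            values={"m": {"s1": 1.0, "s2": 2.0}},
            labels={"s1": "positive", "s2": "positive"},
        )
        with pytest.raises(ValueError, match="negative"):
            score_circuit(CircuitTopology(high_gate={"m"}), matrix)

    @settings(max_examples=100, deadline=None)
    @given(
        pos=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=6),
        neg=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=6),
    )
    def test_auc_equals_mann_whitney_count(self, pos, neg):
        from sklearn.metrics import roc_auc_score

        scores = np.array(pos + neg)
        y = np.array([1] * len(pos) + [0] * len(neg))
        if scores.std() == 0:
            return
        assert roc_auc_score(y, scores) == pytest.approx(
            brute_force_auc(pos, neg), rel=1e-12
        )


class TestEnumeration:
    def test_constraints_respected(self):
        tops = enumerate_topologies(
            ["h1", "h2", "h3"], ["l1", "l2"],
            max_total_inputs=3, max_inputs_per_gate=2,
        )
        assert all(t.n_inputs <= 3 for t in tops)
        assert all(len(t.high_gate) <= 2 for t in tops)
        assert all(t.n_inputs >= 1 for t in tops)
        # brute-force count oracle
        expected = 0
        for kh in range(3):
            for kl in range(3):
                if 1 <= kh + kl <= 3:
                    expected += math.comb(3, kh) * math.comb(2, kl)
        assert len(tops) == expected

    def test_candidate_pool_roles(self, four_sample_matrix):
        binarized = binarize(four_sample_matrix)
        high, low = candidate_pool(binarized)
        assert "miR-high" in high
        assert "miR-low" in low
        assert "miR-low" not in high and "miR-high" not in low


class TestSearch:
    def _planted_matrix(self, seed=0):
        spec = GeneratorSpec(
            seed=seed, n_positive=4, n_negative=8, n_background_mirnas=20,
            planted_high=(PlantedMarker("mark-high", 3000.0, 0.0),),
            planted_low=(PlantedMarker("mark-low", 0.0, 3000.0),),
            noise_cv=0.1,
        )
        return generate_expression(spec)

    def test_recovers_planted_markers(self):
        matrix, manifest = self._planted_matrix()
        ranked = enumerate_and_search(matrix, config=SearchConfig(max_total_inputs=3))
        best = ranked[0].topology
        assert "mark-high" in best.high_gate
        assert "mark-low" in best.low_sensors

    def test_top_circuit_is_global_maximum_by_brute_force(self):
        matrix, _ = self._planted_matrix(seed=3)
        config = SearchConfig(max_total_inputs=2, max_inputs_per_gate=1)
        ranked = enumerate_and_search(matrix, config=config)
        binarized = binarize(matrix, config.t_fraction)
        high, low = candidate_pool(binarized)
        best_cm = max(
            score_circuit(t, matrix).cmargin
            for t in enumerate_topologies(high, low, 2, 1)
        )
        assert ranked[0].cmargin == pytest.approx(best_cm, rel=1e-12)

    def test_single_input_constraint_picks_most_discriminative(self):
        matrix, _ = self._planted_matrix(seed=5)
        config = SearchConfig(max_total_inputs=1, max_inputs_per_gate=1)
        ranked = enumerate_and_search(matrix, config=config)
        assert ranked[0].topology.n_inputs == 1
        binarized = binarize(matrix, config.t_fraction)
        high, low = candidate_pool(binarized)
        singles = enumerate_topologies(high, low, 1, 1)
        best = max(singles, key=lambda t: score_circuit(t, matrix).cmargin)
        assert ranked[0].topology == best

    def test_shuffled_labels_centre_cmargin_near_zero(self):
        matrix, _ = self._planted_matrix(seed=8)
        rng = np.random.default_rng(42)
        tops = []
        for _ in range(10):
            shuffled = matrix.labels.copy()
            shuffled[:] = rng.permutation(shuffled.to_numpy())
            m = make_matrix(
                values=matrix.values.to_dict(),
                labels=shuffled.to_dict(),
            )
            try:
                ranked = enumerate_and_search(
                    m, config=SearchConfig(max_total_inputs=2)
                )
                tops.append(ranked[0].cmargin)
            except ValueError:
                tops.append(0.0)  # empty candidate pool: no signal at all
        planted_cm = score_circuit(
            CircuitTopology(high_gate={"mark-high"}, low_sensors={"mark-low"}),
            matrix,
        ).cmargin
        # shuffling destroys the signal: far below the planted margin
        assert np.mean(tops) < 0.5 * planted_cm

    def test_empty_pool_errors(self):
        matrix = make_matrix(
            values={"m1": {"p": 10.0, "n": 10.0}, "m2": {"p": 1.0, "n": 1.0}},
            labels={"p": "positive", "n": "negative"},
        )
        with pytest.raises(ValueError, match="candidate pool"):
            enumerate_and_search(matrix)

    def test_topology_cap_errors(self):
        matrix, _ = self._planted_matrix(seed=2)
        config = SearchConfig(max_total_inputs=3, max_topologies=1)
        with pytest.raises(ValueError, match="cap"):
            enumerate_and_search(matrix, config=config)

    def test_parameter_recovery_rate(self):
        # >= 95/100 seeded replicates recover the planted 2-marker topology
        hits = 0
        for seed in range(100):
            spec = GeneratorSpec(
                seed=seed, n_positive=3, n_negative=6, n_background_mirnas=15,
                planted_high=(PlantedMarker("mark-high", 3000.0, 10.0),),
                planted_low=(PlantedMarker("mark-low", 0.0, 2000.0),),
                noise_cv=0.2,
            )
            matrix, _ = generate_expression(spec)
            try:
                ranked = enumerate_and_search(
                    matrix, config=SearchConfig(max_total_inputs=2)
                )
            except ValueError:
                continue
            best = ranked[0].topology
            if best.high_gate == {"mark-high"} and best.low_sensors == {"mark-low"}:
                hits += 1
        assert hits >= 95


class TestPruning:
    def test_constant_expression_input_is_pruned(self):
        matrix = make_matrix(
            values={
                "mark-high": {"p1": 3000.0, "p2": 2800.0, "n1": 0.0, "n2": 10.0},
                "constant-low": {"p1": 0.0, "p2": 0.0, "n1": 0.0, "n2": 0.0},
                "bg": {"p1": 10.0, "p2": 10.0, "n1": 10.0, "n2": 10.0},
            },
            labels={"p1": "positive", "p2": "positive",
                    "n1": "negative", "n2": "negative"},
        )
        topology = CircuitTopology(
            high_gate={"mark-high"}, low_sensors={"constant-low"}
        )
        scored = score_circuit(topology, matrix)
        config = SearchConfig(prune=True, seed=1, bootstrap_reps=50)
        pruned = prune_circuit(scored, matrix, config=config)
        assert pruned.topology.inputs == {"mark-high"}

    def test_strong_contributors_survive(self):
        spec = GeneratorSpec(
            seed=21, n_positive=4, n_negative=8, n_background_mirnas=10,
            planted_high=(PlantedMarker("mark-high", 3000.0, 0.0),),
            planted_low=(PlantedMarker("mark-low", 0.0, 3000.0),),
            noise_cv=0.3,
        )
        matrix, _ = generate_expression(spec)
        topology = CircuitTopology(
            high_gate={"mark-high"}, low_sensors={"mark-low"}
        )
        scored = score_circuit(topology, matrix)
        config = SearchConfig(prune=True, seed=2, bootstrap_reps=100)
        pruned = prune_circuit(scored, matrix, config=config)
        assert pruned.topology == topology

    def test_seeded_determinism(self, four_sample_matrix):
        topology = CircuitTopology(
            high_gate={"miR-high"}, low_sensors={"miR-low", "miR-bg"}
        )
        scored = score_circuit(topology, four_sample_matrix)
        config = SearchConfig(prune=True, seed=7, bootstrap_reps=50)
        a = prune_circuit(scored, four_sample_matrix, config=config)
        b = prune_circuit(scored, four_sample_matrix, config=config)
        assert a.topology == b.topology
        assert a.cmargin == b.cmargin

    def test_requires_prune_flag(self, four_sample_matrix):
        scored = score_circuit(
            CircuitTopology(high_gate={"miR-high"}), four_sample_matrix
        )
        with pytest.raises(ValueError, match="prune"):
            prune_circuit(scored, four_sample_matrix, config=SearchConfig())
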