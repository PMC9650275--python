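import numpy as np
import pandas as pd
import pytest

from mircircuit.expression_data import ExpressionMatrix, MiRNARecord


def make_matrix(values: dict, labels: dict, sequences: dict | None = None,
                **kwargs) -> ExpressionMatrix:
    """Small-matrix helper: values is {mirna: {sample: level}}."""
    frame = pd.DataFrame(values, dtype=float)
    sequences = sequences or {}
    records = [
        MiRNARecord(
            name=c,
            mature_sequence=sequences.get(c, _default_seq(i)),
        )
        for i, c in enumerate(frame.columns)
    ]
    return ExpressionMatrix(
        values=frame,
        labels=pd.Series(labels),
        mirnas=records,
        **kwargs,
    )


def _default_seq(i: int) -> str:
    # deterministic distinct 12-mers
    bases = "ACGT"
    return "".join(bases[(i >> (2 * k)) & 3] for k in range(6)) * 2


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_sample_matrix():
    """2 positives / 2 negatives with one clean high and one clean low marker."""
    return make_matrix(
        values={
            "miR-high": {"p1": 3000.0, "p2": 2500.0, "n1": 0.0, "n2": 5.0},
            "miR-low": {"p1": 0.0, "p2": 0.0, "n1": 2000.0, "n2": 1500.0},
            "miR-bg": {"p1": 10.0, "p2": 12.0, "n1": 9.0, "n2": 11.0},
        },
        labels={"p1": "positive", "p2": "positive",
                "n1": "negative", "n2": "negative"},
    )
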