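"""Reading, merging, replicate-averaging and binarization of multi-source
miRNA expression matrices.

The central object is :class:`ExpressionMatrix`: a samples x miRNAs abundance
table together with per-miRNA mature sequences and per-sample class labels
(``positive`` / ``negative``).  Datasets coming from different sequencing
sources use inconsistent miRNA names, so merging identifies miRNAs by their
mature sequence (uppercased, U->T normalized) rather than by name; records
flagged as hairpins (or matching a supplied hairpin-sequence list) are
dropped before merging.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MiRNARecord",
    "ExpressionMatrix",
    "BinarizedMatrix",
    "merge_datasets",
    "average_replicates",
    "binarize",
    "normalize_sequence",
    "read_expression_tables",
    "write_merged",
]

POSITIVE = "positive"
NEGATIVE = "negative"
VALID_LABELS = frozenset({POSITIVE, NEGATIVE})
VALID_UNITS = frozenset({"copies_per_cell", "counts", "fraction"})

_SEQ_ALPHABET = frozenset("ACGUT")


def normalize_sequence(sequence: str) -> str:
    """Canonical sequence key: uppercase with U mapped to T.

    Two records with the same key describe the same mature species and are
    unified during merging.
    """
    key = sequence.strip().upper().replace("U", "T")
    if not key:
        raise ValueError("empty mature sequence")
    bad = set(key) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)!r}")
    return key


@dataclass(frozen=True)
class MiRNARecord:
    """A single miRNA annotation as provided by one source dataset."""

    name: str
    mature_sequence: str
    source_dataset: str = ""
    is_hairpin: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("miRNA record needs a non-empty name")
        object.__setattr__(
            self, "mature_sequence", self.mature_sequence.strip().upper()
        )
        normalize_sequence(self.mature_sequence)  # alphabet check

    @property
    def sequence_key(self) -> str:
        return normalize_sequence(self.mature_sequence)


@dataclass
class ExpressionMatrix:
    """Samples x miRNAs abundance matrix with labels and sequences.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per miRNA name.
        All entries must be finite and non-negative.
    labels
        Per-sample class, ``"positive"`` or ``"negative"``.
    mirnas
        One :class:`MiRNARecord` per column of ``values``.
    cell_state
        Optional free-text state name per sample.
    replicate_group
        Optional per-sample replicate group id (NaN / missing = ungrouped).
    units
        One of ``copies_per_cell``, ``counts``, ``fraction``.
    name
        Source-dataset tag, used to prefix sample ids during merging.
    """

    values: pd.DataFrame
    labels: pd.Series
    mirnas: list[MiRNARecord] = field(default_factory=list)
    cell_state: pd.Series | None = None
    replicate_group: pd.Series | None = None
    units: str = "copies_per_cell"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate miRNA names in matrix columns")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("non-finite abundance values")
        if (arr < 0).any():
            raise ValueError("negative abundance values")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"samples without a label: {missing}")
        bad = set(self.labels.unique()) - VALID_LABELS
        if bad:
            raise ValueError(f"invalid labels {sorted(bad)!r}")
        if not self.mirnas:
            self.mirnas = [
                MiRNARecord(name=c, mature_sequence="A")
                for c in self.values.columns
            ]
        by_name = {rec.name: rec for rec in self.mirnas}
        if len(by_name) != len(self.mirnas):
            raise ValueError("duplicate miRNA names among records")
        missing_recs = [c for c in self.values.columns if c not in by_name]
        if missing_recs:
            raise ValueError(f"columns without a MiRNARecord: {missing_recs}")
        self.mirnas = [by_name[c] for c in self.values.columns]
        if self.cell_state is not None:
            self.cell_state = self.cell_state.reindex(self.values.index)
        if self.replicate_group is not None:
            self.replicate_group = self.replicate_group.reindex(self.values.index)

    # -- convenience accessors -------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def mirna_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def positive_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == POSITIVE])

    @property
    def negative_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == NEGATIVE])

    def record(self, mirna_name: str) -> MiRNARecord:
        for rec in self.mirnas:
            if rec.name == mirna_name:
                return rec
        raise KeyError(mirna_name)

    def with_prefix(self, prefix: str) -> "ExpressionMatrix":
        """Return a copy with every sample id prefixed by ``prefix + '/'``."""
        mapper = {s: f"{prefix}/{s}" for s in self.samples}
        return replace(
            self,
            values=self.values.rename(index=mapper),
            labels=self.labels.rename(index=mapper),
            cell_state=None
            if self.cell_state is None
            else self.cell_state.rename(index=mapper),
            replicate_group=None
            if self.replicate_group is None
            else self.replicate_group.rename(index=mapper),
        )


@dataclass
class BinarizedMatrix:
    """Expression-over-threshold ratios for each sample/miRNA pair.

    ``ratio_over_t[s, m] > 1`` iff miRNA ``m`` exceeds the binarization
    threshold ``t = t_fraction * total abundance of sample s``.
    """

    ratio_over_t: pd.DataFrame
    labels: pd.Series
    t_fraction: float

    def above_threshold(self) -> pd.DataFrame:
        return self.ratio_over_t > 1.0


def _drop_hairpins(
    dataset: ExpressionMatrix, hairpin_keys: frozenset[str]
) -> ExpressionMatrix:
    keep = [
        rec.name
        for rec in dataset.mirnas
        if not rec.is_hairpin and rec.sequence_key not in hairpin_keys
    ]
    return replace(
        dataset,
        values=dataset.values[keep],
        mirnas=[r for r in dataset.mirnas if r.name in set(keep)],
    )


def merge_datasets(
    datasets: Sequence[ExpressionMatrix],
    hairpin_sequences: Iterable[str] = (),
) -> tuple[ExpressionMatrix, dict[str, list[dict[str, str]]]]:
    """Merge several source datasets into a single matrix keyed by sequence.

    Hairpin records (flagged, or matching ``hairpin_sequences``) are removed.
    miRNAs sharing a mature sequence are unified into one column whose
    per-sample abundance is the SUM over the unified records; miRNAs absent
    from a dataset contribute zeros for that dataset's samples.  Sample ids
    are prefixed with the dataset name.

    Returns the merged matrix and a provenance map:
    merged column name -> list of {dataset, name} source records.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    hairpin_keys = frozenset(normalize_sequence(s) for s in hairpin_sequences)

    cleaned = []
    for i, ds in enumerate(datasets):
        ds = _drop_hairpins(ds, hairpin_keys)
        prefix = ds.name or f"ds{i}"
        cleaned.append((prefix, ds.with_prefix(prefix)))

    all_samples: list[str] = []
    for _, ds in cleaned:
        for s in ds.samples:
            if s in all_samples:
                raise ValueError(f"duplicate sample id after prefixing: {s!r}")
            all_samples.append(s)

    # sequence key -> accumulated per-sample sums and source provenance
    by_key: dict[str, dict] = {}
    for prefix, ds in cleaned:
        for rec in ds.mirnas:
            key = rec.sequence_key
            entry = by_key.setdefault(
                key, {"names": [], "sources": [], "records": []}
            )
            entry["names"].append(rec.name)
            entry["sources"].append({"dataset": prefix, "name": rec.name})
            entry["records"].append(rec)

    if not by_key:
        raise ValueError("no usable miRNAs remain after hairpin elimination")

    merged = pd.DataFrame(0.0, index=all_samples, columns=list(by_key))
    for prefix, ds in cleaned:
        key_of = {rec.name: rec.sequence_key for rec in ds.mirnas}
        for col in ds.mirna_names:
            merged.loc[ds.samples, key_of[col]] += ds.values[col].to_numpy()

    canonical = {key: min(e["names"]) for key, e in by_key.items()}
    if len(set(canonical.values())) != len(canonical):
        # same name reused for different sequences across sources; keep
        # columns distinct by appending the sequence key
        seen: dict[str, int] = {}
        for key in canonical:
            nm = canonical[key]
            if nm in seen or list(canonical.values()).count(nm) > 1:
                canonical[key] = f"{nm}|{key[:8]}"
            seen[nm] = 1
    merged = merged.rename(columns=canonical)

    labels = pd.concat([ds.labels for _, ds in cleaned])
    cell_state_parts = [
        ds.cell_state for _, ds in cleaned if ds.cell_state is not None
    ]
    replicate_parts = [
        ds.replicate_group for _, ds in cleaned if ds.replicate_group is not None
    ]
    units = {ds.units for _, ds in cleaned}
    if len(units) > 1:
        raise ValueError(f"datasets disagree on units: {sorted(units)}")

    records = [
        MiRNARecord(
            name=canonical[key],
            mature_sequence=key,
            source_dataset="+".join(
                sorted({s["dataset"] for s in e["sources"]})
            ),
        )
        for key, e in by_key.items()
    ]
    provenance = {canonical[key]: e["sources"] for key, e in by_key.items()}

    out = ExpressionMatrix(
        values=merged,
        labels=labels,
        mirnas=records,
        cell_state=pd.concat(cell_state_parts) if cell_state_parts else None,
        replicate_group=pd.concat(replicate_parts) if replicate_parts else None,
        units=units.pop(),
        name="merged",
    )
    return out, provenance


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate groups to their arithmetic mean.

    Rows without a replicate group are passed through unchanged.  Labels
    (and cell states, when present) must agree within each group.
    """
    if matrix.replicate_group is None or matrix.replicate_group.isna().all():
        raise ValueError("replicate_group is not populated")
    group = matrix.replicate_group.copy()
    ungrouped = group.isna()
    # every ungrouped sample forms its own singleton group
    group[ungrouped] = pd.Series(matrix.samples, index=matrix.values.index)[
        ungrouped
    ]

    new_rows, new_labels, new_states = {}, {}, {}
    for gid, members in group.groupby(group).groups.items():
        members = list(members)
        labels = set(matrix.labels[members])
        if len(labels) > 1:
            raise ValueError(
                f"conflicting labels {sorted(labels)} within replicate "
                f"group {gid!r}"
            )
        new_rows[str(gid)] = matrix.values.loc[members].mean(axis=0)
        new_labels[str(gid)] = labels.pop()
        if matrix.cell_state is not None:
            states = set(matrix.cell_state[members].dropna())
            new_states[str(gid)] = states.pop() if len(states) == 1 else None

    values = pd.DataFrame(new_rows).T[matrix.mirna_names]
    return ExpressionMatrix(
        values=values,
        labels=pd.Series(new_labels),
        mirnas=matrix.mirnas,
        cell_state=pd.Series(new_states) if new_states else None,
        replicate_group=None,
        units=matrix.units,
        name=matrix.name,
    )


def binarize(matrix: ExpressionMatrix, t_fraction: float = 0.01) -> BinarizedMatrix:
    """Compute per-sample expression-over-threshold ratios.

    For each sample the threshold is ``t = t_fraction * total abundance``;
    the returned ratios are ``abundance / t``, so a ratio above 1 marks the
    miRNA as biologically relevant in that sample.
    """
    if not 0.0 < t_fraction < 1.0:
        raise ValueError("t_fraction must lie in (0, 1)")
    totals = matrix.values.sum(axis=1)
    zero = totals[totals <= 0.0]
    if not zero.empty:
        raise ValueError(
            f"sample(s) with zero total abundance: {list(zero.index)}"
        )
    ratio = matrix.values.div(totals * t_fraction, axis=0)
    return BinarizedMatrix(
        ratio_over_t=ratio, labels=matrix.labels.copy(), t_fraction=t_fraction
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_expression_tables(
    matrix_csv: str | Path,
    sequences_csv: str | Path,
    samples_csv: str | Path,
    units: str = "copies_per_cell",
    dataset: str | None = None,
) -> list[ExpressionMatrix]:
    """Read the wide-matrix / sequence-table / sample-sheet CSV triplet.

    ``matrix_csv`` is wide (rows = miRNAs, columns = samples).  The sample
    sheet needs columns ``sample`` and ``label``; ``cell_state``,
    ``replicate_group`` and ``dataset`` are optional.  One
    :class:`ExpressionMatrix` is returned per distinct dataset tag.
    """
    wide = pd.read_csv(matrix_csv, index_col=0)
    seqs = pd.read_csv(sequences_csv)
    sheet = pd.read_csv(samples_csv)

    if "sample" not in sheet.columns or "label" not in sheet.columns:
        raise ValueError("sample sheet needs 'sample' and 'label' columns")
    sheet = sheet.set_index("sample")
    if "dataset" not in sheet.columns:
        sheet["dataset"] = dataset or ""

    seqs = seqs.set_index("name")
    if "is_hairpin" not in seqs.columns:
        seqs["is_hairpin"] = False

    out = []
    for ds_name, sub in sheet.groupby("dataset", sort=True):
        cols = [s for s in sub.index if s in wide.columns]
        missing = set(sub.index) - set(cols)
        if missing:
            raise ValueError(f"samples missing from matrix: {sorted(missing)}")
        values = wide[cols].T
        records = []
        for mirna in values.columns:
            if mirna not in seqs.index:
                raise ValueError(f"no sequence provided for {mirna!r}")
            row = seqs.loc[mirna]
            records.append(
                MiRNARecord(
                    name=mirna,
                    mature_sequence=str(row["sequence"]),
                    source_dataset=str(ds_name),
                    is_hairpin=bool(row["is_hairpin"]),
                )
            )
        out.append(
            ExpressionMatrix(
                values=values,
                labels=sub["label"],
                mirnas=records,
                cell_state=sub.get("cell_state"),
                replicate_group=sub.get("replicate_group"),
                units=units,
                name=str(ds_name),
            )
        )
    return out


def write_merged(
    matrix: ExpressionMatrix,
    provenance: Mapping[str, list[dict[str, str]]],
    out_prefix: str | Path,
) -> None:
    """Write ``<prefix>.csv`` (wide matrix + labels) and ``<prefix>.provenance.json``."""
    out_prefix = Path(out_prefix)
    table = matrix.values.copy()
    table.insert(0, "label", matrix.labels)
    table.to_csv(out_prefix.with_suffix(".csv"), index_label="sample")
    with open(out_prefix.with_suffix(".provenance.json"), "w") as fh:
        json.dump(dict(provenance), fh, indent=2, sort_keys=True)


def read_merged(path: str | Path, units: str = "copies_per_cell") -> ExpressionMatrix:
    """Read a matrix written by :func:`write_merged` (long orientation:
    rows = samples, ``label`` column plus one column per miRNA)."""
    table = pd.read_csv(path, index_col="sample")
    labels = table.pop("label")
    records = [
        MiRNARecord(name=c, mature_sequence="A") for c in table.columns
    ]
    warnings.warn(
        "read_merged reconstructs placeholder sequences; re-merge from the "
        "source tables if sequence identity matters",
        stacklevel=2,
    )
    return ExpressionMatrix(
        values=table, labels=labels, mirnas=records, units=units, name="merged"
    )
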