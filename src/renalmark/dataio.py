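"""Readers and writers for the tabular and sequence formats the pipeline touches.

Canonical tabular dialect is tab-separated text with a plain decimal
point and no thousands separators. Floats are serialized at full
precision (repr round-trip) so every writer/reader pair is lossless.
All genomic-style positions are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ExpressionMatrix",
    "DataIOError",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_fasta_utrs",
    "write_fasta_utrs",
    "read_gmt",
    "write_gmt",
]

# order used for ordinal ranks when the annotation does not give one
_DEFAULT_GROUP_ORDER = ["normal", "T1", "T2", "T3", "T4", "G1", "G2", "G3", "G4"]

_UTR_ALPHABET = set("ACGTN")


class DataIOError(ValueError):
    """Raised for malformed input files."""


@dataclass
class ExpressionMatrix:
    """A features-by-samples expression matrix with group annotations.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows are features (genes or miRNA families), columns are
        sample ids; entries are non-negative expression values.
    groups : pandas.Series
        Group label per sample (index = sample ids), e.g. normal,
        T1..T4 or G1..G4.
    unit : str
        Unit of the values, e.g. "RPKM" for genes or "RPM" for miRNAs.
    ordinal_rank : dict
        Optional group -> integer rank used by ordered-trend tests.
    """

    values: pd.DataFrame
    groups: pd.Series
    unit: str = "RPKM"
    ordinal_rank: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataIOError(f"duplicate feature id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise DataIOError(f"samples missing from annotation: {missing}")
        if self.values.isna().any().any():
            raise DataIOError("matrix contains missing values")

    @property
    def features(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list:
        sel = self.groups.loc[list(self.values.columns)]
        return list(sel.index[sel == group])

    def group_labels(self) -> list:
        seen = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen


def read_annotation(path) -> tuple[pd.Series, dict]:
    """Read a sample-annotation TSV: sample_id, group[, ordinal_rank].

    Returns the group Series and a group -> rank dict (empty when the
    rank column is absent). Ranks must be consistent within a group.
    """
    ann = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if ann.shape[1] < 2:
        raise DataIOError(f"annotation file {path} needs at least sample_id and group columns")
    ann.columns = ["sample_id", "group"] + list(ann.columns[2:])
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataIOError(f"duplicate sample id in annotation: {dup!r}")
    groups = pd.Series(ann["group"].values, index=ann["sample_id"].values, name="group")
    ranks: dict = {}
    if "ordinal_rank" in ann.columns:
        for g, sub in ann.groupby("group"):
            vals = sub["ordinal_rank"].dropna().unique()
            if len(vals) > 1:
                raise DataIOError(f"inconsistent ordinal_rank within group {g!r}: {sorted(vals)}")
            if len(vals) == 1:
                ranks[g] = int(vals[0])
    return groups, ranks


def write_annotation(groups: pd.Series, path, ordinal_rank: dict | None = None) -> None:
    df = pd.DataFrame({"sample_id": groups.index, "group": groups.values})
    if ordinal_rank:
        df["ordinal_rank"] = [ordinal_rank.get(g, "") for g in groups.values]
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path, annotation_path, unit: str = "RPKM") -> ExpressionMatrix:
    """Read a TSV expression matrix plus its sample annotation.

    First column holds feature ids, the header row sample ids. Every
    sample column must be annotated; duplicate feature ids and missing
    cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataIOError(f"duplicate feature id in {path}: {dup!r}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)]
        raise DataIOError(f"missing cells in {path} (first affected feature: {rows[0]!r})")
    if (df.values < 0).any():
        raise DataIOError(f"negative expression values in {path}")
    groups, ranks = read_annotation(annotation_path)
    return ExpressionMatrix(values=df, groups=groups, unit=unit, ordinal_rank=ranks)


def write_matrix(matrix: ExpressionMatrix, path, annotation_path=None) -> None:
    """Write the matrix (and optionally its annotation) as TSV.

    Floats go out via repr so read_matrix recovers them bit-exactly.
    """
    df = matrix.values
    with open(path, "w") as fh:
        fh.write("feature\t" + "\t".join(map(str, df.columns)) + "\n")
        for fid, row in zip(df.index, df.values):
            fh.write(str(fid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    if annotation_path is not None:
        write_annotation(matrix.groups, annotation_path, matrix.ordinal_rank)


def _normalize_seq(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    for pos, ch in enumerate(s):
        if ch not in _UTR_ALPHABET:
            raise DataIOError(
                f"record {record_id!r}: invalid character {ch!r} at position {pos}"
            )
    return s


def read_fasta_utrs(path) -> list[tuple[str, str]]:
    """Read 3'UTR sequences from FASTA.

    Sequences are uppercased with U mapped to T so one DNA alphabet
    serves miRNA and UTR inputs alike. The record id is the first
    whitespace-delimited header token. Empty sequences and characters
    outside {A,C,G,T,U,N} are rejected.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise DataIOError(f"record {rec.id!r}: empty sequence")
        records.append((rec.id, _normalize_seq(seq, rec.id)))
    return records


def write_fasta_utrs(records, path) -> None:
    with open(path, "w") as fh:
        for gid, seq in records:
            fh.write(f">{gid}\n{seq}\n")


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT gene-set file: name TAB description TAB gene TAB gene...

    Duplicate genes within a line collapse to one (first occurrence
    kept, order preserved); lines with fewer than three fields and
    empty sets are rejected with the line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataIOError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = parts[0], parts[1]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise DataIOError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append((name, desc, genes))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *genes]) + "\n")
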