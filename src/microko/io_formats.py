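"""Readers and writers for the external formats the pipeline touches.

Supported formats: BLAST/DIAMOND 12-column tabular hit files ("outfmt 6"),
FASTA (plain and aligned), FASTQ with Phred+33 qualities, Newick trees, and
labeled numeric matrices as TSV.  Every reader/writer pair round-trips on its
valid domain; parsing is locale-independent.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "HitRecord",
    "QualityRead",
    "FormatError",
    "read_hit_table",
    "write_hit_table",
    "read_alignment_fasta",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_newick",
    "write_newick",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

PHRED_OFFSET = 33


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular alignment report.

    Field order mirrors ``qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore``.  ``subject_id`` carries the
    KO identifier (e.g. ``K00001``) when the reference is a KO database.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError(f"negative e-value {self.e_value} for {self.query_id}")
        if self.bit_score < 0:
            raise FormatError(f"negative bit score {self.bit_score} for {self.query_id}")
        if self.q_start > self.q_end:
            raise FormatError(f"q_start > q_end for {self.query_id}")


@dataclass(frozen=True)
class QualityRead:
    """A sequencing read with per-base Phred quality scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 or q > 93 for q in self.quals):
            raise FormatError(f"read {self.read_id}: Phred score outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


def read_hit_table(path: str | os.PathLike) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table into :class:`HitRecord` s.

    Records are returned in file order; per-query rank is file order (the
    aligner emits the best hit first).  Rows may carry extra trailing columns
    (ignored); fewer than 12 columns or non-numeric numeric fields raise
    :class:`FormatError` naming the offending line.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if not math.isfinite(rec.bit_score) or not math.isfinite(rec.e_value):
                raise FormatError(f"{path}:{lineno}: non-finite e-value or bit score")
            records.append(rec)
    return records


def write_hit_table(records: Iterable[HitRecord], path: str | os.PathLike) -> None:
    """Write records as 12-column tab-separated rows (inverse of reader)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        repr(r.percent_identity),
                        str(r.align_length),
                        str(r.mismatches),
                        str(r.gap_opens),
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        repr(r.e_value),
                        repr(r.bit_score),
                    ]
                )
                + "\n"
            )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{label: sequence}`` mapping.

    Sequences are upper-cased; duplicate labels raise :class:`FormatError`.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA label {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_alignment_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read an aligned FASTA file (>= 2 records, all the same length)."""
    seqs = read_fasta(path)
    if len(seqs) < 2:
        raise FormatError(f"{path}: alignment needs >= 2 sequences, got {len(seqs)}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise FormatError(
            f"{path}: unequal aligned sequence lengths {sorted(lengths)}"
        )
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> list[QualityRead]:
    """Read a 4-line-per-record FASTQ file with Phred+33 qualities.

    Quality characters decode as ``ord(c) - 33``; no encoding auto-detection
    is attempted.  Truncated records and base/quality length mismatches raise
    :class:`FormatError`.
    """
    reads: list[QualityRead] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            reads.append(QualityRead(rec.id, str(rec.seq).upper(), quals))
    except ValueError as exc:  # Biopython signals truncation / length mismatch
        raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[QualityRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    """Serialize a tree as Newick with branch lengths at 10 significant digits.

    Requires >= 2 leaves and unique leaf labels; labels needing quoting are
    quoted per the Newick convention so a round-trip reproduces them.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise FormatError("tree must have >= 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise FormatError("duplicate leaf labels")
    text = tree.as_string(
        schema="newick",
        real_value_format_specifier=".10g",
        suppress_rooting=True,
    )
    with open(path, "w") as fh:
        fh.write(text)


def read_newick(
    path: str | os.PathLike,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a labeled numeric matrix from TSV (first row/column are labels).

    Ragged rows, non-numeric cells, missing cells and duplicate labels all
    raise :class:`FormatError`.
    """
    try:
        df = pd.read_csv(str(path), sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate row labels")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate column labels")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells are not allowed")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a labeled matrix as TSV, preserving values to full precision."""
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError("duplicate labels in matrix")
    df.to_csv(str(path), sep="\t", float_format="%.17g")


def decode_phred(qual_string: str) -> tuple[int, ...]:
    """Decode a Phred+33 quality string to integer scores."""
    return tuple(ord(c) - PHRED_OFFSET for c in qual_string)
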