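"""Readers and writers for every external format the pipeline touches.

FASTQ is Phred+33 only (records with out-of-range quality characters are
rejected rather than silently reinterpreted as Phred+64).  Tables are TSV.
All internal coordinates are 0-based half-open; 1-based coordinates appear
only in report files.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("mejamir")

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Well-formed input that violates a pipeline contract."""


@dataclass
class RawRead:
    """One sequenced small-RNA read with per-base Phred qualities."""

    id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValidationError(
                f"read {self.id}: quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )
        if any(q < 0 or q > 60 for q in self.qual):
            raise ValidationError(f"read {self.id}: quality outside [0, 60]")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path) -> Iterator[RawRead]:
    """Stream 4-line FASTQ records as RawRead, in file order.

    Raises ParseError (naming the line number) for truncated records or
    seq/qual length mismatches, and for quality characters outside the
    Phred+33 range 0–60 (which would indicate a Phred+64 file).
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}: line {lineno}: expected '@' header")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ParseError(f"{path}: line {lineno}: truncated record")
            lineno += 3
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            phred = [ord(c) - 33 for c in qual]
            if any(q < 0 or q > 60 for q in phred):
                raise ParseError(
                    f"{path}: line {lineno}: quality outside Phred+33 range (Phred+64 not supported)"
                )
            yield RawRead(header[1:].split()[0] if header[1:].strip() else "", seq.upper(), phred)


def write_fastq(path, reads: Iterable[RawRead]) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.qual) + "\n")
            n += 1
    return n


def read_fasta(path) -> dict[str, str]:
    """FASTA → ordered {id: sequence}; duplicate ids are rejected."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_expression_tsv(path, sample_order: list[str] | None = None) -> pd.DataFrame:
    """Gene × sample expression matrix from TSV.

    Columns are reordered to the sample-sheet order when given.  Negative
    values and duplicate gene ids are validation errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative expression value")
    if sample_order is not None:
        missing = [s for s in sample_order if s not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing sample columns {missing}")
        df = df[sample_order]
    return df


def write_expression_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t")


@dataclass
class AnnotationTable:
    """Flat gene → term memberships plus term names (pathway or GO)."""

    gene_terms: dict[str, set[str]]
    term_names: dict[str, str]

    def __post_init__(self) -> None:
        for g, terms in self.gene_terms.items():
            if not terms:
                raise ValidationError(f"gene {g!r} has an empty term set")

    @property
    def genes(self) -> set[str]:
        return set(self.gene_terms)

    def term_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, terms in self.gene_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(g)
        return out


def read_annotation_tsv(path) -> AnnotationTable:
    """Two- or three-column TSV (gene_id, term_id[, term_name]) → AnnotationTable.

    Repeated memberships collapse to a set; a blank gene id is an error.
    """
    gene_terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >= 2 columns")
            gene, term = parts[0].strip(), parts[1].strip()
            if not gene:
                raise ValidationError(f"{path}: line {lineno}: blank gene id")
            if not term:
                raise ValidationError(f"{path}: line {lineno}: blank term id")
            gene_terms.setdefault(gene, set()).add(term)
            if len(parts) >= 3 and parts[2].strip():
                names[term] = parts[2].strip()
    return AnnotationTable(gene_terms, names)


def write_annotation_tsv(path, table: AnnotationTable) -> None:
    with open(path, "w") as fh:
        for gene in sorted(table.gene_terms):
            for term in sorted(table.gene_terms[gene]):
                name = table.term_names.get(term, "")
                fh.write(f"{gene}\t{term}\t{name}\n")


def log_stage(stage: str, n_in: int, n_out: int, **params) -> None:
    """Per-stage count accounting, one grep-able line."""
    extras = " ".join(f"{k}={v}" for k, v in params.items())
    log.info("%s: in=%d out=%d %s", stage, n_in, n_out, extras)
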