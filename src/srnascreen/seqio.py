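"""Sequence, annotation and table I/O; coordinate and strand conventions.

Conventions used package-wide:

* Files use 1-based inclusive genomic intervals; all reported positions are
  1-based.  (Internal array computations are 0-based half-open.)
* Start-codon-relative positions: the first nt of the start codon is +1, the
  nt immediately 5' of it is -1; there is no position 0.
* DNA input is transparently converted to RNA (T -> U, uppercased).  IUPAC
  ambiguity codes are rejected — they have no defined pairing energy, so
  records carrying them must be cleaned upstream.
* All thermodynamics operate on transcript-oriented (5'->3') sequences;
  minus-strand genes are reverse-complemented once, at transcript build.

Annotations use a documented TSV dialect with columns::

    gene_id  contig  start  end  strand  start_codon  tss  operon_id  operon_rank

``tss``, ``operon_id`` and ``operon_rank`` may be empty.  Strand must be
``+`` or ``-`` (a GFF-style ``.`` is an error: strand is required).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "NucleotideSequence", "GeneAnnotation", "TranscriptModel",
    "ExpressionRecord", "read_fasta", "write_fasta", "read_annotations",
    "write_annotations", "build_transcript", "read_expression",
    "write_expression", "write_table", "reverse_complement",
]

RNA_ALPHABET = set("ACGU")

ANNOTATION_COLUMNS = ["gene_id", "contig", "start", "end", "strand",
                      "start_codon", "tss", "operon_id", "operon_rank"]


class ParseError(ValueError):
    """Malformed input file."""


def _normalize(residues: str) -> str:
    return residues.upper().replace("T", "U")


def reverse_complement(residues: str) -> str:
    return _normalize(str(Seq(_normalize(residues)).reverse_complement_rna()))


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA sequence; residues normalized to uppercase A/C/G/U."""

    id: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", _normalize(self.residues))
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGU characters {sorted(bad)}"
                " (IUPAC ambiguity codes are rejected: no defined pairing energy)")

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive genomic slice."""
        return self.residues[start - 1:end]


@dataclass(frozen=True)
class GeneAnnotation:
    """Strand-resolved gene with translation start and optional TSS/operon."""

    gene_id: str
    contig_id: str
    span: tuple[int, int]
    strand: str
    start_codon_pos: int
    tss_pos: int | None = None
    operon_id: str | None = None
    operon_rank: int | None = None

    def __post_init__(self):
        s, e = self.span
        if s > e or s < 1:
            raise ValueError(f"{self.gene_id}: empty or invalid span {self.span}")
        if self.strand not in ("+", "-"):
            raise ParseError(f"{self.gene_id}: strand required (+ or -), got "
                             f"{self.strand!r}")
        if not s <= self.start_codon_pos <= e:
            raise ValueError(f"{self.gene_id}: start codon {self.start_codon_pos}"
                             f" outside span {self.span}")
        if self.tss_pos is not None:
            upstream = (self.tss_pos <= self.start_codon_pos if self.strand == "+"
                        else self.tss_pos >= self.start_codon_pos)
            if not upstream:
                raise ValueError(f"{self.gene_id}: TSS {self.tss_pos} not upstream"
                                 " of the start codon in transcript orientation")
        if self.operon_rank is not None and self.operon_rank < 1:
            raise ValueError(f"{self.gene_id}: operon_rank must be >= 1")


@dataclass(frozen=True)
class TranscriptModel:
    """Transcript in 5'->3' orientation with translation-start bookkeeping.

    ``utr_length`` is None when the 5'-UTR start is unknown (the sequence
    then begins at the configured fallback distance upstream of the start
    codon); ``start_codon_offset`` is the transcript-local (1-based) position
    of the first start-codon nt.
    """

    gene_id: str
    sequence: NucleotideSequence
    utr_length: int | None
    start_codon_offset: int

    def __post_init__(self):
        if self.utr_length is not None and \
                self.start_codon_offset != self.utr_length + 1:
            raise ValueError(f"{self.gene_id}: start_codon_offset must equal"
                             " utr_length + 1 when the UTR is known")
        if len(self.sequence) < self.start_codon_offset:
            raise ValueError(f"{self.gene_id}: sequence shorter than the"
                             " start-codon offset")


@dataclass(frozen=True)
class ExpressionRecord:
    """Mutant/wild-type transcript-level ratio for one gene."""

    gene_id: str
    fold_change: float

    def __post_init__(self):
        if not self.fold_change > 0:
            raise ValueError(f"{self.gene_id}: fold change must be positive")

    @property
    def direction(self) -> str:
        """'up' for fold >= 1, 'down' otherwise."""
        return "up" if self.fold_change >= 1.0 else "down"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[NucleotideSequence]:
    """Read a multi-FASTA file; T is normalized to U, case folded upper.

    Ambiguity codes or empty records raise :class:`ParseError` naming the
    offending line.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = _normalize(str(rec.seq))
        if not raw:
            raise ParseError(f"{path}: record {rec.id!r} is empty "
                             f"(line {_find_line(path, rec.id)})")
        bad = set(raw) - RNA_ALPHABET
        if bad:
            line = _find_bad_line(path, rec.id, bad)
            raise ParseError(f"{path}: record {rec.id!r} contains non-ACGU "
                             f"character(s) {sorted(bad)} (line {line})")
        records.append(NucleotideSequence(rec.id, raw))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _find_line(path, rec_id) -> int:
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[0:1] == [rec_id]:
                return ln
    return 0


def _find_bad_line(path, rec_id, bad) -> int:
    in_rec = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_rec = line[1:].split()[0:1] == [rec_id]
            elif in_rec and set(_normalize(line.strip())) & bad:
                return ln
    return 0


def write_fasta(records: Iterable[NucleotideSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path) -> list[GeneAnnotation]:
    """Read the documented annotation TSV dialect (see module docstring)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str,
                                                         "contig": str})
    missing = {"gene_id", "contig", "start", "end", "strand",
               "start_codon"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        tss = getattr(row, "tss", None)
        tss = None if pd.isna(tss) else int(tss)
        op = getattr(row, "operon_id", None)
        op = None if pd.isna(op) else str(op)
        rank = getattr(row, "operon_rank", None)
        rank = None if pd.isna(rank) else int(rank)
        out.append(GeneAnnotation(
            gene_id=str(row.gene_id), contig_id=str(row.contig),
            span=(int(row.start), int(row.end)), strand=str(row.strand),
            start_codon_pos=int(row.start_codon), tss_pos=tss,
            operon_id=op, operon_rank=rank))
    return out


def write_annotations(annotations: Iterable[GeneAnnotation], path,
                      comments: Iterable[str] = ()) -> None:
    rows = [{
        "gene_id": a.gene_id, "contig": a.contig_id, "start": a.span[0],
        "end": a.span[1], "strand": a.strand, "start_codon": a.start_codon_pos,
        "tss": a.tss_pos, "operon_id": a.operon_id, "operon_rank": a.operon_rank,
    } for a in annotations]
    write_table(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS), path, comments)


def build_transcript(annotation: GeneAnnotation, genome: NucleotideSequence,
                     utr_fallback: int = 200) -> TranscriptModel:
    """Extract a transcript 5'->3' from the genome.

    When the TSS is unknown the transcript begins ``utr_fallback`` nt
    upstream of the annotated translation start (truncated at the contig
    edge, with a warning) and ``utr_length`` is flagged unknown (None).
    """
    s, e = annotation.span
    n = len(genome)
    if s < 1 or e > n:
        raise ValueError(f"{annotation.gene_id}: span {annotation.span} exceeds"
                         f" contig bounds 1..{n}")
    plus = annotation.strand == "+"
    codon = annotation.start_codon_pos
    if annotation.tss_pos is not None:
        five = annotation.tss_pos
        utr = abs(codon - five)
    else:
        five = codon - utr_fallback if plus else codon + utr_fallback
        utr = None
        if plus and five < 1:
            warnings.warn(f"{annotation.gene_id}: UTR fallback truncated at"
                          " contig start")
            five = 1
        elif not plus and five > n:
            warnings.warn(f"{annotation.gene_id}: UTR fallback truncated at"
                          " contig end")
            five = n
    if plus:
        residues = genome.slice(five, e)
        offset = codon - five + 1
    else:
        residues = reverse_complement(genome.slice(s, five))
        offset = five - codon + 1
    return TranscriptModel(
        gene_id=annotation.gene_id,
        sequence=NucleotideSequence(annotation.gene_id, residues),
        utr_length=utr,
        start_codon_offset=offset)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression(path, log2: bool = False) -> list[ExpressionRecord]:
    """Read a TSV of per-gene fold changes (ratio scale, or signed log2 with
    ``log2=True``).  Duplicated gene ids and non-positive ratios are errors."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    col = "log2_fold_change" if log2 else "fold_change"
    if "gene_id" not in df.columns or col not in df.columns:
        raise ParseError(f"{path}: need columns gene_id and {col}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    out = []
    for row in df.itertuples(index=False):
        fc = float(getattr(row, col))
        if log2:
            fc = 2.0 ** fc
        out.append(ExpressionRecord(str(row.gene_id), fc))
    return out


def write_expression(records: Iterable[ExpressionRecord], path,
                     comments: Iterable[str] = ()) -> None:
    df = pd.DataFrame([{"gene_id": r.gene_id, "fold_change": r.fold_change}
                       for r in records], columns=["gene_id", "fold_change"])
    write_table(df, path, comments)


def write_table(df: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    """TSV with a header line and '#'-prefixed provenance comments."""
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)
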