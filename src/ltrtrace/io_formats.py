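"""Readers and writers for on-disk formats, and the coordinate boundary.

Every coordinate held in memory anywhere in this package is 0-based,
half-open. Formats that are 1-based inclusive on disk (SAM, GFF3,
RepeatMasker ``.out``) are converted at parse time and converted back on
write; BED passes through unchanged. Soft-masked (lowercase) bases are
uppercased on read unless the caller asks otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GenomicInterval",
    "RepeatHit",
    "SamRecord",
    "FastqRead",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_sam",
    "write_sam",
    "read_bed",
    "write_bed",
    "read_gff_genes",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_panel_table",
    "write_panel_table",
]

_VALID_STRANDS = ("+", "-", ".")
_SEQ_RE = re.compile(r"^[ACGTN]+$")


class FormatError(ValueError):
    """A file violates the expectations of its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named reference sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RepeatHit:
    """One repeat-library match on an assembly (one ``.out`` data line)."""

    score: float
    pct_div: float
    query: GenomicInterval
    te_name: str
    te_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not (0.0 <= self.pct_div <= 100.0):
            raise ValueError("pct_div must be within [0, 100]")
        if self.te_span[0] < 0 or self.te_span[0] >= self.te_span[1]:
            raise ValueError(f"invalid te_span {self.te_span}")

    @property
    def span_length(self) -> int:
        return self.te_span[1] - self.te_span[0]


class SamRecord(NamedTuple):
    qname: str
    rname: str | None
    pos: int  # 0-based leftmost reference position; -1 when unmapped
    cigar: str | None
    mapq: int
    flags: int
    seq: str

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & 0x4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & 0x10)


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _check_sequence(name: str, seq: str) -> None:
    if not seq:
        raise FormatError(f"record {name!r}: empty sequence")
    if not _SEQ_RE.match(seq.upper()):
        bad = sorted(set(seq.upper()) - set("ACGTN"))
        raise FormatError(f"record {name!r}: illegal characters {bad}")


def read_fasta(path, keep_case: bool = False) -> list[tuple[str, str]]:
    """Read a nucleotide FASTA file as ``[(id, sequence), ...]`` in file order."""
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        _check_sequence(rec.id, seq)
        records.append((rec.id, seq if keep_case else seq.upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    seq_records = []
    for name, seq in records:
        _check_sequence(name, seq)
        seq_records.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_alignment_fasta(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA (gaps allowed) as ``[(id, row), ...]``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        row = str(rec.seq).upper()
        if not row:
            raise FormatError(f"record {rec.id!r}: empty row")
        bad = sorted(set(row) - set("ACGTN-"))
        if bad:
            raise FormatError(f"record {rec.id!r}: illegal characters {bad}")
        records.append((rec.id, row))
    return records


def read_fastq(path) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if len(r.sequence) != len(r.quality):
                raise FormatError(f"read {r.name!r}: sequence/quality length mismatch")
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# SAM

_CIGAR_QUERY_OPS = set("MIS=X")
_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into ``[(length, op), ...]``."""
    ops = _CIGAR_TOKEN.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return [(int(n), op) for n, op in ops]


def cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in cigar_ops(cigar) if op in _CIGAR_QUERY_OPS)


def cigar_reference_length(cigar: str) -> int:
    return sum(n for n, op in cigar_ops(cigar) if op in "MDN=X")


def read_sam(path) -> list[SamRecord]:
    """Read a text SAM file; positions become 0-based, unmapped reads kept."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        header_lines = str(sam.header).count("\n")
        records = []
        iterator = enumerate(sam)
        while True:
            try:
                i, aln = next(iterator)
            except StopIteration:
                break
            except OSError as exc:
                raise FormatError(
                    f"line {header_lines + len(records) + 1}: malformed SAM record"
                ) from exc
            line_no = header_lines + i + 1
            seq = aln.query_sequence or ""
            cigar = aln.cigarstring
            if cigar is not None and seq:
                if cigar_query_length(cigar) != len(seq):
                    raise FormatError(
                        f"line {line_no}: CIGAR {cigar} does not match "
                        f"{len(seq)} nt sequence"
                    )
            records.append(
                SamRecord(
                    qname=aln.query_name,
                    rname=aln.reference_name,
                    pos=aln.reference_start if not aln.is_unmapped else -1,
                    cigar=cigar,
                    mapq=aln.mapping_quality,
                    flags=aln.flag,
                    seq=seq,
                )
            )
    return records


def write_sam(records: Iterable[SamRecord], refs: list[tuple[str, int]], path) -> None:
    """Write text SAM; internal 0-based positions become 1-based on disk."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in refs:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in records:
            rname = r.rname if r.rname is not None else "*"
            pos = r.pos + 1 if r.pos >= 0 else 0
            cigar = r.cigar if r.cigar else "*"
            fh.write(
                f"{r.qname}\t{r.flags}\t{rname}\t{pos}\t{r.mapq}\t{cigar}"
                f"\t*\t0\t0\t{r.seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# BED

_BED_COLUMNS = ["seq_id", "start", "end", "name", "score", "strand"]


def read_bed(path) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED (3–6 columns) as ``[(interval, name, score), ...]``."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {line_no}: fewer than 3 BED columns")
            name = cols[3] if len(cols) > 3 else "."
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            strand = cols[5] if len(cols) > 5 else "."
            out.append(
                (GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand), name, score)
            )
    return out


def write_bed(features: Iterable[tuple[GenomicInterval, str, float]], path) -> None:
    with open(path, "w") as fh:
        for iv, name, score in features:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models


@dataclass
class GeneModel:
    """A gene span with (possibly empty) exon structure."""

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"exon {ex} outside gene span of {self.gene_id}")

    @property
    def first_exon_anchor(self) -> int:
        """Transcription-start anchor: the 5'-most exon edge, strand-aware."""
        if not self.exons:
            return self.span.start if self.span.strand != "-" else self.span.end
        if self.span.strand == "-":
            return max(ex.end for ex in self.exons)
        return min(ex.start for ex in self.exons)


def read_gff_genes(path) -> list[GeneModel]:
    """Read gene and exon features from GFF3 (1-based inclusive on disk)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        span = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        exons = [
            GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand)
            for ex in db.children(gene, featuretype="exon", order_by="start")
        ]
        models.append(GeneModel(gene.id, span, exons))
    return models


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeatmasker_out(path) -> list[RepeatHit]:
    """Parse a standard RepeatMasker ``.out`` table (3 header lines).

    Assembly coordinates are converted from 1-based inclusive to 0-based
    half-open; orientation ``C`` becomes strand ``-`` and the repeat span is
    taken from the reversed coordinate columns.
    """
    hits = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for line_no, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped:
            continue
        low = stripped.lower()
        if low.startswith(("sw", "score", "there were no")):
            continue
        cols = stripped.split()
        if len(cols) < 14:
            raise FormatError(f"line {line_no}: fewer than 14 columns")
        score = float(cols[0])
        pct_div = float(cols[1])
        q_name, q_begin, q_end = cols[4], int(cols[5]), int(cols[6])
        orientation = cols[8]
        te_name = cols[9]
        if orientation == "C":
            # reversed layout: (left), end, begin
            strand = "-"
            r_end, r_begin = int(cols[12]), int(cols[13])
        elif orientation == "+":
            strand = "+"
            r_begin, r_end = int(cols[11]), int(cols[12])
        else:
            raise FormatError(f"line {line_no}: orientation {orientation!r}")
        hits.append(
            RepeatHit(
                score=score,
                pct_div=pct_div,
                query=GenomicInterval(q_name, q_begin - 1, q_end, strand),
                te_name=te_name,
                te_span=(r_begin - 1, r_end),
            )
        )
    return hits


def write_repeatmasker_out(hits: Iterable[RepeatHit], path) -> None:
    """Write hits back in the canonical ``.out`` layout (round-trip partner)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query    matching"
            "  repeat         position in repeat\n"
            "score   div. del. ins.  sequence  begin end   (left)   repeat"
            "  class/family   begin end (left)  ID\n\n"
        )
        for i, h in enumerate(hits, 1):
            q = h.query
            if q.strand == "-":
                rep_cols = f"(0) {h.te_span[1]} {h.te_span[0] + 1}"
                orient = "C"
            else:
                rep_cols = f"{h.te_span[0] + 1} {h.te_span[1]} (0)"
                orient = "+"
            fh.write(
                f"{h.score:.0f} {h.pct_div:.1f} 0.0 0.0 {q.seq_id} "
                f"{q.start + 1} {q.end} (0) {orient} {h.te_name} "
                f"Unknown {rep_cols} {i}\n"
            )


# ---------------------------------------------------------------------------
# Panel metadata


def read_panel_table(path) -> pd.DataFrame:
    """Read a tab-separated strain panel (strain, year, location[, extra]).

    Years parse to pandas nullable integers; unparsable or absent years are
    left missing so downstream dating can exclude them. Duplicate strain ids
    are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    required = {"strain", "year", "location"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"panel table missing columns: {sorted(missing)}")
    dups = df["strain"][df["strain"].duplicated()].tolist()
    if dups:
        raise FormatError(f"duplicate strain ids: {sorted(set(dups))}")
    df["year"] = pd.to_numeric(df["year"], errors="coerce").astype("Int64")
    return df


def write_panel_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
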