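"""Genomic distribution and population frequency of element insertions.

Where an element lands (promoters, exons, introns, piRNA clusters) shapes
both its fitness cost and the host response; how often independent strains
carry the same insertion locus separates recent, still-segregating copies
from ancient fixed relics. Because each strain is assembled independently,
insertions are compared across strains by their flanking sequence: the
±1 kb flanks of each insertion are mapped onto one common reference genome,
and mapped flank loci that land within a small slop of each other are merged
into one locus. A locus's population frequency is the fraction of strains
carrying it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, SamRecord
from .io_formats import GeneModel  # re-exported for callers
from .quantify import naive_map

__all__ = [
    "InsertionCall",
    "Locus",
    "classify_insertion",
    "cluster_overlap",
    "flank_map_frequency",
    "frequency_spectrum",
    "shared_gene_insertions",
]

_CLASS_PRIORITY = ("exon", "intron", "promoter", "intergenic")


@dataclass
class InsertionCall:
    """A detected element copy in one strain's assembly."""

    interval: GenomicInterval
    strain: str = ""
    pct_div: float = 0.0
    length_fraction: float = 1.0
    label: str = "canonical"  # canonical | degraded | full-length
    feature_class: str | None = None
    cluster_id: str | None = None
    locus_id: int | None = None


@dataclass
class Locus:
    """A merged insertion site on the common reference."""

    locus_id: int
    seq_id: str
    position: int
    strains: set[str] = field(default_factory=set)
    labels: list[str] = field(default_factory=list)
    frequency: float = 0.0

    @property
    def majority_label(self) -> str:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return max(sorted(counts), key=counts.get)


# ---------------------------------------------------------------------------
# feature classification


def _promoter_window(gene: GeneModel, promoter_len: int) -> GenomicInterval | None:
    anchor = gene.first_exon_anchor
    if gene.span.strand == "-":
        start, end = anchor, anchor + promoter_len
    else:
        start, end = anchor - promoter_len, anchor
    start = max(start, 0)
    if start >= end:
        return None
    return GenomicInterval(gene.span.seq_id, start, end, gene.span.strand)


def classify_insertion(
    insertion: GenomicInterval,
    genes: list[GeneModel],
    promoter_len: int = 1000,
) -> str:
    """Assign one of exon > intron > promoter > intergenic (that priority).

    Promoters are the strand-aware ``promoter_len`` window upstream of the
    first exon (or the gene start when no exon model exists). Any >= 1 bp
    overlap counts; half-open adjacency does not.
    """
    if promoter_len <= 0:
        raise ValueError("promoter_len must be positive")
    hit_exon = hit_intron = hit_promoter = False
    for gene in genes:
        if any(insertion.overlaps(ex) for ex in gene.exons):
            hit_exon = True
            continue
        if insertion.overlaps(gene.span):
            hit_intron = True
            continue
        win = _promoter_window(gene, promoter_len)
        if win is not None and insertion.overlaps(win):
            hit_promoter = True
    if hit_exon:
        return "exon"
    if hit_intron:
        return "intron"
    if hit_promoter:
        return "promoter"
    return "intergenic"


# ---------------------------------------------------------------------------
# piRNA cluster overlap


def cluster_overlap(
    insertions: list[InsertionCall],
    clusters: list[tuple[GenomicInterval, str]],
) -> pd.DataFrame:
    """Count insertions overlapping piRNA clusters (>= 1 bp, half-open).

    Returns a tidy per-(strain, cluster) count table; strains with no
    cluster insertion appear with count 0 so "x of n strains without a
    single cluster insertion" can be read off directly. Overlapping
    insertions get their ``cluster_id`` set as a side effect.
    """
    strains = sorted({ins.strain for ins in insertions})
    counts: dict[tuple[str, str], int] = {}
    for ins in insertions:
        for iv, cluster_id in clusters:
            if ins.interval.overlaps(iv):
                ins.cluster_id = cluster_id
                counts[(ins.strain, cluster_id)] = counts.get((ins.strain, cluster_id), 0) + 1
                break
    rows = []
    cluster_ids = [cid for _, cid in clusters]
    for strain in strains:
        total = 0
        for cid in cluster_ids:
            c = counts.get((strain, cid), 0)
            total += c
            if c:
                rows.append({"strain": strain, "cluster": cid, "count": c})
        rows.append({"strain": strain, "cluster": "__total__", "count": total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flank-mapped population frequency


def flank_map_frequency(
    strain_insertions: dict[str, tuple[dict[str, str], list[InsertionCall]]],
    common_ref: list[tuple[str, str]],
    flank: int = 1000,
    merge_slop: int = 100,
    k: int = 15,
    max_mismatch: int = 25,
) -> list[Locus]:
    """Merge insertions across strains into loci on a common reference.

    For every insertion the ±``flank`` sequence is extracted from that
    strain's assembly, the element body excised, and the flanks mapped onto
    the common reference; mapped insertion points within ``merge_slop`` of
    one another (single-linkage) are one locus. The left flank's right edge
    locates an insertion; the right flank is the fallback when the left one
    fails to map uniquely. Frequency = carrying strains / assayed strains.
    Each member insertion receives its ``locus_id``.
    """
    if len(strain_insertions) < 2:
        raise ValueError("need at least 2 strains")
    n_strains = len(strain_insertions)
    flank_reads = []  # parallel to `meta`
    meta = []  # (strain, insertion, which)
    for strain, (assembly, insertions) in sorted(strain_insertions.items()):
        for ins_i, ins in enumerate(insertions):
            contig = assembly[ins.interval.seq_id]
            left = contig[max(0, ins.interval.start - flank) : ins.interval.start]
            right = contig[ins.interval.end : ins.interval.end + flank]
            for which, seq in (("left", left), ("right", right)):
                if len(seq) >= k:
                    flank_reads.append((f"{strain}:{ins_i}:{which}", seq))
                    meta.append((strain, ins, which))
    alignments = naive_map(flank_reads, common_ref, k=k, max_mismatch=max_mismatch)
    located: dict[int, tuple[str, int, str, InsertionCall]] = {}
    for (strain, ins, which), (name, seq), aln in zip(meta, flank_reads, alignments):
        if aln.is_unmapped or aln.mapq == 0:
            continue
        key = id(ins)
        if key in located and which == "right":
            continue  # left flank already placed this insertion
        if which == "left":
            pos = aln.pos + len(seq) if not aln.is_reverse else aln.pos
        else:
            pos = aln.pos if not aln.is_reverse else aln.pos + len(seq)
        located[key] = (aln.rname, pos, strain, ins)
    points = sorted(located.values(), key=lambda t: (t[0], t[1]))
    loci: list[Locus] = []
    for seq_id, pos, strain, ins in points:
        last = loci[-1] if loci else None
        if (
            last is not None
            and last.seq_id == seq_id
            and pos - last.position <= merge_slop
        ):
            last.strains.add(strain)
            last.labels.append(ins.label)
            last.position = pos  # chain extension (single linkage)
            ins.locus_id = last.locus_id
        else:
            locus = Locus(
                locus_id=len(loci),
                seq_id=seq_id,
                position=pos,
                strains={strain},
                labels=[ins.label],
            )
            ins.locus_id = locus.locus_id
            loci.append(locus)
    for locus in loci:
        locus.frequency = len(locus.strains) / n_strains
    return loci


def frequency_spectrum(loci: list[Locus], n_strains: int) -> pd.DataFrame:
    """Locus counts per (divergence class x frequency bin k/n).

    Recently active elements pile up in the 1/n bin (private insertions);
    old fixed relics sit at n/n.
    """
    if not loci:
        raise ValueError("no loci provided")
    labels = sorted({locus.majority_label for locus in loci} | {"canonical", "degraded"})
    bins = [(kk + 1) / n_strains for kk in range(n_strains)]
    table = pd.DataFrame(0, index=labels, columns=[f"{kk + 1}/{n_strains}" for kk in range(n_strains)])
    for locus in loci:
        kk = round(locus.frequency * n_strains)
        kk = min(max(kk, 1), n_strains)
        table.loc[locus.majority_label, f"{kk}/{n_strains}"] += 1
    return table


# ---------------------------------------------------------------------------
# shared genic insertions


def shared_gene_insertions(
    strain_insertions: dict[str, tuple[dict[str, str], list[InsertionCall]]],
    genes_by_strain: dict[str, list[GeneModel]],
    common_ref: list[tuple[str, str]],
    flank: int = 1000,
    merge_slop: int = 100,
    **map_kwargs,
) -> pd.DataFrame:
    """Independent insertion events per gene across strains.

    Insertions falling in the same (shared-id) gene are one event iff their
    flank loci merge on the common reference; distinct loci in one gene are
    independent events (repeated targets of insertion).
    """
    loci = flank_map_frequency(
        strain_insertions, common_ref, flank=flank, merge_slop=merge_slop, **map_kwargs
    )
    gene_events: dict[str, set[int]] = {}
    for strain, (assembly, insertions) in strain_insertions.items():
        genes = genes_by_strain.get(strain, [])
        for ins in insertions:
            if ins.locus_id is None:
                continue
            for gene in genes:
                if ins.interval.overlaps(gene.span):
                    gene_events.setdefault(gene.gene_id, set()).add(ins.locus_id)
    rows = [
        {"gene": gid, "independent_insertions": len(loci_ids)}
        for gid, loci_ids in sorted(gene_events.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "independent_insertions"])
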