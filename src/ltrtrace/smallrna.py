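"""Small-RNA processing and the ping-pong signature.

piRNAs (23-29 nt PIWI-bound small RNAs) silence transposons in the
Drosophila germline. The ping-pong amplification cycle leaves a diagnostic
footprint: Slicer cleavage across the duplex places the 5' ends of sense and
antisense piRNAs exactly 10 nt apart, so an active cycle shows up as a sharp
excess of 10 nt 5'-overlaps between sense and antisense reads mapping to the
element. The pipeline here trims the 3' sequencing adapter, size-selects
reads, assigns them to a prioritised reference database, and scores the
overlap histogram with a z-score for the 10 nt bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import FastqRead, SamRecord
from .quantify import naive_map

__all__ = [
    "PingPongProfile",
    "trim_adapter",
    "filter_length",
    "assign_reads",
    "ping_pong",
    "DEFAULT_ADAPTER",
]

DEFAULT_ADAPTER = "GAATTCTCGGGTGCCAAGG"


def trim_adapter(
    reads: list[FastqRead], adapter: str = DEFAULT_ADAPTER, min_overlap: int = 5
) -> list[FastqRead]:
    """Truncate each read at the first exact occurrence of an adapter prefix
    of length >= ``min_overlap`` (searched from position 1 on); reads without
    a hit pass through unchanged."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = adapter.upper()
    out = []
    for r in reads:
        seq = r.sequence
        cut = None
        # full adapter (or its longest fitting prefix) first, then shorter
        for ov in range(min(len(adapter), len(seq) - 1), min_overlap - 1, -1):
            pos = seq.find(adapter[:ov], 1)
            if pos != -1:
                cut = pos
                break
        if cut is None:
            out.append(r)
        else:
            out.append(FastqRead(r.name, seq[:cut], r.quality[:cut]))
    return out


def filter_length(
    reads: list[FastqRead], min_len: int = 18, max_len: int = 36
) -> list[FastqRead]:
    """Keep reads with ``min_len <= length <= max_len`` (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [r for r in reads if min_len <= len(r.sequence) <= max_len]


def assign_reads(
    reads: list[FastqRead],
    categories: list[tuple[str, list[tuple[str, str]]]],
    k: int = 12,
    max_mismatch: int = 3,
) -> dict[str, list[SamRecord]]:
    """Assign each read to the best-matching reference over a pooled,
    prioritised database.

    ``categories`` is an ordered list of (category name, FASTA records);
    when a read matches references in several categories equally well the
    earliest category wins (e.g. rRNA before TEs, so structural RNA
    fragments never count as element piRNAs). Unassigned reads land in the
    ``"unassigned"`` bucket.
    """
    if not categories:
        raise ValueError("need at least one category")
    pooled: list[tuple[str, str]] = []
    ref_category: dict[str, tuple[int, str]] = {}
    for prio, (cat, records) in enumerate(categories):
        for name, seq in records:
            tagged = f"{cat}::{name}"
            pooled.append((tagged, seq))
            ref_category[tagged] = (prio, cat)
    alignments = naive_map(reads, pooled, k=k, max_mismatch=max_mismatch)
    # mapq 0 means tied placements; re-map ties restricted per category in
    # priority order to find the first category achieving the same score
    by_cat: dict[str, list[SamRecord]] = {cat: [] for cat, _ in categories}
    by_cat["unassigned"] = []
    ambiguous: list[int] = []
    for i, aln in enumerate(alignments):
        if aln.is_unmapped:
            by_cat["unassigned"].append(aln)
        elif aln.mapq > 0:
            by_cat[ref_category[aln.rname][1]].append(aln)
        else:
            ambiguous.append(i)
    if ambiguous:
        amb_reads = [reads[i] for i in ambiguous]
        resolved: dict[int, SamRecord | None] = {i: None for i in ambiguous}
        best_mm: dict[int, int] = {}
        for cat, records in categories:
            if not records:
                continue
            sub = naive_map(amb_reads, records, k=k, max_mismatch=max_mismatch)
            for j, aln in zip(ambiguous, sub):
                if aln.is_unmapped:
                    continue
                mm = _mismatches(aln, dict(records))
                if resolved[j] is None or mm < best_mm[j]:
                    resolved[j] = SamRecord(
                        aln.qname, f"{cat}::{aln.rname}", aln.pos, aln.cigar,
                        aln.mapq, aln.flags, aln.seq,
                    )
                    best_mm[j] = mm
        for j in ambiguous:
            aln = resolved[j]
            if aln is None:
                by_cat["unassigned"].append(
                    SamRecord(reads[j][0], None, -1, None, 0, 0x4, reads[j][1])
                )
            else:
                by_cat[ref_category[aln.rname][1]].append(aln)
    return by_cat


def _mismatches(aln: SamRecord, refs: dict[str, str]) -> int:
    # aligned sequences are stored reference-oriented (SAM convention)
    ref = refs[aln.rname]
    window = ref[aln.pos : aln.pos + len(aln.seq)].upper()
    return sum(a != b for a, b in zip(window, aln.seq))


@dataclass
class PingPongProfile:
    """Per-position 5' abundances and the sense/antisense overlap histogram.

    Abundances are in reads per million mapped piRNAs. ``overlap_hist[k]``
    (1-based overlap length ``k`` stored at index ``k-1``) is the summed
    product of sense and antisense 5' abundances at distance ``k``; ``z10``
    is the z-score of the 10 nt bin against all other bins, or ``None`` when
    the library is too shallow to support the statistic.
    """

    sense5: np.ndarray
    antisense5: np.ndarray
    overlap_hist: np.ndarray
    z10: float | None
    pair_mass: float
    n_mapped: int


def ping_pong(
    alignments: list[SamRecord],
    te_length: int,
    max_overlap: int = 23,
    min_pair_mass: float = 100.0,
) -> PingPongProfile:
    """Ping-pong signature from stranded element alignments.

    A sense read's 5' end is its leftmost position; an antisense read
    occupying ``[a, a+m)`` has its 5' end at ``a+m-1``. For each overlap
    ``k``, the histogram accumulates ``sum_p sense5[p] * antisense5[p+k-1]``
    over normalised abundances. The z-score for the 10 nt bin is withheld
    when the raw pair mass (same sum over raw counts, all bins) is below
    ``min_pair_mass`` — too few overlapping piRNAs to support the statistic.
    """
    if max_overlap < 10:
        raise ValueError("max_overlap must be at least 10")
    sense = np.zeros(te_length)
    antis = np.zeros(te_length)
    n_mapped = 0
    for aln in alignments:
        if aln.is_unmapped:
            continue
        n_mapped += 1
        if aln.is_reverse:
            p5 = aln.pos + len(aln.seq) - 1
            if 0 <= p5 < te_length:
                antis[p5] += 1
        else:
            if 0 <= aln.pos < te_length:
                sense[aln.pos] += 1
    raw_hist = np.array(
        [
            float(np.dot(sense[: te_length - (k - 1)], antis[k - 1 :]))
            for k in range(1, max_overlap + 1)
        ]
    )
    pair_mass = float(raw_hist.sum())
    scale = 1e6 / n_mapped if n_mapped else 0.0
    sense_n, antis_n = sense * scale, antis * scale
    hist = raw_hist * scale * scale
    z10 = None
    background = np.delete(hist, 9)
    nonzero_bg = np.count_nonzero(background)
    if pair_mass >= min_pair_mass and nonzero_bg >= 3:
        sd = background.std(ddof=1)
        if sd > 0:
            z10 = float((hist[9] - background.mean()) / sd)
    return PingPongProfile(
        sense5=sense_n,
        antisense5=antis_n,
        overlap_hist=hist,
        z10=z10,
        pair_mass=pair_mass,
        n_mapped=n_mapped,
    )
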