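"""Consensus building and structural annotation of an LTR retrotransposon.

An LTR retrotransposon is delimited by two near-identical long terminal
repeats (LTRs). On insertion the integrase duplicates a short target site
(TSD) that ends up flanking the element, and reverse transcription is primed
at a primer binding site (PBS) complementary to the 3' end of a host tRNA,
located just downstream of the 5' LTR. These hallmarks — plus an internal
poly-A tract, the terminal dinucleotides of the LTR, and a long polyprotein
ORF — are what this module recovers from sequence alone.

Coordinates follow the package-wide 0-based half-open convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .io_formats import GenomicInterval

__all__ = [
    "MSAProfile",
    "TEConsensus",
    "ConsensusResult",
    "TSDReport",
    "ORF",
    "build_consensus",
    "detect_ltrs",
    "detect_tsd",
    "tsd_motif_enrichment",
    "detect_polyA",
    "find_pbs",
    "terminal_motif",
    "find_orfs",
    "annotate_element",
]

_BASES = "ACGT"
_MSA_ALPHABET = set("ACGTN-")


@dataclass
class MSAProfile:
    """A multiple sequence alignment over ``{A, C, G, T, N, -}``."""

    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an MSA needs at least 2 rows")
        self.rows = [r.upper() for r in self.rows]
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(f"row {i} has length {len(row)}, expected {width}")
            bad = set(row) - _MSA_ALPHABET
            if bad:
                raise ValueError(f"row {i}: illegal symbols {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])


@dataclass
class ORF:
    interval: tuple[int, int]  # on the forward strand, includes the stop codon
    frame: int  # 0..2 forward, -1..-3 reverse
    aa_length: int  # includes the initial Met, excludes the stop


@dataclass
class TEConsensus:
    """An element consensus plus its structural annotation."""

    id: str
    sequence: str
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    tsd_length: int | None = None
    pbs_offset: int | None = None
    polyA: tuple[int, int] | None = None
    orfs: list[ORF] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ltr_length(self) -> int | None:
        if self.ltr5 is None:
            return None
        return self.ltr5[1] - self.ltr5[0]


@dataclass
class ConsensusResult:
    sequence: str
    dropped_gap_columns: int
    dropped_uninformative_columns: int


@dataclass
class TSDReport:
    """Observed TSDs of a set of insertions and their motif enrichment."""

    lengths: list[int]
    motif_counts: dict[str, int]
    motif_frequencies: dict[str, float]
    enrichment: dict[str, float]
    background_composition: dict[str, float]


# ---------------------------------------------------------------------------
# Consensus


def build_consensus(msa: MSAProfile, tie_rule: str = "ACGT") -> ConsensusResult:
    """Majority-rule consensus: the most abundant nucleotide per column.

    Columns where the gap is the strict majority are dropped, as are columns
    containing only N/gap symbols; N never wins a column. Ties between bases
    are broken by their order in ``tie_rule``.
    """
    out = []
    dropped_gap = 0
    dropped_uninformative = 0
    for col in range(msa.n_cols):
        counts = Counter(row[col] for row in msa.rows)
        if counts.get("-", 0) * 2 > msa.n_rows:
            dropped_gap += 1
            continue
        base_counts = {b: counts.get(b, 0) for b in _BASES}
        best = max(base_counts.values())
        if best == 0:
            dropped_uninformative += 1
            continue
        winner = min(
            (b for b, c in base_counts.items() if c == best),
            key=tie_rule.index,
        )
        out.append(winner)
    return ConsensusResult("".join(out), dropped_gap, dropped_uninformative)


# ---------------------------------------------------------------------------
# LTR detection


def _best_subsegment(mism: np.ndarray, min_len: int, min_identity: float):
    """Maximum-scoring subarray (match +1 / mismatch -1) that still satisfies
    the identity floor after greedy trimming; returns (start, end) or None."""
    score = np.where(mism, -1.0, 1.0)
    best, cur, cur_start = None, 0.0, 0
    best_bounds = (0, 0)
    best_score = 0.0
    for i, s in enumerate(score):
        cur += s
        if cur <= 0:
            cur, cur_start = 0.0, i + 1
            continue
        if best is None or cur > best_score:
            best_score, best_bounds = cur, (cur_start, i + 1)
            best = True
    if best is None:
        return None
    a, b = best_bounds
    # trim mismatching edges, then check constraints
    while a < b and mism[a]:
        a += 1
    while b > a and mism[b - 1]:
        b -= 1
    if b - a < min_len:
        return None
    identity = 1.0 - mism[a:b].mean()
    if identity < min_identity:
        return None
    return a, b


def detect_ltrs(
    seq: str,
    min_len: int = 100,
    max_len: int = 1000,
    min_identity: float = 0.9,
    k: int = 13,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Find the near-identical terminal repeat pair of an element.

    Shared ``k``-mers between the first and last ``max_len`` nt anchor
    candidate diagonals; each diagonal is scored by ungapped comparison and
    the longest block of identity >= ``min_identity`` and length >=
    ``min_len`` wins. Returns ``(ltr5, ltr3)`` intervals or ``None``.
    """
    n = len(seq)
    if n <= 2 * min_len:
        return None
    w = min(max_len, n // 2)
    head, tail = seq[:w], seq[n - w :]
    tail_kmers: dict[str, list[int]] = {}
    for j in range(w - k + 1):
        tail_kmers.setdefault(tail[j : j + k], []).append(j)
    diagonals = set()
    for i in range(w - k + 1):
        for j in tail_kmers.get(head[i : i + k], ()):
            diagonals.add(j - i)
    head_arr = np.frombuffer(head.encode(), dtype=np.uint8)
    tail_arr = np.frombuffer(tail.encode(), dtype=np.uint8)
    best = None
    for d in sorted(diagonals):
        if d >= 0:
            h, t = head_arr[: w - d], tail_arr[d:]
            h_off = 0
        else:
            h, t = head_arr[-d:], tail_arr[: w + d]
            h_off = -d
        mism = h != t
        seg = _best_subsegment(mism, min_len, min_identity)
        if seg is None:
            continue
        a, b = seg
        length = b - a
        if best is None or length > best[0]:
            start5 = h_off + a
            start3 = n - w + (a + max(d, 0) if d >= 0 else a)
            best = (length, (start5, start5 + length), (start3, start3 + length))
    if best is None:
        return None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# TSD


def detect_tsd(left_flank: str, right_flank: str, max_tsd: int = 10) -> tuple[int, str]:
    """Longest exact match between a suffix of the left flank and a prefix of
    the right flank, capped at ``max_tsd``; ``(0, "")`` when none."""
    left_flank, right_flank = left_flank.upper(), right_flank.upper()
    cap = min(max_tsd, len(left_flank), len(right_flank))
    for k in range(cap, 0, -1):
        if left_flank[-k:] == right_flank[:k]:
            return k, right_flank[:k]
    return 0, ""


def tsd_motif_enrichment(
    tsds: list[str], background: list[str]
) -> TSDReport:
    """Observed TSD motif frequencies against a mononucleotide background.

    Expected frequency of a motif is the product of the background base
    frequencies; enrichment is observed / expected.
    """
    tsds = [t.upper() for t in tsds if t]
    if not tsds:
        raise ValueError("no TSD sequences provided")
    bg = Counter("".join(background).upper())
    total = sum(bg[b] for b in _BASES)
    if total == 0:
        raise ValueError("background contains no A/C/G/T bases")
    composition = {b: bg[b] / total for b in _BASES}
    counts = Counter(tsds)
    n = len(tsds)
    frequencies = {m: c / n for m, c in counts.items()}
    enrichment = {}
    for motif, freq in frequencies.items():
        expected = 1.0
        for b in motif:
            expected *= composition.get(b, 0.0)
        enrichment[motif] = freq / expected if expected > 0 else float("inf")
    return TSDReport(
        lengths=[len(t) for t in tsds],
        motif_counts=dict(counts),
        motif_frequencies=frequencies,
        enrichment=enrichment,
        background_composition=composition,
    )


# ---------------------------------------------------------------------------
# poly-A


def detect_polyA(
    seq: str, min_run: int = 30, max_mismatch_frac: float = 0.1
) -> tuple[int, int] | None:
    """Longest A-rich window (A-fraction >= 1 - max_mismatch_frac), maximally
    extended on both sides; ``None`` when no window reaches ``min_run``."""
    seq = seq.upper()
    is_a = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("A")
    # weight so that any window with A-fraction >= threshold has sum >= 0
    thresh = 1.0 - max_mismatch_frac
    w = np.where(is_a, 1.0 - thresh, -thresh)
    best_sum, cur, cur_start = -1.0, 0.0, 0
    best = None
    for i, x in enumerate(w):
        cur += x
        if cur < 0:
            cur, cur_start = 0.0, i + 1
            continue
        if best is None or cur > best_sum:
            best_sum, best = cur, (cur_start, i + 1)
    if best is None:
        return None
    a, b = best
    while a < b and not is_a[a]:
        a += 1
    while b > a and not is_a[b - 1]:
        b -= 1
    # greedy extension keeping the fraction constraint
    n_a = int(is_a[a:b].sum())
    changed = True
    while changed:
        changed = False
        if a > 0 and (n_a + is_a[a - 1]) / (b - a + 1) >= thresh:
            a -= 1
            n_a += int(is_a[a])
            changed = True
        if b < len(w) and (n_a + is_a[b]) / (b - a + 1) >= thresh:
            n_a += int(is_a[b])
            b += 1
            changed = True
    while a < b and not is_a[a]:
        n_a -= 0
        a += 1
    while b > a and not is_a[b - 1]:
        b -= 1
    if b - a < min_run:
        return None
    return a, b


# ---------------------------------------------------------------------------
# PBS


def find_pbs(
    seq: str,
    ltr5: tuple[int, int],
    trna_3prime_ends: dict[str, str],
    min_match: int = 10,
    window: int = 30,
) -> tuple[int, str] | None:
    """Scan downstream of the 5' LTR for a PBS: an exact reverse-complement
    match (>= min_match nt) to a tRNA 3' end. Returns (offset, tRNA id)."""
    region = seq[ltr5[1] : ltr5[1] + window + min_match].upper()
    hits = []
    for trna_id, trna in trna_3prime_ends.items():
        probe = str(Seq(trna[-min_match:].upper()).reverse_complement())
        pos = region.find(probe)
        if pos != -1 and pos <= window:
            hits.append((pos, trna_id))
    if not hits:
        return None
    return min(hits)


# ---------------------------------------------------------------------------
# Terminal motif


def terminal_motif(ltr_seq: str) -> tuple[str, str]:
    """First and last dinucleotide of an LTR (classically TG…CA; some
    families deviate)."""
    if len(ltr_seq) < 4:
        raise ValueError("LTR sequence shorter than 4 nt")
    s = ltr_seq.upper()
    return s[:2], s[-2:]


# ---------------------------------------------------------------------------
# ORFs

_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_one_strand(seq: str, min_aa: int, reverse: bool, total: int) -> list[ORF]:
    out = []
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if start is not None:
                    aa = (pos - start) // 3
                    if aa >= min_aa:
                        iv = (start, pos + 3)
                        if reverse:
                            iv = (total - iv[1], total - iv[0])
                        out.append(ORF(iv, -(frame + 1) if reverse else frame, aa))
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
    return out


def find_orfs(seq: str, min_aa: int = 100) -> list[ORF]:
    """ATG-to-stop open reading frames on both strands, >= ``min_aa`` amino
    acids (Met included, stop excluded), longest first. Intervals are on the
    forward strand and include the stop codon."""
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    orfs = _orfs_one_strand(seq, min_aa, False, len(seq)) + _orfs_one_strand(
        rc, min_aa, True, len(seq)
    )
    return sorted(orfs, key=lambda o: (-o.aa_length, o.interval))


# ---------------------------------------------------------------------------
# One-stop annotation


def annotate_element(
    name: str,
    sequence: str,
    trna_3prime_ends: dict[str, str] | None = None,
    min_ltr: int = 100,
    min_orf_aa: int = 100,
) -> TEConsensus:
    """Annotate a consensus sequence with every structural feature this
    module can detect."""
    te = TEConsensus(id=name, sequence=sequence.upper())
    ltrs = detect_ltrs(te.sequence, min_len=min_ltr)
    if ltrs is not None:
        te.ltr5, te.ltr3 = ltrs
        if trna_3prime_ends:
            pbs = find_pbs(te.sequence, te.ltr5, trna_3prime_ends)
            if pbs is not None:
                te.pbs_offset = pbs[0]
    te.polyA = detect_polyA(te.sequence)
    te.orfs = find_orfs(te.sequence, min_aa=min_orf_aa)
    return te
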