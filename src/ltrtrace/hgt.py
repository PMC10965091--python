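"""Cross-species screening for horizontal transfer, and divergence statistics.

Horizontal transfer of a transposon is classically supported by (i) a patchy
distribution of the element across related species, (ii) a phylogenetic
discrepancy between element and host trees, and (iii) an element divergence
between donor and recipient far below that of orthologous host genes. This
module provides the quantitative pieces: a per-assembly similarity statistic
``s = rms_best / rms_max`` (the best element-hit alignment score in an
assembly, normalised by the best score anywhere in the screen), canonical /
full-length hit classification, Nei-Gojobori (1986) synonymous and
nonsynonymous divergence with the Jukes-Cantor correction, pairwise
p-distances, a Welch two-sample test for group-distance comparisons, and
neighbor-joining newick export for eyeballing tree nesting.

The built-in scanner is a k-mer anchored ungapped local aligner; its scores
are not those of an external repeat masker, but ``s`` only needs scores
comparable within one screen. Externally produced hit tables can be supplied
instead (see :func:`ltrtrace.io_formats.read_repeatmasker_out`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .element_model import MSAProfile, TEConsensus
from .io_formats import GenomicInterval, RepeatHit

__all__ = [
    "AssemblySimilarity",
    "DivergenceEstimate",
    "StatTestResult",
    "ScoringScheme",
    "scan_assembly",
    "similarity_scores",
    "classify_hits",
    "ng86",
    "p_distance_matrix",
    "group_distance_test",
    "nj_tree",
]


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0  # accepted for interface parity; scanner is ungapped
    gap_extend: float = -1.0


@dataclass
class AssemblySimilarity:
    assembly: str
    species: str
    rms_best: float
    rms_max: float
    s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("s must be within [0, 1]")


@dataclass
class DivergenceEstimate:
    dS: float | None
    dN: float | None
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float


@dataclass
class StatTestResult:
    t: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# assembly scanning

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


def _diagonal_hits(
    contig: str,
    contig_id: str,
    element: str,
    te_name: str,
    strand: str,
    scoring: ScoringScheme,
    k: int,
    min_score: float,
) -> list[RepeatHit]:
    """Best-scoring ungapped segment on every seeded diagonal."""
    m, n = len(element), len(contig)
    elem_kmers: dict[str, list[int]] = {}
    for i in range(m - k + 1):
        elem_kmers.setdefault(element[i : i + k], []).append(i)
    diagonals: set[int] = set()
    step = max(1, k // 2)
    for j in range(0, n - k + 1, step):
        for i in elem_kmers.get(contig[j : j + k], ()):
            diagonals.add(j - i)
    contig_arr = np.frombuffer(contig.encode(), dtype=np.uint8)
    elem_arr = np.frombuffer(element.encode(), dtype=np.uint8)
    hits = []
    for d in sorted(diagonals):
        e_lo = max(0, -d)
        e_hi = min(m, n - d)
        if e_hi - e_lo < k:
            continue
        mism = elem_arr[e_lo:e_hi] != contig_arr[e_lo + d : e_hi + d]
        weight = np.where(mism, scoring.mismatch, scoring.match)
        best, cur, cur_start = None, 0.0, 0
        best_score, best_bounds = 0.0, (0, 0)
        for idx, w in enumerate(weight):
            cur += w
            if cur <= 0:
                cur, cur_start = 0.0, idx + 1
                continue
            if best is None or cur > best_score:
                best_score, best_bounds = cur, (cur_start, idx + 1)
                best = True
        if best is None or best_score < min_score:
            continue
        a, b = best_bounds
        while a < b and mism[a]:
            a += 1
        while b > a and mism[b - 1]:
            b -= 1
        seg_mism = int(mism[a:b].sum())
        seg_len = b - a
        if seg_len < k:
            continue
        e_start, e_end = e_lo + a, e_lo + b
        q_start, q_end = e_start + d, e_end + d
        if strand == "-":
            e_start, e_end = m - e_end, m - e_start
        hits.append(
            RepeatHit(
                score=best_score,
                pct_div=100.0 * seg_mism / seg_len,
                query=GenomicInterval(contig_id, q_start, q_end, strand),
                te_name=te_name,
                te_span=(e_start, e_end),
            )
        )
    return hits


def _merge_hits(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Drop hits whose assembly interval overlaps a higher-scoring one."""
    kept: list[RepeatHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.query.start)):
        if not any(h.query.overlaps(k.query) for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: h.query.start)


def scan_assembly(
    assembly: list[tuple[str, str]],
    element: TEConsensus | str,
    scoring: ScoringScheme = ScoringScheme(),
    k: int = 11,
    min_score: float = 30.0,
) -> list[RepeatHit]:
    """Find element-similar sequence in an assembly on both strands.

    k-mer anchors define diagonals; each diagonal contributes its maximum
    scoring ungapped segment; overlapping hits are merged keeping the higher
    score. Substitution-level divergence is reported per hit.
    """
    if not assembly:
        raise ValueError("assembly is empty")
    elem_seq = element.sequence if isinstance(element, TEConsensus) else element
    elem_seq = elem_seq.upper()
    te_name = element.id if isinstance(element, TEConsensus) else "element"
    hits: list[RepeatHit] = []
    for contig_id, contig in assembly:
        contig = contig.upper()
        for strand, elem in (("+", elem_seq), ("-", _revcomp(elem_seq))):
            hits.extend(
                _diagonal_hits(
                    contig, contig_id, elem, te_name, strand, scoring, k, min_score
                )
            )
    return _merge_hits(hits)


def similarity_scores(
    hits_by_assembly: dict[str, list[RepeatHit]],
    species: dict[str, str] | None = None,
) -> list[AssemblySimilarity]:
    """The screen-wide similarity statistic ``s = rms_best / rms_max``.

    Hitless assemblies get ``s = 0``; an entirely hitless screen is an error
    (the normaliser is undefined).
    """
    if not hits_by_assembly:
        raise ValueError("no assemblies in screen")
    best = {
        asm: max((h.score for h in hits), default=0.0)
        for asm, hits in hits_by_assembly.items()
    }
    rms_max = max(best.values())
    if rms_max <= 0:
        raise ValueError("no assembly has any hit; s is undefined")
    return [
        AssemblySimilarity(
            assembly=asm,
            species=(species or {}).get(asm, asm),
            rms_best=b,
            rms_max=rms_max,
            s=b / rms_max,
        )
        for asm, b in best.items()
    ]


def classify_hits(
    hits: list[RepeatHit],
    element_length: int,
    min_len_frac: float = 0.8,
    max_div: float = 5.0,
    require_ltr: bool = False,
    ltr5: tuple[int, int] | None = None,
    ltr3: tuple[int, int] | None = None,
) -> list[str]:
    """Label hits ``canonical`` / ``full-length`` / ``degraded``.

    Canonical: matched span strictly more than ``min_len_frac`` of the
    element and divergence strictly below ``max_div`` percent. With
    ``require_ltr``, a hit additionally needs to cover at least one LTR
    entirely to count (then labelled ``full-length``); other hits are
    ``degraded``.
    """
    if element_length <= 0:
        raise ValueError("element_length must be positive")
    labels = []
    for h in hits:
        long_enough = h.span_length > min_len_frac * element_length
        similar = h.pct_div < max_div
        if long_enough and similar:
            if require_ltr:
                covers_ltr = any(
                    span is not None
                    and h.te_span[0] <= span[0]
                    and h.te_span[1] >= span[1]
                    for span in (ltr5, ltr3)
                )
                labels.append("full-length" if covers_ltr else "degraded")
            else:
                labels.append("canonical")
        else:
            labels.append("degraded")
    return labels


# ---------------------------------------------------------------------------
# NG86 synonymous / nonsynonymous divergence

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_BASES = "ACGT"


def _codon_syn_sites(codon: str) -> float:
    """Synonymous site count of one codon: at each position, the fraction of
    the three possible changes that preserve the amino acid. Changes to stop
    codons count as nonsynonymous, keeping S + N = 3 per codon."""
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


_SYN_SITES = {c: _codon_syn_sites(c) for c in _CODON_TABLE if _CODON_TABLE[c] != "*"}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons,
    averaged over all minimal mutational pathways that avoid stop codons
    (all pathways if every one passes through a stop)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                through_stop = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not through_stop:
            valid.append((sd, nd))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * float(np.log(arg))


def ng86(seq1: str, seq2: str) -> DivergenceEstimate:
    """Nei-Gojobori (1986) dS/dN with the Jukes-Cantor correction.

    Site counts are the per-codon fraction-of-synonymous-changes rule,
    averaged over both sequences; difference counts average over all minimal
    mutational pathways between differing codons (pathways through stops
    excluded). ``dS``/``dN`` are ``None`` where the correction's argument is
    non-positive. Codons containing N, or gaps, are not supported; internal
    stops are an error.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    if len(seq1) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    n_codons = len(seq1) // 3
    S = N = Sd = Nd = 0.0
    for i in range(n_codons):
        c1, c2 = seq1[3 * i : 3 * i + 3], seq2[3 * i : 3 * i + 3]
        for label, c in (("first", c1), ("second", c2)):
            if _CODON_TABLE.get(c, "*") == "*":
                raise ValueError(f"stop or invalid codon {c} at codon {i} ({label} sequence)")
        s_i = (_SYN_SITES[c1] + _SYN_SITES[c2]) / 2.0
        S += s_i
        N += 3.0 - s_i
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return DivergenceEstimate(
        dS=_jc(ps), dN=_jc(pn), S_sites=S, N_sites=N, Sd=Sd, Nd=Nd
    )


# ---------------------------------------------------------------------------
# distances and tests


def p_distance_matrix(alignment: MSAProfile) -> np.ndarray:
    """Pairwise proportion of differing sites over shared non-gap columns;
    NaN where a pair shares no informative column."""
    rows = alignment.rows
    n = len(rows)
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in rows]
    informative = [ (a != ord("-")) & (a != ord("N")) for a in arrs ]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = informative[i] & informative[j]
            total = int(shared.sum())
            if total == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            d = int(((arrs[i] != arrs[j]) & shared).sum()) / total
            out[i, j] = out[j, i] = d
    return out


def group_distance_test(
    distances_a: list[float], distances_b: list[float]
) -> StatTestResult:
    """Welch's two-sample t-test (unequal variances, Satterthwaite df)."""
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return StatTestResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        raise ValueError("zero variance in both groups with unequal means")
    if a.var(ddof=1) == 0 or b.var(ddof=1) == 0:
        raise ValueError("zero variance in a group; Welch test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return StatTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def nj_tree(distance_matrix: np.ndarray, labels: list[str]) -> str:
    """Neighbor-joining newick string with branch lengths.

    Taxa are processed in sorted label order so that the output is invariant
    to the input ordering of equivalent matrices.
    """
    import io

    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = np.asarray(distance_matrix, dtype=float)
    if dm.shape[0] != dm.shape[1] or dm.shape[0] != len(labels):
        raise ValueError("matrix/label shape mismatch")
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    dm = dm[np.ix_(order, order)]
    sorted_labels = [labels[i] for i in order]
    tree = nj(DistanceMatrix(dm, ids=sorted_labels))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
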