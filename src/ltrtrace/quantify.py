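"""Copy-number and composition estimation from short reads.

The element's haploid copy number in a sample is estimated the way
coverage-normalisation tools do it: short reads are aligned to a small
library holding the element consensus plus known single-copy genes, and the
mean read depth over the element is divided by the mean depth over the
single-copy genes. Variants among the dispersed copies of the element show
up as intermediate-frequency alleles in the element pileup; their
frequencies summarise the element "composition" of the sample and feed the
sample-by-SNP matrix used for embedding.

A deliberately naive exact-seed ungapped mapper is bundled so the pipeline
runs end to end on synthetic data without an external aligner; any SAM
produced by a real aligner can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    FastqRead,
    FormatError,
    SamRecord,
    cigar_ops,
)

__all__ = [
    "RefPileup",
    "PileupProfile",
    "CopyNumberEstimate",
    "SNPCall",
    "naive_map",
    "pileup",
    "copy_number",
    "call_snps",
    "build_snp_matrix",
    "presence_call",
    "quantify_sample",
]

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")
_BASE_INDEX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


# ---------------------------------------------------------------------------
# naive mapper


def naive_map(
    reads: list[FastqRead] | list[tuple[str, str]],
    refs: list[tuple[str, str]],
    k: int = 15,
    max_mismatch: int = 10,
) -> list[SamRecord]:
    """Exact k-mer seeding + full-length ungapped placement, both strands.

    The best placement (fewest mismatches) is reported; reads whose best
    mismatch count is achieved at more than one locus are flagged ambiguous
    with mapping quality 0. Reads shorter than ``k``, or with no placement
    within ``max_mismatch``, are unmapped. Deterministic given input order.
    """
    if not refs:
        raise ValueError("reference set is empty")
    index: dict[str, list[tuple[int, int]]] = {}
    ref_arrays = []
    for ri, (_, seq) in enumerate(refs):
        seq = seq.upper()
        ref_arrays.append(np.frombuffer(seq.encode(), dtype=np.uint8))
        for p in range(len(seq) - k + 1):
            index.setdefault(seq[p : p + k], []).append((ri, p))

    out: list[SamRecord] = []
    for read in reads:
        name, seq = read[0], read[1].upper()
        n = len(seq)
        record = SamRecord(name, None, -1, None, 0, 0x4, seq)
        if n >= k:
            best_mism = max_mismatch + 1
            best_hit = None
            n_best = 0
            for strand, s in ((0, seq), (1, seq.encode().translate(_COMPLEMENT)[::-1].decode())):
                arr = np.frombuffer(s.encode(), dtype=np.uint8)
                candidates: set[tuple[int, int]] = set()
                for off in range(0, n - k + 1, k):
                    for ri, p in index.get(s[off : off + k], ()):
                        start = p - off
                        if 0 <= start and start + n <= len(ref_arrays[ri]):
                            candidates.add((ri, start))
                for ri, start in sorted(candidates):
                    mism = int(
                        np.count_nonzero(ref_arrays[ri][start : start + n] != arr)
                    )
                    if mism < best_mism:
                        best_mism, best_hit, n_best = mism, (ri, start, strand), 1
                    elif mism == best_mism:
                        n_best += 1
            if best_hit is not None:
                ri, start, strand = best_hit
                # SAM convention: sequence is stored reference-oriented
                oriented = (
                    seq
                    if not strand
                    else seq.encode().translate(_COMPLEMENT)[::-1].decode()
                )
                record = SamRecord(
                    qname=name,
                    rname=refs[ri][0],
                    pos=start,
                    cigar=f"{n}M",
                    mapq=37 if n_best == 1 else 0,
                    flags=0x10 if strand else 0,
                    seq=oriented,
                )
        out.append(record)
    return out


# ---------------------------------------------------------------------------
# pileup


@dataclass
class RefPileup:
    depth_total: np.ndarray
    depth_unique: np.ndarray
    alleles: np.ndarray  # shape (4, L): A, C, G, T counts
    deletions: np.ndarray
    insertions: np.ndarray

    @property
    def length(self) -> int:
        return len(self.depth_total)


@dataclass
class PileupProfile:
    refs: dict[str, RefPileup] = field(default_factory=dict)

    def __getitem__(self, ref_id: str) -> RefPileup:
        return self.refs[ref_id]


def pileup(records: list[SamRecord], refs: list[tuple[str, str]]) -> PileupProfile:
    """CIGAR-aware depth and allele counts per reference position.

    Soft-clipped bases are ignored; deleted reference bases receive depth and
    a deletion count; insertion events are counted at their left-anchoring
    base. Reads aligned past the reference end are a format error.
    """
    profile = PileupProfile()
    lengths = {}
    for name, seq in refs:
        L = len(seq)
        lengths[name] = L
        profile.refs[name] = RefPileup(
            depth_total=np.zeros(L, dtype=np.int64),
            depth_unique=np.zeros(L, dtype=np.int64),
            alleles=np.zeros((4, L), dtype=np.int64),
            deletions=np.zeros(L, dtype=np.int64),
            insertions=np.zeros(L, dtype=np.int64),
        )
    for rec in records:
        if rec.is_unmapped or rec.rname is None:
            continue
        if rec.rname not in profile.refs:
            raise FormatError(f"alignment to unknown reference {rec.rname!r}")
        ref = profile.refs[rec.rname]
        L = lengths[rec.rname]
        unique = rec.mapq > 0
        read = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        qpos, rpos = 0, rec.pos
        for n, op in cigar_ops(rec.cigar or f"{len(rec.seq)}M"):
            if op in "M=X":
                if rpos + n > L:
                    raise FormatError(
                        f"read {rec.qname}: alignment past end of {rec.rname}"
                    )
                ref.depth_total[rpos : rpos + n] += 1
                if unique:
                    ref.depth_unique[rpos : rpos + n] += 1
                codes = _BASE_INDEX[read[qpos : qpos + n]]
                valid = codes < 4
                np.add.at(
                    ref.alleles,
                    (codes[valid], np.arange(rpos, rpos + n)[valid]),
                    1,
                )
                qpos += n
                rpos += n
            elif op == "D":
                if rpos + n > L:
                    raise FormatError(
                        f"read {rec.qname}: alignment past end of {rec.rname}"
                    )
                ref.depth_total[rpos : rpos + n] += 1
                if unique:
                    ref.depth_unique[rpos : rpos + n] += 1
                ref.deletions[rpos : rpos + n] += 1
                rpos += n
            elif op == "I":
                ref.insertions[max(rpos - 1, 0)] += 1
                qpos += n
            elif op == "S":
                qpos += n
            elif op == "N":
                rpos += n
            # H and P consume nothing we track
    return profile


# ---------------------------------------------------------------------------
# copy number


@dataclass
class CopyNumberEstimate:
    te_id: str
    copies: float
    breadth: float
    masked: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.copies < 0 or not (0.0 <= self.breadth <= 1.0):
            raise ValueError("invalid copy-number estimate")


def copy_number(
    profile: PileupProfile,
    te_id: str,
    scg_ids: list[str],
    mask: list[tuple[int, int]] | None = None,
    unique_only: bool = False,
) -> CopyNumberEstimate:
    """Element coverage normalised by single-copy-gene coverage.

    ``copies`` is the mean depth over unmasked element positions divided by
    the mean depth over all positions of all single-copy genes; masked
    intervals (typically the poly-A tract, where mapping artifacts inflate
    depth) are excluded from the element mean. ``breadth`` is the fraction
    of element positions with nonzero uniquely-mapping depth.
    """
    te = profile[te_id]
    depth_attr = "depth_unique" if unique_only else "depth_total"
    keep = np.ones(te.length, dtype=bool)
    for start, end in mask or ():
        keep[start:end] = False
    if not keep.any():
        raise ValueError("mask removes every element position")
    te_mean = float(getattr(te, depth_attr)[keep].mean())
    scg_depths = np.concatenate(
        [getattr(profile[g], depth_attr) for g in scg_ids]
    )
    scg_mean = float(scg_depths.mean()) if len(scg_depths) else 0.0
    if scg_mean <= 0:
        raise ValueError("single-copy-gene coverage is zero; cannot normalize")
    breadth = float((te.depth_unique > 0).mean())
    return CopyNumberEstimate(
        te_id=te_id,
        copies=te_mean / scg_mean,
        breadth=breadth,
        masked=list(mask or ()),
    )


# ---------------------------------------------------------------------------
# SNPs


@dataclass
class SNPCall:
    position: int
    major: str
    minor: str
    major_count: int
    minor_count: int
    frequency: float
    biallelic: bool


_BASES_STR = "ACGT"


def call_snps(
    profile: PileupProfile,
    te_id: str,
    min_count: int = 2,
    min_freq: float = 0.1,
) -> list[SNPCall]:
    """Sites where >= 2 alleles each reach ``min_count`` reads and the minor
    allele frequency reaches ``min_freq``; biallelic when exactly 2 pass."""
    te = profile[te_id]
    calls = []
    passing_mask = te.alleles >= min_count
    candidate_cols = np.nonzero(passing_mask.sum(axis=0) >= 2)[0]
    for pos in candidate_cols:
        counts = te.alleles[:, pos]
        passing = [(int(counts[i]), _BASES_STR[i]) for i in range(4) if passing_mask[i, pos]]
        passing.sort(key=lambda t: (-t[0], t[1]))
        (major_count, major), (minor_count, minor) = passing[0], passing[1]
        freq = minor_count / (major_count + minor_count)
        if freq < min_freq:
            continue
        calls.append(
            SNPCall(
                position=int(pos),
                major=major,
                minor=minor,
                major_count=major_count,
                minor_count=minor_count,
                frequency=freq,
                biallelic=len(passing) == 2,
            )
        )
    return calls


def build_snp_matrix(
    samples: list[tuple[str, list[SNPCall]]],
    min_samples: int = 3,
    covered: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Sample-by-SNP minor-allele-frequency matrix.

    Columns are biallelic SNPs, keyed ``(position, minor allele)``, kept only
    when called in strictly more than ``min_samples`` samples. Entries are
    the minor-allele frequency; where a per-sample coverage mask is given,
    uncovered sites are missing (NaN) and covered-but-uncalled sites are 0.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    occupancy: dict[tuple[int, str], int] = {}
    for _, calls in samples:
        for c in calls:
            if c.biallelic:
                key = (c.position, c.minor)
                occupancy[key] = occupancy.get(key, 0) + 1
    columns = sorted(k for k, n in occupancy.items() if n > min_samples)
    data = np.zeros((len(samples), len(columns)))
    index = []
    col_pos = {c: j for j, c in enumerate(columns)}
    for i, (sid, calls) in enumerate(samples):
        index.append(sid)
        if covered is not None and sid in covered:
            cov = covered[sid]
            for (pos, _), j in col_pos.items():
                if pos >= len(cov) or not cov[pos]:
                    data[i, j] = np.nan
        for c in calls:
            j = col_pos.get((c.position, c.minor))
            if j is not None and c.biallelic:
                data[i, j] = c.frequency
    return pd.DataFrame(data, index=index, columns=columns)


def presence_call(
    estimate: CopyNumberEstimate,
    min_copies: float = 0.5,
    min_breadth: float = 0.33,
) -> str:
    """``present`` iff both the normalised copy number and the covered
    breadth clear their thresholds — the breadth term keeps localized
    degraded relics from being called present."""
    ok = estimate.copies >= min_copies and estimate.breadth >= min_breadth
    return "present" if ok else "absent"


# ---------------------------------------------------------------------------
# convenience pipeline


def quantify_sample(
    reads,
    library: list[tuple[str, str]],
    te_id: str,
    scg_ids: list[str],
    mask: list[tuple[int, int]] | None = None,
    k: int = 15,
    max_mismatch: int = 10,
    alignments: list[SamRecord] | None = None,
):
    """Map reads to the element+single-copy-gene library (or use supplied
    alignments), then estimate copy number and call SNPs."""
    if alignments is None:
        alignments = naive_map(reads, library, k=k, max_mismatch=max_mismatch)
    profile = pileup(alignments, library)
    estimate = copy_number(profile, te_id, scg_ids, mask=mask)
    snps = call_snps(profile, te_id)
    return estimate, snps, profile
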