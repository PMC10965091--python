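"""Synthetic data with known truth for every stage of the pipeline.

The generator emulates the study design the package is built for: a host
genome carrying planted retrotransposon copies (canonical ones near the
consensus, plus degraded truncated relics), uniform-coverage short reads
with substitution errors, a panel of strains collected in different calendar
years in which the element is absent before an invasion year and present
after it, small-RNA libraries with a tunable fraction of ping-pong pairs
(sense/antisense 5' ends overlapping by exactly 10 nt), and a set of
assemblies at graded divergence from the consensus for the cross-species
screen.

Determinism: one run seed; each stage derives its own generator from the
run seed plus a fixed stage offset, so adding a stage never perturbs the
output of earlier ones. The mutation model for planted copies is
substitution-only, keeping the recorded per-copy divergence an exact
p-distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

import pandas as pd

from .element_model import TEConsensus
from .io_formats import FastqRead, GenomicInterval

__all__ = [
    "SimConfig",
    "InsertionTruth",
    "make_element",
    "random_sequence",
    "mutate_sequence",
    "plant_insertions",
    "simulate_reads",
    "simulate_panel",
    "simulate_pirnas",
    "simulate_assembly_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# fixed per-stage offsets for deriving sub-generators from the run seed
_STAGE = {
    "element": 11,
    "genome": 23,
    "insertions": 37,
    "reads": 51,
    "panel": 67,
    "pirna": 83,
    "assemblies": 97,
}


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the element the pipeline was built around: a 5216 nt
    LTR retrotransposon with 349 nt LTRs, a 4 nt TSD, a poly-A tract at
    positions 4639-4700 (1-based; stored 0-based half-open) and a long
    gag-pol-like ORF. Canonical planted copies diverge 2% from the
    consensus, well inside the <5% canonical filter.
    """

    seed: int = 0
    element_length: int = 5216
    ltr_length: int = 349
    tsd_length: int = 4
    polyA: tuple[int, int] = (4638, 62)  # (start, length), 0-based
    orf_aa: int = 695
    n_insertions: int = 20
    per_copy_divergence: float = 0.02
    degraded_fraction: float = 0.0
    host_length: int = 50_000
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.01
    invasion_year: int = 1988
    pingpong_fraction: float = 0.5
    copies_range: tuple[int, int] = (5, 30)
    adapter: str = "GAATTCTCGGGTGCCAAGG"

    def __post_init__(self) -> None:
        for name in ("element_length", "ltr_length", "tsd_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("per_copy_divergence", "degraded_fraction", "pingpong_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be within [0, 1]")
        if 2 * self.ltr_length >= self.element_length:
            raise ValueError("two LTRs do not fit into the element")
        pa_start, pa_len = self.polyA
        if pa_len > 0 and (
            pa_start < self.ltr_length
            or pa_start + pa_len > self.element_length - self.ltr_length
        ):
            raise ValueError("poly-A tract overlaps an LTR")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGE[stage], self.seed])


@dataclass
class InsertionTruth:
    """Ground truth for one planted copy, on the post-insertion genome."""

    interval: GenomicInterval
    divergence: float  # realized p-distance to the consensus
    degraded: bool
    length_fraction: float  # of the full consensus


# ---------------------------------------------------------------------------
# basic sequence machinery


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def mutate_sequence(
    seq: str, divergence: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Substitute bases at the given per-site rate; returns the mutated
    sequence and the realized (exact) p-distance."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(n) < divergence)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), len(hit) / n if n else 0.0


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# element


def make_element(config: SimConfig, name: str = "element") -> TEConsensus:
    """Build a synthetic element with identical LTRs (TG…TA termini), an
    internal poly-A tract and a long sense-strand ORF."""
    rng = config.rng("element")
    L = config.ltr_length
    ltr = list(random_sequence(L, rng))
    ltr[0:2] = "TG"
    ltr[-2:] = "TA"
    ltr = "".join(ltr)

    internal_len = config.element_length - 2 * L
    internal = list(random_sequence(internal_len, rng))

    pa_start, pa_len = config.polyA
    pa_internal = (pa_start - L, pa_start - L + pa_len) if pa_len > 0 else None
    if pa_internal is not None:
        internal[pa_internal[0] : pa_internal[1]] = "A" * pa_len

    orf_nt = config.orf_aa * 3 + 3
    gap_before = (pa_internal[0] if pa_internal else internal_len)
    if orf_nt + 50 <= gap_before:
        orf_at = 50
    elif pa_internal and orf_nt <= internal_len - pa_internal[1] - 50:
        orf_at = pa_internal[1] + 50
    else:
        raise ValueError("ORF does not fit into the internal region")
    codons = rng.choice(len(_SENSE_CODONS), config.orf_aa - 1)
    orf_seq = "ATG" + "".join(_SENSE_CODONS[i] for i in codons) + "TAA"
    internal[orf_at : orf_at + orf_nt] = orf_seq

    sequence = ltr + "".join(internal) + ltr
    assert len(sequence) == config.element_length
    return TEConsensus(
        id=name,
        sequence=sequence,
        ltr5=(0, L),
        ltr3=(config.element_length - L, config.element_length),
        tsd_length=config.tsd_length,
        polyA=(pa_start, pa_start + pa_len) if pa_len > 0 else None,
    )


# ---------------------------------------------------------------------------
# planted insertions


def plant_insertions(
    genome: str,
    element: TEConsensus,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    exclude: list[tuple[int, int]] | None = None,
) -> tuple[str, list[InsertionTruth]]:
    """Insert element copies at uniform positions, each independently
    mutated, canonical copies flanked by a duplicated target site.

    Degraded copies are 5'/3' truncations (10-50% of the element) mutated at
    15-25% and inserted without a TSD, mimicking ancient relics. ``exclude``
    intervals (pre-insertion coordinates) receive no insertion.
    """
    if rng is None:
        rng = config.rng("insertions")
    n = config.n_insertions
    if n == 0:
        return genome, []
    tsd = config.tsd_length
    if len(genome) < n * (tsd + 2) + 2 * tsd:
        raise ValueError("genome too short for the requested insertions")
    n_degraded = int(round(n * config.degraded_fraction))

    positions: list[int] = []
    lo, hi = tsd, len(genome) - tsd
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise ValueError("cannot place insertions outside excluded regions")
        p = int(rng.integers(lo, hi))
        if exclude and any(s <= p < e for s, e in exclude):
            continue
        if all(abs(p - q) > tsd for q in positions):
            positions.append(p)
    positions.sort()
    degraded_flags = np.zeros(n, dtype=bool)
    if n_degraded:
        degraded_flags[rng.choice(n, n_degraded, replace=False)] = True

    pieces: list[str] = []
    truth: list[InsertionTruth] = []
    prev = 0
    offset = 0
    full_len = len(element.sequence)
    for p, degraded in zip(positions, degraded_flags):
        pieces.append(genome[prev:p])
        if degraded:
            frac = rng.uniform(0.10, 0.50)
            keep = max(20, int(round(frac * full_len)))
            source = (
                element.sequence[:keep]
                if rng.random() < 0.5
                else element.sequence[-keep:]
            )
            copy, div = mutate_sequence(source, rng.uniform(0.15, 0.25), rng)
            site_dup = ""
        else:
            copy, div = mutate_sequence(element.sequence, config.per_copy_divergence, rng)
            site_dup = genome[p : p + tsd]
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = copy if strand == "+" else _revcomp(copy)
        pieces.append(site_dup)
        pieces.append(inserted)
        start = p + offset + len(site_dup)
        truth.append(
            InsertionTruth(
                interval=GenomicInterval("genome", start, start + len(copy), strand),
                divergence=div,
                degraded=bool(degraded),
                length_fraction=len(copy) / full_len,
            )
        )
        offset += len(site_dup) + len(copy)
        prev = p
    pieces.append(genome[prev:])
    return "".join(pieces), truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genome: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    name_prefix: str = "r",
) -> list[FastqRead]:
    """Uniform-coverage error-bearing reads from both strands; read names
    encode the true origin as ``prefix<i>:<start>:<strand>``."""
    if rng is None:
        rng = config.rng("reads")
    rl = config.read_length
    if rl > len(genome):
        raise ValueError("read length exceeds genome length")
    n_reads = int(round(config.coverage * len(genome) / rl))
    starts = rng.integers(0, len(genome) - rl + 1, n_reads)
    strands = rng.random(n_reads) < 0.5
    n_err = rng.binomial(rl, config.error_rate, n_reads)
    qual = "I" * rl
    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        seq = genome[s : s + rl]
        strand = "+" if strands[i] else "-"
        if strand == "-":
            seq = _revcomp(seq)
        if n_err[i]:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            for pos in rng.choice(rl, n_err[i], replace=False):
                arr[pos] = rng.choice(_BASES[_BASES != arr[pos]])
            seq = arr.tobytes().decode()
        reads.append(FastqRead(f"{name_prefix}{i}:{s}:{strand}", seq, qual))
    return reads


# ---------------------------------------------------------------------------
# full sample (study-in-a-box)


@dataclass
class SimulatedSample:
    """Everything one short-read sample of one strain consists of."""

    element: TEConsensus
    genome: str
    truth: list[InsertionTruth]
    reads: list[FastqRead]
    library: list[tuple[str, str]]  # element + single-copy genes
    scg_ids: list[str]
    mask: list[tuple[int, int]]  # poly-A interval on the element


def simulate_sample(
    config: SimConfig,
    n_scg: int = 3,
    scg_length: int = 3000,
    element: TEConsensus | None = None,
) -> SimulatedSample:
    """Generate one complete sample: an element, a host genome carrying
    ``n_scg`` embedded single-copy genes and the planted copies, reads, and
    the mapping library (element + single-copy genes).

    Insertions are kept out of the single-copy genes so that their coverage
    stays a clean normaliser, mirroring the choice of well-behaved reference
    genes in real panels.
    """
    if element is None:
        element = make_element(config)
    host = random_sequence(config.host_length, config.rng("genome"))
    spacing = config.host_length // (n_scg + 1)
    if spacing <= scg_length:
        raise ValueError("host too short for the requested single-copy genes")
    scg_windows = [
        (spacing * (i + 1) - scg_length // 2, spacing * (i + 1) + scg_length // 2)
        for i in range(n_scg)
    ]
    scg_ids = [f"scg{i + 1}" for i in range(n_scg)]
    library = [(element.id, element.sequence)] + [
        (sid, host[s:e]) for sid, (s, e) in zip(scg_ids, scg_windows)
    ]
    genome, truth = plant_insertions(host, element, config, exclude=scg_windows)
    reads = simulate_reads(genome, config)
    mask = [element.polyA] if element.polyA else []
    return SimulatedSample(
        element=element,
        genome=genome,
        truth=truth,
        reads=reads,
        library=library,
        scg_ids=scg_ids,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# dated strain panel


def simulate_panel(
    years: list[int],
    config: SimConfig,
    outliers: list[int] | None = None,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """A dated strain panel under the step model of an invasion.

    Strains sampled before ``config.invasion_year`` carry 0 copies; strains
    from that year on carry a copy number drawn uniformly from
    ``config.copies_range``. ``outliers`` flips the status of the strains at
    the given panel indices (a pre-invasion carrier, or a post-invasion
    strain the element has not reached). Returns the panel table (strain,
    year, location, copies) and the true step-model presence per strain.
    """
    if not years:
        raise ValueError("years must be non-empty")
    rng = config.rng("panel")
    locations = ["Providence", "Harare", "Vienna", "Ithaca", "Beijing", "Hobart"]
    outset = set(outliers or ())
    rows = []
    truth: dict[str, bool] = {}
    lo, hi = config.copies_range
    for i, year in enumerate(years):
        strain = f"strain{i:03d}"
        true_present = year >= config.invasion_year
        observed = not true_present if i in outset else true_present
        copies = int(rng.integers(lo, hi + 1)) if observed else 0
        rows.append(
            {
                "strain": strain,
                "year": year,
                "location": locations[i % len(locations)],
                "copies": copies,
            }
        )
        truth[strain] = true_present
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# piRNA libraries


def simulate_pirnas(
    element: TEConsensus,
    n: int,
    config: SimConfig,
    with_adapter: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[list[FastqRead], list[tuple[str, str]]]:
    """Small-RNA reads from the element, 23-29 nt, a ``pingpong_fraction``
    of them as sense/antisense pairs with exact 10 nt 5' overlap.

    Sense reads run 5'->3' on the element; an antisense read occupying
    ``[a, a+m)`` has its 5' end at ``a+m-1``. For a pair with sense 5' end at
    ``s`` the antisense 5' end sits at ``s+9``. Returns the reads and the
    list of (sense name, antisense name) pair memberships.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = config.rng("pirna")
    seq = element.sequence
    L = len(seq)
    n_pairs = int(round(n * config.pingpong_fraction / 2))
    reads: list[FastqRead] = []
    pairs: list[tuple[str, str]] = []

    def emit(name: str, insert: str) -> None:
        raw = insert + config.adapter if with_adapter else insert
        reads.append(FastqRead(name, raw, "I" * len(raw)))

    for i in range(n_pairs):
        ls = int(rng.integers(23, 30))
        la = int(rng.integers(23, 30))
        s = int(rng.integers(max(0, la - 10), L - max(ls, 10) + 1))
        a = s + 10 - la
        sense = seq[s : s + ls]
        antis = _revcomp(seq[a : a + la])
        s_name = f"pp{i}_s:{s}:+"
        a_name = f"pp{i}_as:{a}:-"
        emit(s_name, sense)
        emit(a_name, antis)
        pairs.append((s_name, a_name))
    n_bg = n - 2 * n_pairs
    for i in range(n_bg):
        length = int(rng.integers(23, 30))
        start = int(rng.integers(0, L - length + 1))
        insert = seq[start : start + length]
        strand = "+"
        if rng.random() < 0.5:
            insert = _revcomp(insert)
            strand = "-"
        emit(f"bg{i}:{start}:{strand}", insert)
    return reads, pairs


# ---------------------------------------------------------------------------
# divergent assemblies


def simulate_assembly_set(
    element: TEConsensus,
    divergences: list[float],
    seed: int = 0,
    background_length: int = 20_000,
) -> tuple[dict[str, list[tuple[str, str]]], dict[str, list[InsertionTruth]]]:
    """One small assembly per divergence level, each carrying 1-3 element
    copies mutated at that level, plus a copy-free negative control."""
    rng = np.random.default_rng([_STAGE["assemblies"], seed])
    assemblies: dict[str, list[tuple[str, str]]] = {}
    truth: dict[str, list[InsertionTruth]] = {}
    for level_idx, div in enumerate(divergences):
        if not (0.0 <= div <= 1.0):
            raise ValueError("divergences must be within [0, 1]")
        name = f"asm_div{div:g}"
        n_copies = int(rng.integers(1, 4))
        contig = random_sequence(background_length, rng)
        pieces = []
        truths = []
        step = background_length // (n_copies + 1)
        prev = 0
        offset = 0
        for c in range(n_copies):
            p = step * (c + 1)
            copy, realized = mutate_sequence(element.sequence, div, rng)
            pieces.append(contig[prev:p])
            pieces.append(copy)
            start = p + offset
            truths.append(
                InsertionTruth(
                    interval=GenomicInterval("contig1", start, start + len(copy), "+"),
                    divergence=realized,
                    degraded=False,
                    length_fraction=1.0,
                )
            )
            offset += len(copy)
            prev = p
        pieces.append(contig[prev:])
        assemblies[name] = [("contig1", "".join(pieces))]
        truth[name] = truths
    control = random_sequence(background_length, rng)
    assemblies["asm_control"] = [("contig1", control)]
    truth["asm_control"] = []
    return assemblies, truth
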