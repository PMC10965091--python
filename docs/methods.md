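# Methods

This note records the models behind each `ltrtrace` stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter when reading results.

## Coordinate and format conventions

Every coordinate in memory is 0-based half-open. SAM, GFF3 and RepeatMasker
`.out` are 1-based inclusive on disk and are converted at the reader/writer
boundary; BED passes through unchanged. Soft-masked (lowercase) bases are
uppercased on read (a flag preserves case where masking matters). Unknown
sampling years in panel tables are kept as missing and excluded from dating
rather than imputed.

## Synthetic data: the study conditions

The generator (`ltrtrace.simulate`) emulates the data a recent LTR
retrotransposon invasion leaves behind. Its defaults define the conditions
every recovery test runs under:

| parameter | default | meaning |
|---|---|---|
| `element_length` | 5216 nt | full element, LTRs included |
| `ltr_length` | 349 nt | identical terminal repeats, TG…TA termini |
| `tsd_length` | 4 nt | target-site duplication created on insertion |
| `polyA` | (4638, 62) | internal poly-A tract (0-based start, length) |
| `orf_aa` | 695 | planted gag-pol-like sense-strand ORF |
| `n_insertions` | 20 | planted copies per genome |
| `per_copy_divergence` | 0.02 | substitutions/site per canonical copy |
| `host_length` | 50 kb | random host background per sample |
| `read_length`, `coverage`, `error_rate` | 100 nt, 30×, 0.01 | short-read model |
| `invasion_year` | 1988 | step-model cutoff for panels |
| `pingpong_fraction` | 0.5 | fraction of piRNA reads in 10 nt-overlap pairs |
| `copies_range` | 5–30 | per-strain copy number once invaded |

One run seed feeds every stage; each stage derives its own generator from
the seed plus a fixed offset, so adding a stage never changes the output of
an earlier one and identical configurations are byte-identical.

Mutation of planted copies is substitution-only by default, which keeps the
recorded per-copy divergence an exact p-distance to the consensus — the
basis of the truth-consistency tests. Degraded copies model ancient relics:
5′ or 3′ truncations to 10–50% of the element, mutated at 15–25%, inserted
without a TSD. Canonical copies duplicate the 4 nt target site.

What the generator does **not** emulate: indels and structural variants
inside copies, GC- or chromatin-biased insertion preferences, nested
insertions, sequencing-quality gradients, PCR duplicates, and long-read
error profiles. Passing recovery tests therefore demonstrates correctness
of the estimators under a clean substitution-and-uniform-coverage model,
not robustness to every artifact of real libraries. The per-strain copy
range 5–30 after invasion is a modeling choice (the sources report presence
and normalized abundance, not a per-strain true count distribution).

`simulate_sample` embeds three 3 kb single-copy genes in the host at fixed
spacing and keeps insertions out of them, mirroring the practice of
normalising against well-behaved reference genes.

## Element structure

- **Consensus** is per-column majority over {A,C,G,T}. Columns where the gap
  is a strict majority are dropped (not emitted as N) so the consensus is an
  insertable sequence; all-N/gap columns are dropped and counted. Base ties
  break alphabetically. With ≥5 copies at ≤5% independent divergence, the
  probability that a column's majority differs from the ancestor is small
  enough that the consensus matches at ≥99.9% of positions (verified by
  simulation).
- **LTR detection** anchors shared 13-mers between the first and last
  1000 nt, scores each candidate diagonal by ungapped match/mismatch (+1/−1)
  and keeps the longest block with identity ≥0.9 and length ≥100 nt.
  Ungapped extension is adequate at the ≤5% divergence of recent copies; it
  will fragment on indel-rich ancient relics, which is acceptable because
  those fail the canonical filters anyway.
- **TSD detection** is the longest *exact* match between the left flank's
  suffix and the right flank's prefix, capped at 10 nt. Exact matching is
  conservative and deterministic for a 4 nt signal; allowing mismatches in
  so short a motif would mostly add noise.
- **Poly-A** is the longest window with A-fraction ≥ 0.9 (≥30 nt), found by
  maximum-scoring subarray and greedy extension; endpoints always lie on A.
- **PBS** scanning looks for an exact reverse-complement match of ≥10 nt to
  a supplied tRNA 3′ end within 30 nt downstream of the 5′ LTR and reports
  the offset (0 = directly abutting the LTR).
- **ORFs** are ATG-to-stop on both strands; the reported length includes the
  initial Met and excludes the stop. Protein-domain identification and
  superfamily classification are out of scope; ORF coordinates are the
  deliverable.

## Copy number and composition

The bundled `naive_map` is an exact-k-mer-seeded (k = 15), full-length
ungapped, both-strand mapper over the element + single-copy-gene library.
Its purpose is self-containment, not generality: reads are placed at the
fewest-mismatch locus (≤10 mismatches); ties across loci give mapping
quality 0 ("ambiguous"), which matters because reads from the two identical
LTRs always tie. Any SAM from a real aligner can be substituted.

Copy number = mean element depth over unmasked positions / mean depth over
all single-copy-gene positions, using all mapped reads (unique + ambiguous)
by default; a unique-only mode exists. The poly-A tract is masked by
default — homopolymer mapping artifacts concentrate there. The arithmetic
mean (not median/trimmed) is used: with the poly-A masked, the depth profile
has no other pathological region under this read model, and the mean is the
literal coverage-normalisation statistic. Multiplying all depths by a
constant leaves the estimate unchanged.

Presence calls require copies ≥ 0.5 **and** breadth ≥ 0.33 (breadth =
fraction of element positions with nonzero uniquely-mapping depth). The
breadth term is what keeps localized degraded relics — a few high-identity
fragments attracting reads over 5% of the element — from being called
present. Both thresholds are configurable operationalizations of what is
otherwise a visual judgement.

SNPs are sites where ≥2 alleles each reach 2 reads and the minor allele
frequency reaches 0.1; biallelic means exactly 2 passing alleles. The
sample-by-SNP matrix keeps biallelic SNPs called in strictly more than 3
samples. Where coverage masks are available, uncovered sites are missing
(NaN) and covered-but-uncalled sites are 0; for embedding, missing entries
are imputed as 0 (allele not observed) with the missing mask retained.

## Invasion dating

The step model says a strain is absent iff sampled before a cutoff year.
`infer_window` chooses the cutoff minimising misclassifications, breaking
ties toward the earliest cutoff (conservative: widens the absence era).
Misclassified strains are the outliers; the window is (latest consistent
absence, earliest consistent presence], and raw bounds without outlier
exclusion are reported alongside. An all-absent or all-present panel yields
a one-sided window, not an error. By brute force on small panels, the
outlier set is minimal: no smaller relabelling makes the panel
step-consistent. Geography is carried as metadata only; no spatial model is
attempted.

## piRNA processing and ping-pong

Adapter trimming removes the first exact occurrence of an adapter prefix
(≥5 nt, searched from position 1); exact matching is appropriate for
synthetic reads and errs toward leaving real reads untrimmed. Size
selection keeps 18–36 nt inclusive. Reads are assigned against a pooled,
prioritised database (structural RNAs before elements) so rRNA fragments
never count as element piRNAs; ties resolve to the earliest category.

A sense read's 5′ end is its leftmost coordinate; an antisense read
occupying [a, a+m) has its 5′ end at a+m−1. The overlap histogram at k is
Σ_p sense5[p]·antisense5[p+k−1] over per-million-normalised 5′-end
abundances (k = 1…23), and z10 compares bin 10 against the mean and SD of
all other bins. The statistic is withheld when the raw pair mass (the same
sum over raw counts) is below 100 — too few overlapping piRNAs to support a
z-score — or when fewer than 3 background bins are nonzero. The histogram
is invariant under a proper strand relabelling (reverse-complementing the
reference coordinate system) and under duplicating the read set.

## Horizontal-transfer screen and divergence

The built-in scanner seeds 11-mers, takes each diagonal's maximum-scoring
ungapped segment (match +1 / mismatch −1, floor 30), and keeps the
higher-scoring hit where hits overlap. Scores are not an external masker's
scores, but the similarity statistic s = rms_best / rms_max is invariant to
any within-screen rescaling, which is all it needs; the statistic is
undefined (error) on an entirely hitless screen, and hitless assemblies
score 0. Per-hit divergence is the mismatch fraction of the best segment —
accurate to a few points up to ~30% divergence under the substitution-only
copy model.

Classification follows strict printed thresholds: canonical = span > 80% of
the element **and** divergence < 5% (both strict); full-length additionally
requires at least one LTR entirely covered.

Synonymous divergence is Nei–Gojobori (1986): per-codon synonymous site
fractions averaged over both sequences (changes to stop codons count as
nonsynonymous, keeping S + N = 3 per codon), multi-difference codons
averaged over all minimal mutational pathways with stop-crossing pathways
excluded (all pathways if none avoids a stop), and the Jukes–Cantor
correction dS = −(3/4)·ln(1 − (4/3)·ps), undefined when the argument is
non-positive. NG86 is transparent and dependency-free; for rank/quantile
comparisons of an element's dS against a distribution of orthologous-gene
dS values it is an adequate substitute for codon-model maximum likelihood.
The implementation is verified against an exhaustive enumeration oracle
over all 61×61 sense-codon pairs.

Group distance comparisons use Welch's t-test (unequal variances,
Satterthwaite df); p-distances are computed over shared non-gap columns
with pairs sharing no column flagged NaN. Neighbor joining (via scikit-bio)
is exported as newick for eyeballing tree nesting only — no support values,
no rooting; taxa are pre-sorted by label so equivalent inputs give
identical output.

## Insertion landscape

Feature classes follow the fixed priority exon > intron > promoter >
intergenic; the promoter is the strand-aware 1 kb window upstream of the
first exon (gene start when no exon model exists). The priority is a
declared choice — promoters are tabulated as a class distinct from genic
insertions — and is configurable. Cluster membership is ≥1 bp overlap under
half-open semantics, so abutting intervals never count.

Population frequency works on independently assembled strains by mapping
each insertion's ±1 kb flanks (element body excised) onto one common
reference; the left flank's right edge locates the insertion, the right
flank is the fallback. Mapped insertion points within 100 nt of each other
across strains (single linkage) are one locus; frequency = carrying strains
/ assayed strains. The 100 nt slop replaces manual inspection of overlap
calls and absorbs target-site and assembly jitter; it is configurable and
reported. Insertions whose flanks fail to map uniquely drop out of the
frequency analysis rather than being force-placed. Shared genic insertions
use the same flank-locus rule: insertions in the same gene are one event iff
their loci merge.

## Problem sizes

Recovery checks run at: 60 simulated samples (20 seeds × {5, 20, 50}
insertions) at 30×/1% error on 50 kb hosts for copy number; 100 simulated
24-strain panels for window recovery; 50 planted insertions on a 400 kb
host for TSD recovery; 10,000-read piRNA libraries (one signal library, 20
null libraries) for ping-pong; 20 kb assemblies at divergence 0–0.3 for the
similarity screen; 8 strains on an 80 kb host for locus frequencies. These
sizes make every recovery statistically comfortable while keeping a full
run within a few minutes on one core.

## Known limitations

- The naive mapper is ungapped and exact-seeded; it is a fixture-scale
  stand-in, not an aligner for real libraries.
- The assembly scanner reports substitution divergence only; indel-rich
  relics fragment into multiple hits.
- Consensus building consumes an existing MSA; alignment itself is out of
  scope.
- NG86 underestimates dS at high divergence relative to ML codon models;
  conclusions should rest on ranks, not absolute values.
- The step model dates one global invasion; staggered per-region spread
  shows up only as outliers, not as per-region windows.
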