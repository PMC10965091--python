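"""Insertion classification, cluster overlap and flank-mapped frequencies."""

import numpy as np
import pytest

from ltrtrace.io_formats import GeneModel, GenomicInterval
from ltrtrace.landscape import (
    InsertionCall,
    classify_insertion,
    cluster_overlap,
    flank_map_frequency,
    frequency_spectrum,
    shared_gene_insertions,
)
from ltrtrace.simulate import SimConfig, make_element, random_sequence


def _gene(gid, start, end, strand="+", exons=None):
    return GeneModel(
        gid,
        GenomicInterval("chr", start, end, strand),
        [GenomicInterval("chr", s, e, strand) for s, e in (exons or [])],
    )


class TestClassifyInsertion:
    def test_upstream_of_plus_gene_is_promoter(self):
        gene = _gene("g", 10_000, 12_000)
        ins = GenomicInterval("chr", 9_400, 9_600)  # 500 nt upstream of start
        assert classify_insertion(ins, [gene]) == "promoter"

    def test_upstream_of_minus_gene_is_promoter(self):
        gene = _gene("g", 10_000, 12_000, strand="-")
        ins = GenomicInterval("chr", 12_300, 12_500)
        assert classify_insertion(ins, [gene]) == "promoter"

    def test_exon_outranks_neighboring_promoter(self):
        exonic = _gene("g1", 5_000, 6_000, exons=[(5_000, 6_000)])
        neighbor = _gene("g2", 6_400, 8_000)
        ins = GenomicInterval("chr", 5_500, 5_700)  # in g1 exon, 800 nt upstream of g2
        assert classify_insertion(ins, [exonic, neighbor]) == "exon"

    def test_intron_between_exons(self):
        gene = _gene("g", 1_000, 5_000, exons=[(1_000, 1_500), (4_000, 5_000)])
        ins = GenomicInterval("chr", 2_000, 2_100)
        assert classify_insertion(ins, [gene]) == "intron"

    def test_far_from_everything_is_intergenic(self):
        gene = _gene("g", 1_000, 2_000)
        ins = GenomicInterval("chr", 50_000, 50_100)
        assert classify_insertion(ins, [gene]) == "intergenic"

    def test_promoter_anchored_on_first_exon(self):
        # gene span starts at 1000 but the first exon starts at 1600:
        # the 1 kb promoter window is [600, 1600)
        gene = _gene("g", 1_000, 5_000, exons=[(1_600, 2_000), (4_000, 5_000)])
        ins = GenomicInterval("chr", 700, 800)
        assert classify_insertion(ins, [gene]) == "promoter"

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            genes = []
            for gi in range(10):
                start = int(rng.integers(0, 90_000))
                end = start + int(rng.integers(500, 5_000))
                strand = "+" if rng.random() < 0.5 else "-"
                n_ex = int(rng.integers(0, 4))
                bounds = sorted(rng.integers(start, end, 2 * n_ex)) if n_ex else []
                exons = [
                    (int(bounds[2 * i]), int(bounds[2 * i + 1]))
                    for i in range(n_ex)
                    if bounds[2 * i] < bounds[2 * i + 1]
                ]
                genes.append(_gene(f"g{gi}", start, end, strand, exons))
            for _ in range(50):
                s = int(rng.integers(0, 99_000))
                ins = GenomicInterval("chr", s, s + int(rng.integers(1, 1_000)))
                got = classify_insertion(ins, genes)
                assert got == self._oracle(ins, genes)
            # invariance under gene-list permutation
            ins = GenomicInterval("chr", 40_000, 41_000)
            perm = list(genes)
            rng.shuffle(perm)
            assert classify_insertion(ins, genes) == classify_insertion(ins, perm)

    @staticmethod
    def _oracle(ins, genes, promoter_len=1000):
        def ov(a_start, a_end):
            return ins.start < a_end and a_start < ins.end

        classes = set()
        for g in genes:
            if any(ov(e.start, e.end) for e in g.exons):
                classes.add("exon")
            elif ov(g.span.start, g.span.end):
                classes.add("intron")
            else:
                if g.exons:
                    anchor = (
                        min(e.start for e in g.exons)
                        if g.span.strand != "-"
                        else max(e.end for e in g.exons)
                    )
                else:
                    anchor = g.span.start if g.span.strand != "-" else g.span.end
                if g.span.strand == "-":
                    w = (anchor, anchor + promoter_len)
                else:
                    w = (max(0, anchor - promoter_len), anchor)
                if w[0] < w[1] and ov(*w):
                    classes.add("promoter")
        for c in ("exon", "intron", "promoter"):
            if c in classes:
                return c
        return "intergenic"


class TestClusterOverlap:
    CLUSTERS = [(GenomicInterval("chr", 10_000, 20_000), "42AB")]

    def _ins(self, start, end, strain="s1"):
        return InsertionCall(GenomicInterval("chr", start, end), strain=strain)

    def test_contained_insertion_counted(self):
        df = cluster_overlap([self._ins(12_000, 17_000)], self.CLUSTERS)
        assert df[df.cluster == "42AB"]["count"].sum() == 1

    def test_abutting_insertion_not_counted(self):
        df = cluster_overlap([self._ins(20_000, 25_000)], self.CLUSTERS)
        assert df[df.cluster == "42AB"].empty

    def test_planted_mixture(self):
        inside = [self._ins(10_000 + i * 2_000, 11_000 + i * 2_000) for i in range(3)]
        outside = [self._ins(30_000 + i * 2_000, 31_000 + i * 2_000) for i in range(5)]
        df = cluster_overlap(inside + outside, self.CLUSTERS)
        assert df[df.cluster == "42AB"]["count"].sum() == 3
        total = df[(df.strain == "s1") & (df.cluster == "__total__")]["count"].iloc[0]
        assert total == 3

    def test_strains_without_cluster_insertion_reported_zero(self):
        df = cluster_overlap(
            [self._ins(12_000, 13_000, "s1"), self._ins(40_000, 41_000, "s2")],
            self.CLUSTERS,
        )
        totals = df[df.cluster == "__total__"].set_index("strain")["count"]
        assert totals["s1"] == 1 and totals["s2"] == 0


@pytest.fixture(scope="module")
def flank_world():
    """Eight strains sharing a host genome with planted shared/private loci."""
    cfg = SimConfig(seed=30, n_insertions=0)
    element = make_element(cfg)
    rng = np.random.default_rng(31)
    host = random_sequence(80_000, rng)

    def build(positions_labels):
        genome = host
        offset = 0
        calls = []
        for pos, label in sorted(positions_labels):
            p = pos + offset
            body = element.sequence if label == "canonical" else element.sequence[:1500]
            genome = genome[: p + 4] + body + genome[p:]
            calls.append(
                InsertionCall(
                    GenomicInterval("chr", p + 4, p + 4 + len(body)), label=label
                )
            )
            offset += len(body) + 4
        return {"chr": genome}, calls

    # degraded locus at 20 kb in every strain; canonical shared locus at 40 kb
    # in strains 0-3 (freq 4/8); private canonical loci per strain elsewhere
    strains = {}
    for i in range(8):
        spec = [(20_000, "degraded")]
        if i < 4:
            spec.append((40_000, "canonical"))
        spec.append((55_000 + i * 2_500, "canonical"))  # private
        assembly, calls = build(spec)
        name = f"strain{i}"
        for c in calls:
            c.strain = name
        strains[name] = (assembly, calls)
    return host, element, strains


class TestFlankMapFrequency:
    def test_recovers_planted_frequencies(self, flank_world):
        host, _, strains = flank_world
        loci = flank_map_frequency(strains, [("chr", host)])
        by_freq = sorted(locus.frequency for locus in loci)
        assert by_freq == [1 / 8] * 8 + [4 / 8, 8 / 8]
        shared = [l for l in loci if l.frequency == 1.0]
        assert shared[0].majority_label == "degraded"
        half = [l for l in loci if l.frequency == 0.5]
        assert half[0].majority_label == "canonical"

    def test_two_of_two_shared_is_frequency_one(self, flank_world):
        host, _, strains = flank_world
        two = {k: strains[k] for k in ["strain0", "strain1"]}
        loci = flank_map_frequency(two, [("chr", host)])
        freqs = sorted(l.frequency for l in loci)
        assert freqs == [0.5, 0.5, 1.0, 1.0]

    def test_frequency_times_n_counts_members(self, flank_world):
        host, _, strains = flank_world
        loci = flank_map_frequency(strains, [("chr", host)])
        total_records = sum(len(calls) for _, calls in strains.values())
        assert sum(round(l.frequency * 8) for l in loci) == total_records

    def test_single_strain_rejected(self, flank_world):
        host, _, strains = flank_world
        with pytest.raises(ValueError):
            flank_map_frequency({"s": strains["strain0"]}, [("chr", host)])


class TestFrequencySpectrum:
    def test_planted_contrast(self, flank_world):
        """Degraded relics sit at high frequency, fresh canonical copies at
        low frequency — the hallmark of a recent invasion."""
        host, _, strains = flank_world
        loci = flank_map_frequency(strains, [("chr", host)])
        spec = frequency_spectrum(loci, 8)
        assert spec.loc["degraded", "8/8"] == 1
        assert spec.loc["canonical", "1/8"] == 8
        assert spec.loc["canonical", "4/8"] == 1

    def test_all_private_mass_in_first_bin(self):
        from ltrtrace.landscape import Locus

        loci = [
            Locus(i, "chr", i * 1000, strains={f"s{i}"}, labels=["canonical"], frequency=0.25)
            for i in range(4)
        ]
        spec = frequency_spectrum(loci, 4)
        assert spec.loc["canonical", "1/4"] == 4

    def test_empty_degraded_class_is_zero_row(self):
        from ltrtrace.landscape import Locus

        loci = [Locus(0, "chr", 0, strains={"a"}, labels=["canonical"], frequency=0.5)]
        spec = frequency_spectrum(loci, 2)
        assert spec.loc["degraded"].sum() == 0

    def test_empty_loci_rejected(self):
        with pytest.raises(ValueError):
            frequency_spectrum([], 8)


class TestSharedGeneInsertions:
    def test_shared_and_independent_counts(self, flank_world):
        host, _, strains = flank_world
        # one gene containing the half-shared locus (40 kb) and one
        # containing all eight private loci (55-75 kb)
        genes = [
            _gene("shared_gene", 38_000, 47_000),
            _gene("hot_gene", 54_000, 79_000),
        ]
        genes_by_strain = {}
        for name, (assembly, calls) in strains.items():
            # lift gene spans: insertions upstream shift coordinates, so use
            # generous spans on each strain's own assembly
            genes_by_strain[name] = [
                _gene("shared_gene", 38_000, 52_000),
                _gene("hot_gene", 54_000, 105_000),
            ]
        df = shared_gene_insertions(strains, genes_by_strain, [("chr", host)])
        counts = df.set_index("gene")["independent_insertions"]
        assert counts["shared_gene"] == 1
        assert counts["hot_gene"] == 8
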