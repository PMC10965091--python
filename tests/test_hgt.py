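"""Cross-assembly screen, NG86 divergence, distance statistics, NJ export."""

import itertools

import numpy as np
import pytest

from ltrtrace.element_model import MSAProfile
from ltrtrace.hgt import (
    classify_hits,
    group_distance_test,
    ng86,
    nj_tree,
    p_distance_matrix,
    scan_assembly,
    similarity_scores,
)
from ltrtrace.io_formats import GenomicInterval, RepeatHit
from ltrtrace.simulate import SimConfig, make_element, random_sequence, simulate_assembly_set


class TestScanAssembly:
    def test_exact_copy_found_full_length(self, element):
        rng = np.random.default_rng(1)
        contig = random_sequence(3000, rng) + element.sequence + random_sequence(3000, rng)
        hits = scan_assembly([("c1", contig)], element)
        best = max(hits, key=lambda h: h.score)
        assert best.te_span == (0, len(element.sequence))
        assert best.pct_div == 0.0
        assert best.query.start == 3000

    def test_random_assembly_has_no_hit(self, element):
        rng = np.random.default_rng(2)
        contig = random_sequence(20_000, rng)
        # verify the premise: no shared 11-mer with the element
        elem_kmers = {
            element.sequence[i : i + 11] for i in range(len(element.sequence) - 10)
        }
        shared = any(contig[i : i + 11] in elem_kmers for i in range(len(contig) - 10))
        hits = scan_assembly([("c1", contig)], element)
        if not shared:
            assert hits == []
        else:  # a chance seed may exist; it must stay below the score floor
            assert all(h.score < 30 for h in hits)

    def test_planted_divergent_copy_divergence_estimate(self, element):
        assemblies, truth = simulate_assembly_set(element, [0.1], seed=3)
        hits = scan_assembly(assemblies["asm_div0.1"], element)
        best = max(hits, key=lambda h: h.score)
        assert abs(best.pct_div - 10.0) <= 3.0

    def test_reverse_strand_copy_detected(self, element):
        from Bio.Seq import Seq

        rng = np.random.default_rng(4)
        rc = str(Seq(element.sequence).reverse_complement())
        contig = random_sequence(2000, rng) + rc + random_sequence(2000, rng)
        hits = scan_assembly([("c1", contig)], element)
        best = max(hits, key=lambda h: h.score)
        assert best.query.strand == "-"
        assert best.te_span == (0, len(element.sequence))


class TestSimilarityScores:
    def _hit(self, score):
        return RepeatHit(score, 1.0, GenomicInterval("c", 0, 100), "te", (0, 100))

    def test_single_assembly_scores_one(self):
        (sim,) = similarity_scores({"a": [self._hit(123.0)]})
        assert sim.s == 1.0

    def test_direct_division(self):
        sims = similarity_scores(
            {"a": [self._hit(1000.0)], "b": [self._hit(500.0)], "c": []}
        )
        by = {s.assembly: s.s for s in sims}
        assert by == {"a": 1.0, "b": 0.5, "c": 0.0}

    def test_all_hitless_screen_rejected(self):
        with pytest.raises(ValueError):
            similarity_scores({"a": [], "b": []})

    def test_monotone_decreasing_with_divergence(self, element):
        assemblies, _ = simulate_assembly_set(element, [0.0, 0.1, 0.2, 0.3], seed=5)
        hits = {name: scan_assembly(asm, element) for name, asm in assemblies.items()}
        by = {s.assembly: s.s for s in similarity_scores(hits)}
        series = [by[f"asm_div{d:g}"] for d in (0.0, 0.1, 0.2, 0.3)]
        assert series[0] == 1.0
        assert all(a > b for a, b in zip(series, series[1:]))
        assert by["asm_control"] == 0.0


class TestClassifyHits:
    def _hit(self, span_frac, div, te_span=None, L=1000):
        span = te_span or (0, int(span_frac * L))
        return RepeatHit(100.0, div, GenomicInterval("c", 0, 100), "te", span)

    def test_canonical(self):
        (label,) = classify_hits([self._hit(0.85, 2.0)], 1000)
        assert label == "canonical"

    def test_too_diverged_is_degraded(self):
        (label,) = classify_hits([self._hit(0.85, 12.0)], 1000)
        assert label == "degraded"

    def test_exact_80_percent_boundary_excluded(self):
        (label,) = classify_hits([self._hit(0.80, 2.0)], 1000)
        assert label == "degraded"

    def test_just_under_5_percent_divergence_included(self):
        (label,) = classify_hits([self._hit(0.85, 4.999)], 1000)
        assert label == "canonical"

    def test_exact_5_percent_divergence_excluded(self):
        (label,) = classify_hits([self._hit(0.85, 5.0)], 1000)
        assert label == "degraded"

    def test_full_length_requires_covered_ltr(self):
        with_ltr = self._hit(None, 2.0, te_span=(0, 900))
        without_ltr = self._hit(None, 2.0, te_span=(60, 990))
        labels = classify_hits(
            [with_ltr, without_ltr],
            1000,
            require_ltr=True,
            ltr5=(0, 50),
            ltr3=(950, 1000),
        )
        assert labels == ["full-length", "degraded"]


# ---------------------------------------------------------------------------
# NG86 with a brute-force oracle

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")


def oracle_sites(codon):
    """Exhaustive enumeration of the 9 single-base changes."""
    s = 0.0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if _CODON_TABLE[alt] == _CODON_TABLE[codon]:
            s += 1 / 3
    return s


def oracle_path_counts(c1, c2):
    """Average syn/nonsyn steps over all stop-free minimal pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                ok = False
            sd += _CODON_TABLE[nxt] == _CODON_TABLE[cur]
            nd += _CODON_TABLE[nxt] != _CODON_TABLE[cur]
            cur = nxt
        paths.append((ok, sd, nd))
    valid = [(s, n) for ok, s, n in paths if ok] or [(s, n) for _, s, n in paths]
    return (
        sum(p[0] for p in valid) / len(valid),
        sum(p[1] for p in valid) / len(valid),
    )


class TestNg86:
    def test_identical_sequences(self):
        est = ng86("ATGGCTAAA", "ATGGCTAAA")
        assert est.dS == 0.0 and est.dN == 0.0

    def test_hand_derived_example(self):
        est = ng86("AAAGGGCCCTTT", "AAGGGGCCCTTT")
        assert est.S_sites == pytest.approx(8 / 3)
        assert est.Sd == pytest.approx(1.0)
        ps = 1.0 / (8 / 3)
        assert ps == pytest.approx(0.375)
        assert est.dS == pytest.approx(-0.75 * np.log(1 - 4 * ps / 3), abs=1e-9)
        assert est.dS == pytest.approx(0.52, abs=0.005)

    def test_purely_nonsynonymous_change(self):
        # GGG -> AGG is Gly -> Arg at a site where every change is nonsyn
        est = ng86("GGGAAA", "AGGAAA")
        assert est.dS == 0.0 and est.dN > 0.0

    def test_sites_sum_to_three_per_codon(self):
        est = ng86("ATGGCTAAATTT", "ATGGCAAAATTC")
        assert est.S_sites + est.N_sites == pytest.approx(12.0)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="codon 1"):
            ng86("AAATAAGGG", "AAATAAGGG")

    def test_unequal_or_non_triplet_rejected(self):
        with pytest.raises(ValueError):
            ng86("AAAT", "AAAT")
        with pytest.raises(ValueError):
            ng86("AAA", "AAATTT")

    def test_matches_oracle_on_codon_pair_sample(self):
        """Spot-check against the exhaustive oracle on a random sample of
        sense-codon pairs (the full 61x61 sweep runs in the acceptance
        suite)."""
        rng = np.random.default_rng(9)
        idx = rng.integers(0, 61, size=(200, 2))
        for i, j in idx:
            c1, c2 = SENSE_CODONS[i], SENSE_CODONS[j]
            est = ng86(c1, c2)
            s_exp = (oracle_sites(c1) + oracle_sites(c2)) / 2
            sd_exp, nd_exp = oracle_path_counts(c1, c2)
            assert est.S_sites == pytest.approx(s_exp)
            assert est.Sd == pytest.approx(sd_exp)
            assert est.Nd == pytest.approx(nd_exp)

    def test_saturated_divergence_undefined(self):
        # force ps > 3/4: every codon pair differs synonymously
        est = ng86("TTATTATTA", "CTGCTGCTG")
        assert est.dS is None


class TestPDistance:
    def test_identical_rows_zero(self):
        m = p_distance_matrix(MSAProfile(["ACGTACGTAC", "ACGTACGTAC"]))
        assert m[0, 1] == 0.0

    def test_three_of_ten_shared_columns(self):
        a = "AAAAAAAAAA"
        b = "AAAAAAATTT"
        m = p_distance_matrix(MSAProfile([a, b]))
        assert m[0, 1] == pytest.approx(0.3)

    def test_gap_columns_excluded_from_denominator(self):
        a = "AA--AAAAAA"
        b = "AATTAAAAAT"
        m = p_distance_matrix(MSAProfile([a, b]))
        assert m[0, 1] == pytest.approx(1 / 8)

    def test_no_shared_columns_flagged_nan(self):
        m = p_distance_matrix(MSAProfile(["AAAA----", "----TTTT"]))
        assert np.isnan(m[0, 1])


class TestGroupDistanceTest:
    def test_identical_groups(self):
        res = group_distance_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_welch_example(self):
        res = group_distance_test([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == pytest.approx(4.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            group_distance_test([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])

    def test_matches_welch_formulas_on_random_data(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(3, 30)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 30)))
            res = group_distance_test(list(a), list(b))
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_exp = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df_exp = (va + vb) ** 2 / (
                va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
            )
            assert res.t == pytest.approx(t_exp)
            assert res.df == pytest.approx(df_exp)
            assert 0.0 <= res.p <= 1.0


class TestNjTree:
    @staticmethod
    def _patristic(newick):
        from skbio import TreeNode
        import io as _io

        tree = TreeNode.read(_io.StringIO(newick))
        tips = sorted(t.name for t in tree.tips())
        return {
            (a, b): tree.find(a).distance(tree.find(b))
            for a in tips
            for b in tips
            if a < b
        }

    def test_three_taxa_additive(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        newick = nj_tree(d, ["x", "y", "z"])
        pat = self._patristic(newick)
        assert pat[("x", "y")] == pytest.approx(3.0)
        assert pat[("x", "z")] == pytest.approx(4.0)
        assert pat[("y", "z")] == pytest.approx(5.0)

    def test_four_taxon_additive_topology_recovered(self):
        # tree ((a:1,b:2):3,(c:1.5,d:2.5)); additive distances
        d = np.array(
            [
                [0.0, 3.0, 5.5, 6.5],
                [3.0, 0.0, 6.5, 7.5],
                [5.5, 6.5, 0.0, 4.0],
                [6.5, 7.5, 4.0, 0.0],
            ]
        )
        labels = ["a", "b", "c", "d"]
        pat = self._patristic(nj_tree(d, labels))
        for (i, j), expected in zip(
            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
            [3.0, 5.5, 6.5, 6.5, 7.5, 4.0],
        ):
            key = tuple(sorted((labels[i], labels[j])))
            assert pat[key] == pytest.approx(expected)

    def test_label_permutation_invariance(self):
        d = np.array(
            [
                [0.0, 3.0, 5.5, 6.5],
                [3.0, 0.0, 6.5, 7.5],
                [5.5, 6.5, 0.0, 4.0],
                [6.5, 7.5, 4.0, 0.0],
            ]
        )
        labels = ["a", "b", "c", "d"]
        perm = [2, 0, 3, 1]
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        assert self._patristic(nj_tree(d, labels)) == self._patristic(
            nj_tree(d2, labels2)
        )

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d, ["a", "b", "c"])
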