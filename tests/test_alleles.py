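"""Allele extraction, homology grouping, and paralog classification."""

import numpy as np
import pytest

from pacn.alleles import (
    ExonRecord,
    PAllele,
    classify_paralog,
    containment,
    extract_pa_intervals,
    extract_pas,
    filter_low_confidence,
    group_homologous_pas,
    paralog_class,
)
from pacn.kmers import kmer_set

CLEN = {("h0", "c1"): 1_000_000}


def _exons(*spans, gene="G", hap="h0", contig="c1"):
    return [ExonRecord(contig, s, e, gene, hap) for s, e in spans]


class TestExtraction:
    def test_close_exons_merge_into_one_allele(self):
        # 10 kb apart (< 20 kb): one interval spanning both plus 5 kb anchors
        ivs = extract_pa_intervals(_exons((100_000, 101_000), (111_000, 112_000)), CLEN)
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end) == (95_000, 117_000)

    def test_distant_exons_split_and_pad(self):
        # 30 kb apart: two alleles, each padded up to the 15 kb minimum
        ivs = extract_pa_intervals(_exons((100_000, 101_000), (131_000, 132_000)), CLEN)
        assert len(ivs) == 2
        assert all(iv.end - iv.start == 15_000 for iv in ivs)
        assert not any(iv.partial for iv in ivs)

    def test_merge_gap_boundary(self):
        # gap of 19,999 merges; 20,000 splits
        merged = extract_pa_intervals(_exons((100_000, 100_100), (120_099, 120_200)), CLEN)
        split = extract_pa_intervals(_exons((100_000, 100_100), (120_100, 120_200)), CLEN)
        assert len(merged) == 1
        assert len(split) == 2

    def test_single_small_exon_centered(self):
        ivs = extract_pa_intervals(_exons((50_000, 50_100)), CLEN)
        (iv,) = ivs
        assert iv.end - iv.start == 15_000
        # centered on the exon plus flanks
        assert (iv.start, iv.end) == (42_550, 57_550)

    def test_contig_end_clipping_and_partial(self):
        short = {("h0", "c1"): 9_000}
        ivs = extract_pa_intervals(_exons((4_000, 4_100)), short)
        (iv,) = ivs
        assert (iv.start, iv.end) == (0, 9_000)
        assert iv.partial

    def test_out_of_bounds_exon_rejected(self):
        ivs = extract_pa_intervals(_exons((999_900, 1_000_500)), CLEN)
        assert ivs == []

    def test_empty_input(self):
        assert extract_pa_intervals([], CLEN) == []

    def test_overlapping_intervals_merge_across_genes(self):
        exons = _exons((100_000, 101_000)) + _exons((103_000, 104_000), gene="H")
        ivs = extract_pa_intervals(exons, CLEN)
        assert len(ivs) == 1
        assert sorted(ivs[0].gene_labels) == ["G", "H"]

    def test_idempotent_on_own_output(self):
        ivs = extract_pa_intervals(_exons((100_000, 101_000), (131_000, 132_000)), CLEN)
        again = extract_pa_intervals(
            [ExonRecord(iv.contig, iv.start, iv.end, f"g{i}", iv.haplotype)
             for i, iv in enumerate(ivs)],
            CLEN, flank_bp=0,
        )
        assert [(iv.start, iv.end) for iv in again] == [(iv.start, iv.end) for iv in ivs]


def _pa(pid, seq, hap="h0", genes=None):
    return PAllele(pid, hap, "c1", 0, len(seq), "+", seq, ["G"], 0,
                   gene_intervals=genes or [])


class TestGrouping:
    def test_identical_sequences_one_group(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        groups = group_homologous_pas([_pa("a", seq), _pa("b", seq)], k=15)
        assert len(groups) == 1

    def test_disjoint_sequences_two_groups(self, rng):
        a = "".join(rng.choice(list("ACGT"), 200))
        b = "".join(rng.choice(list("ACGT"), 200))
        groups = group_homologous_pas([_pa("a", a), _pa("b", b)], k=15)
        assert len(groups) == 2

    def test_single_linkage_closure_matches_bruteforce(self, rng):
        # random related/unrelated sequences; partition must equal the
        # brute-force union-find closure over the containment matrix
        base = "".join(rng.choice(list("ACGT"), 500))

        def mutate(s, n):
            s = list(s)
            for i in rng.choice(len(s), n, replace=False):
                s[i] = "ACGT"[(("ACGT".index(s[i])) + 1) % 4]
            return "".join(s)

        seqs = [base, mutate(base, 30), mutate(base, 60),
                "".join(rng.choice(list("ACGT"), 500))]
        pas = [_pa(f"p{i}", s) for i, s in enumerate(seqs)]
        k, thr = 15, 0.5
        groups = group_homologous_pas(pas, k=k, grouping_similarity=thr)
        sets = [kmer_set(s, k) for s in seqs]
        n = len(seqs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if containment(sets[i], sets[j]) >= thr:
                    parent[find(j)] = find(i)
        oracle = {}
        for i in range(n):
            oracle.setdefault(find(i), set()).add(f"p{i}")
        got = {frozenset(g.members) for g in groups}
        assert got == {frozenset(m) for m in oracle.values()}

    def test_prefilter_gives_same_partition(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(6)]
        pas = [_pa(f"p{i}", s) for i, s in enumerate(seqs)]
        exact = {frozenset(g.members) for g in group_homologous_pas(pas, k=15)}
        fast = {frozenset(g.members)
                for g in group_homologous_pas(pas, k=15, prefilter=True)}
        assert exact == fast

    def test_partition_property_and_monotonicity(self, small_truth):
        from pacn.alleles import extract_pa_intervals as epi

        clens = {(h, c): len(s) for h, cs in small_truth.assemblies.items()
                 for c, s in cs.items()}
        ivs = epi(small_truth.exons, clens, 500, 150, 400)
        pas = extract_pas(small_truth.assemblies, ivs, 150)
        lo = group_homologous_pas(pas, k=21, grouping_similarity=0.1, prefilter=True)
        hi = group_homologous_pas(pas, k=21, grouping_similarity=0.6, prefilter=True)
        for groups in (lo, hi):
            ids = [m for g in groups for m in g.members]
            assert sorted(ids) == sorted(p.id for p in pas)
        assert len(lo) <= len(hi)

    def test_short_pa_excluded_with_warning(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        with pytest.warns(UserWarning, match="shorter than k"):
            groups = group_homologous_pas([_pa("a", seq), _pa("tiny", "ACGT")], k=15)
        assert all("tiny" not in g.members for g in groups)


class TestClassification:
    def test_threshold_flip_exact(self):
        assert paralog_class(0.80) == "duplicative_paralog"
        assert paralog_class(0.80 - 1e-9) == "diverged_paralog"
        assert paralog_class(0.95) == "duplicative_paralog"
        assert paralog_class(0.50) == "diverged_paralog"

    def test_sequence_level_classes_match_measured_similarity(self, rng):
        ref_seq = "".join(rng.choice(list("ACGT"), 1_000))
        ref = _pa("ref", ref_seq)
        for n_mut in (5, 120):
            s = list(ref_seq)
            for i in rng.choice(len(s), n_mut, replace=False):
                s[i] = "ACGT"[(("ACGT".index(s[i])) + 1) % 4]
            pa = _pa("q", "".join(s))
            sim = containment(kmer_set(pa.sequence, 15), kmer_set(ref_seq, 15))
            ann = classify_paralog(pa, ref, k=15)
            assert ann.similarity_to_reference == pytest.approx(sim)
            assert ann.klass == paralog_class(sim)
            if ann.klass == "duplicative_paralog":
                assert ann.similarity_to_reference >= 0.80

    def test_ortholog_classes(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 400))
        ref = _pa("ref", seq)
        ann = classify_paralog(_pa("q", seq), ref, k=15,
                               locus_is_reference=True, in_reference_subgroup=True)
        assert ann.klass == "reference_allele"
        ann = classify_paralog(_pa("q", seq), ref, k=15,
                               locus_is_reference=True, in_reference_subgroup=False)
        assert ann.klass == "alternative_allele"

    def test_missing_reference_defers(self, rng):
        pa = _pa("q", "".join(rng.choice(list("ACGT"), 400)))
        ann = classify_paralog(pa, None, k=15)
        assert ann.klass is None

    def test_proximal_and_runway(self, rng):
        seq = "A" * 70_000
        close3 = [("G", 0, 1_000), ("G", 10_000, 11_000), ("G", 21_000, 22_000)]
        ann = classify_paralog(_pa("a", seq, genes=close3), None, k=15)
        assert ann.proximal_duplication and ann.runway
        close2 = close3[:2]
        ann = classify_paralog(_pa("b", seq, genes=close2), None, k=15)
        assert ann.proximal_duplication and not ann.runway
        far = [("G", 0, 1_000), ("G", 30_000, 31_000)]
        ann = classify_paralog(_pa("c", seq, genes=far), None, k=15)
        assert not ann.proximal_duplication and not ann.runway


def test_low_confidence_filter(rng):
    good = _pa("good", "".join(rng.choice(list("ACGT"), 1_000)))
    bad = _pa("bad", "N" * 100 + "".join(rng.choice(list("ACGT"), 900)))
    kept, dropped = filter_low_confidence([good, bad], max_n_frac=0.05)
    assert [p.id for p in kept] == ["good"]
    assert [p.id for p in dropped] == ["bad"]


def test_pallele_invariants():
    with pytest.raises(ValueError, match="length"):
        PAllele("x", "h", "c", 0, 5, "+", "ACGT", [], 0)
    with pytest.raises(ValueError, match="invalid"):
        PAllele("x", "h", "c", 0, 4, "+", "ACGX", [], 0)
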