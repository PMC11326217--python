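"""Simulator: determinism, truth consistency, planted features."""

from collections import Counter

import numpy as np
import pytest

from pacn.kmers import kmer_set
from pacn.simulate import (
    SimConfig,
    mendelian_trio,
    simulate_pangenome,
    simulate_sample,
    write_fastq,
)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SimConfig(seed=3, n_haplotypes=4, n_families=2, gene_length_bp=800,
                        spacer_len_bp=600)
        t1 = simulate_pangenome(cfg)
        t2 = simulate_pangenome(cfg)
        assert t1.assemblies == t2.assemblies
        assert t1.coords.equals(t2.coords)
        r1, _ = simulate_sample(t1, ("h00", "h01"), seed=9)
        r2, _ = simulate_sample(t2, ("h00", "h01"), seed=9)
        assert r1 == r2

    def test_trio_choice_deterministic(self):
        cfg = SimConfig(seed=3, n_haplotypes=4, n_families=1, gene_length_bp=600,
                        spacer_len_bp=600)
        t = simulate_pangenome(cfg)
        picks = {mendelian_trio(t, ("h00", "h01"), ("h02", "h03"), seed=5)
                 for _ in range(3)}
        assert len(picks) == 1


class TestPlantedVariation:
    def test_zero_divergence_identical_to_ancestor(self):
        cfg = SimConfig(seed=1, n_haplotypes=4, n_families=2, n_paralog_loci=1,
                        gene_length_bp=800, paralog_divergence=0.0,
                        founder_divergence=0.0, ortholog_divergence=0.0,
                        sv_rate=0.0, conversion_rate=0.0,
                        cnv_rate=0.0, cnv_max_extra=0, del_rate=0.0, spacer_len_bp=600)
        t = simulate_pangenome(cfg)
        for rec in t.alleles.values():
            assert rec.sequence == t.locus_ancestors[rec.family][rec.locus]

    def test_conversion_tract_kmers_match_source(self):
        cfg = SimConfig(seed=2, n_haplotypes=2, n_families=1, n_paralog_loci=2,
                        gene_length_bp=1500, paralog_divergence=0.02,
                        founder_divergence=0.0, ortholog_divergence=0.0,
                        sv_rate=0.0, conversion_rate=1.0,
                        conversion_tract_bp=500, cnv_rate=0.0, cnv_max_extra=0,
                        del_rate=0.0, spacer_len_bp=600)
        t = simulate_pangenome(cfg)
        converted = [a for a in t.alleles.values() if a.conversion is not None]
        assert converted
        k = 21
        for rec in converted:
            src, start, length = rec.conversion
            tract = rec.sequence[start : start + length]
            source_anc = t.locus_ancestors[rec.family][src]
            target_anc = t.locus_ancestors[rec.family][rec.locus]
            assert tract == source_anc[start : start + length]
            # interior tract k-mers belong to the source paralog
            inner = tract[k:-k] if length > 2 * k else tract
            src_set = set(map(int, kmer_set(source_anc, k)))
            assert set(map(int, kmer_set(inner, k))) <= src_set
            # flanks still match the target paralog
            flank = rec.sequence[:start][:200]
            if len(flank) >= k:
                tgt_set = set(map(int, kmer_set(target_anc[:start][:200], k)))
                assert set(map(int, kmer_set(flank, k))) == tgt_set

    def test_sv_recorded_and_changes_length(self):
        cfg = SimConfig(seed=4, n_haplotypes=8, n_families=2, n_paralog_loci=1,
                        gene_length_bp=1500, sv_rate=0.8, sv_size_bp=(100, 200),
                        ortholog_divergence=0.0, conversion_rate=0.0,
                        cnv_rate=0.0, cnv_max_extra=0, del_rate=0.0, spacer_len_bp=600)
        t = simulate_pangenome(cfg)
        with_sv = [a for a in t.alleles.values() if a.svs]
        assert with_sv
        for rec in with_sv:
            kind, _, size = rec.svs[0]
            delta = len(rec.sequence) - cfg.gene_length_bp
            assert delta == (size if kind == "ins" else -size)
        gaps = t.sv_gap_table(0)
        assert gaps and max(gaps.values()) >= 100

    def test_cnv_copies_recorded(self):
        cfg = SimConfig(seed=6, n_haplotypes=8, n_families=1, n_paralog_loci=1,
                        gene_length_bp=800, cnv_rate=0.9, cnv_max_extra=2,
                        del_rate=0.0, sv_rate=0.0, conversion_rate=0.0,
                        ortholog_divergence=0.005, spacer_len_bp=600)
        t = simulate_pangenome(cfg)
        assert any(max(c.values()) >= 2 for c in t.hap_allele_counts.values() if c)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError, match="SV size"):
            SimConfig(gene_length_bp=400, sv_size_bp=(50, 500)).validate()


class TestTruthConsistency:
    def test_recount_from_assemblies(self, small_truth):
        """Gene copies cut out of the emitted FASTA reproduce the truth CN."""
        for hap in small_truth.haplotypes():
            seq = small_truth.assemblies[hap]["chr1"]
            sub = small_truth.coords[small_truth.coords["hap"] == hap]
            for fam in range(small_truth.cfg.n_families):
                observed = Counter()
                for row in sub[sub["family"] == fam].itertuples(index=False):
                    piece = seq[row.start : row.end]
                    rec = small_truth.alleles[row.allele_id]
                    assert piece == rec.sequence
                    observed[row.allele_id] += 1
                assert observed == small_truth.hap_allele_counts[(hap, fam)]

    def test_sample_pacn_is_sum_of_haplotypes(self, small_truth):
        pair = ("h00", "h00")  # homozygous: every count doubles
        single = small_truth.pacn(("h00", "h01"), 0)
        double = small_truth.pacn(pair, 0)
        h0 = small_truth.hap_allele_counts[("h00", 0)]
        h1 = small_truth.hap_allele_counts[("h01", 0)]
        assert single == h0 + h1
        assert double == h0 + h0


class TestReads:
    def test_coverage_calibration(self, small_truth, small_db):
        """Panel k-mer counts match 2x coverage up to the read-edge factor.

        A read of length L contains L-k+1 windows, so k-mer depth is
        coverage * (L-k+1)/L; the panel median must sit within 10% of it.
        """
        from pacn.genotype import count_sample_kmers

        cfg = small_truth.cfg
        reads, _ = simulate_sample(small_truth, ("h00", "h01"), seed=13)
        counts = count_sample_kmers(reads, small_db.lookup())
        k = small_db.config.k
        factor = (cfg.read_length_bp - k + 1) / cfg.read_length_bp
        expected = 2 * cfg.coverage * factor
        assert np.median(counts.panel_counts) == pytest.approx(expected, rel=0.1)

    def test_empty_read_request(self, small_truth, tmp_path):
        cfg = SimConfig(**{**small_truth.cfg.__dict__, "coverage": 1e-9})
        path = tmp_path / "empty.fq"
        out, _ = simulate_sample(small_truth, ("h00", "h01"), cfg=cfg,
                                 seed=1, out_fastq=path)
        assert path.read_text() == ""

    def test_fastq_gzip_written(self, tmp_path):
        path = tmp_path / "r.fq.gz"
        write_fastq(["ACGT"], path)
        import gzip

        assert gzip.open(path, "rt").read() == "@read0\nACGT\n+\nIIII\n"


class TestMendelianTrio:
    def test_child_from_parental_pools(self, small_truth):
        f, m = ("h00", "h01"), ("h02", "h03")
        c1, c2 = mendelian_trio(small_truth, f, m, seed=11)
        assert c1 in f and c2 in m

    def test_no_de_novo_child_pacn_is_transmitted_sum(self, small_truth):
        f, m = ("h00", "h01"), ("h02", "h03")
        child = mendelian_trio(small_truth, f, m, seed=2)
        for fam in range(small_truth.cfg.n_families):
            expected = (small_truth.hap_allele_counts[(child[0], fam)]
                        + small_truth.hap_allele_counts[(child[1], fam)])
            assert small_truth.pacn(child, fam) == expected
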