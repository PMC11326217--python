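"""Projection, depth estimation, recursive rounding, model fit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pacn.evaluation import best_integer_solution, nnls_by_enumeration, random_projection_instance
from pacn.genotype import (
    CopyNumberModel,
    InsufficientCoverageError,
    estimate_depth,
    project_copy_numbers,
    recursive_round,
)
from pacn.matrix import KmerMatrix
from pacn.phylo import build_tree, pairwise_distance_matrix


def _km(M, ids=None):
    M = np.asarray(M)
    ids = ids or [f"p{i}" for i in range(M.shape[0])]
    return KmerMatrix("g", 21, ids, np.arange(M.shape[1], dtype=np.uint64),
                      M.astype(np.uint16))


class TestProjection:
    def test_identity_rows(self):
        c, r, _ = project_copy_numbers(_km([[1, 0], [0, 1]]), np.array([3.0, 2.0]))
        assert c == pytest.approx([3.0, 2.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_example_exact(self):
        # normal equations: MM' = [[5,1],[1,2]], Mv = (7,5) -> c = (1,2)
        c, r, _ = project_copy_numbers(_km([[2, 1, 0], [0, 1, 1]]), np.array([2.0, 3.0, 2.0]))
        assert c == pytest.approx([1.0, 2.0], abs=1e-10)

    def test_hand_example_noisy(self):
        # Mv = (7.1, 4.9) -> c = (9.3/9, 17.4/9)
        c, _, _ = project_copy_numbers(_km([[2, 1, 0], [0, 1, 1]]),
                                       np.array([2.1, 2.9, 2.0]))
        assert c == pytest.approx([1.0333333, 1.9333333], abs=1e-6)

    def test_all_zero_counts_absent_locus(self):
        c, r, _ = project_copy_numbers(_km([[2, 1, 0], [0, 1, 1]]), np.zeros(3))
        assert (c == 0).all() and r == 0.0

    def test_degenerate_flagged(self):
        _, _, deg = project_copy_numbers(_km([[1, 1], [1, 1]]), np.array([2.0, 2.0]))
        assert deg

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            M, _, v = random_projection_instance(rng)
            c, r, _ = project_copy_numbers(_km(M), v)
            _, r_oracle = nnls_by_enumeration(M, v)
            assert r == pytest.approx(r_oracle, rel=1e-6, abs=1e-9)


class TestDepth:
    def test_definition(self):
        assert estimate_depth(np.full(100, 60)) == 30.0

    def test_override_wins(self):
        assert estimate_depth(np.full(100, 60), depth_override=25) == 25.0

    def test_poisson_panel_within_5pct(self, rng):
        counts = rng.poisson(60, size=1000)
        assert estimate_depth(counts) == pytest.approx(30.0, rel=0.05)

    def test_zero_coverage_aborts(self):
        with pytest.raises(InsufficientCoverageError):
            estimate_depth(np.zeros(100))


class TestRecursiveRound:
    def _tree(self, M, ids):
        return build_tree(pairwise_distance_matrix(np.asarray(M)), ids)

    def test_integral_passthrough(self):
        ids = ["A", "B", "C"]
        t = self._tree([[2, 0, 0], [0, 2, 0], [0, 0, 2]], ids)
        assert recursive_round(t, np.array([2.0, 0.0, 1.0]), ids).tolist() == [2, 0, 1]

    def test_worked_example(self):
        # ((A,B),C): clade sums (2.0, 1.2) -> (2,1); within (A,B) -> (1,1)
        from pacn.phylo import PhyloTree, TreeNode

        root = TreeNode(children=[
            TreeNode(children=[TreeNode("A", 0.1), TreeNode("B", 0.1)], length=0.1),
            TreeNode("C", 0.2),
        ])
        t = PhyloTree("g", root)
        out = recursive_round(t, np.array([1.4, 0.6, 1.2]), ["A", "B", "C"])
        assert out.tolist() == [1, 1, 1]

    def test_half_split_tie_goes_to_tree_order(self):
        from pacn.phylo import PhyloTree, TreeNode

        t = PhyloTree("g", TreeNode(children=[TreeNode("A", 0.1), TreeNode("B", 0.1)]))
        assert recursive_round(t, np.array([0.5, 0.5]), ["A", "B"]).tolist() == [1, 0]

    def test_negative_entries_clamped(self):
        from pacn.phylo import PhyloTree, TreeNode

        t = PhyloTree("g", TreeNode(children=[TreeNode("A", 0.1), TreeNode("B", 0.1)]))
        out = recursive_round(t, np.array([-0.4, 2.1]), ["A", "B"])
        assert out.tolist() == [0, 2]

    @given(st.integers(0, 10_000))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        M, _, v = random_projection_instance(rng)
        ids = [f"p{i}" for i in range(M.shape[0])]
        t = self._tree(M, ids)
        c = np.maximum(rng.normal(1.0, 0.8, M.shape[0]), -0.2)
        out = recursive_round(t, c, ids)
        assert (out >= 0).all()
        assert out.sum() == int(np.floor(np.maximum(c, 0).sum() + 0.5))

    def test_near_oracle_on_random_instances(self, rng):
        ok = 0
        n = 100
        for _ in range(n):
            M, _, v = random_projection_instance(rng)
            ids = [f"p{i}" for i in range(M.shape[0])]
            km = _km(M, ids)
            c, _, _ = project_copy_numbers(km, v)
            t = self._tree(M, ids)
            pacn = recursive_round(t, c, ids)
            r_int = np.linalg.norm(M.T @ pacn - v)
            _, r_best = best_integer_solution(M, v)
            if r_int <= 1.1 * r_best + 1e-9:
                ok += 1
        assert ok >= 0.95 * n


class TestModelFit:
    def test_residual_ordering_and_conservation(self, rng):
        for _ in range(20):
            M, _, v = random_projection_instance(rng)
            model = CopyNumberModel(_km(M))
            res = model.fit(v, normalized=True)
            assert res.residual_integer >= res.residual_fractional - 1e-9
            assert res.subgroup_cn.sum() == res.pacn.sum() == res.total_cn

    def test_depth_invariance(self, rng):
        M, c_true, _ = random_projection_instance(rng, noise_sd=0.0)
        model = CopyNumberModel(_km(M))
        v = M.T @ c_true
        base = model.fit(v * 30, depth=30)
        for lam in (0.5, 2, 7):
            scaled = model.fit(v * 30 * lam, depth=30 * lam)
            assert (scaled.pacn == base.pacn).all()
        assert (base.pacn.to_numpy() == c_true).all()

    def test_summary_renders(self, rng):
        M, _, v = random_projection_instance(rng)
        res = CopyNumberModel(_km(M)).fit(v, normalized=True)
        text = res.summary()
        assert "total copy number" in text and "paCN" in text


class TestCounting:
    def test_single_pa_readthrough_identity(self, small_truth, small_db):
        from pacn.genotype import count_sample_kmers

        g = small_db.groups[0]
        pid = g.matrix.pa_ids[0]
        seq = small_db.pas[pid].sequence
        counts = count_sample_kmers([seq], small_db.lookup())
        assert (counts.group_counts[g.group_id] == g.matrix.row(pid)).all()

    def test_empty_input_zero_vectors(self, small_db):
        from pacn.genotype import count_sample_kmers

        counts = count_sample_kmers([], small_db.lookup())
        assert all((v == 0).all() for v in counts.group_counts.values())

    def test_thirty_copies_scale_linearly(self, small_truth, small_db):
        from pacn.genotype import count_sample_kmers

        g = small_db.groups[0]
        pid = g.matrix.pa_ids[0]
        seq = small_db.pas[pid].sequence
        counts = count_sample_kmers([seq] * 30, small_db.lookup())
        assert (counts.group_counts[g.group_id] == 30 * g.matrix.row(pid).astype(np.int64)).all()

    def test_fastq_files_gzip_round_trip(self, tmp_path, small_truth, small_db):
        from pacn.genotype import count_sample_kmers
        from pacn.simulate import write_fastq

        g = small_db.groups[0]
        pid = g.matrix.pa_ids[0]
        seq = small_db.pas[pid].sequence
        path = tmp_path / "reads.fq.gz"
        write_fastq([seq, seq], path)
        counts = count_sample_kmers([path], small_db.lookup(), from_files=True)
        assert (counts.group_counts[g.group_id] == 2 * g.matrix.row(pid).astype(np.int64)).all()
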