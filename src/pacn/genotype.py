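"""Copy-number genotyping of an NGS sample against k-mer matrices.

The observation model: a sample's genome is an unknown non-negative integer
combination c of the matrix rows (alleles).  Counting the matrix k-mers in
the reads and dividing by haploid sequencing depth d gives a vector ṽ whose
expectation is Mᵀc.  Genotyping solves

    c* = argmin_{c >= 0} || Mᵀ c − ṽ ||²          (non-negative least squares)

and then converts c* to integers by recursive rounding on the phylogenetic
tree: the root receives budget T = round(Σ c*), and at every internal node
the budget is apportioned to child clades by largest-remainder allocation
of their fractional clade sums, down to the leaves.  Allocating along the
tree keeps copies within the clade they came from, so mass moved during
rounding shifts between near-identical alleles rather than distant ones.

`CopyNumberModel` / `CopyNumberResults` expose this as a fit/results pair;
`genotype_matrix` is the one-call functional form.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .kmers import window_codes
from .matrix import KmerMatrix
from .phylo import (
    PhyloTree,
    SubgroupPartition,
    build_tree,
    define_subgroups,
    pairwise_distance_matrix,
)

log = logging.getLogger(__name__)

__all__ = [
    "CopyNumberModel",
    "CopyNumberResults",
    "GenotypeCall",
    "InsufficientCoverageError",
    "KmerLookup",
    "SampleKmerCounts",
    "count_sample_kmers",
    "estimate_depth",
    "genotype_matrix",
    "iter_read_sequences",
    "project_copy_numbers",
    "recursive_round",
]


class InsufficientCoverageError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# k-mer counting in reads


class KmerLookup:
    """Single-pass lookup from canonical k-mer code to (group, column).

    Built once from all matrices plus the single-copy depth panel; k-mers
    claimed by more than one group are ambiguous and must be removed before
    construction (the database builder guarantees this).
    """

    def __init__(self, matrices: Sequence[KmerMatrix], panel: np.ndarray) -> None:
        ks = {m.k for m in matrices}
        if len(ks) > 1:
            raise ValueError(f"matrices disagree on k: {sorted(ks)}")
        self.k = ks.pop() if ks else None
        self.group_ids = [m.group_id for m in matrices]
        self.shapes = {m.group_id: m.shape[1] for m in matrices}
        codes = [m.kmers for m in matrices]
        gidx = [np.full(m.kmers.size, gi, dtype=np.int32) for gi, m in enumerate(matrices)]
        cidx = [np.arange(m.kmers.size, dtype=np.int32) for m in matrices]
        allc = np.concatenate(codes) if codes else np.empty(0, dtype=np.uint64)
        order = np.argsort(allc, kind="stable")
        self.codes = allc[order]
        if self.codes.size and (np.diff(self.codes) == 0).any():
            raise ValueError("k-mer claimed by more than one group/column")
        self.gidx = (np.concatenate(gidx) if gidx else np.empty(0, np.int32))[order]
        self.cidx = (np.concatenate(cidx) if cidx else np.empty(0, np.int32))[order]
        self.panel = np.asarray(panel, dtype=np.uint64)
        # flat output slot per code: group offset + column
        sizes = [self.shapes[g] for g in self.group_ids]
        self.offsets = np.concatenate(([0], np.cumsum(sizes))).astype(np.int64)
        self.flat = self.offsets[self.gidx] + self.cidx

    def count_sequences(self, seqs: Iterable[str], chunk_bases: int = 4_000_000):
        """Count canonical k-mers of ``seqs`` into per-group vectors.

        Sequences are joined with N separators and processed in chunks, so
        reads never produce windows spanning read boundaries.
        """
        if self.k is None:
            raise ValueError("empty lookup")
        total = int(self.offsets[-1]) if len(self.offsets) else 0
        flat_counts = np.zeros(total, dtype=np.int64)
        panel_counts = np.zeros(self.panel.size, dtype=np.int64)
        buf: list[str] = []
        size = 0

        def flush() -> None:
            nonlocal buf, size, flat_counts, panel_counts
            if not buf:
                return
            codes = window_codes("N".join(buf), self.k)
            buf, size = [], 0
            if codes.size == 0:
                return
            idx = np.searchsorted(self.codes, codes)
            ok = idx < self.codes.size
            ok[ok] = self.codes[idx[ok]] == codes[ok]
            hit = idx[ok]
            if hit.size:
                flat_counts += np.bincount(self.flat[hit], minlength=total)
            if self.panel.size:
                pidx = np.searchsorted(self.panel, codes)
                pok = pidx < self.panel.size
                pok[pok] = self.panel[pidx[pok]] == codes[pok]
                if pok.any():
                    panel_counts += np.bincount(pidx[pok], minlength=self.panel.size)

        for s in seqs:
            buf.append(s)
            size += len(s)
            if size >= chunk_bases:
                flush()
        flush()
        vecs = {
            g: flat_counts[self.offsets[gi] : self.offsets[gi + 1]].copy()
            for gi, g in enumerate(self.group_ids)
        }
        return vecs, panel_counts


@dataclass
class SampleKmerCounts:
    """Raw per-matrix k-mer counts of one sample plus depth-panel counts."""

    group_counts: dict[str, np.ndarray]
    panel_counts: np.ndarray
    depth: float | None = None

    def normalized(self, group_id: str) -> np.ndarray:
        if self.depth is None or self.depth <= 0:
            raise InsufficientCoverageError("depth not set")
        return self.group_counts[group_id] / self.depth


def iter_read_sequences(paths: Sequence[str | Path]) -> Iterable[str]:
    """Stream read sequences from FASTQ files (gzip transparent)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    for path in paths:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                yield seq


def count_sample_kmers(
    reads: Iterable[str] | Sequence[str | Path],
    lookup: KmerLookup,
    from_files: bool = False,
) -> SampleKmerCounts:
    """One pass over the reads, emitting per-matrix raw count vectors."""
    seqs = iter_read_sequences(reads) if from_files else reads
    vecs, panel = lookup.count_sequences(seqs)
    return SampleKmerCounts(group_counts=vecs, panel_counts=panel)


def estimate_depth(
    panel_counts: np.ndarray,
    ploidy: int = 2,
    depth_override: float | None = None,
) -> float:
    """Haploid sequencing depth from single-copy panel k-mer counts.

    d = median(panel counts) / ploidy: the expected count of one copy of a
    k-mer.  The median is robust to the occasional repetitive or dropped
    panel k-mer.  An explicit ``depth_override`` wins.
    """
    if depth_override is not None:
        if depth_override <= 0:
            raise ValueError("depth override must be > 0")
        return float(depth_override)
    if len(panel_counts) == 0:
        raise InsufficientCoverageError("empty depth panel")
    med = float(np.median(panel_counts))
    if med <= 0:
        raise InsufficientCoverageError("insufficient coverage: panel median is 0")
    return med / ploidy


# ---------------------------------------------------------------------------
# projection and rounding


def project_copy_numbers(matrix: KmerMatrix, v_norm: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Fractional copy numbers: NNLS of Mᵀc against normalized counts.

    Returns (c*, residual norm, degenerate flag).  Degeneracy means M is
    row-rank deficient (e.g. duplicated alleles), in which case individual
    entries of c* are not identifiable even though clade sums are.
    """
    M = matrix.M.astype(np.float64)
    v = np.asarray(v_norm, dtype=np.float64)
    if v.shape != (M.shape[1],):
        raise ValueError(f"count vector has shape {v.shape}, expected ({M.shape[1]},)")
    if not v.any():
        return np.zeros(M.shape[0]), 0.0, False
    c, rnorm = nnls(M.T, v)
    degenerate = np.linalg.matrix_rank(M) < M.shape[0]
    return c, float(rnorm), degenerate


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def recursive_round(tree: PhyloTree, cstar: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Integer copy numbers by largest-remainder allocation down the tree.

    The root budget is T = round(Σ c*).  At each internal node the integer
    budget splits over children: each child clade starts at the floor of
    its fractional sum, and the leftover units go one at a time to the
    largest fractional remainders (ties to tree order).  Σ paCN = T always.
    Negative fractional entries are clamped to zero first (logged).
    """
    c = np.asarray(cstar, dtype=np.float64).copy()
    if (c < 0).any():
        log.info("clamping %d negative fractional entries to 0", int((c < 0).sum()))
        c = np.maximum(c, 0.0)
    pos = {pid: i for i, pid in enumerate(ids)}
    leaf_order = tree.leaf_names()
    if sorted(leaf_order) != sorted(ids):
        raise ValueError("tree leaves do not match copy-number entries")
    out = np.zeros(len(ids), dtype=np.int64)

    def clade_sum(node) -> float:
        if node.is_leaf:
            return c[pos[node.name]]
        return sum(clade_sum(ch) for ch in node.children)

    def allocate(node, budget: int) -> None:
        if node.is_leaf:
            out[pos[node.name]] = budget
            return
        sums = [clade_sum(ch) for ch in node.children]
        alloc = [int(math.floor(s)) for s in sums]
        diff = budget - sum(alloc)
        while diff > 0:
            rem = [s - a for s, a in zip(sums, alloc)]
            j = max(range(len(rem)), key=lambda i: (rem[i], -i))
            alloc[j] += 1
            diff -= 1
        while diff < 0:
            rem = [s - a if a > 0 else np.inf for s, a in zip(sums, alloc)]
            j = min(range(len(rem)), key=lambda i: (rem[i], i))
            alloc[j] -= 1
            diff += 1
        for ch, a in zip(node.children, alloc):
            allocate(ch, a)

    allocate(tree.root, _round_half_up(float(c.sum())))
    return out


# ---------------------------------------------------------------------------
# model / results


@dataclass
class CopyNumberResults:
    """Fitted copy numbers for one matrix and one sample."""

    group_id: str
    pa_ids: list[str]
    fractional: pd.Series  # c* per allele row
    pacn: pd.Series  # integer copy number per allele row
    residual_fractional: float
    residual_integer: float
    subgroup_cn: pd.Series
    aggregate_cn: pd.Series  # per reference gene
    degenerate: bool
    status: str = "ok"

    @property
    def total_cn(self) -> int:
        return int(self.pacn.sum())

    def summary(self) -> str:
        lines = [
            f"Copy-number genotype: group {self.group_id}  (status: {self.status})",
            f"  residual ||M'c - v||: fractional {self.residual_fractional:.4f}, "
            f"integer {self.residual_integer:.4f}",
            f"  total copy number: {self.total_cn}"
            + ("  [degenerate rows: subgroup CN only]" if self.degenerate else ""),
            "",
            f"  {'allele':<30}{'subgroup':<10}{'c*':>8}{'paCN':>6}",
        ]
        sg = self.subgroup_of
        for pid in self.pa_ids:
            lines.append(
                f"  {pid:<30}{sg.get(pid, '-'):<10}"
                f"{self.fractional[pid]:>8.3f}{int(self.pacn[pid]):>6}"
            )
        if len(self.aggregate_cn):
            lines.append("")
            lines.append("  aggregate CN per gene: " + ", ".join(
                f"{g}={int(v)}" for g, v in self.aggregate_cn.items()))
        return "\n".join(lines)

    # filled by the model
    subgroup_of: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_id": self.group_id,
                "pa_id": self.pa_ids,
                "subgroup_id": [self.subgroup_of.get(p, "") for p in self.pa_ids],
                "fractional": [float(self.fractional[p]) for p in self.pa_ids],
                "paCN": [int(self.pacn[p]) for p in self.pa_ids],
                "subgroup_CN": [
                    int(self.subgroup_cn.get(self.subgroup_of.get(p, ""), 0))
                    for p in self.pa_ids
                ],
                "residual": self.residual_integer,
                "status": self.status,
            }
        )


GenotypeCall = CopyNumberResults


class CopyNumberModel:
    """Least-squares copy-number model of one homology group.

    Parameters
    ----------
    matrix : KmerMatrix
        Group-exclusive k-mer multiplicities (rows = alleles).
    tree : PhyloTree, optional
        Phylogeny guiding integer rounding; rebuilt from weighted-Jaccard
        row distances when omitted.
    subgroups : SubgroupPartition, optional
        Near-identical allele states; one subgroup per row when omitted.
    gene_map : mapping pa_id -> {gene: copies}, optional
        Gene content per row, for aggregate CN per reference gene.
    """

    def __init__(
        self,
        matrix: KmerMatrix,
        tree: PhyloTree | None = None,
        subgroups: SubgroupPartition | None = None,
        gene_map: Mapping[str, Mapping[str, int]] | None = None,
    ) -> None:
        self.matrix = matrix
        self.distances = pairwise_distance_matrix(matrix.M)
        self.tree = tree if tree is not None else build_tree(
            self.distances, matrix.pa_ids, matrix.group_id
        )
        self.subgroups = subgroups if subgroups is not None else define_subgroups(
            self.tree, self.distances, matrix.pa_ids, 0.0
        )
        self.gene_map = {p: dict(g) for p, g in (gene_map or {}).items()}

    def fit(
        self,
        counts: np.ndarray,
        depth: float | None = None,
        normalized: bool = False,
    ) -> CopyNumberResults:
        """Fit copy numbers from raw counts + depth, or normalized counts."""
        counts = np.asarray(counts, dtype=np.float64)
        if normalized:
            v = counts
        else:
            if depth is None or depth <= 0:
                raise ValueError("raw counts require depth > 0")
            v = counts / depth
        mat = self.matrix
        if mat.shape[1] == 0:
            return self._empty_call("unsolvable")
        c, res_frac, degenerate = project_copy_numbers(mat, v)
        pacn = recursive_round(self.tree, c, mat.pa_ids)
        Mf = mat.M.astype(np.float64)
        res_int = float(np.linalg.norm(Mf.T @ pacn - v))
        frac = pd.Series(c, index=mat.pa_ids, dtype=float)
        pacn_s = pd.Series(pacn, index=mat.pa_ids, dtype=int)
        sg_cn: dict[str, int] = {}
        for pid, sid in self.subgroups.assignment.items():
            sg_cn[sid] = sg_cn.get(sid, 0) + int(pacn_s[pid])
        agg: dict[str, int] = {}
        for pid in mat.pa_ids:
            for gene, copies in self.gene_map.get(pid, {}).items():
                agg[gene] = agg.get(gene, 0) + copies * int(pacn_s[pid])
        res = CopyNumberResults(
            group_id=mat.group_id,
            pa_ids=list(mat.pa_ids),
            fractional=frac,
            pacn=pacn_s,
            residual_fractional=res_frac,
            residual_integer=res_int,
            subgroup_cn=pd.Series(sg_cn, dtype=int).sort_index(),
            aggregate_cn=pd.Series(agg, dtype=int).sort_index(),
            degenerate=degenerate or bool(mat.degenerate_rows),
        )
        res.subgroup_of = dict(self.subgroups.assignment)
        return res

    def _empty_call(self, status: str) -> CopyNumberResults:
        ids = self.matrix.pa_ids
        zero = pd.Series(np.zeros(len(ids)), index=ids)
        res = CopyNumberResults(
            group_id=self.matrix.group_id,
            pa_ids=list(ids),
            fractional=zero.astype(float),
            pacn=zero.astype(int),
            residual_fractional=float("nan"),
            residual_integer=float("nan"),
            subgroup_cn=pd.Series(dtype=int),
            aggregate_cn=pd.Series(dtype=int),
            degenerate=False,
            status=status,
        )
        res.subgroup_of = dict(self.subgroups.assignment)
        return res


def genotype_matrix(
    matrix: KmerMatrix,
    tree: PhyloTree | None,
    subgroups: SubgroupPartition | None,
    v_norm: np.ndarray,
    gene_map: Mapping[str, Mapping[str, int]] | None = None,
) -> CopyNumberResults:
    """Project -> round -> aggregate, as a single call."""
    model = CopyNumberModel(matrix, tree=tree, subgroups=subgroups, gene_map=gene_map)
    return model.fit(v_norm, normalized=True)
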