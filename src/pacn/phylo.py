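"""Per-matrix phylogenies, highly similar subgroups, and major groups.

Distances between matrix rows are weighted Jaccard on k-mer multiplicity
vectors; trees are neighbor-joining with midpoint rooting (scikit-bio
underneath, re-expressed as a lightweight rooted node structure that the
genotyper's recursive rounding walks).  Subgroups are the deepest clades
whose maximal intra-clade distance stays below a threshold; major groups
are single-linkage unions of subgroups with no structural variant larger
than ``sv_size_bp`` (default 300 bp) between members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PhyloTree",
    "SubgroupPartition",
    "TreeNode",
    "build_tree",
    "define_major_groups",
    "define_subgroups",
    "pairwise_distance_matrix",
    "pairwise_kmer_distance",
]


def pairwise_kmer_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Weighted Jaccard distance 1 - sum(min)/sum(max) between profiles.

    Bounded in [0, 1], zero iff equal; two all-zero rows are undefined and
    reported as 1 with a warning.
    """
    a = np.asarray(row_a, dtype=np.float64)
    b = np.asarray(row_b, dtype=np.float64)
    denom = np.maximum(a, b).sum()
    if denom == 0:
        warnings.warn("distance between two all-zero rows is undefined; reporting 1")
        return 1.0
    return float(1.0 - np.minimum(a, b).sum() / denom)


def pairwise_distance_matrix(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=np.float64)
    n = M.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(M[i], M[i + 1 :]).sum(axis=1)
        maxs = np.maximum(M[i], M[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = 1.0 - np.where(maxs > 0, mins / np.where(maxs > 0, maxs, 1.0), 0.0)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return D


@dataclass
class TreeNode:
    """Rooted tree node; leaves carry allele ids."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6g}"

        return fmt(self).rsplit(":", 1)[0] + ";"


@dataclass
class PhyloTree:
    group_id: str
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def newick(self) -> str:
        return self.root.newick()


def _from_skbio(node) -> TreeNode:
    length = float(node.length) if node.length is not None else 0.0
    out = TreeNode(name=node.name, length=max(0.0, length))
    for child in node.children:
        out.children.append(_from_skbio(child))
    return out


def build_tree(distances: np.ndarray, ids: Sequence[str], group_id: str = "") -> PhyloTree:
    """Neighbor-joining tree over matrix rows, midpoint rooted.

    Distances must be symmetric with zero diagonal.  Negative NJ branch
    lengths are clamped to zero; ties resolve deterministically by row
    order.  One or two leaves degenerate to trivial trees.
    """
    D = np.asarray(distances, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.abs(np.diag(D)).max(initial=0) > 0:
        raise ValueError("distances must be a symmetric, zero-diagonal matrix")
    ids = list(ids)
    if n == 0:
        raise ValueError("no leaves")
    if n == 1:
        return PhyloTree(group_id, TreeNode(name=ids[0]))
    if n == 2:
        half = D[0, 1] / 2.0
        root = TreeNode(children=[TreeNode(ids[0], half), TreeNode(ids[1], half)])
        return PhyloTree(group_id, root)
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix((D + D.T) / 2.0, ids)
    tree = nj(dm)
    tree = tree.root_at_midpoint()
    return PhyloTree(group_id, _from_skbio(tree))


@dataclass
class SubgroupPartition:
    """Clade-refined partition of matrix rows into near-identical states."""

    assignment: dict[str, str]  # pa_id -> subgroup_id
    representative: dict[str, str]  # subgroup_id -> representative pa_id
    threshold: float

    def subgroup_ids(self) -> list[str]:
        return sorted(self.representative)

    def members(self, subgroup_id: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == subgroup_id]


def define_subgroups(
    tree: PhyloTree,
    distances: np.ndarray,
    ids: Sequence[str],
    max_intra_distance: float = 0.05,
) -> SubgroupPartition:
    """Deepest clades whose max intra-clade distance <= threshold.

    Threshold 0 keeps one subgroup per distinct row; a threshold at or
    above the tree's diameter collapses everything into one subgroup.
    Representatives are clade medoids (ties to tree order).
    """
    if max_intra_distance < 0:
        raise ValueError("max_intra_distance must be >= 0")
    idx = {pid: i for i, pid in enumerate(ids)}
    D = np.asarray(distances, dtype=np.float64)

    def max_intra(leafset: list[str]) -> float:
        ii = [idx[p] for p in leafset]
        return float(D[np.ix_(ii, ii)].max(initial=0.0))

    clades: list[list[str]] = []

    def walk(node: TreeNode) -> None:
        leafset = node.leaf_names()
        if max_intra(leafset) <= max_intra_distance:
            clades.append(leafset)
        else:
            for c in node.children:
                walk(c)

    walk(tree.root)
    assignment: dict[str, str] = {}
    representative: dict[str, str] = {}
    for si, leafset in enumerate(clades):
        sid = f"sg{si:03d}"
        ii = [idx[p] for p in leafset]
        sub = D[np.ix_(ii, ii)]
        med = int(np.argmin(sub.sum(axis=1)))
        representative[sid] = leafset[med]
        for p in leafset:
            assignment[p] = sid
    return SubgroupPartition(assignment, representative, max_intra_distance)


def define_major_groups(
    subgroups: SubgroupPartition,
    gap_profiles: Mapping[tuple[str, str], float],
    sv_size_bp: int = 300,
) -> dict[str, str]:
    """Single-linkage unions of subgroups devoid of SVs > ``sv_size_bp``.

    ``gap_profiles`` maps subgroup-representative pairs (either order) to
    the largest indel between them, in bp.  Missing pairs are treated as
    SV-containing (conservative split) with a warning.  Chains merge
    transitively, a documented consequence of single linkage.
    Returns subgroup_id -> major_group_id.
    """
    sids = subgroups.subgroup_ids()
    parent = {s: s for s in sids}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for i, a in enumerate(sids):
        for b in sids[i + 1 :]:
            ra, rb = subgroups.representative[a], subgroups.representative[b]
            gap = gap_profiles.get((ra, rb), gap_profiles.get((rb, ra)))
            if gap is None:
                warnings.warn(f"no gap profile for ({ra}, {rb}); treating as SV-containing")
                continue
            if gap <= sv_size_bp:
                pa, pb = find(a), find(b)
                if pa != pb:
                    parent[max(pa, pb)] = min(pa, pb)
    roots = sorted({find(s) for s in sids})
    rename = {r: f"mg{mi:03d}" for mi, r in enumerate(roots)}
    return {s: rename[find(s)] for s in sids}
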