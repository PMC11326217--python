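"""End-to-end orchestration: assemblies -> database -> genotypes.

``build_database`` runs extraction, grouping, background masking, matrix
construction, tree building and subgroup definition for every homology
group, and assembles the single-copy depth panel.  ``genotype_sample``
counts a sample's reads once and fits the copy-number model of every
group.  A database round-trips through a plain-text directory layout
(FASTA + TSV + newick).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alleles import (
    DEFAULT_FLANK,
    DEFAULT_MERGE_GAP,
    DEFAULT_MIN_LEN,
    ExonRecord,
    PAllele,
    extract_pa_intervals,
    extract_pas,
    filter_low_confidence,
    group_homologous_pas,
)
from .genotype import (
    CopyNumberModel,
    KmerLookup,
    SampleKmerCounts,
    count_sample_kmers,
    estimate_depth,
)
from .kmers import decode_kmer, encode_kmer
from .matrix import (
    BackgroundIndex,
    KmerMatrix,
    UnsolvableGroupError,
    build_depth_panel,
    build_matrix,
    read_matrix,
    select_informative_kmers,
    write_matrix,
)
from .phylo import (
    PhyloTree,
    SubgroupPartition,
    build_tree,
    define_subgroups,
    pairwise_distance_matrix,
)

log = logging.getLogger(__name__)

__all__ = ["Database", "DatabaseConfig", "GroupBundle", "build_database",
           "drop_haplotype", "genotype_sample", "load_database", "save_database"]


@dataclass(frozen=True)
class DatabaseConfig:
    """Tunable knobs of database construction.

    Production-scale defaults follow the allele definition (20 kb exon
    merge gap, 5 kb anchors, 15 kb minimum allele, k = 31, strict
    background exclusion); desk-scale runs shrink the length parameters
    together with the simulated genes.
    """

    k: int = 31
    merge_gap_bp: int = DEFAULT_MERGE_GAP
    flank_bp: int = DEFAULT_FLANK
    min_len_bp: int = DEFAULT_MIN_LEN
    grouping_similarity: float = 0.2
    max_background_count: int = 0
    subgroup_max_intra: float = 0.05
    max_n_frac: float = 0.05
    min_nonrepeat_bp: int = 1_000
    panel_max: int = 5_000
    collapse_identical: bool = True


@dataclass
class GroupBundle:
    """Everything the genotyper needs for one homology group."""

    group_id: str
    matrix: KmerMatrix
    tree: PhyloTree
    subgroups: SubgroupPartition
    gene_map: dict[str, dict[str, int]]
    status: str = "ok"

    def model(self) -> CopyNumberModel:
        return CopyNumberModel(self.matrix, self.tree, self.subgroups, self.gene_map)


@dataclass
class Database:
    config: DatabaseConfig
    groups: list[GroupBundle]
    panel: np.ndarray
    pas: dict[str, PAllele] = field(default_factory=dict)
    unsolvable: list[str] = field(default_factory=list)
    _lookup: KmerLookup | None = None

    def lookup(self) -> KmerLookup:
        if self._lookup is None:
            self._lookup = KmerLookup([g.matrix for g in self.groups], self.panel)
        return self._lookup

    def group(self, group_id: str) -> GroupBundle:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)


def _gene_counter(pa: PAllele) -> dict[str, int]:
    return dict(Counter(g for g, _s, _e in pa.gene_intervals) or Counter(pa.gene_labels))


def _build_group(
    group_id: str,
    members: list[PAllele],
    background: BackgroundIndex,
    cfg: DatabaseConfig,
) -> tuple[list[PAllele], np.ndarray, int, dict[str, list[str]]] | None:
    reps: list[PAllele] = members
    row_members: dict[str, list[str]] = {m.id: [m.id] for m in members}
    if cfg.collapse_identical:
        by_seq: dict[str, PAllele] = {}
        row_members = {}
        for m in sorted(members, key=lambda p: p.id):
            if m.sequence in by_seq:
                row_members[by_seq[m.sequence].id].append(m.id)
            else:
                by_seq[m.sequence] = m
                row_members[m.id] = [m.id]
        reps = sorted(by_seq.values(), key=lambda p: p.id)
    try:
        kmers, excluded = select_informative_kmers(
            reps, background, cfg.k, cfg.max_background_count
        )
    except UnsolvableGroupError as exc:
        log.warning("%s unsolvable: %s", group_id, exc)
        return None
    return reps, kmers, excluded, row_members


def build_database(
    assemblies: Mapping[str, Mapping[str, str]],
    exons: Iterable[ExonRecord],
    config: DatabaseConfig | None = None,
    repeat_mask: Mapping[tuple[str, str], Sequence[tuple[int, int]]] | None = None,
) -> Database:
    cfg = config or DatabaseConfig()
    contig_lengths = {
        (hap, contig): len(seq)
        for hap, contigs in assemblies.items()
        for contig, seq in contigs.items()
    }
    intervals = extract_pa_intervals(
        exons, contig_lengths, cfg.merge_gap_bp, cfg.flank_bp, cfg.min_len_bp
    )
    pas = extract_pas(assemblies, intervals, cfg.flank_bp)
    pas, dropped = filter_low_confidence(pas, cfg.max_n_frac, cfg.min_nonrepeat_bp, repeat_mask)
    if dropped:
        log.info("dropped %d low-confidence alleles", len(dropped))
    groups = group_homologous_pas(pas, cfg.k, cfg.grouping_similarity, prefilter=True)
    pa_by_id = {p.id: p for p in pas}
    mask: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for p in pas:
        mask.setdefault((p.haplotype_id, p.contig), []).append((p.start, p.end))
    background = BackgroundIndex.from_assemblies(assemblies, mask, cfg.k)
    panel = build_depth_panel(assemblies, mask, cfg.k, cfg.panel_max)

    prepared = []
    unsolvable = []
    for hg in groups:
        members = [pa_by_id[m] for m in hg.members]
        built = _build_group(hg.group_id, members, background, cfg)
        if built is None:
            unsolvable.append(hg.group_id)
        else:
            prepared.append((hg.group_id, *built))

    # enforce cross-group exclusivity: a k-mer claimed by two groups is
    # ambiguous in a single-pass counter and is dropped from both
    if prepared:
        allk = np.concatenate([p[2] for p in prepared])
        uniq, counts = np.unique(allk, return_counts=True)
        shared = uniq[counts > 1]
    else:
        shared = np.empty(0, dtype=np.uint64)

    bundles = []
    for group_id, reps, kmers, excluded, row_members in prepared:
        if shared.size:
            keep = ~np.isin(kmers, shared)
            excluded += int((~keep).sum())
            kmers = kmers[keep]
        if kmers.size == 0:
            log.warning("%s unsolvable after cross-group exclusion", group_id)
            unsolvable.append(group_id)
            continue
        mat = build_matrix(group_id, reps, kmers, cfg.k, excluded)
        mat.row_members = row_members
        D = pairwise_distance_matrix(mat.M)
        tree = build_tree(D, mat.pa_ids, group_id)
        subgroups = define_subgroups(tree, D, mat.pa_ids, cfg.subgroup_max_intra)
        gene_map = {p.id: _gene_counter(p) for p in reps}
        bundles.append(GroupBundle(group_id, mat, tree, subgroups, gene_map))
    return Database(cfg, bundles, panel, pa_by_id, unsolvable)


def genotype_sample(
    db: Database,
    reads: Iterable[str] | Sequence[str | Path],
    from_files: bool = False,
    depth: float | None = None,
) -> tuple[pd.DataFrame, SampleKmerCounts]:
    """Count reads once, then fit every group's copy-number model.

    Returns the genotype table (one row per allele) and the raw counts.
    """
    counts = count_sample_kmers(reads, db.lookup(), from_files=from_files)
    counts.depth = estimate_depth(counts.panel_counts, depth_override=depth)
    frames = []
    for g in db.groups:
        res = g.model().fit(counts.group_counts[g.group_id], depth=counts.depth)
        frame = res.to_frame()
        gene_col, agg_col = [], []
        for pid in res.pa_ids:
            genes = sorted(g.gene_map.get(pid, {}))
            gene = genes[0] if genes else ""
            gene_col.append(gene)
            agg_col.append(int(res.aggregate_cn.get(gene, 0)) if gene else 0)
        frame["gene"] = gene_col
        frame["aggregate_CN"] = agg_col
        frames.append(frame)
    cols = ["group_id", "pa_id", "subgroup_id", "fractional", "paCN",
            "subgroup_CN", "gene", "aggregate_CN", "residual", "status"]
    table = pd.concat(frames, ignore_index=True)[cols] if frames else pd.DataFrame(columns=cols)
    return table, counts


def drop_haplotype(db: Database, bundle: GroupBundle, haplotype: str) -> GroupBundle | None:
    """Rebuild a group without one haplotype's alleles (leave-one-out).

    Rows contributed only by ``haplotype`` disappear; shared rows lose that
    member.  Columns are re-derived from the remaining rows.  Returns None
    when nothing remains.
    """
    keep_reps: list[PAllele] = []
    row_members: dict[str, list[str]] = {}
    for pid in bundle.matrix.pa_ids:
        members = [m for m in bundle.matrix.row_members.get(pid, [pid])
                   if db.pas[m].haplotype_id != haplotype]
        if not members:
            continue
        rep = db.pas[members[0]]
        keep_reps.append(rep)
        row_members[rep.id] = members
    if not keep_reps:
        return None
    # restrict to the original column space so exclusivity is preserved
    from .kmers import window_codes

    cand = np.unique(np.concatenate([window_codes(p.sequence, bundle.matrix.k)
                                     for p in keep_reps]))
    kmers = cand[np.isin(cand, bundle.matrix.kmers)]
    if kmers.size == 0:
        return None
    mat = build_matrix(bundle.group_id, keep_reps, kmers, bundle.matrix.k,
                       bundle.matrix.background_excluded)
    mat.row_members = row_members
    D = pairwise_distance_matrix(mat.M)
    tree = build_tree(D, mat.pa_ids, bundle.group_id)
    subgroups = define_subgroups(tree, D, mat.pa_ids, db.config.subgroup_max_intra)
    gene_map = {p.id: _gene_counter(p) for p in keep_reps}
    return GroupBundle(bundle.group_id, mat, tree, subgroups, gene_map)


# ---------------------------------------------------------------------------
# directory serialization


def save_database(db: Database, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(db.config), fh)
    with open(outdir / "panel.tsv", "w") as fh:
        fh.write("kmer\n")
        for code in db.panel:
            fh.write(decode_kmer(int(code), db.config.k) + "\n")
    rows = []
    for g in db.groups:
        rows.append({"group_id": g.group_id, "status": g.status,
                     "n_rows": g.matrix.shape[0], "n_cols": g.matrix.shape[1]})
        write_matrix(g.matrix, outdir)
        with open(outdir / f"{g.group_id}.nwk", "w") as fh:
            fh.write(g.tree.newick() + "\n")
        with open(outdir / f"{g.group_id}.subgroups.tsv", "w") as fh:
            fh.write("pa_id\tsubgroup_id\trepresentative\n")
            rep_of = {s: r for s, r in g.subgroups.representative.items()}
            for pid, sid in sorted(g.subgroups.assignment.items()):
                fh.write(f"{pid}\t{sid}\t{rep_of[sid]}\n")
        with open(outdir / f"{g.group_id}.genes.tsv", "w") as fh:
            fh.write("pa_id\tgene\tcopies\n")
            for pid, genes in sorted(g.gene_map.items()):
                for gene, c in sorted(genes.items()):
                    fh.write(f"{pid}\t{gene}\t{c}\n")
    for gid in db.unsolvable:
        rows.append({"group_id": gid, "status": "unsolvable", "n_rows": 0, "n_cols": 0})
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)


def load_database(outdir: str | Path) -> Database:
    outdir = Path(outdir)
    with open(outdir / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    cfg = DatabaseConfig(**{k: v for k, v in raw.items()
                            if k in DatabaseConfig.__dataclass_fields__})
    panel_df = pd.read_csv(outdir / "panel.tsv", sep="\t")
    panel = np.asarray(sorted(encode_kmer(k) for k in panel_df["kmer"]), dtype=np.uint64)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")
    bundles = []
    unsolvable = []
    from skbio import TreeNode as SkbioTree

    from .phylo import _from_skbio

    for row in manifest.itertuples(index=False):
        gid = row.group_id
        if row.status == "unsolvable":
            unsolvable.append(gid)
            continue
        mat = read_matrix(outdir, gid)
        sk = SkbioTree.read(str(outdir / f"{gid}.nwk"), convert_underscores=False)
        tree = PhyloTree(gid, _from_skbio(sk))
        sub_df = pd.read_csv(outdir / f"{gid}.subgroups.tsv", sep="\t")
        assignment = dict(zip(sub_df["pa_id"], sub_df["subgroup_id"]))
        representative = dict(zip(sub_df["subgroup_id"], sub_df["representative"]))
        subgroups = SubgroupPartition(assignment, representative, cfg.subgroup_max_intra)
        gene_map: dict[str, dict[str, int]] = {}
        gdf = pd.read_csv(outdir / f"{gid}.genes.tsv", sep="\t")
        for r in gdf.itertuples(index=False):
            gene_map.setdefault(r.pa_id, {})[r.gene] = int(r.copies)
        bundles.append(GroupBundle(gid, mat, tree, subgroups, gene_map))
    return Database(cfg, bundles, panel, {}, unsolvable)
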