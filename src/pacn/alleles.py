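"""Pangenome-derived alleles (PAs) and homology grouping.

A PA is a haplotype segment covering a gene: consecutive exons separated by
less than a merge gap (default 20 kb) are merged into one interval, anchor
flanks (default 5 kb) are added on each side, and short intervals are padded
symmetrically up to a minimum size (default 15 kb) where the contig permits.
PAs from all haplotypes are then partitioned into homology groups — one
group per genotyping matrix — by single-linkage closure over canonical
k-mer containment, and annotated relative to the reference locus as
reference/alternative alleles or duplicative/diverged paralogs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kmers import kmer_set

log = logging.getLogger(__name__)

__all__ = [
    "ExonRecord",
    "HomologyGroup",
    "PAllele",
    "ParalogAnnotation",
    "classify_paralog",
    "containment",
    "extract_pa_intervals",
    "extract_pas",
    "filter_low_confidence",
    "group_homologous_pas",
    "paralog_class",
]

#: gap below which consecutive exons are merged into one allele interval
DEFAULT_MERGE_GAP = 20_000
#: anchor sequence added on each side of the merged exon span
DEFAULT_FLANK = 5_000
#: minimum allele length; shorter intervals are padded where possible
DEFAULT_MIN_LEN = 15_000
#: k-mer similarity separating duplicative from diverged paralogs
DUPLICATIVE_SIMILARITY = 0.80
#: distance below which a second gene copy counts as a proximal duplication
PROXIMAL_BP = 20_000
#: proximal copies needed to call a runway duplication
RUNWAY_COPIES = 3


@dataclass(frozen=True)
class ExonRecord:
    """One annotated exon on one haplotype assembly (0-based half-open)."""

    contig: str
    start: int
    end: int
    gene: str
    haplotype: str
    strand: str = "+"


@dataclass
class PAInterval:
    """An extracted allele interval prior to sequence attachment."""

    haplotype: str
    contig: str
    start: int
    end: int
    strand: str
    gene_labels: list[str]
    gene_intervals: list[tuple[str, int, int]]
    partial: bool = False


@dataclass
class PAllele:
    """One pangenome-derived allele.

    ``gene_intervals`` keeps the absolute coordinates of every annotated
    gene copy inside the allele, which is what proximal/runway duplication
    calls are made from.
    """

    id: str
    haplotype_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    gene_labels: list[str]
    flank_bp: int
    gene_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    partial: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"{self.id}: interval length {self.end - self.start} != "
                f"sequence length {len(self.sequence)}"
            )
        extra = set(self.sequence.upper()) - set("ACGTN")
        if extra:
            raise ValueError(f"{self.id}: invalid characters {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HomologyGroup:
    group_id: str
    members: list[str]
    reference_gene: str | None = None


@dataclass
class ParalogAnnotation:
    pa_id: str
    klass: str | None  # reference_allele / alternative_allele / duplicative_paralog / diverged_paralog / pseudogene
    similarity_to_reference: float | None
    proximal_duplication: bool = False
    runway: bool = False


# ---------------------------------------------------------------------------
# interval extraction


def _merge_sorted(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def extract_pa_intervals(
    exons: Iterable[ExonRecord],
    contig_lengths: Mapping[tuple[str, str], int],
    merge_gap_bp: int = DEFAULT_MERGE_GAP,
    flank_bp: int = DEFAULT_FLANK,
    min_len_bp: int = DEFAULT_MIN_LEN,
) -> list[PAInterval]:
    """Turn per-gene exon annotations into allele intervals.

    Consecutive exons of one gene with gap < ``merge_gap_bp`` are merged;
    each merged span gets ``flank_bp`` anchors on both sides, clipped at
    contig ends; spans shorter than ``min_len_bp`` are padded symmetrically
    where the contig permits, otherwise flagged ``partial``.  Overlapping
    intervals on one haplotype contig (across genes) are merged, their gene
    labels pooled.  Exons outside contig bounds are rejected with a logged
    diagnostic.
    """
    by_gene: dict[tuple[str, str, str], list[ExonRecord]] = {}
    for ex in exons:
        clen = contig_lengths.get((ex.haplotype, ex.contig))
        if clen is None:
            log.warning("exon %s: unknown contig %s/%s; rejected", ex.gene, ex.haplotype, ex.contig)
            continue
        if ex.start < 0 or ex.end > clen or ex.start >= ex.end:
            log.warning(
                "exon of %s at %s:%d-%d outside contig bounds [0,%d); rejected",
                ex.gene, ex.contig, ex.start, ex.end, clen,
            )
            continue
        by_gene.setdefault((ex.haplotype, ex.contig, ex.gene), []).append(ex)

    raw: dict[tuple[str, str], list[PAInterval]] = {}
    for (hap, contig, gene), exs in by_gene.items():
        clen = contig_lengths[(hap, contig)]
        strand = exs[0].strand
        spans = _merge_sorted(sorted((e.start, e.end) for e in exs), merge_gap_bp)
        for s, e in spans:
            gs, ge = s, e  # gene span before anchors
            s = max(0, s - flank_bp)
            e = min(clen, e + flank_bp)
            partial = False
            if e - s < min_len_bp:
                need = min_len_bp - (e - s)
                left = need // 2
                s2 = s - left
                e2 = e + (need - left)
                # push padding to the other side when clipped
                if s2 < 0:
                    e2 += -s2
                    s2 = 0
                if e2 > clen:
                    s2 -= e2 - clen
                    e2 = clen
                if s2 < 0:
                    s2 = 0
                    partial = True  # contig shorter than the minimum size
                s, e = s2, e2
            raw.setdefault((hap, contig), []).append(
                PAInterval(hap, contig, s, e, strand, [gene], [(gene, gs, ge)], partial)
            )

    out: list[PAInterval] = []
    for (hap, contig), ivs in sorted(raw.items()):
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur: PAInterval | None = None
        for iv in ivs:
            if cur is not None and iv.start < cur.end:
                cur.end = max(cur.end, iv.end)
                cur.gene_intervals.extend(iv.gene_intervals)
                for g in iv.gene_labels:
                    if g not in cur.gene_labels:
                        cur.gene_labels.append(g)
                cur.partial = cur.partial or iv.partial
            else:
                cur = iv
                out.append(cur)
    for iv in out:
        iv.gene_intervals.sort(key=lambda t: (t[1], t[2]))
    return out


def extract_pas(
    assemblies: Mapping[str, Mapping[str, str]],
    intervals: Sequence[PAInterval],
    flank_bp: int = DEFAULT_FLANK,
) -> list[PAllele]:
    """Attach sequences to extracted intervals.

    ``assemblies`` maps haplotype id -> contig name -> sequence.  Alleles are
    stored in annotated gene orientation; canonical k-mers make downstream
    matrices strand-independent either way.
    """
    pas = []
    for iv in intervals:
        seq = assemblies[iv.haplotype][iv.contig][iv.start : iv.end]
        pid = f"{iv.haplotype}_{iv.contig}_{iv.start}_{iv.end}"
        pas.append(
            PAllele(
                id=pid,
                haplotype_id=iv.haplotype,
                contig=iv.contig,
                start=iv.start,
                end=iv.end,
                strand=iv.strand,
                sequence=seq,
                gene_labels=list(iv.gene_labels),
                flank_bp=flank_bp,
                gene_intervals=list(iv.gene_intervals),
                partial=iv.partial,
            )
        )
    return pas


# ---------------------------------------------------------------------------
# low-confidence filter


def filter_low_confidence(
    pas: Sequence[PAllele],
    max_n_frac: float = 0.05,
    min_nonrepeat_bp: int = 1_000,
    repeat_mask: Mapping[tuple[str, str], Sequence[tuple[int, int]]] | None = None,
) -> tuple[list[PAllele], list[PAllele]]:
    """Drop low-confidence alleles.

    An allele is dropped when more than ``max_n_frac`` of its bases are N,
    or when (given an optional repeat mask of (haplotype, contig) ->
    intervals) fewer than ``min_nonrepeat_bp`` bases are unmasked.
    Returns (kept, dropped).
    """
    kept, dropped = [], []
    for pa in pas:
        n_frac = pa.sequence.upper().count("N") / max(1, len(pa))
        bad = n_frac > max_n_frac
        if not bad and repeat_mask is not None:
            masked = 0
            for ms, me in repeat_mask.get((pa.haplotype_id, pa.contig), ()):
                masked += max(0, min(me, pa.end) - max(ms, pa.start))
            if len(pa) - masked < min_nonrepeat_bp:
                bad = True
        (dropped if bad else kept).append(pa)
    return kept, dropped


# ---------------------------------------------------------------------------
# homology grouping


def containment(a: np.ndarray, b: np.ndarray) -> float:
    """Containment coefficient |A∩B| / min(|A|, |B|) of two sorted code sets."""
    if a.size == 0 or b.size == 0:
        return 0.0
    inter = np.intersect1d(a, b, assume_unique=True).size
    return inter / min(a.size, b.size)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_homologous_pas(
    pas: Sequence[PAllele],
    k: int = 21,
    grouping_similarity: float = 0.2,
    reference_genes: Mapping[str, str] | None = None,
    prefilter: bool = False,
) -> list[HomologyGroup]:
    """Partition alleles into homology groups by k-mer containment.

    Any two alleles whose canonical k-mer sets have containment >=
    ``grouping_similarity`` end up in the same group (single-linkage
    transitive closure), pulling in orthologs, paralogs and homologous
    pseudogenes alike.  Alleles shorter than ``k`` are excluded with a
    warning.  ``reference_genes`` optionally maps a gene label to itself to
    anchor ``reference_gene`` on groups containing it.

    With ``prefilter=True`` candidate pairs are restricted to alleles
    sharing at least one k-mer from a deterministic 1/4 subsample before
    the exact containment check — linear-ish for large cohorts where most
    allele pairs are unrelated, and lossless in practice at the default
    threshold (related pairs share far more than four sampled k-mers).
    """
    usable: list[int] = []
    sets: list[np.ndarray] = []
    for i, pa in enumerate(pas):
        if len(pa) < k:
            warnings.warn(f"{pa.id}: shorter than k={k}; excluded from grouping")
            continue
        usable.append(i)
        sets.append(kmer_set(pa.sequence, k))
    uf = _UnionFind(len(usable))
    if prefilter:
        candidates: set[tuple[int, int]] = set()
        bucket: dict[int, list[int]] = {}
        for i, s in enumerate(sets):
            for code in s[(s & np.uint64(3)) == 0]:
                bucket.setdefault(int(code), []).append(i)
        for hits in bucket.values():
            for a in range(len(hits)):
                for b in range(a + 1, len(hits)):
                    candidates.add((hits[a], hits[b]))
        for i, j in sorted(candidates):
            if uf.find(i) != uf.find(j) and containment(sets[i], sets[j]) >= grouping_similarity:
                uf.union(i, j)
    else:
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                if containment(sets[i], sets[j]) >= grouping_similarity:
                    uf.union(i, j)
    roots: dict[int, list[int]] = {}
    for i in range(len(usable)):
        roots.setdefault(uf.find(i), []).append(i)
    groups = []
    for gi, root in enumerate(sorted(roots)):
        member_idx = [usable[i] for i in roots[root]]
        members = [pas[i].id for i in member_idx]
        ref = None
        if reference_genes:
            for i in member_idx:
                for g in pas[i].gene_labels:
                    if g in reference_genes:
                        ref = reference_genes[g]
                        break
                if ref:
                    break
        groups.append(HomologyGroup(group_id=f"g{gi:04d}", members=members, reference_gene=ref))
    return groups


# ---------------------------------------------------------------------------
# paralog classification


def paralog_class(similarity: float) -> str:
    """Duplicative vs diverged split at the 80% k-mer similarity threshold."""
    return "duplicative_paralog" if similarity >= DUPLICATIVE_SIMILARITY else "diverged_paralog"


def _proximal_runway(pa: PAllele) -> tuple[bool, bool]:
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for g, s, e in pa.gene_intervals:
        by_gene.setdefault(g, []).append((s, e))
    proximal = runway = False
    for spans in by_gene.values():
        spans.sort()
        run = 1
        best = 1
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 - e0 < PROXIMAL_BP:
                run += 1
            else:
                run = 1
            best = max(best, run)
        if best >= 2:
            proximal = True
        if best >= RUNWAY_COPIES:
            runway = True
    return proximal, runway


def classify_paralog(
    pa: PAllele,
    reference_pa: PAllele | None,
    k: int = 21,
    *,
    locus_is_reference: bool = False,
    in_reference_subgroup: bool | None = None,
    is_pseudogene: bool = False,
) -> ParalogAnnotation:
    """Annotate one allele relative to the reference-locus allele.

    Paralogs (alleles at a non-reference locus) split at >=80% k-mer
    similarity into duplicative vs diverged; orthologs are reference or
    alternative alleles depending on whether they share the reference
    gene's subgroup.  Proximal duplication is called when a second copy of
    a gene lies <20 kb away inside the allele; runway when at least three
    proximal copies chain.  With no reference allele available the class
    is left unset (deferred), similarity recorded as missing.
    """
    proximal, runway = _proximal_runway(pa)
    if is_pseudogene:
        return ParalogAnnotation(pa.id, "pseudogene", None, proximal, runway)
    if reference_pa is None and not locus_is_reference:
        return ParalogAnnotation(pa.id, None, None, proximal, runway)
    sim = None
    if reference_pa is not None:
        sim = containment(kmer_set(pa.sequence, k), kmer_set(reference_pa.sequence, k))
    if locus_is_reference:
        klass = "reference_allele" if in_reference_subgroup else "alternative_allele"
    else:
        klass = paralog_class(float(sim))
    return ParalogAnnotation(pa.id, klass, sim, proximal, runway)
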