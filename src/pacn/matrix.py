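"""Group-exclusive k-mer multiplicity matrices.

For each homology group the genotyping matrix M has one row per allele and
one column per canonical k-mer that occurs in at least one group member and
at most ``max_background_count`` times (default 0: "not elsewhere in the
genome") in the rest of the assemblies.  M[i, j] is the multiplicity of
k-mer j in allele i.  A background index over the PA-masked assemblies
enforces exclusivity and supplies a panel of single-copy k-mers used for
sequencing-depth estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alleles import PAllele
from .kmers import decode_kmer, encode_kmer, window_codes

log = logging.getLogger(__name__)

__all__ = [
    "BackgroundIndex",
    "KmerMatrix",
    "UnsolvableGroupError",
    "build_depth_panel",
    "build_matrix",
    "read_matrix",
    "select_informative_kmers",
    "write_matrix",
]

#: storage cap on multiplicities; larger values are clipped and logged
MULTIPLICITY_CAP = 255


class UnsolvableGroupError(RuntimeError):
    """Raised when a group retains no informative k-mer."""


def _mask_assembly(
    assemblies: Mapping[str, Mapping[str, str]],
    mask: Mapping[tuple[str, str], Sequence[tuple[int, int]]],
) -> Iterable[str]:
    """Yield assembly sequence with masked intervals replaced by N."""
    for hap in sorted(assemblies):
        for contig in sorted(assemblies[hap]):
            seq = assemblies[hap][contig]
            ivs = mask.get((hap, contig))
            if ivs:
                chars = list(seq)
                for s, e in ivs:
                    chars[max(0, s) : min(len(seq), e)] = "N" * (min(len(seq), e) - max(0, s))
                seq = "".join(chars)
            yield seq


@dataclass
class BackgroundIndex:
    """Canonical k-mer counts over all assembly sequence outside the PAs."""

    k: int
    codes: np.ndarray  # sorted uint64
    counts: np.ndarray  # int64, parallel to codes

    @classmethod
    def from_assemblies(
        cls,
        assemblies: Mapping[str, Mapping[str, str]],
        mask: Mapping[tuple[str, str], Sequence[tuple[int, int]]],
        k: int,
    ) -> "BackgroundIndex":
        chunks = [window_codes(seq, k) for seq in _mask_assembly(assemblies, mask)]
        allc = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
        codes, counts = np.unique(allc, return_counts=True)
        return cls(k=k, codes=codes, counts=counts.astype(np.int64))

    def count(self, query: np.ndarray) -> np.ndarray:
        """Background count for each query code (0 when absent)."""
        idx = np.searchsorted(self.codes, query)
        out = np.zeros(query.size, dtype=np.int64)
        ok = idx < self.codes.size
        hit = np.zeros(query.size, dtype=bool)
        hit[ok] = self.codes[idx[ok]] == query[ok]
        out[hit] = self.counts[idx[hit]]
        return out


def build_depth_panel(
    assemblies: Mapping[str, Mapping[str, str]],
    mask: Mapping[tuple[str, str], Sequence[tuple[int, int]]],
    k: int,
    max_panel: int = 5_000,
) -> np.ndarray:
    """Single-copy k-mer panel for depth estimation.

    Selects canonical k-mers that occur exactly once in every input
    haplotype (outside the allele intervals), so a diploid sample carries
    each exactly twice.  The panel is capped at ``max_panel`` k-mers taken
    evenly across the sorted candidates, deterministically.
    """
    panel: np.ndarray | None = None
    for hap in sorted(assemblies):
        chunks = [
            window_codes(seq, k)
            for seq in _mask_assembly({hap: assemblies[hap]}, mask)
        ]
        allc = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
        codes, counts = np.unique(allc, return_counts=True)
        single = codes[counts == 1]
        panel = single if panel is None else np.intersect1d(panel, single, assume_unique=True)
    if panel is None:
        panel = np.empty(0, dtype=np.uint64)
    if panel.size > max_panel:
        take = np.linspace(0, panel.size - 1, max_panel).astype(np.int64)
        panel = panel[take]
    return panel


def select_informative_kmers(
    group_pas: Sequence[PAllele],
    background: BackgroundIndex,
    k: int,
    max_background_count: int = 0,
) -> tuple[np.ndarray, int]:
    """Columns of the group matrix: k-mers in >=1 member, rare elsewhere.

    Returns (sorted codes, number excluded for background occurrence).
    Raises :class:`UnsolvableGroupError` when nothing survives.
    """
    union = np.unique(
        np.concatenate([window_codes(pa.sequence, k) for pa in group_pas])
        if group_pas
        else np.empty(0, dtype=np.uint64)
    )
    if union.size == 0:
        raise UnsolvableGroupError("group has no k-mers")
    bg = background.count(union)
    keep = bg <= max_background_count
    excluded = int((~keep).sum())
    kept = union[keep]
    if kept.size == 0:
        raise UnsolvableGroupError(
            f"no informative k-mers: all {union.size} occur in the background"
        )
    return kept, excluded


@dataclass
class KmerMatrix:
    """Multiplicity matrix of one homology group."""

    group_id: str
    k: int
    pa_ids: list[str]
    kmers: np.ndarray  # sorted uint64 codes, one per column
    M: np.ndarray  # uint16 rows x columns (values capped at MULTIPLICITY_CAP)
    background_excluded: int = 0
    degenerate_rows: list[int] = field(default_factory=list)
    #: rows collapsed onto each retained row (identical sequences), by pipeline
    row_members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape

    def row(self, pa_id: str) -> np.ndarray:
        return self.M[self.pa_ids.index(pa_id)]


def build_matrix(
    group_id: str,
    group_pas: Sequence[PAllele],
    kmers: np.ndarray,
    k: int,
    background_excluded: int = 0,
) -> KmerMatrix:
    """Fill M[i, j] = multiplicity of k-mer j in allele i.

    All-zero rows (alleles sharing no informative k-mer) are flagged
    degenerate, as are groups of byte-identical rows, which cannot be told
    apart at matrix level.
    """
    ids = [pa.id for pa in group_pas]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{group_id}: duplicate pa_ids")
    M = np.zeros((len(group_pas), kmers.size), dtype=np.uint16)
    for i, pa in enumerate(group_pas):
        codes = window_codes(pa.sequence, k)
        idx = np.searchsorted(kmers, codes)
        ok = idx < kmers.size
        ok[ok] = kmers[idx[ok]] == codes[ok]
        np.add.at(M[i], idx[ok], 1)
    over = M > MULTIPLICITY_CAP
    if over.any():
        log.warning("%s: %d entries exceed %d; capped", group_id, int(over.sum()), MULTIPLICITY_CAP)
        M = np.minimum(M, MULTIPLICITY_CAP)
    degenerate = [i for i in range(M.shape[0]) if not M[i].any()]
    seen: dict[bytes, int] = {}
    for i in range(M.shape[0]):
        key = M[i].tobytes()
        if key in seen:
            for j in (seen[key], i):
                if j not in degenerate:
                    degenerate.append(j)
        else:
            seen[key] = i
    return KmerMatrix(
        group_id=group_id,
        k=k,
        pa_ids=ids,
        kmers=kmers,
        M=M,
        background_excluded=background_excluded,
        degenerate_rows=sorted(degenerate),
    )


# ---------------------------------------------------------------------------
# serialization: sparse triplet TSV (canonical interchange form)


def write_matrix(mat: KmerMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = mat.group_id
    with open(outdir / f"{g}.kmers.tsv", "w") as fh:
        fh.write("kmer\tcol\n")
        for j, code in enumerate(mat.kmers):
            fh.write(f"{decode_kmer(int(code), mat.k)}\t{j}\n")
    with open(outdir / f"{g}.rows.tsv", "w") as fh:
        fh.write("row\tpa_id\tdegenerate\tmembers\n")
        for i, pid in enumerate(mat.pa_ids):
            members = ",".join(mat.row_members.get(pid, [pid]))
            fh.write(f"{i}\t{pid}\t{int(i in mat.degenerate_rows)}\t{members}\n")
    with open(outdir / f"{g}.matrix.tsv", "w") as fh:
        fh.write(f"#group={g}\tk={mat.k}\tbackground_excluded={mat.background_excluded}\n")
        fh.write("row\tcol\tmultiplicity\n")
        rows, cols = np.nonzero(mat.M)
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t{int(mat.M[r, c])}\n")


def read_matrix(outdir: str | Path, group_id: str) -> KmerMatrix:
    outdir = Path(outdir)
    with open(outdir / f"{group_id}.matrix.tsv") as fh:
        header = fh.readline().strip().lstrip("#")
        meta = dict(part.split("=", 1) for part in header.split("\t"))
        fh.readline()
        triplets = [tuple(int(x) for x in line.split("\t")) for line in fh if line.strip()]
    k = int(meta["k"])
    kmers = []
    with open(outdir / f"{group_id}.kmers.tsv") as fh:
        fh.readline()
        for line in fh:
            kmer, _ = line.rstrip("\n").split("\t")
            kmers.append(encode_kmer(kmer))
    pa_ids: list[str] = []
    degenerate: list[int] = []
    row_members: dict[str, list[str]] = {}
    with open(outdir / f"{group_id}.rows.tsv") as fh:
        fh.readline()
        for line in fh:
            row, pid, deg, members = line.rstrip("\n").split("\t")
            pa_ids.append(pid)
            if int(deg):
                degenerate.append(int(row))
            row_members[pid] = members.split(",")
    M = np.zeros((len(pa_ids), len(kmers)), dtype=np.uint16)
    for r, c, v in triplets:
        M[r, c] = v
    return KmerMatrix(
        group_id=group_id,
        k=k,
        pa_ids=pa_ids,
        kmers=np.asarray(kmers, dtype=np.uint64),
        M=M,
        background_excluded=int(meta["background_excluded"]),
        degenerate_rows=degenerate,
        row_members=row_members,
    )
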