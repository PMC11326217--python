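"""Synthetic pangenomes, samples and reads with known truth.

The generator emulates the variation classes the genotyper must cope with:
paralogous loci diverged from a family ancestor, orthologous haplotype
variation on each locus, structural variants (indels), gene-conversion
tracts copied between paralogs, copy-number haplotypes (whole-gene
deletions and extra duplications, translocated by default so every copy is
its own allele segment, or tandem to exercise proximal-duplication
annotation), a shared background genome with planted repeats, and
uniform-coverage reads with per-base substitution errors.  A fixed seed
fixes every byte of output.

Scale defaults are desk scale (kilobase genes, a handful of haplotypes) so
whole pipelines run in seconds; every length and rate is configurable.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alleles import ExonRecord

__all__ = [
    "AlleleRecord",
    "SimConfig",
    "TruthSet",
    "mendelian_trio",
    "simulate_pangenome",
    "simulate_sample",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic pangenome.

    Rates are per-base probabilities; lengths in bp; coverage is per
    haplotype (a diploid sample sees a single-copy k-mer ~2x coverage).
    """

    seed: int = 0
    n_haplotypes: int = 16
    n_families: int = 4
    n_paralog_loci: int = 2
    gene_length_bp: int = 2_000
    paralog_divergence: float = 0.01
    #: founder alleles per locus: haplotypes share alleles identity-by-descent
    n_founder_alleles: int = 4
    founder_divergence: float = 0.01
    #: private per-haplotype divergence on top of the founder allele
    ortholog_divergence: float = 0.002
    sv_rate: float = 0.05
    sv_size_bp: tuple[int, int] = (50, 500)
    conversion_rate: float = 0.02
    conversion_tract_bp: int = 500
    cnv_rate: float = 0.10
    cnv_max_extra: int = 2
    del_rate: float = 0.02
    cnv_mode: str = "translocated"  # or "tandem"
    tandem_gap_bp: int = 200
    spacer_len_bp: int = 1_500
    repeat_len_bp: int = 300
    repeat_copies: int = 3
    read_length_bp: int = 150
    coverage: float = 30.0
    error_rate: float = 0.002

    def validate(self) -> None:
        for name in ("paralog_divergence", "ortholog_divergence", "sv_rate",
                     "conversion_rate", "cnv_rate", "del_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_haplotypes", "n_families", "n_paralog_loci",
                     "gene_length_bp", "read_length_bp", "spacer_len_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sv_size_bp[1] >= self.gene_length_bp:
            raise ValueError("SV size must be smaller than the gene")
        if self.conversion_tract_bp >= self.gene_length_bp:
            raise ValueError("conversion tract must be smaller than the gene")
        if self.cnv_mode not in ("translocated", "tandem"):
            raise ValueError(f"unknown cnv_mode {self.cnv_mode!r}")


@dataclass
class AlleleRecord:
    allele_id: str
    family: int
    locus: int
    sequence: str
    svs: tuple[tuple[str, int, int], ...]  # (kind, pos, size)
    conversion: tuple[int, int, int] | None  # (source locus, start, length)


@dataclass
class TruthSet:
    """Everything the simulator knows: the ground truth for every test."""

    cfg: SimConfig
    assemblies: dict[str, dict[str, str]]
    exons: list[ExonRecord]
    locus_ancestors: list[list[str]]  # [family][locus]
    alleles: dict[str, AlleleRecord]  # allele_id -> record
    hap_allele_counts: dict[tuple[str, int], Counter]  # (hap, family) -> Counter
    coords: pd.DataFrame  # hap, contig, start, end, family, locus, allele_id
    samples: dict[str, tuple[str, str]] = field(default_factory=dict)

    def haplotypes(self) -> list[str]:
        return sorted(self.assemblies)

    def family_alleles(self, family: int) -> list[AlleleRecord]:
        return [a for a in self.alleles.values() if a.family == family]

    def pacn(self, hap_pair: tuple[str, str], family: int) -> Counter:
        """True allele-specific copy numbers of a diploid sample."""
        out: Counter = Counter()
        for hap in hap_pair:
            out.update(self.hap_allele_counts.get((hap, family), Counter()))
        return out

    def pacn_table(self, hap_pair: tuple[str, str]) -> pd.DataFrame:
        rows = []
        for fam in range(self.cfg.n_families):
            for aid, cn in sorted(self.pacn(hap_pair, fam).items()):
                rows.append({"family": fam, "allele_id": aid, "paCN": cn})
        return pd.DataFrame(rows, columns=["family", "allele_id", "paCN"])

    # -- truth-derived divergence and SV tables ---------------------------

    def pair_divergences(self, family: int) -> tuple[list[float], list[float]]:
        """(paralog, ortholog) per-pair substitution divergences.

        Computed by direct sequence comparison between distinct alleles of
        equal length (pairs separated by an indel are skipped: divergence
        is defined on alignable, substitution-only sequence).
        """
        recs = self.family_alleles(family)
        par, ort = [], []
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                if len(a.sequence) != len(b.sequence):
                    continue
                d = _hamming(a.sequence, b.sequence) / len(a.sequence)
                (ort if a.locus == b.locus else par).append(d)
        return par, ort

    def sv_gap_table(self, family: int) -> dict[tuple[str, str], int]:
        """Largest indel difference (bp) between each pair of alleles."""
        recs = self.family_alleles(family)
        out = {}
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                diff = set(a.svs) ^ set(b.svs)
                gap = max((size for _, _, size in diff), default=0)
                out[(a.allele_id, b.allele_id)] = gap
        return out


def _hamming(a: str, b: str) -> int:
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return int((xa != xb).sum())


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        # shift by 1-3 positions in base order: always a different base
        cur = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(cur + rng.integers(1, 4, hits.size)) % 4]
    return arr.tobytes().decode()


def simulate_pangenome(cfg: SimConfig) -> TruthSet:
    """Generate haplotype assemblies, exon annotations and full truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # family/locus ancestors, and founder alleles per locus (the clusters
    # haplotypes draw from, emulating identity-by-descent allele sharing)
    locus_ancestors: list[list[str]] = []
    founders: list[list[list[str]]] = []
    for _f in range(cfg.n_families):
        anc = _rand_seq(rng, cfg.gene_length_bp)
        loci = [_mutate(anc, cfg.paralog_divergence, rng) for _ in range(cfg.n_paralog_loci)]
        locus_ancestors.append(loci)
        founders.append(
            [[_mutate(loc, cfg.founder_divergence, rng)
              for _ in range(max(1, cfg.n_founder_alleles))]
             for loc in loci]
        )

    # fixed slot layout shared by all haplotypes: per family, per locus,
    # 1 + cnv_max_extra slots; spacers are identical across haplotypes so
    # every spacer k-mer is single copy in every assembly (depth panel).
    slots_per_locus = 1 + (cfg.cnv_max_extra if cfg.cnv_mode == "translocated" else 0)
    n_slots = cfg.n_families * cfg.n_paralog_loci * slots_per_locus
    spacers = [_rand_seq(rng, cfg.spacer_len_bp) for _ in range(n_slots + 1)]
    if cfg.repeat_copies > 1 and cfg.repeat_len_bp > 0:
        # plant a repeated segment inside the first few spacers to exercise
        # background exclusion (its k-mers are multi-copy, never panel/column)
        rep = _rand_seq(rng, cfg.repeat_len_bp)
        for i in range(min(cfg.repeat_copies, len(spacers))):
            s = spacers[i]
            mid = len(s) // 2
            spacers[i] = s[: mid - len(rep) // 2] + rep + s[mid + len(rep) - len(rep) // 2 :]

    haps = [f"h{i:02d}" for i in range(cfg.n_haplotypes)]
    registry: list[dict[str, str]] = [dict() for _ in range(cfg.n_families)]
    alleles: dict[str, AlleleRecord] = {}
    hap_counts: dict[tuple[str, int], Counter] = {}
    assemblies: dict[str, dict[str, str]] = {}
    exons: list[ExonRecord] = []
    coords_rows = []

    def register(fam: int, locus: int, seq: str, svs, conv) -> str:
        reg = registry[fam]
        if seq not in reg:
            aid = f"f{fam}_a{len(reg):03d}"
            reg[seq] = aid
            alleles[aid] = AlleleRecord(aid, fam, locus, seq, tuple(svs), conv)
        return reg[seq]

    for hap in haps:
        parts: list[str] = []
        pos = 0
        slot = 0

        def emit_spacer() -> None:
            nonlocal pos, slot
            parts.append(spacers[slot])
            pos += len(spacers[slot])
            slot += 1

        def emit_gene(fam: int, locus: int, seq: str, aid: str) -> None:
            nonlocal pos
            gene = f"fam{fam:02d}_loc{locus}"
            parts.append(seq)
            exons.append(ExonRecord("chr1", pos, pos + len(seq), gene, hap, "+"))
            coords_rows.append(
                {"hap": hap, "contig": "chr1", "start": pos, "end": pos + len(seq),
                 "family": fam, "locus": locus, "allele_id": aid}
            )
            pos += len(seq)

        parts.append(spacers[-1][: cfg.spacer_len_bp // 2])
        pos = len(parts[0])
        for fam in range(cfg.n_families):
            hap_counts[(hap, fam)] = Counter()
            for locus in range(cfg.n_paralog_loci):
                # draw the haplotype's allele at this locus
                fi = int(rng.integers(0, max(1, cfg.n_founder_alleles)))
                seq = founders[fam][locus][fi]
                conv = None
                if cfg.n_paralog_loci > 1 and rng.random() < cfg.conversion_rate:
                    src = int(rng.integers(0, cfg.n_paralog_loci - 1))
                    src += src >= locus
                    t = int(rng.integers(0, cfg.gene_length_bp - cfg.conversion_tract_bp + 1))
                    seq = (seq[:t]
                           + locus_ancestors[fam][src][t : t + cfg.conversion_tract_bp]
                           + seq[t + cfg.conversion_tract_bp :])
                    conv = (src, t, cfg.conversion_tract_bp)
                seq = _mutate(seq, cfg.ortholog_divergence, rng)
                svs: list[tuple[str, int, int]] = []
                if rng.random() < cfg.sv_rate:
                    size = int(rng.integers(cfg.sv_size_bp[0], cfg.sv_size_bp[1] + 1))
                    p = int(rng.integers(0, len(seq) - size))
                    if rng.random() < 0.5:
                        seq = seq[:p] + seq[p + size :]
                        svs.append(("del", p, size))
                    else:
                        seq = seq[:p] + _rand_seq(rng, size) + seq[p:]
                        svs.append(("ins", p, size))
                deleted = rng.random() < cfg.del_rate
                extra = 0
                if not deleted and rng.random() < cfg.cnv_rate:
                    extra = int(rng.integers(1, cfg.cnv_max_extra + 1))
                aid = None if deleted else register(fam, locus, seq, svs, conv)

                if cfg.cnv_mode == "translocated":
                    emit_spacer()
                    if not deleted:
                        emit_gene(fam, locus, seq, aid)
                        hap_counts[(hap, fam)][aid] += 1
                    for e in range(cfg.cnv_max_extra):
                        emit_spacer()
                        if not deleted and e < extra:
                            emit_gene(fam, locus, seq, aid)
                            hap_counts[(hap, fam)][aid] += 1
                else:  # tandem
                    emit_spacer()
                    if not deleted:
                        gap = _rand_seq(rng, cfg.tandem_gap_bp)
                        for e in range(1 + extra):
                            if e > 0:
                                parts.append(gap)
                                pos += len(gap)
                            emit_gene(fam, locus, seq, aid)
                            hap_counts[(hap, fam)][aid] += 1
        parts.append(spacers[-1][cfg.spacer_len_bp // 2 :])
        assemblies[hap] = {"chr1": "".join(parts)}

    coords = pd.DataFrame(
        coords_rows, columns=["hap", "contig", "start", "end", "family", "locus", "allele_id"]
    )
    return TruthSet(
        cfg=cfg,
        assemblies=assemblies,
        exons=exons,
        locus_ancestors=locus_ancestors,
        alleles=alleles,
        hap_allele_counts=hap_counts,
        coords=coords,
    )


# ---------------------------------------------------------------------------
# reads


def simulate_sample(
    truth: TruthSet,
    hap_pair: tuple[str, str],
    cfg: SimConfig | None = None,
    seed: int | None = None,
    out_fastq: str | Path | None = None,
) -> tuple[list[str] | Path, pd.DataFrame]:
    """Uniform-coverage reads from a diploid plus its true paCN table.

    Coverage, read length and error rate come from ``cfg`` (defaults to the
    truth's own config).  Returns the read sequences (or the FASTQ path if
    ``out_fastq`` is given) and the truth copy-number table.
    """
    cfg = cfg or truth.cfg
    if cfg.coverage <= 0:
        raise ValueError("coverage must be > 0")
    for h in hap_pair:
        if h not in truth.assemblies:
            raise KeyError(f"unknown haplotype {h}")
    rng = np.random.default_rng(cfg.seed + 7_919 if seed is None else seed)
    contigs = [truth.assemblies[h]["chr1"] for h in hap_pair]
    lens = np.array([len(c) for c in contigs], dtype=float)
    rl = cfg.read_length_bp
    n_reads = int(round(cfg.coverage * lens.sum() / rl))
    reads: list[str] = []
    if n_reads > 0:
        which = rng.choice(len(contigs), size=n_reads, p=lens / lens.sum())
        strands = rng.random(n_reads) < 0.5
        n_err = rng.binomial(rl, cfg.error_rate, size=n_reads)
        from .kmers import revcomp

        for i in range(n_reads):
            seq = contigs[which[i]]
            start = int(rng.integers(0, max(1, len(seq) - rl + 1)))
            r = seq[start : start + rl]
            if n_err[i]:
                r = _mutate_fixed(r, int(n_err[i]), rng)
            if strands[i]:
                r = revcomp(r)
            reads.append(r)
    table = truth.pacn_table(hap_pair)
    if out_fastq is not None:
        write_fastq(reads, out_fastq)
        return Path(out_fastq), table
    return reads, table


def _mutate_fixed(seq: str, n_err: int, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = rng.choice(arr.size, size=min(n_err, arr.size), replace=False)
    cur = np.searchsorted(_BASES, arr[hits])
    arr[hits] = _BASES[(cur + rng.integers(1, 4, hits.size)) % 4]
    return arr.tobytes().decode()


def write_fastq(reads: Sequence[str], path: str | Path) -> None:
    """Write reads as FASTQ (gzip when the path ends in .gz); valid when empty."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i}\n{r}\n+\n{'I' * len(r)}\n")


def mendelian_trio(
    truth: TruthSet,
    father_pair: tuple[str, str],
    mother_pair: tuple[str, str],
    seed: int = 0,
    de_novo_rate: float = 0.0,
) -> tuple[str, str]:
    """Child haplotype pair: one uniformly chosen haplotype per parent.

    De-novo events are off by default; a nonzero rate re-draws the
    transmitted haplotype from the full pool (a simple surrogate for a
    novel event at desk scale).
    """
    rng = np.random.default_rng(seed)
    picks = []
    for pair in (father_pair, mother_pair):
        h = pair[int(rng.integers(0, 2))]
        if de_novo_rate > 0 and rng.random() < de_novo_rate:
            h = truth.haplotypes()[int(rng.integers(0, len(truth.haplotypes())))]
        picks.append(h)
    return picks[0], picks[1]
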