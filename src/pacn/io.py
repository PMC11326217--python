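"""File-format helpers: FASTA (via Biopython), BED, simple TSV tables."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .alleles import ExonRecord

__all__ = ["read_bed_exons", "read_fasta", "write_bed_exons", "write_fasta"]


def _opener(path: Path):
    return gzip.open if str(path).endswith(".gz") else open


def read_fasta(path: str | Path) -> dict[str, str]:
    """Contig name -> sequence (gzip transparent)."""
    from Bio import SeqIO

    path = Path(path)
    with _opener(path)(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with _opener(path)(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed_exons(path: str | Path, haplotype: str) -> list[ExonRecord]:
    """BED (contig, start, end, gene[, score, strand]) -> exon records."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 else "+"
        out.append(ExonRecord(str(row[0]), int(row[1]), int(row[2]), str(row[3]),
                              haplotype, str(strand)))
    return out


def write_bed_exons(exons: Iterable[ExonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ex in exons:
            fh.write(f"{ex.contig}\t{ex.start}\t{ex.end}\t{ex.gene}\t0\t{ex.strand}\n")
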