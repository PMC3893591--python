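"""Genome coordinate space and gene models.

Coordinates are 1-based closed in memory; BED files on disk are 0-based
half-open, conversion happens at the I/O boundary (:mod:`cisnet.insertions`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["GenomeDefinition", "GeneModel", "read_gene_bed"]


@dataclass(frozen=True)
class GenomeDefinition:
    """An ordered set of chromosomes with their lengths in base pairs."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome must contain at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self.lengths

    def length_of(self, chromosome: str) -> int:
        try:
            return self.lengths[chromosome]
        except KeyError:
            raise KeyError(f"chromosome {chromosome!r} not in genome definition") from None

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


@dataclass(frozen=True)
class GeneModel:
    """A gene body on the genome (1-based closed interval)."""

    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.symbol}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.symbol}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def read_gene_bed(path) -> list[GeneModel]:
    """Read gene models from a 6-column BED file (name = gene symbol).

    BED starts are 0-based half-open; the in-memory interval is 1-based closed.
    """
    genes: list[GeneModel] = []
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["chrom", "start", "end", "name", "score", "strand"],
                        dtype={"chrom": str, "name": str})
    for row in frame.itertuples(index=False):
        strand = row.strand if row.strand in {"+", "-"} else "+"
        genes.append(GeneModel(symbol=str(row.name), chromosome=str(row.chrom),
                               start=int(row.start) + 1, end=int(row.end), strand=strand))
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes
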