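"""Shared data model for the regulon-analysis pipeline.

All genomic coordinates are 0-based half-open internally; format readers and
writers convert at the boundary (GFF3 is 1-based inclusive on disk).  Genes are
modeled as single intervals without exon structure: the assignment rules
operate only on transcription start/end sites and the gene span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "CoverageTrack",
    "TimeSeries",
    "GeneSet",
    "PeakRegion",
    "PeakSet",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene as a stranded interval.

    TSS is ``start`` on the + strand and ``end - 1`` on the - strand;
    the transcription end site (TES) is symmetric.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end ({self.start} >= {self.end})")
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: negative start {self.start}")

    @property
    def tss(self) -> int:
        """Transcription start site position (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end (stop) site position (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    """Gene models plus chromosome sizes for one genome assembly.

    ``genome_gene_count`` is the number of predicted genes in the genome and
    may exceed ``len(genes)`` (e.g. when only a subset is annotated here); it
    is the default population size for enrichment tests.
    """

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    genome_gene_count: int = 0

    def __post_init__(self) -> None:
        if self.genome_gene_count == 0:
            self.genome_gene_count = len(self.genes)
        if self.genome_gene_count < len(self.genes):
            raise ValueError("genome_gene_count smaller than the number of annotated genes")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.end > size:
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} beyond chromosome {g.chrom} length {size}"
                )

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {c: [] for c in self.chrom_sizes}
        for g in self.genes:
            out[g.chrom].append(g)
        return out

    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}


@dataclass
class CoverageTrack:
    """Per-base forward- and reverse-strand read coverage for one chromosome."""

    chrom: str
    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd)
        self.rev = np.asarray(self.rev)
        if self.fwd.shape != self.rev.shape or self.fwd.ndim != 1:
            raise ValueError("fwd and rev must be 1-D vectors of equal length")
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise ValueError("coverage values must be non-negative")

    def __len__(self) -> int:
        return int(self.fwd.shape[0])

    @property
    def combined(self) -> np.ndarray:
        """Strand-summed coverage (the quantity the background model scores)."""
        return self.fwd + self.rev


@dataclass
class TimeSeries:
    """A reporter bioluminescence trace: hours in constant darkness vs counts."""

    t: np.ndarray
    y: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D vectors of equal length")
        if len(self.t) >= 2 and not (np.diff(self.t) > 0).all():
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.shape[0])


@dataclass
class GeneSet:
    label: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


@dataclass
class PeakRegion:
    """A called enriched region.

    ``min_p`` is the smallest per-position upper-tail probability inside the
    region under the lognormal background; ``q`` its BH adjustment across the
    sample's candidate regions.  ``shift`` is the estimated forward-to-reverse
    coverage lag in bp (-1 when undefined, e.g. zero-variance window).
    """

    chrom: str
    start: int
    end: int
    summit: int
    min_p: float
    q: float = float("nan")
    shift: int = -1
    passed_shift: bool = False
    signal: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: summit {self.summit} outside region")
        if not (0.0 <= self.min_p <= 1.0):
            raise ValueError(f"min_p out of [0, 1]: {self.min_p}")

    def __len__(self) -> int:
        return self.end - self.start


class PeakSet(list):
    """A list of PeakRegion sorted by (chrom, start)."""

    def __init__(self, peaks: Iterable[PeakRegion] = ()):  # noqa: D107
        super().__init__(sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)))

    def chroms(self) -> list[str]:
        seen = dict.fromkeys(p.chrom for p in self)
        return list(seen)
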