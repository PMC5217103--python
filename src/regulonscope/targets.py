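"""Peak-to-gene assignment by promoter/terminator distance windows.

A peak is assigned to every gene whose window its summit falls in: within
``up_bp`` (default 5 kb) upstream of the transcription start site, within
``down_bp`` (default 3 kb) downstream of the transcription end site, or
inside the gene span.  Windows are strand-aware and boundaries inclusive.
One peak between two divergently transcribed genes is assigned to both.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .core import GeneModel, GenomeAnnotation, GeneSet, PeakRegion

__all__ = [
    "TargetAssignment",
    "assign_peaks",
    "assign_peaks_brute_force",
    "union_targets",
    "location_distribution",
]

# classification priority when a summit satisfies several windows of one gene
_CLASS_PRIORITY = {"genic": 0, "upstream": 1, "downstream": 2}


@dataclass(frozen=True)
class TargetAssignment:
    gene_id: str
    peak: PeakRegion
    location_class: str  # upstream | genic | downstream
    distance: int        # bp from summit to TSS (upstream) / TES (downstream); 0 for genic

    def __post_init__(self) -> None:
        if self.location_class not in _CLASS_PRIORITY:
            raise ValueError(f"bad location_class {self.location_class!r}")


def _classify(summit: int, gene: GeneModel, up_bp: int, down_bp: int,
              ) -> tuple[str, int] | None:
    """Window predicate for one (summit, gene) pair; genic > upstream > downstream."""
    if gene.start <= summit < gene.end:
        return "genic", 0
    if gene.strand == "+":
        if summit < gene.start:
            d = gene.tss - summit
            return ("upstream", d) if d <= up_bp else None
        d = summit - gene.tes
        return ("downstream", d) if d <= down_bp else None
    # minus strand: upstream is to the right of the TSS (= end - 1)
    if summit > gene.end - 1:
        d = summit - gene.tss
        return ("upstream", d) if d <= up_bp else None
    d = gene.tes - summit
    return ("downstream", d) if d <= down_bp else None


def assign_peaks(peaks: list[PeakRegion], annotation: GenomeAnnotation,
                 up_bp: int = 5000, down_bp: int = 3000) -> list[TargetAssignment]:
    """Assign each peak summit to all genes whose windows contain it.

    Candidate genes are found with an interval tree over the padded gene
    spans, then the exact strand-aware window predicate is applied.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in annotation.genes:
        pad = max(up_bp, down_bp)
        trees[g.chrom].addi(max(0, g.start - pad), g.end + pad, g)
    out: list[TargetAssignment] = []
    for p in peaks:
        if p.chrom not in annotation.chrom_sizes:
            raise ValueError(f"peak on unknown chromosome {p.chrom!r}")
        hits = sorted(trees[p.chrom][p.summit], key=lambda iv: iv.data.gene_id)
        for iv in hits:
            res = _classify(p.summit, iv.data, up_bp, down_bp)
            if res is not None:
                out.append(TargetAssignment(iv.data.gene_id, p, res[0], res[1]))
    return out


def assign_peaks_brute_force(peaks: list[PeakRegion], annotation: GenomeAnnotation,
                             up_bp: int = 5000, down_bp: int = 3000,
                             ) -> list[TargetAssignment]:
    """Reference double loop over all (peak, gene) pairs; oracle for the tree path."""
    out = []
    for p in peaks:
        if p.chrom not in annotation.chrom_sizes:
            raise ValueError(f"peak on unknown chromosome {p.chrom!r}")
        for g in sorted(annotation.genes, key=lambda g: g.gene_id):
            if g.chrom != p.chrom:
                continue
            res = _classify(p.summit, g, up_bp, down_bp)
            if res is not None:
                out.append(TargetAssignment(g.gene_id, p, res[0], res[1]))
    return out


def union_targets(per_condition: dict[str, GeneSet] | list[GeneSet],
                  label: str = "targets_union") -> GeneSet:
    """Union of assigned gene ids across conditions."""
    sets = list(per_condition.values()) if isinstance(per_condition, dict) else list(per_condition)
    if not sets:
        raise ValueError("need at least one condition")
    members: set[str] = set()
    for s in sets:
        members |= s.members
    return GeneSet(label=label, members=members)


def location_distribution(assignments: list[TargetAssignment]) -> dict[str, float]:
    """Fraction of peaks by binding location, each peak counted once.

    A peak assigned to several genes takes its highest-priority class
    (genic > upstream > downstream).  Fractions sum to 1.
    """
    if not assignments:
        raise ValueError("empty assignment list")
    best: dict[int, str] = {}
    for a in assignments:
        key = id(a.peak)
        prev = best.get(key)
        if prev is None or _CLASS_PRIORITY[a.location_class] < _CLASS_PRIORITY[prev]:
            best[key] = a.location_class
    n = len(best)
    return {
        cls: sum(1 for v in best.values() if v == cls) / n
        for cls in ("upstream", "downstream", "genic")
    }
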