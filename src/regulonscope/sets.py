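"""Gene-set integration: light/clock membership partition, hypergeometric
term enrichment, and between-condition peak-set reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import false_discovery_control

from .core import CoverageTrack, GeneSet, PeakRegion

__all__ = [
    "MembershipPartition",
    "EnrichmentResult",
    "partition_membership",
    "hypergeom_enrichment",
    "peak_set_correlation",
]


@dataclass
class MembershipPartition:
    """Four-way partition of a focal gene set by light/clock membership."""

    counts: dict[str, int]
    percentages: dict[str, float]
    genes: dict[str, set[str]]

    CELLS = ("both", "light_only", "clock_only", "neither")


def partition_membership(focal: GeneSet, light_set: GeneSet, clock_set: GeneSet,
                         ) -> MembershipPartition:
    """Partition the focal set into {light & clock, light-only, clock-only, neither}."""
    if len(focal) == 0:
        raise ValueError("empty focal set")
    cells = {
        "both": focal.members & light_set.members & clock_set.members,
        "light_only": (focal.members & light_set.members) - clock_set.members,
        "clock_only": (focal.members & clock_set.members) - light_set.members,
        "neither": focal.members - light_set.members - clock_set.members,
    }
    n = len(focal)
    counts = {k: len(v) for k, v in cells.items()}
    assert sum(counts.values()) == n
    return MembershipPartition(
        counts=counts,
        percentages={k: 100.0 * c / n for k, c in counts.items()},
        genes=cells,
    )


@dataclass
class EnrichmentResult:
    term_id: str
    x: int   # study hits
    n: int   # study size
    K: int   # population hits
    N: int   # population size
    p: float
    q: float = float("nan")


def hypergeom_enrichment(study: GeneSet, population: GeneSet,
                         term_map: dict[str, set[str]],
                         min_term_size: int = 2) -> list[EnrichmentResult]:
    """Over-representation test per term against the whole-population background.

    p = P(X >= x) under Hypergeometric(N, K, n) — the probability of drawing
    at least the observed number of term members in a random study-sized
    sample.  Terms with fewer than ``min_term_size`` population members are
    skipped as uninformative; BH adjustment is across the terms tested.
    """
    offenders = study.members - population.members
    if offenders:
        raise ValueError(f"study genes absent from population: {sorted(offenders)}")
    N, n = len(population), len(study)
    results = []
    for term_id in sorted(term_map):
        members = term_map[term_id] & population.members
        K = len(members)
        if K < min_term_size:
            continue
        x = len(study.members & members)
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        results.append(EnrichmentResult(term_id=term_id, x=x, n=n, K=K, N=N,
                                        p=min(p, 1.0)))
    if results:
        qvals = false_discovery_control(np.array([r.p for r in results]), method="bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
    return results


def _merged_union(peaks_a: list[PeakRegion], peaks_b: list[PeakRegion],
                  ) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in list(peaks_a) + list(peaks_b):
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def peak_set_correlation(peaks_a: list[PeakRegion], peaks_b: list[PeakRegion],
                         tracks_a: dict[str, CoverageTrack],
                         tracks_b: dict[str, CoverageTrack]) -> float:
    """Reproducibility of two peak sets as R^2 over their interval union.

    The union of both sets' intervals (overlaps merged) defines the regions;
    each sample contributes its summed combined coverage per region, and R^2
    is the squared Pearson correlation of the log2(x + 1)-transformed sums.
    Symmetric in its arguments.
    """
    merged = _merged_union(peaks_a, peaks_b)
    if not any(merged.values()):
        raise ValueError("empty peak-interval union")
    va, vb = [], []
    for chrom, ivs in sorted(merged.items()):
        if chrom not in tracks_a or chrom not in tracks_b:
            raise ValueError(f"coverage missing for chromosome {chrom!r}")
        ca = tracks_a[chrom].combined
        cb = tracks_b[chrom].combined
        for s, e in ivs:
            va.append(ca[s:e].sum())
            vb.append(cb[s:e].sum())
    if len(va) < 2:
        raise ValueError("need at least two union intervals for a correlation")
    xa = np.log2(np.asarray(va, dtype=float) + 1)
    xb = np.log2(np.asarray(vb, dtype=float) + 1)
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)
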