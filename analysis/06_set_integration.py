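#!/usr/bin/env python
"""Partition targets by light/clock membership, test term enrichment, and
quantify peak reproducibility between replicate conditions.

Simulates light-regulated and clock-controlled gene lists enriched among the
targets, computes the four-way membership partition of the target union,
runs the hypergeometric over-representation test against the whole-genome
background, and reports R^2 between two conditions' peak coverage over the
union of their peak intervals.
"""

import argparse
import json
from pathlib import Path

from regulonscope import io as rio
from regulonscope.core import GeneSet
from regulonscope.sets import hypergeom_enrichment, partition_membership, \
    peak_set_correlation
from regulonscope.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--peaks", type=Path, default=ROOT / "results" / "peaks")
    ap.add_argument("--targets", type=Path, default=ROOT / "results" / "targets")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "integration")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    annotation = rio.read_gff(args.data / "genes.gff3")
    union = rio.read_gene_set(args.targets / "targets_union.txt", "targets")

    # membership lists: enriched among targets, sparse elsewhere
    rng = SimConfig(seed=args.seed).rng("membership")
    light, clock = set(), set()
    for g in annotation.genes:
        in_t = g.gene_id in union.members
        if rng.random() < (0.30 if in_t else 0.10):
            light.add(g.gene_id)
        if rng.random() < (0.26 if in_t else 0.15):
            clock.add(g.gene_id)
    light_set, clock_set = GeneSet("light", light), GeneSet("clock", clock)
    rio.write_gene_set(light_set, args.out / "light_regulated.txt")
    rio.write_gene_set(clock_set, args.out / "clock_controlled.txt")

    part = partition_membership(union, light_set, clock_set)
    (args.out / "partition.json").write_text(json.dumps(
        {"counts": part.counts, "percentages": part.percentages}, indent=1))
    print("target partition: " + ", ".join(
        f"{k} {part.percentages[k]:.0f}%" for k in part.CELLS))

    population = GeneSet("genome", annotation.gene_ids())
    results = hypergeom_enrichment(union, population,
                                   {"light_regulated": light, "clock_controlled": clock})
    with open(args.out / "enrichment.tsv", "w") as fh:
        fh.write("term_id\tx\tn\tK\tN\tp\tq\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.x}\t{r.n}\t{r.K}\t{r.N}\t{r.p:.4g}\t{r.q:.4g}\n")
            print(f"enrichment of {r.term_id}: {r.x}/{r.n} vs {r.K}/{r.N}, "
                  f"p = {r.p:.3g}, q = {r.q:.3g}")

    sizes = {}
    for line in (args.data / "chrom_sizes.tsv").read_text().splitlines():
        c, s = line.split("\t")
        sizes[c] = int(s)
    ta = rio.read_coverage_tracks(args.data / "LL0_fwd.bedgraph",
                                  args.data / "LL0_rev.bedgraph", sizes)
    tb = rio.read_coverage_tracks(args.data / "LL15_fwd.bedgraph",
                                  args.data / "LL15_rev.bedgraph", sizes)
    pa = rio.read_peaks(args.peaks / "peaks_LL0.narrowPeak")
    pb = rio.read_peaks(args.peaks / "peaks_LL15.narrowPeak")
    r2 = peak_set_correlation(list(pa), list(pb), ta, tb)
    (args.out / "replicate_r2.json").write_text(json.dumps({"r2_LL0_vs_LL15": r2}))
    print(f"peak-coverage reproducibility between LL0 and LL15: R^2 = {r2:.3f}")


if __name__ == "__main__":
    main()
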