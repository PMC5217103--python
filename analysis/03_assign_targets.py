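#!/usr/bin/env python
"""Assign peaks to genes and form per-condition and union target sets.

Uses the 5 kb-upstream / gene-body / 3 kb-downstream windows around each
peak summit; peaks between divergently transcribed genes count for both.
Writes per-condition gene lists, the union list, an assignment TSV, and the
binding-location distribution.
"""

import argparse
import json
from pathlib import Path

from regulonscope import io as rio
from regulonscope.core import GeneSet
from regulonscope.targets import assign_peaks, location_distribution, union_targets

ROOT = Path(__file__).resolve().parent.parent
CONDITIONS = ("LL0", "LL15", "LL60")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--peaks", type=Path, default=ROOT / "results" / "peaks")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "targets")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    annotation = rio.read_gff(args.data / "genes.gff3")
    per_cond = {}
    all_assignments = []
    with open(args.out / "assignments.tsv", "w") as fh:
        fh.write("condition\tgene_id\tchrom\tsummit\tlocation_class\tdistance\n")
        for cond in CONDITIONS:
            peaks = rio.read_peaks(args.peaks / f"peaks_{cond}.narrowPeak")
            assignments = assign_peaks(list(peaks), annotation)
            all_assignments.extend(assignments)
            for a in assignments:
                fh.write(f"{cond}\t{a.gene_id}\t{a.peak.chrom}\t{a.peak.summit}"
                         f"\t{a.location_class}\t{a.distance}\n")
            gset = GeneSet(cond, {a.gene_id for a in assignments})
            per_cond[cond] = gset
            rio.write_gene_set(gset, args.out / f"targets_{cond}.txt")
            print(f"{cond}: {len(peaks)} peaks -> {len(assignments)} assignments "
                  f"-> {len(gset)} genes")

    union = union_targets(per_cond)
    rio.write_gene_set(union, args.out / "targets_union.txt")
    dist = location_distribution(all_assignments)
    (args.out / "location_distribution.json").write_text(json.dumps(dist, indent=1))
    print(f"union across conditions: {len(union)} unique target genes "
          f"(more genes than peaks when sites sit between divergent pairs)")
    print("binding-location distribution: "
          + ", ".join(f"{k} {100 * v:.0f}%" for k, v in dist.items()))


if __name__ == "__main__":
    main()
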