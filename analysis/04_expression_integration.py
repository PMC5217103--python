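#!/usr/bin/env python
"""Filter the DE table and partition targets into direct and indirect.

Keeps genes changing >= 2-fold with q <= 0.2 in any condition, classifies
them as activated (lower in the deletion strain) or repressed, intersects
with the ChIP target union to split direct from indirect targets, checks the
calls against the planted truth, and exports the log2(FPKM + 1) matrix that
heat maps display.
"""

import argparse
import json
from pathlib import Path

from regulonscope import io as rio
from regulonscope.expression import (
    classify_regulation,
    filter_de,
    log2_matrix,
    partition_direct_indirect,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--targets", type=Path, default=ROOT / "results" / "targets")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "expression")
    ap.add_argument("--min-fold", type=float, default=2.0)
    ap.add_argument("--max-q", type=float, default=0.2)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = rio.read_de_table(args.data / "de_table.tsv")
    truth = {r["gene_id"]: r["label"]
             for r in json.loads((args.data / "truth.json").read_text())["de"]}

    de_set = filter_de(table, args.min_fold, args.max_q)
    calls = classify_regulation(table, de_set, args.min_fold, args.max_q)
    n_act = sum(1 for c in calls if c.direction == "activated")
    agree = sum(1 for c in calls if truth.get(c.gene_id) == c.direction)
    known = sum(1 for c in calls if truth.get(c.gene_id) != "null")
    print(f"{len(de_set)} genes pass >= {args.min_fold}-fold with q <= {args.max_q} "
          f"({n_act} activated, {len(calls) - n_act} repressed)")
    print(f"direction calls agree with planted truth for {agree}/{known} planted genes")

    union = rio.read_gene_set(args.targets / "targets_union.txt")
    direct, indirect = partition_direct_indirect(de_set, union)
    print(f"direct targets (bound + differentially expressed): {len(direct)}; "
          f"indirect (expression change only): {len(indirect)}")

    rio.write_gene_set(de_set, args.out / "de_genes.txt")
    rio.write_gene_set(direct, args.out / "direct_targets.txt")
    rio.write_gene_set(indirect, args.out / "indirect_targets.txt")
    with open(args.out / "regulation_calls.tsv", "w") as fh:
        fh.write("gene_id\tdirection\tcondition\tlog2fc\tis_direct\n")
        for c in sorted(calls, key=lambda c: c.gene_id):
            fh.write(f"{c.gene_id}\t{c.direction}\t{c.condition}\t{c.log2fc:.4f}"
                     f"\t{c.gene_id in direct.members}\n")
    log2_matrix(table, sorted(de_set.members)).to_csv(args.out / "log2_matrix.tsv", sep="\t")


if __name__ == "__main__":
    main()
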