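"""Differential-expression filtering, regulation calls, and direct/indirect partition.

Works on the internal DE schema (one row per gene x condition with columns
gene_id, condition, fpkm_wt, fpkm_mut, log2fc, p, q), where log2fc is
log2(mutant / WT).  A gene *activated* by the factor has lower expression in
the deletion strain, i.e. negative log2fc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneSet

__all__ = [
    "RegulationCall",
    "CONDITION_ORDER",
    "filter_de",
    "classify_regulation",
    "partition_direct_indirect",
    "log2_matrix",
]

CONDITION_ORDER = ("LL0", "LL15", "LL30", "LL60")


def _condition_rank(cond: str) -> tuple[int, str]:
    try:
        return (CONDITION_ORDER.index(cond), cond)
    except ValueError:
        return (len(CONDITION_ORDER), cond)


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    direction: str        # activated | repressed
    is_direct: bool = False
    condition: str = ""   # the condition that determined the direction
    log2fc: float = 0.0


def _check_columns(records: pd.DataFrame) -> None:
    for col in ("gene_id", "condition", "log2fc", "q"):
        if col not in records.columns:
            raise ValueError(f"DE table missing required column {col!r}")


def filter_de(records: pd.DataFrame, min_fold: float = 2.0, max_q: float = 0.2,
              label: str = "de_genes") -> GeneSet:
    """Genes changing >= min_fold with q <= max_q in at least one condition.

    Both thresholds are inclusive; the returned set is the union across
    conditions ("any condition" semantics).
    """
    _check_columns(records)
    if min_fold <= 0:
        raise ValueError("min_fold must be positive")
    lfc_cut = math.log2(min_fold)
    hit = (records["log2fc"].abs() >= lfc_cut) & (records["q"] <= max_q)
    return GeneSet(label=label, members=set(records.loc[hit, "gene_id"]))


def classify_regulation(records: pd.DataFrame, de_set: GeneSet,
                        min_fold: float = 2.0, max_q: float = 0.2,
                        ) -> list[RegulationCall]:
    """Direction of regulation for each filtered gene.

    Taken from the sign of log2fc in the qualifying condition of maximal
    |log2fc| (ties broken by condition order LL0 < LL15 < LL30 < LL60):
    negative (lower in the deletion strain) = activated by the factor,
    positive = repressed.
    """
    _check_columns(records)
    missing = de_set.members - set(records["gene_id"])
    if missing:
        raise ValueError(f"genes absent from records: {sorted(missing)[:5]}")
    lfc_cut = math.log2(min_fold)
    calls = []
    sub = records[records["gene_id"].isin(de_set.members)]
    for gid, rows in sub.groupby("gene_id", sort=True):
        qualifying = rows[(rows["log2fc"].abs() >= lfc_cut) & (rows["q"] <= max_q)]
        if qualifying.empty:  # gene entered the set by other thresholds; use all rows
            qualifying = rows
        ranked = sorted(
            qualifying.itertuples(),
            key=lambda r: (-abs(r.log2fc), _condition_rank(r.condition)),
        )
        top = ranked[0]
        if top.log2fc == 0:
            raise ValueError(f"unclassifiable gene {gid}: log2fc = 0 in qualifying conditions")
        calls.append(RegulationCall(
            gene_id=str(gid),
            direction="activated" if top.log2fc < 0 else "repressed",
            condition=top.condition, log2fc=float(top.log2fc),
        ))
    return calls


def partition_direct_indirect(de_set: GeneSet, chip_union: GeneSet,
                              ) -> tuple[GeneSet, GeneSet]:
    """Direct targets = differentially expressed and bound; indirect = DE only."""
    direct = GeneSet(label="direct", members=de_set.members & chip_union.members)
    indirect = GeneSet(label="indirect", members=de_set.members - chip_union.members)
    assert len(direct) + len(indirect) == len(de_set)
    return direct, indirect


def log2_matrix(records: pd.DataFrame, gene_order: list[str],
                pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(FPKM + pseudocount) matrix: rows = genes (input order preserved),
    columns = genotype x condition — the quantity heat maps display."""
    _check_columns(records)
    for col in ("fpkm_wt", "fpkm_mut"):
        if col not in records.columns:
            raise ValueError(f"DE table missing required column {col!r}")
    present = set(records["gene_id"])
    absent = [g for g in gene_order if g not in present]
    if absent:
        raise ValueError(f"genes absent from records: {absent[:5]}")
    conditions = sorted(records["condition"].unique(), key=_condition_rank)
    wide = records.pivot_table(index="gene_id", columns="condition",
                               values=["fpkm_wt", "fpkm_mut"], aggfunc="first")
    out = pd.DataFrame(index=pd.Index(gene_order, name="gene_id"))
    for geno, col in (("wt", "fpkm_wt"), ("mut", "fpkm_mut")):
        for cond in conditions:
            out[f"{geno}_{cond}"] = np.log2(wide[(col, cond)].reindex(gene_order) + pseudocount)
    return out
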