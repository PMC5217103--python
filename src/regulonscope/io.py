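"""Readers and writers for the standard text formats the pipeline consumes.

Formats: GFF3 (gene annotation, 1-based inclusive on disk), bedGraph
(per-strand coverage, 0-based half-open), ENCODE narrowPeak (peak output),
plain one-gene-per-line lists, CSV time series and tab-delimited
differential-expression tables.  Internal coordinates are always 0-based
half-open; conversion happens here and nowhere else.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CoverageTrack, GeneModel, GenomeAnnotation, GeneSet, PeakRegion, PeakSet, TimeSeries

__all__ = [
    "read_gff",
    "write_gff",
    "read_coverage",
    "read_coverage_tracks",
    "write_bedgraph",
    "write_peaks",
    "read_peaks",
    "read_gene_set",
    "write_gene_set",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_de_table",
    "write_de_table",
    "read_cuffdiff_table",
    "NEGLOG10_CAP",
]

# -log10(0) written as this finite cap in narrowPeak output
NEGLOG10_CAP = 400.0


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> GenomeAnnotation:
    """Read gene models from a GFF3 file.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Chromosome sizes come from ``##sequence-region`` pragmas when present,
    otherwise they are inferred as the maximum gene end per chromosome.
    Features whose type is not in ``feature_types`` are ignored.
    """
    path = Path(path)
    chrom_sizes: dict[str, int] = {}
    declared = False
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(f"{path}:{lineno}: malformed sequence-region pragma")
                chrom_sizes[parts[1]] = int(parts[3])
                declared = True
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            if declared and chrom not in chrom_sizes:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            gene_id = _gff_attr(attrs, "ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: feature lacks an ID attribute")
            genes.append(GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                                   start=start1 - 1, end=end1))
    if not declared:
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes=genes, chrom_sizes=chrom_sizes)


def _gff_attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1:]
    return None


def write_gff(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation as GFF3 (gene features only, with sequence-region pragmas)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in annotation.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tregulonscope\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph coverage


def _read_bedgraph(path: str | Path, chrom_sizes: dict[str, int]
                   ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    path = Path(path)
    vectors = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            chrom, start_s, end_s, value_s = fields[:4]
            if chrom not in chrom_sizes:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            start, end = int(start_s), int(end_s)
            value = int(round(float(value_s)))
            if end > chrom_sizes[chrom]:
                raise ParseError(f"{path}:{lineno}: interval end {end} beyond chromosome end")
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if covered[chrom][start:end].any():
                raise ParseError(f"{path}:{lineno}: overlapping intervals on one strand")
            covered[chrom][start:end] = True
            vectors[chrom][start:end] = value
    # chromosomes with data are reported separately so strand agreement can be checked
    seen = {c: v for c, v in vectors.items() if covered[c].any()}
    return seen, vectors


def read_coverage_tracks(path_fwd: str | Path, path_rev: str | Path,
                         chrom_sizes: dict[str, int]) -> dict[str, CoverageTrack]:
    """Read a forward/reverse bedGraph pair into dense per-base tracks, one per chromosome."""
    fwd_seen, fwd_full = _read_bedgraph(path_fwd, chrom_sizes)
    rev_seen, rev_full = _read_bedgraph(path_rev, chrom_sizes)
    if set(fwd_seen) != set(rev_seen):
        raise ParseError(
            f"strand tracks disagree: forward covers {sorted(fwd_seen)}, reverse covers {sorted(rev_seen)}"
        )
    return {
        c: CoverageTrack(chrom=c, fwd=fwd_full[c], rev=rev_full[c]) for c in sorted(fwd_seen)
    }


def read_coverage(path_fwd: str | Path, path_rev: str | Path,
                  chrom_sizes: dict[str, int]) -> CoverageTrack:
    """Single-chromosome convenience wrapper around :func:`read_coverage_tracks`."""
    tracks = read_coverage_tracks(path_fwd, path_rev, chrom_sizes)
    if len(tracks) != 1:
        raise ParseError(f"expected a single chromosome, found {sorted(tracks)}")
    return next(iter(tracks.values()))


def write_bedgraph(values_by_chrom: dict[str, np.ndarray], path: str | Path) -> None:
    """Write dense per-base vectors as run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(values_by_chrom):
            v = np.asarray(values_by_chrom[chrom])
            if len(v) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(v)]))
            for s, e in zip(starts, ends):
                val = int(v[s])
                if val != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")


# ---------------------------------------------------------------------------
# narrowPeak


def _neglog10(p: float) -> float:
    if p <= 0.0:
        return NEGLOG10_CAP
    return min(-math.log10(p), NEGLOG10_CAP)


def write_peaks(peaks: Iterable[PeakRegion], path: str | Path) -> None:
    """Write peaks in ENCODE narrowPeak format.

    col7 = signal (mean combined coverage), col8 = -log10 p, col9 = -log10 q,
    col10 = summit offset from chromStart.
    """
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        f"peak_{i + 1}",
                        "0",
                        ".",
                        f"{p.signal:.6g}",
                        f"{_neglog10(p.min_p):.6g}",
                        f"{_neglog10(p.q):.6g}" if not math.isnan(p.q) else "-1",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


def read_peaks(path: str | Path) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ParseError(f"{path}:{lineno}: expected 10 narrowPeak fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            signal = float(fields[6])
            min_p = 10.0 ** (-float(fields[7]))
            q = float("nan") if fields[8] == "-1" else 10.0 ** (-float(fields[8]))
            summit = start + int(fields[9])
            peaks.append(
                PeakRegion(chrom=chrom, start=start, end=end, summit=summit,
                           min_p=min(min_p, 1.0), q=q if math.isnan(q) else min(q, 1.0),
                           signal=signal, passed_shift=True)
            )
    return PeakSet(peaks)


# ---------------------------------------------------------------------------
# gene sets, time series, DE tables


def read_gene_set(path: str | Path, label: str | None = None) -> GeneSet:
    """Read a one-gene-id-per-line text file."""
    path = Path(path)
    members = set()
    with open(path) as fh:
        for raw in fh:
            gid = raw.strip()
            if gid and not gid.startswith("#"):
                members.add(gid)
    return GeneSet(label=label or path.stem, members=members)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(gene_set.members):
            fh.write(gid + "\n")


def read_timeseries_csv(path: str | Path) -> list[TimeSeries]:
    """Read a plate-reader-style CSV with columns time_h, value, replicate."""
    df = pd.read_csv(path)
    required = {"time_h", "value", "replicate"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for rep, sub in df.groupby("replicate", sort=True):
        sub = sub.sort_values("time_h")
        out.append(TimeSeries(t=sub["time_h"].to_numpy(), y=sub["value"].to_numpy(),
                              replicate_id=str(rep)))
    return out


def write_timeseries_csv(series: Sequence[TimeSeries], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_h", "value", "replicate"])
        for ts in series:
            for t, y in zip(ts.t, ts.y):
                w.writerow([f"{t:.6g}", f"{y:.10g}", ts.replicate_id])


DE_COLUMNS = ["gene_id", "condition", "fpkm_wt", "fpkm_mut", "log2fc", "p", "q"]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read the internal tab-delimited DE schema (one row per gene x condition)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing DE columns {missing}")
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_cuffdiff_table(path: str | Path, condition: str,
                        mutant_is_sample_2: bool = True) -> pd.DataFrame:
    """Convert a Cuffdiff gene_exp.diff-style table into the internal DE schema.

    Cuffdiff reports log2(value_2/value_1).  ``mutant_is_sample_2`` states the
    orientation of the comparison; flip it if the deletion strain was sample_1,
    so that internal log2fc is always log2(mutant/WT).
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "value_1", "value_2", "log2(fold_change)", "p_value", "q_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing Cuffdiff columns {missing}")
    sign = 1.0 if mutant_is_sample_2 else -1.0
    wt_col, mut_col = ("value_1", "value_2") if mutant_is_sample_2 else ("value_2", "value_1")
    return pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "condition": condition,
            "fpkm_wt": df[wt_col],
            "fpkm_mut": df[mut_col],
            "log2fc": sign * df["log2(fold_change)"],
            "p": df["p_value"],
            "q": df["q_value"],
        }
    )
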