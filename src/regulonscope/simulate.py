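"""Synthetic data generators for end-to-end testing of the pipeline.

Emulates the statistical structure of the study inputs: a compact annotated
genome with divergently transcribed gene pairs, stranded ChIP coverage with an
i.i.d. lognormal background and planted strand-shifted binding peaks,
WT-vs-deletion differential-expression tables with planted >= 2-fold effects,
and damped, trending sinusoidal reporter-luminescence series sampled every
1.5 h.  Every generator is deterministic under a fixed seed, and each dataset
comes with its planted truth so downstream recovery tests are self-contained.

What this emulates and what it does not: the background is i.i.d. per base
(matching the peak caller's modeling assumption; real coverage is
autocorrelated), genes are single intervals, and the internal DE test is a
plain two-sample t-test on log2(FPKM + 1) that exists only so synthetic tables
carry coherent p/q columns.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import false_discovery_control

from .core import CoverageTrack, GeneModel, GenomeAnnotation, TimeSeries

__all__ = [
    "SimConfig",
    "LuciferaseConfig",
    "PeakTruth",
    "simulate_annotation",
    "plant_peak_truths",
    "simulate_chip_coverage",
    "simulate_de_table",
    "simulate_luciferase",
    "write_dataset",
]

DE_CONDITIONS = ("LL0", "LL15", "LL60")


@dataclass
class LuciferaseConfig:
    """Reporter-trace generator settings (hours / arbitrary luminescence units)."""

    period_h: float = 22.0       # free-running period of the organism's clock
    phase_h: float = 16.0        # time of first oscillation peak
    amplitude: float = 100.0
    damping_per_h: float = 0.005  # exponential amplitude decay toward the end of runs
    trend_per_h: float = -0.5    # slow baseline drift
    baseline: float = 500.0
    noise_sd: float = 10.0
    sampling_h: float = 1.5      # plate-reader recordings every 90 min
    duration_h: float = 114.0    # ~4.75 d in constant darkness
    n_replicates: int = 12


@dataclass
class PeakTruth:
    """A planted binding site: fragment pileups offset by ``fragment_offset`` bp."""

    chrom: str
    center: int
    fragment_offset: int = 70
    n_fragments: int = 600
    assigned_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        if self.fragment_offset < 0:
            raise ValueError("fragment_offset must be non-negative")


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 50
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chrI": 500_000, "chrII": 400_000})
    gene_len_range: tuple[int, int] = (1000, 3000)
    min_spacing: int = 12_000          # bp between placed genes/pairs
    divergent_fraction: float = 0.2    # fraction of genes in head-to-head pairs with TSSs < 5 kb apart
    background_mu: float = 3.0         # ln-scale lognormal background (median ~20x coverage)
    background_sigma: float = 0.5
    n_peaks: int = 20
    peak_height: float = 30.0          # planted summit height in multiples of the background median
    fragment_offset: int = 70          # fwd/rev coverage-mode separation d, bp
    fragment_jitter_sd: float = 35.0   # positional jitter of each fragment's anchors, bp
    read_len: int = 50
    de_fraction: float = 0.2
    de_log2fc_mean: float = 2.0
    de_log2fc_sd: float = 0.25
    de_noise_sd: float = 0.25          # replicate noise on the log2 scale
    peak_height_log_sd: float = 0.5    # per-peak strength spread (ln-scale); real sites vary widely
    de_baseline_mu: float = 4.0        # ln-scale lognormal baseline FPKM
    de_baseline_sigma: float = 1.0
    luciferase: LuciferaseConfig = field(default_factory=LuciferaseConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.background_sigma <= 0 or self.peak_height < 0:
            raise ValueError("scale parameters must be positive")
        if self.luciferase.sampling_h <= 0:
            raise ValueError("sampling_h must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic sub-generator: one named stream per generator function."""
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(cfg: SimConfig) -> GenomeAnnotation:
    """Place non-overlapping genes with >= min_spacing bp between placements.

    A ``divergent_fraction`` of genes come as head-to-head pairs (a - strand
    gene followed by a + strand gene) whose TSSs face each other across an
    intergenic gap < 5 kb, so one upstream peak can be assigned to both.
    """
    rng = cfg.rng("annotation")
    n_pairs = int(round(cfg.divergent_fraction * cfg.n_genes / 2))
    n_singles = cfg.n_genes - 2 * n_pairs
    # interleave pairs among singles deterministically
    placements = ["pair"] * n_pairs + ["single"] * n_singles
    rng.shuffle(placements)

    chroms = sorted(cfg.chrom_sizes)
    total = sum(cfg.chrom_sizes.values())
    genes: list[GeneModel] = []
    gi = 0
    pi = 0
    for chrom in chroms:
        share = round(len(placements) * cfg.chrom_sizes[chrom] / total)
        todo = placements[pi:pi + share] if chrom != chroms[-1] else placements[pi:]
        pi += len(todo)
        pos = int(rng.integers(2000, 5000))
        size = cfg.chrom_sizes[chrom]
        for kind in todo:
            glen = int(rng.integers(*cfg.gene_len_range))
            if kind == "single":
                strand = "+" if rng.random() < 0.5 else "-"
                end = pos + glen
                if end > size:
                    raise ValueError(
                        f"cannot place {cfg.n_genes} genes with {cfg.min_spacing} bp "
                        f"spacing in {total} bp of sequence"
                    )
                gi += 1
                genes.append(GeneModel(f"g{gi:04d}", chrom, strand, pos, end))
                pos = end + cfg.min_spacing
            else:
                glen2 = int(rng.integers(*cfg.gene_len_range))
                gap = int(rng.integers(500, 4500))  # TSS-to-TSS distance < 5 kb
                end2 = pos + glen + gap + glen2
                if end2 > size:
                    raise ValueError(
                        f"cannot place {cfg.n_genes} genes with {cfg.min_spacing} bp "
                        f"spacing in {total} bp of sequence"
                    )
                gi += 1
                genes.append(GeneModel(f"g{gi:04d}", chrom, "-", pos, pos + glen))
                gi += 1
                genes.append(GeneModel(f"g{gi:04d}", chrom, "+", pos + glen + gap, end2))
                pos = end2 + cfg.min_spacing
    if gi != cfg.n_genes:
        raise ValueError("internal packing error: gene count mismatch")
    return GenomeAnnotation(genes=genes, chrom_sizes=dict(cfg.chrom_sizes))


# ---------------------------------------------------------------------------
# ChIP coverage


def plant_peak_truths(annotation: GenomeAnnotation, cfg: SimConfig,
                      up_bp: int = 5000, down_bp: int = 3000,
                      location_probs: tuple[float, float, float] = (0.67, 0.31, 0.02),
                      ) -> list[PeakTruth]:
    """Choose planted binding-site positions relative to genes.

    Sites are placed upstream of the TSS, downstream of the TES, or inside the
    gene span with the given probabilities (defaults emulate the binding-site
    location distribution of a typical promoter-binding factor).
    ``assigned_gene_ids`` lists every gene whose assignment window contains
    the center, including both members of divergent pairs.
    """
    rng = cfg.rng("truths")
    if cfg.n_peaks > len(annotation.genes):
        raise ValueError("n_peaks exceeds the number of genes to anchor them to")
    chosen = rng.choice(len(annotation.genes), size=cfg.n_peaks, replace=False)
    median_bg = math.exp(cfg.background_mu)
    # 0.7 ~ fraction of fragments whose reads overlap the combined-coverage mode
    base_frag = cfg.peak_height * median_bg / 0.7
    if round(base_frag) == 0:
        return []  # zero-height peaks leave the background untouched
    truths = []
    for idx in sorted(chosen.tolist()):
        g = annotation.genes[idx]
        n_frag = max(1, int(round(base_frag * rng.lognormal(0.0, cfg.peak_height_log_sd))))
        loc = rng.choice(3, p=location_probs)
        margin = cfg.fragment_offset + 2 * int(cfg.fragment_jitter_sd) + cfg.read_len
        if loc == 0:  # upstream of TSS
            d = int(rng.integers(200, min(up_bp, 4000)))
            center = g.tss - d if g.strand == "+" else g.tss + d
        elif loc == 1:  # downstream of TES
            d = int(rng.integers(200, min(down_bp, 2500)))
            center = g.tes + d if g.strand == "+" else g.tes - d
        else:  # genic
            center = (g.start + g.end) // 2
        size = annotation.chrom_sizes[g.chrom]
        center = int(np.clip(center, margin, size - margin - 1))
        assigned = tuple(
            sorted(h.gene_id for h in annotation.genes
                   if h.chrom == g.chrom and _in_window(center, h, up_bp, down_bp))
        )
        truths.append(PeakTruth(chrom=g.chrom, center=center,
                                fragment_offset=cfg.fragment_offset,
                                n_fragments=n_frag, assigned_gene_ids=assigned))
    return truths


def _in_window(pos: int, g: GeneModel, up_bp: int, down_bp: int) -> bool:
    if g.start <= pos < g.end:
        return True
    if g.strand == "+":
        if pos < g.start:
            return g.start - pos <= up_bp
        return pos - (g.end - 1) <= down_bp
    if pos > g.end - 1:
        return pos - (g.end - 1) <= up_bp
    return g.start - pos <= down_bp


def simulate_chip_coverage(annotation: GenomeAnnotation, truths: list[PeakTruth],
                           cfg: SimConfig, stream: str = "chip",
                           ) -> dict[str, CoverageTrack]:
    """Stranded coverage: i.i.d. rounded-lognormal background plus planted peaks.

    Background: each base's combined coverage is round(LogNormal(mu, sigma)),
    split binomially between strands.  Peaks: each of ``n_fragments``
    fragments adds one forward read whose coverage is centered (read extended
    symmetrically about its anchor) at N(center - d/2, jitter) and one reverse
    read centered at N(center + d/2, jitter), so the fwd/rev coverage modes
    sit d bp apart — the signature the shift filter tests.
    """
    rng = cfg.rng(stream)
    tracks: dict[str, CoverageTrack] = {}
    half = cfg.read_len // 2
    for chrom in sorted(annotation.chrom_sizes):
        size = annotation.chrom_sizes[chrom]
        background = np.rint(rng.lognormal(cfg.background_mu, cfg.background_sigma, size)
                             ).astype(np.int64)
        fwd = rng.binomial(background, 0.5)
        rev = background - fwd
        for t in truths:
            if t.chrom != chrom:
                continue
            d = t.fragment_offset
            fa = np.rint(rng.normal(t.center - d / 2, cfg.fragment_jitter_sd, t.n_fragments)
                         ).astype(np.int64)
            ra = np.rint(rng.normal(t.center + d / 2, cfg.fragment_jitter_sd, t.n_fragments)
                         ).astype(np.int64)
            _add_reads(fwd, fa - half, cfg.read_len, size)
            _add_reads(rev, ra - half, cfg.read_len, size)
        tracks[chrom] = CoverageTrack(chrom=chrom, fwd=fwd, rev=rev)
    return tracks


def _add_reads(cover: np.ndarray, starts: np.ndarray, read_len: int, size: int) -> None:
    """Increment coverage over [start, start + read_len) per read, via a diff array."""
    starts = np.clip(starts, 0, size - read_len)
    delta = np.zeros(size + 1, dtype=np.int64)
    np.add.at(delta, starts, 1)
    np.add.at(delta, starts + read_len, -1)
    cover += np.cumsum(delta[:-1])


# ---------------------------------------------------------------------------
# differential expression


def simulate_de_table(annotation: GenomeAnnotation, cfg: SimConfig,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """WT-vs-deletion DE table over LL0/LL15/LL60 plus planted truth labels.

    Baseline FPKMs are lognormal; a ``de_fraction`` of genes get a planted
    |log2 fold change| ~ N(de_log2fc_mean, de_log2fc_sd) with random sign in a
    random non-empty subset of conditions.  Two replicates per genotype carry
    multiplicative noise; p comes from a two-sample t-test on log2(FPKM + 1)
    and q from BH within each condition.  log2fc is log2(mutant / WT), so
    genes *activated* by the factor (lower in the deletion strain) have
    negative planted log2fc.

    Returns (table, truth) where truth has columns gene_id, label
    (activated / repressed / null) and planted_log2fc.
    """
    rng = cfg.rng("de")
    gene_ids = [g.gene_id for g in annotation.genes]
    n = len(gene_ids)
    n_de = int(round(cfg.de_fraction * n))
    if cfg.de_fraction > 0 and n_de < 1:
        raise ValueError("de_fraction * n_genes must be >= 1 when de_fraction > 0")
    de_idx = set(rng.choice(n, size=n_de, replace=False).tolist())

    baseline = rng.lognormal(cfg.de_baseline_mu, cfg.de_baseline_sigma, n)
    labels = np.array(["null"] * n, dtype=object)
    planted = np.zeros(n)
    cond_mask = np.zeros((n, len(DE_CONDITIONS)), dtype=bool)
    for i in range(n):
        if i in de_idx:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            planted[i] = sign * rng.normal(cfg.de_log2fc_mean, cfg.de_log2fc_sd)
            labels[i] = "repressed" if sign > 0 else "activated"
            m = rng.random(len(DE_CONDITIONS)) < 0.6
            if not m.any():
                m[rng.integers(len(DE_CONDITIONS))] = True
            cond_mask[i] = m

    rows = []
    for j, cond in enumerate(DE_CONDITIONS):
        effect = np.where(cond_mask[:, j], planted, 0.0)
        wt_reps = np.empty((n, 2))
        mut_reps = np.empty((n, 2))
        for r in range(2):
            wt_reps[:, r] = np.log2(baseline + 1) + rng.normal(0, cfg.de_noise_sd, n)
            mut_reps[:, r] = np.log2(baseline + 1) + effect + rng.normal(0, cfg.de_noise_sd, n)
        tstat, p = stats.ttest_ind(mut_reps, wt_reps, axis=1)
        p = np.nan_to_num(p, nan=1.0)
        q = false_discovery_control(p, method="bh")
        fpkm_wt = np.exp2(wt_reps).mean(axis=1) - 1
        fpkm_mut = np.exp2(mut_reps).mean(axis=1) - 1
        log2fc = mut_reps.mean(axis=1) - wt_reps.mean(axis=1)
        rows.append(pd.DataFrame({
            "gene_id": gene_ids, "condition": cond,
            "fpkm_wt": np.maximum(fpkm_wt, 0.0), "fpkm_mut": np.maximum(fpkm_mut, 0.0),
            "log2fc": log2fc, "p": p, "q": q,
        }))
    table = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({"gene_id": gene_ids, "label": labels, "planted_log2fc": planted})
    return table, truth


# ---------------------------------------------------------------------------
# luciferase


def simulate_luciferase(cfg: SimConfig,
                        truth: dict | None = None) -> tuple[list[TimeSeries], dict]:
    """Damped, trending sinusoidal reporter traces.

    y(t) = c + m*t + A*exp(-lambda*t)*sin(2*pi*(t - phi)/T) + eps,
    eps ~ N(0, noise_sd), sampled every ``sampling_h`` for ``duration_h``
    (inclusive of both endpoints).  Returns the replicate list and the truth
    parameters used.
    """
    lc = cfg.luciferase
    rng = cfg.rng("luciferase")
    params = {
        "T": lc.period_h, "phi": lc.phase_h, "A": lc.amplitude,
        "c": lc.baseline, "m": lc.trend_per_h, "damping": lc.damping_per_h,
    }
    if truth:
        params.update(truth)
    n_samples = int(math.floor(lc.duration_h / lc.sampling_h + 1e-9)) + 1
    t = np.arange(n_samples) * lc.sampling_h
    series = []
    for r in range(lc.n_replicates):
        clean = (params["c"] + params["m"] * t
                 + params["A"] * np.exp(-params["damping"] * t)
                 * np.sin(2 * np.pi * (t - params["phi"]) / params["T"]))
        y = clean + rng.normal(0, lc.noise_sd, n_samples) if lc.noise_sd > 0 else clean
        series.append(TimeSeries(t=t, y=y, replicate_id=f"rep{r + 1:02d}"))
    return series, params


# ---------------------------------------------------------------------------
# dataset export


def write_dataset(out_dir: str | Path, cfg: SimConfig,
                  conditions: tuple[str, ...] = ("LL0", "LL15", "LL60")) -> dict:
    """Generate and write a full synthetic dataset (GFF3, bedGraph pairs per
    condition, DE TSV, luciferase CSV) plus a truth JSON; returns the truth."""
    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(cfg)
    rio.write_gff(annotation, out / "genes.gff3")
    truths = plant_peak_truths(annotation, cfg)
    for cond in conditions:
        tracks = simulate_chip_coverage(annotation, truths, cfg, stream=f"chip:{cond}")
        rio.write_bedgraph({c: tr.fwd for c, tr in tracks.items()}, out / f"{cond}_fwd.bedgraph")
        rio.write_bedgraph({c: tr.rev for c, tr in tracks.items()}, out / f"{cond}_rev.bedgraph")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for c, s in sorted(annotation.chrom_sizes.items()):
            fh.write(f"{c}\t{s}\n")
    de_table, de_truth = simulate_de_table(annotation, cfg)
    rio.write_de_table(de_table, out / "de_table.tsv")
    series, luc_truth = simulate_luciferase(cfg)
    rio.write_timeseries_csv(series, out / "luciferase.csv")
    truth = {
        "seed": cfg.seed,
        "peaks": [asdict(t) for t in truths],
        "de": de_truth.to_dict(orient="records"),
        "luciferase": luc_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
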