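"""End-to-end orchestration: simulate -> call peaks -> assign targets ->
filter DE -> rhythm analysis -> set integration, with a machine-readable
report of the counts surviving every stage.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .core import GeneSet
from . import io as rio
from . import expression, rhythm, sets, targets
from .peaks import PeakCallerConfig, call_peaks, fit_background, score_positions, merge_regions
from .simulate import SimConfig, plant_peak_truths, simulate_annotation, \
    simulate_chip_coverage, simulate_de_table, simulate_luciferase

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    conditions: tuple[str, ...] = ("LL0", "LL15", "LL60")
    up_bp: int = 5000
    down_bp: int = 3000
    min_fold: float = 2.0
    max_q: float = 0.2
    drop_before_h: float = 24.0
    rhythm_threshold: float = 0.95
    period_bounds: tuple[float, float] = (16.0, 32.0)
    light_in_targets: float = 0.30   # membership rates used to simulate the
    clock_in_targets: float = 0.26   # light-regulated / clock-controlled lists
    light_background: float = 0.10
    clock_background: float = 0.15
    sim: SimConfig = field(default_factory=SimConfig)
    caller: PeakCallerConfig = field(default_factory=PeakCallerConfig)

    def __post_init__(self) -> None:
        self.sim.seed = self.seed


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; missing keys take defaults."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**raw.pop("sim", {}))
    caller = PeakCallerConfig(**raw.pop("caller", {}))
    cfg = PipelineConfig(sim=sim, caller=caller, **raw)
    return cfg


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic-data pipeline; returns and writes the report.

    Writes all stage outputs under ``cfg.out_dir`` plus ``report.json`` and
    ``report.md``.  The report lists the counts surviving every filter, which
    are mutually consistent (later counts never exceed their predecessors
    where a stage only filters).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}

    # --- simulate ---------------------------------------------------------
    try:
        annotation = simulate_annotation(cfg.sim)
        rio.write_gff(annotation, out / "genes.gff3")
        truths = plant_peak_truths(annotation, cfg.sim, cfg.up_bp, cfg.down_bp)
        de_table, de_truth = simulate_de_table(annotation, cfg.sim)
        rio.write_de_table(de_table, out / "de_table.tsv")
        series, luc_truth = simulate_luciferase(cfg.sim)
        rio.write_timeseries_csv(series, out / "luciferase.csv")
        _log("simulate", f"{len(annotation.genes)} genes, {len(truths)} planted peaks, "
                         f"{len(series)} reporter replicates")
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    report["stages"]["simulate"] = {
        "n_genes": len(annotation.genes),
        "n_planted_peaks": len(truths),
        "n_replicates": len(series),
    }

    # --- callpeaks (per condition) ---------------------------------------
    per_condition_sets: dict[str, GeneSet] = {}
    peak_stage: dict = {}
    peaksets = {}
    trackmaps = {}
    try:
        for cond in cfg.conditions:
            tracks = simulate_chip_coverage(annotation, truths, cfg.sim, stream=f"chip:{cond}")
            trackmaps[cond] = tracks
            track_list = [tracks[c] for c in sorted(tracks)]
            bg = fit_background(track_list)
            n_enriched = 0
            n_candidates = 0
            for tr in track_list:
                mask = score_positions(tr, bg, cfg.caller.alpha_position)
                n_enriched += int(mask.sum())
                n_candidates += len(merge_regions(mask, cfg.caller))
            peaks = call_peaks(track_list, cfg.caller, bg=bg)
            peaksets[cond] = peaks
            rio.write_peaks(peaks, out / f"peaks_{cond}.narrowPeak")
            peak_stage[cond] = {
                "positions_enriched": n_enriched,
                "candidate_regions": n_candidates,
                "retained_peaks": len(peaks),
            }
            _log("callpeaks", f"{cond}: {n_enriched} enriched positions -> "
                              f"{n_candidates} candidates -> {len(peaks)} peaks")
    except Exception as exc:
        raise StageError("callpeaks", exc) from exc
    report["stages"]["callpeaks"] = peak_stage

    # --- assign -----------------------------------------------------------
    try:
        assign_stage = {}
        all_assignments = []
        for cond in cfg.conditions:
            assignments = targets.assign_peaks(list(peaksets[cond]), annotation,
                                               cfg.up_bp, cfg.down_bp)
            all_assignments.extend(assignments)
            gset = GeneSet(label=f"targets_{cond}",
                           members={a.gene_id for a in assignments})
            per_condition_sets[cond] = gset
            rio.write_gene_set(gset, out / f"targets_{cond}.txt")
            assign_stage[cond] = {"assignments": len(assignments), "genes": len(gset)}
        chip_union = targets.union_targets(per_condition_sets)
        rio.write_gene_set(chip_union, out / "targets_union.txt")
        location = (targets.location_distribution(all_assignments)
                    if all_assignments else {})
        _log("assign", f"union of {len(chip_union)} target genes")
    except Exception as exc:
        raise StageError("assign", exc) from exc
    report["stages"]["assign"] = {
        "per_condition": assign_stage,
        "union_size": len(chip_union),
        "location_distribution": location,
    }

    # --- defilter ---------------------------------------------------------
    try:
        de_set = expression.filter_de(de_table, cfg.min_fold, cfg.max_q)
        calls = expression.classify_regulation(de_table, de_set, cfg.min_fold, cfg.max_q)
        direct, indirect = expression.partition_direct_indirect(de_set, chip_union)
        n_act = sum(1 for c in calls if c.direction == "activated")
        rio.write_gene_set(de_set, out / "de_genes.txt")
        rio.write_gene_set(direct, out / "direct_targets.txt")
        rio.write_gene_set(indirect, out / "indirect_targets.txt")
        matrix = expression.log2_matrix(de_table, sorted(de_set.members))
        matrix.to_csv(out / "log2_matrix.tsv", sep="\t")
        _log("defilter", f"{len(de_set)} DE genes ({n_act} activated, "
                         f"{len(calls) - n_act} repressed); "
                         f"{len(direct)} direct / {len(indirect)} indirect")
    except Exception as exc:
        raise StageError("defilter", exc) from exc
    report["stages"]["defilter"] = {
        "de_genes": len(de_set),
        "activated": n_act,
        "repressed": len(calls) - n_act,
        "direct": len(direct),
        "indirect": len(indirect),
    }

    # --- rhythm -----------------------------------------------------------
    try:
        rcalls = []
        for ts in series:
            pre = rhythm.preprocess(ts, cfg.drop_before_h)
            rcalls.append(rhythm.rhythm_test(pre, cfg.rhythm_threshold, cfg.period_bounds))
        summary = rhythm.summarize_replicates(rcalls)
        _log("rhythm", f"{summary['n_rhythmic']}/{summary['n_total']} rhythmic, "
                       f"period {summary['mean_period']:.2f} +/- {summary['sd_period']:.2f} h")
    except Exception as exc:
        raise StageError("rhythm", exc) from exc
    report["stages"]["rhythm"] = {
        "n_rhythmic": summary["n_rhythmic"],
        "n_total": summary["n_total"],
        "mean_period_h": summary["mean_period"],
        "sd_period_h": summary["sd_period"],
        "mean_phase_h": summary["mean_phase"],
    }

    # --- integrate --------------------------------------------------------
    try:
        rng = cfg.sim.rng("membership")
        light, clock = set(), set()
        for g in annotation.genes:
            in_t = g.gene_id in chip_union.members
            if rng.random() < (cfg.light_in_targets if in_t else cfg.light_background):
                light.add(g.gene_id)
            if rng.random() < (cfg.clock_in_targets if in_t else cfg.clock_background):
                clock.add(g.gene_id)
        light_set = GeneSet("light_regulated", light)
        clock_set = GeneSet("clock_controlled", clock)
        rio.write_gene_set(light_set, out / "light_regulated.txt")
        rio.write_gene_set(clock_set, out / "clock_controlled.txt")
        focal = chip_union if len(chip_union) else GeneSet("all", annotation.gene_ids())
        part = sets.partition_membership(focal, light_set, clock_set)
        population = GeneSet("genome", annotation.gene_ids())
        term_map = {"light_regulated": light, "clock_controlled": clock}
        enrich = sets.hypergeom_enrichment(focal, population, term_map)
        r2 = float("nan")
        if len(cfg.conditions) >= 2:
            c1, c2 = cfg.conditions[0], cfg.conditions[1]
            if len(peaksets[c1]) or len(peaksets[c2]):
                r2 = sets.peak_set_correlation(list(peaksets[c1]), list(peaksets[c2]),
                                               trackmaps[c1], trackmaps[c2])
        _log("integrate", f"partition {part.counts}; replicate R^2 = {r2:.3f}")
    except Exception as exc:
        raise StageError("integrate", exc) from exc
    report["stages"]["integrate"] = {
        "partition_counts": part.counts,
        "partition_pct": part.percentages,
        "enrichment": [asdict(e) for e in enrich],
        "replicate_r2": r2,
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _write_markdown(report, out / "report.md")
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Pipeline report", ""]
    lines.append(f"Seed: {report['seed']}")
    for stage, payload in report["stages"].items():
        lines.append("")
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(payload, indent=1, sort_keys=True))
        lines.append("```")
    path.write_text("\n".join(lines) + "\n")
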