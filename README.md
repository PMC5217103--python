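# regulonscope

Tools for mapping the regulon of a light-responsive, clock-controlled
transcription factor — the analysis style used for *Neurospora crassa* ADV-1,
a WCC-downstream TF whose binding and regulatory output were profiled by
ChIP-seq and RNA-seq across dark and light conditions, with circadian output
assayed by luciferase reporters.

The package implements the full computational chain as a tested library plus
numbered analysis drivers:

1. **Peak calling** — per-base combined (fwd + rev) ChIP coverage is scored
   against a lognormal background, ln *X* ~ N(μ, σ) fitted to
   positive-coverage bases. Positions with upper-tail *P* ≤ 0.01 are enriched;
   maximal enriched runs > 100 bp become candidate regions; candidates are
   ranked by their minimum per-position *p*, Benjamini–Hochberg adjusted, and
   kept at *q* < 0.01. Because true binding sites show a forward→reverse
   pileup offset at the sequencing-fragment scale, a cross-correlation filter
   additionally requires a lag ≥ 60 bp.
2. **Target assignment** — a peak summit is assigned to every gene for which
   it lies ≤ 5 kb upstream of the TSS, ≤ 3 kb downstream of the TES, or
   inside the gene body (strand-aware, inclusive); one summit between two
   divergently transcribed genes counts for both. Per-condition target sets
   are unioned across conditions.
3. **Expression integration** — genes changing ≥ 2-fold with *q* ≤ 0.2 in any
   condition are kept; negative log2(mutant/WT) means the factor *activates*
   the gene. Intersecting with the ChIP union splits direct from indirect
   targets.
4. **Rhythm analysis** — reporter traces lose their first day, are detrended
   by a 24 h centered moving average, and are fitted with a line (k = 3) and
   a sinusoid y = c + A·sin(2π(t − φ)/T) (k = 5). The models are compared by
   AICc; the sine model's Akaike weight is read as the probability that a
   sine fits better than a line, with rhythmic meaning weight ≥ 0.95.
5. **Set integration** — four-way light × clock membership partitions,
   hypergeometric over-representation tests with BH correction, and peak-set
   reproducibility as R² of log2 coverage sums over the union of peak
   intervals.

A synthetic-data module generates annotated toy genomes, stranded coverage
with an i.i.d. lognormal background and planted strand-shifted peaks, DE
tables with planted ≥ 2-fold effects, and damped trending sinusoidal
luminescence series — each with its planted truth, so every stage is tested
end to end by recovery, calibration, and oracle-equivalence tests.

## Worked example

```bash
python analysis/01_simulate_data.py --seed 1
python analysis/02_call_peaks.py
python analysis/03_assign_targets.py
python analysis/04_expression_integration.py
python analysis/05_rhythm_analysis.py
python analysis/06_set_integration.py --seed 1
```

prints (seed 1):

```
LL0: 9451 enriched positions -> 20 candidates -> 20 peaks; 20/20 planted sites recovered
...
union across conditions: 21 unique target genes (more genes than peaks when sites sit between divergent pairs)
binding-location distribution: upstream 55%, downstream 40%, genic 5%
7 genes pass >= 2.0-fold with q <= 0.2 (5 activated, 2 repressed)
direct targets (bound + differentially expressed): 2; indirect (expression change only): 5
12/12 replicates rhythmic at weight >= 0.95
period 21.88 +/- 0.07 h (planted 22.0 h); circular mean phase 21.6 h
target partition: both 14%, light_only 14%, clock_only 14%, neither 57%
peak-coverage reproducibility between LL0 and LL15: R^2 = 1.000
```

Reading this: all 20 planted binding sites are called in every condition with
no false positives; the union of per-condition targets (21 genes) exceeds the
peak count because sites between divergent gene pairs regulate two genes; of
the differentially expressed genes, those also bound are the factor's direct
targets; the reporter's 22 h planted free-running period is recovered within
the replicate scatter (the small downward bias comes from fitting a plain
sine to a damped trace); and peak coverage is nearly perfectly reproducible
between conditions sharing the same binding sites.

The same stages are available as a CLI (`regulonscope simulate | callpeaks |
assign | defilter | rhythm | integrate | enrich | run`) operating on standard
formats: GFF3, bedGraph, ENCODE narrowPeak, tab-delimited DE tables
(Cuffdiff-style input supported), plate-reader CSV, and one-gene-per-line
lists.

## Layout

```
src/regulonscope/   library: core, io, simulate, peaks, targets,
                    expression, rhythm, sets, pipeline, cli
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit, property, acceptance)
docs/methods.md     modeling assumptions, parameter choices, limitations
```
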