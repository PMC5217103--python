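# Methods

## Peak calling

**Model.** The background of a ChIP sample's per-base combined (fwd + rev)
coverage is lognormal: ln X ~ N(μ, σ), with μ and σ the sample mean and
standard deviation (ddof = 1) of ln(coverage) over positive-coverage bases,
pooled across the sample's chromosomes. The lognormal has support (0, ∞), so
zero-coverage bases are excluded from the fit and are unenriched by
definition. A fit with σ < 1e-6 is flagged degenerate and scoring refuses to
proceed (a quantile-threshold fallback is the caller's job, not silently
substituted). Fitting requires ≥ 1000 positive bases.

**Scoring and regions.** A position is enriched iff its coverage c > 0 and
P(X ≥ c) ≤ α (default 0.01). Coverage is integer-valued and the tail
probability is monotone in it, so scoring thresholds the unique coverage
values. Candidate regions are maximal runs of enriched positions strictly
longer than 100 bp. Gap-bridging between runs is available
(`max_merge_gap`), but the default is 0: "a region of enrichment" is read as
a contiguous run. With bridging at the fragment scale, i.i.d.-noise chains
longer than 100 bp become common enough that, combined with the min-p region
statistic below, pure background would yield spurious calls; contiguous runs
of > 100 positions each individually in the 1% tail essentially never occur
by chance.

**FDR.** The region statistic is the minimum per-position tail probability
(equal to the tail probability of the region's maximum coverage). Candidates
are Benjamini–Hochberg adjusted across the whole sample and kept at
q < 0.01. BH is the standard choice where only an FDR level is specified.
The background is fitted per sample (all chromosomes pooled); per-chromosome
fitting can be had by calling the fitter per track.

**Shift filter.** True binding sites produce forward- and reverse-strand
pileups offset by roughly the sequencing-fragment size, while symmetric
artifacts do not. For each FDR-passing region, the region ± 500 bp (clipped
at chromosome ends) is scanned for the lag ℓ ∈ [0, 300] maximizing the
Pearson correlation of fwd(x) with rev(x + ℓ), leftmost lag on ties. The
region is kept iff ℓ ≥ 60 bp. A zero-variance window reports shift −1 and
fails. The summit is the leftmost argmax of combined coverage in the region.

## Target assignment

Distances are measured from the peak summit — the best point estimate of the
binding site — not from region edges (an edge-based variant would only
change distances by half the region width). A summit is assigned to a gene
if it is within 5 kb upstream of the TSS, 3 kb downstream of the TES, or
inside the gene span; boundaries inclusive; genes are plain intervals (the
assignment rule only uses the transcription start/stop sites, so exon
structure is irrelevant). When a summit satisfies several windows of the
same gene the priority is genic > upstream > downstream, and the same
priority makes the per-peak location distribution mutually exclusive.
Candidate genes come from an interval tree over padded gene spans; the exact
predicate is then applied, and a brute-force double loop serves as the test
oracle.

## Expression integration

log2fc is log2(mutant/WT); the loader for Cuffdiff-style tables exposes an
orientation flag because the comparison order in such tables is
convention-dependent. A gene is differentially expressed if |log2fc| ≥ 1
(2-fold) and q ≤ 0.2 in *any* condition, both thresholds inclusive. The
regulation direction is the sign in the qualifying condition of maximal
|log2fc| (ties broken by condition order LL0 < LL15 < LL30 < LL60); genes
moving both ways across conditions therefore take the direction of their
largest change. Direct targets are the DE ∩ ChIP-union intersection. The
heat-map export is log2(FPKM + 1); the pseudocount of 1 maps zero expression
to exactly 0.

## Rhythm analysis

The first 24 h are dropped (transfer artifacts), then a centered moving
average with a 24 h window is subtracted. Near the edges the window shrinks
symmetrically so it stays centered: this removes any linear trend exactly at
every sample, at the price of weaker smoothing in the last few hours.
Detrending follows exclusion, so the average is never contaminated by the
discarded first day.

The line fit is OLS (k = 3 counting the residual variance). The sine model
y = c + A·sin(2π(t − φ)/T) is fitted by variable projection: for fixed T the
model is linear in (A, φ, c) via harmonic regression, so a 1 h period grid
over the bounds (default 16–32 h, bracketing the organism's ~20–22 h
free-running period) is solved exactly and the best grid period seeds a
bounded 1-D minimization of the profiled RSS (xatol 1e-8). This reaches the
same optimum as per-start full nonlinear refinement, deterministically and
cheaply. The reported phase is the time of the first model peak in [0, T);
amplitude is non-negative with the sign absorbed into the phase. Damping is
deliberately not part of the fitted model — the procedure fits period,
phase, and amplitude only — and exists only in the simulator to stress the
fitter; it induces a small downward period bias (~0.1 h at the default
damping of 0.005/h), well inside the ±0.5 h recovery tolerance.

Model comparison uses AICc = n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1) (traces have
~60 points after first-day exclusion, so the small-sample correction
matters; it converges to plain AIC as n grows). The sine model's two-model
Akaike weight is reported as the probability that a sine fits better than a
line; its complement is also derivable from the same number. A trace is
rhythmic iff the weight ≥ 0.95 and the sine fit converged. A perfect fit
(rss = 0) is floored at 1e-300 to keep the comparison finite, which drives
the weight to 1 as intended. Replicate summaries give period mean ± sd
(ddof = 1, sd 0 with a flag for a single replicate) and the phase as a
circular mean modulo the mean period.

## Set integration

The membership partition is the exact four-way split of a focal set by two
reference sets. Enrichment is the hypergeometric upper tail
p = Σ_{k≥x} C(K,k)·C(N−K,n−k)/C(N,n) against the whole-genome population by
default (an expressed-genes background can be passed instead); terms with
fewer than 2 population members are skipped as uninformative, and BH runs
across the terms tested. Peak-set reproducibility merges the union of both
sets' intervals and correlates log2(sum of combined coverage + 1) per
interval; the log transform keeps a handful of very strong sites from
dominating the correlation. The quantity is symmetric in its arguments.

## Synthetic data

The generators define the conditions every recovery and calibration test
runs at; all are deterministic given the seed, with independent named
sub-streams (CRC-derived spawn keys) so partial reruns reproduce.

- **Genome**: 50 genes of 1–3 kb on two chromosomes (500 + 400 kb), ≥ 12 kb
  between placements; 20% of genes form divergent head-to-head pairs with
  TSSs facing across < 5 kb, so upstream peaks can be doubly assigned.
- **ChIP coverage**: background combined coverage is round(LogNormal(μ = 3.0,
  σ = 0.5)) i.i.d. per base — median ~20× coverage, deep-coverage fungal
  ChIP scale — split binomially between strands. The i.i.d. choice matches
  the caller's modeling assumption, making calibration tests exact; real
  coverage is autocorrelated, so passing calibration here does not certify
  behavior on structured real backgrounds. Planted sites add fragment reads
  whose fwd/rev coverage modes sit exactly d = 70 bp apart (35 bp Gaussian
  jitter, 50 bp reads extended symmetrically about their anchors); the
  nominal summit height is 30× the background median, with per-peak
  lognormal spread (ln-sd 0.5) because real site strengths vary over orders
  of magnitude — this spread is what makes between-replicate coverage
  correlation informative.
- **DE tables**: lognormal baseline FPKMs; a 20% planted fraction gets
  |log2fc| ~ N(2, 0.25) with random sign in a random non-empty subset of
  conditions; two replicates per genotype with 0.25 log2-scale noise; p from
  a two-sample t-test on log2(FPKM + 1) and q by BH per condition. The
  internal test exists only so synthetic tables carry coherent p/q columns —
  it is not a substitute DE method and real tables are consumed as given.
- **Luciferase**: y(t) = c + m·t + A·e^{−λt}·sin(2π(t − φ)/T) + ε with
  T = 22 h, A = 100, λ = 0.005/h, trend −0.5/h, noise sd 10 (10% of A),
  sampled every 1.5 h for 114 h (77 points), 12 replicates.

## Numerical choices and degenerate inputs

−log10 of zero p-values is capped at 400 in narrowPeak output (the format
needs finite numbers). Summit and shift ties break leftmost for
determinism. Empty inputs raise rather than return silent empties wherever a
statistic would be undefined (empty focal set, empty peak union, no rhythmic
replicates, degenerate time axis). Internal coordinates are 0-based
half-open everywhere; GFF3 converts at the boundary.

## Problem sizes

The default test and acceptance runs use 1 Mb null genomes (20 seeds), a
0.9 Mb two-chromosome planted genome, 200 damped and 500 null reporter
traces, and exhaustive hypergeometric enumeration to N = 12 — sizes chosen
so the full chain, including oracle comparisons, runs in well under a minute
apiece while keeping Monte-Carlo rates stable to a few percent.

## Known limitations

No input-control subtraction, duplicate handling, or mappability
correction; genes are single intervals; the DE stage consumes external
statistics rather than computing them from counts; the rhythm model is an
undamped sine, so heavily damped traces bias the period low; and enrichment
ships no ontology — any term → gene map is accepted.
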