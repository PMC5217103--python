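"""Background fitting, position scoring, region rules, shift filter, and the
full caller against planted truth and a naive reference implementation."""

import math

import numpy as np
import pytest
from scipy import stats

from regulonscope.core import CoverageTrack
from regulonscope.peaks import (
    PeakCallerConfig,
    call_peaks,
    estimate_shift,
    fit_background,
    merge_regions,
    score_positions,
)
from regulonscope.simulate import SimConfig, plant_peak_truths, simulate_annotation, \
    simulate_chip_coverage


def _track(fwd, rev=None, chrom="c"):
    fwd = np.asarray(fwd)
    return CoverageTrack(chrom, fwd, np.zeros_like(fwd) if rev is None else np.asarray(rev))


class TestFitBackground:
    def test_constant_coverage_is_degenerate(self):
        tr = _track(np.full(2000, 8))
        bg = fit_background(tr)
        assert bg.mu == pytest.approx(math.log(8))
        assert bg.sigma == pytest.approx(0.0, abs=1e-12)
        assert bg.degenerate

    def test_moments_match_log_sample_and_generating_law(self, rng):
        c = np.rint(rng.lognormal(3.0, 0.5, 100_000)).astype(int)
        c = np.maximum(c, 0)
        tr = _track(c)
        bg = fit_background(tr)
        logs = np.log(c[c > 0])
        # exact agreement with the moment oracle on the log sample
        assert bg.mu == pytest.approx(logs.mean(), abs=1e-12)
        assert bg.sigma == pytest.approx(logs.std(ddof=1), abs=1e-12)
        # and closeness to the generating parameters (rounding bias is tiny here)
        assert bg.mu == pytest.approx(3.0, abs=0.02)
        assert bg.sigma == pytest.approx(0.5, abs=0.02)

    def test_insufficient_positive_bases(self):
        fwd = np.zeros(5000, dtype=int)
        fwd[:500] = 3
        with pytest.raises(ValueError, match="insufficient coverage"):
            fit_background(_track(fwd))

    def test_pooled_across_chromosomes(self, rng):
        a = _track(np.rint(rng.lognormal(2, 0.3, 2000)).astype(int), chrom="c1")
        b = _track(np.rint(rng.lognormal(2, 0.3, 2000)).astype(int), chrom="c2")
        bg = fit_background([a, b])
        assert bg.n_fit == int((a.combined > 0).sum() + (b.combined > 0).sum())


class TestScorePositions:
    def _bg(self, mu, sigma):
        from regulonscope.peaks import LognormalBackground

        return LognormalBackground(mu=mu, sigma=sigma, n_fit=10_000)

    def test_standard_normal_quantile_threshold(self):
        """mu=0, sigma=1, alpha=0.01: threshold exp(z_0.99) ~ 10.24, so
        coverage 11 is enriched and 10 is not."""
        bg = self._bg(0.0, 1.0)
        tr = _track([0, 1, 10, 11, 50])
        mask = score_positions(tr, bg, alpha=0.01)
        assert mask.tolist() == [False, False, False, True, True]

    def test_alpha_one_marks_every_positive_position(self):
        bg = self._bg(1.0, 0.5)
        tr = _track([0, 1, 2, 0, 3])
        assert score_positions(tr, bg, alpha=1.0).tolist() == [False, True, True, False, True]

    def test_zero_coverage_never_enriched(self):
        bg = self._bg(0.0, 1.0)
        tr = _track(np.zeros(10, dtype=int))
        assert not score_positions(tr, bg, alpha=1.0).any()

    def test_degenerate_background_instructs_fallback(self):
        bg = self._bg(2.0, 0.0)
        with pytest.raises(ValueError, match="fallback quantile"):
            score_positions(_track([1, 2, 3]), bg, 0.01)

    def test_calibration_on_iid_lognormal(self, rng):
        """The enriched fraction tracks alpha within 3 binomial SEs."""
        c = np.rint(rng.lognormal(3.0, 0.5, 1_000_000)).astype(int)
        tr = _track(c)
        mask = score_positions(tr, fit_background(tr), 0.01)
        se = math.sqrt(0.01 * 0.99 / len(c))
        assert abs(mask.mean() - 0.01) <= 3 * se


class TestMergeRegions:
    CFG = PeakCallerConfig()

    def _mask(self, runs, n=1000):
        m = np.zeros(n, dtype=bool)
        for s, e in runs:
            m[s:e] = True
        return m

    def test_run_of_150_retained(self):
        assert merge_regions(self._mask([(100, 250)]), self.CFG) == [(100, 250)]

    def test_run_of_exactly_100_dropped_strict_inequality(self):
        assert merge_regions(self._mask([(100, 200)]), self.CFG) == []
        assert merge_regions(self._mask([(100, 201)]), self.CFG) == [(100, 201)]

    def test_gap_joining_when_configured(self):
        cfg = PeakCallerConfig(max_merge_gap=50)
        mask = self._mask([(0, 80), (110, 190)])
        assert merge_regions(mask, cfg) == [(0, 190)]
        # without merging the two 80 bp runs are each too short
        assert merge_regions(mask, self.CFG) == []

    def test_gap_wider_than_limit_not_joined(self):
        cfg = PeakCallerConfig(max_merge_gap=50)
        mask = self._mask([(0, 120), (180, 301)])
        assert merge_regions(mask, cfg) == [(0, 120), (180, 301)]


class TestEstimateShift:
    def _shifted_tracks(self, lag, n=2000):
        rng = np.random.default_rng(0)
        base = np.zeros(n)
        centers = [600, 1000, 1400]
        x = np.arange(n)
        for c in centers:
            base += 50 * np.exp(-((x - c) ** 2) / (2 * 40.0**2))
        fwd = np.rint(base).astype(int)
        rev = np.roll(fwd, lag)
        return CoverageTrack("c", fwd, rev)

    @pytest.mark.parametrize("lag,passed", [(70, True), (60, True), (59, False), (0, False)])
    def test_lag_recovery_and_threshold(self, lag, passed):
        tr = self._shifted_tracks(lag)
        shift, ok = estimate_shift((900, 1100), tr, PeakCallerConfig())
        assert shift == lag
        assert ok is passed

    def test_zero_variance_window_fails_with_undefined_shift(self):
        tr = CoverageTrack("c", np.zeros(500, dtype=int), np.zeros(500, dtype=int))
        shift, ok = estimate_shift((200, 300), tr, PeakCallerConfig())
        assert (shift, ok) == (-1, False)


class TestCallPeaks:
    def test_planted_peaks_recovered_no_false_positives(self):
        cfg = SimConfig(seed=21)
        ann = simulate_annotation(cfg)
        truths = plant_peak_truths(ann, cfg)
        tracks = simulate_chip_coverage(ann, truths, cfg)
        peaks = call_peaks(list(tracks.values()))
        hits = 0
        claimed = set()
        for t in truths:
            match = [i for i, p in enumerate(peaks)
                     if p.chrom == t.chrom and abs(p.summit - t.center) <= 50]
            if match:
                hits += 1
                claimed.update(match)
        assert hits >= len(truths) - 1
        assert len(peaks) == len(claimed)  # every called peak explains a truth

    def test_relaxing_shift_filter_is_monotone(self):
        cfg = SimConfig(seed=22)
        ann = simulate_annotation(cfg)
        truths = plant_peak_truths(ann, cfg)
        tracks = list(simulate_chip_coverage(ann, truths, cfg).values())
        n_default = len(call_peaks(tracks, PeakCallerConfig()))
        n_noshift = len(call_peaks(tracks, PeakCallerConfig(min_shift=0)))
        assert n_noshift >= n_default

    @pytest.mark.parametrize(
        "strict", [
            PeakCallerConfig(alpha_position=0.001),
            PeakCallerConfig(min_region_len=200),
            PeakCallerConfig(min_shift=100),
            PeakCallerConfig(fdr=0.001),
        ],
    )
    def test_tightening_any_threshold_never_adds_peaks(self, strict):
        cfg = SimConfig(seed=23)
        ann = simulate_annotation(cfg)
        truths = plant_peak_truths(ann, cfg)
        tracks = list(simulate_chip_coverage(ann, truths, cfg).values())
        assert len(call_peaks(tracks, strict)) <= len(call_peaks(tracks, PeakCallerConfig()))

    def test_null_background_yields_no_peaks(self, rng):
        c = np.rint(rng.lognormal(3.0, 0.5, 300_000)).astype(np.int64)
        fwd = rng.binomial(c, 0.5)
        tr = CoverageTrack("c", fwd, c - fwd)
        assert len(call_peaks(tr)) == 0

    def test_matches_naive_reference_on_small_chromosome(self):
        """On a <= 10 kb chromosome the vectorized caller retains exactly the
        regions a position-by-position reference computes."""
        cfg = SimConfig(seed=31, n_genes=1, n_peaks=1, chrom_sizes={"chrI": 10_000},
                        gene_len_range=(500, 800), min_spacing=1000,
                        divergent_fraction=0.0)
        ann = simulate_annotation(cfg)
        truths = plant_peak_truths(ann, cfg)
        (tr,) = simulate_chip_coverage(ann, truths, cfg).values()
        ccfg = PeakCallerConfig()
        peaks = call_peaks(tr, ccfg)
        ref = _naive_call(tr, ccfg)
        assert [(p.start, p.end, p.summit) for p in peaks] == ref


def _naive_call(tr, cfg):
    """Brute-force reference: per-position scoring, run scanning, BH by the
    sorted-p formula, and the same shift rule via np.corrcoef."""
    bg = fit_background(tr)
    c = tr.combined
    enr = [c[i] > 0 and stats.norm.sf((math.log(c[i]) - bg.mu) / bg.sigma) <= cfg.alpha_position
           for i in range(len(c))]
    regions = []
    i = 0
    while i < len(enr):
        if enr[i]:
            j = i
            while j + 1 < len(enr) and enr[j + 1]:
                j += 1
            if (j + 1 - i) > cfg.min_region_len:
                regions.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    if not regions:
        return []
    pvals = [float(stats.norm.sf((math.log(c[s:e].max()) - bg.mu) / bg.sigma))
             for s, e in regions]
    m = len(pvals)
    order = sorted(range(m), key=lambda k: pvals[k])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, k in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvals[k] * m / rank)
        q[k] = prev
    out = []
    for (s, e), qv in zip(regions, q):
        if not qv < cfg.fdr:
            continue
        lo, hi = max(0, s - cfg.shift_flank), min(len(c), e + cfg.shift_flank)
        best, best_r = -1, -np.inf
        for lag in range(0, min(cfg.shift_search_max, hi - lo - 2) + 1):
            a = tr.fwd[lo:hi - lag].astype(float)
            b = tr.rev[lo + lag:hi].astype(float)
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r > best_r:
                best_r, best = r, lag
        if best >= cfg.min_shift:
            out.append((s, e, s + int(np.argmax(c[s:e]))))
    return out
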