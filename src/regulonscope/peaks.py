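"""Lognormal-background ChIP-seq peak calling with a strand-shift filter.

The background per-base coverage of a ChIP sample is modeled as lognormal;
each position is scored by the upper-tail probability of its combined
(fwd + rev) coverage under that law.  Positions with P <= alpha are enriched;
maximal enriched runs longer than ``min_region_len`` bp become candidate
regions; candidates are ranked by their smallest per-position tail
probability, BH-adjusted across the sample, and retained at q < fdr.  True
protein-binding sites show a forward-to-reverse pileup offset at the
sequencing-fragment scale, so retained regions must additionally show a
cross-correlation lag of at least ``min_shift`` bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CoverageTrack, PeakRegion, PeakSet

__all__ = [
    "LognormalBackground",
    "PeakCallerConfig",
    "fit_background",
    "score_positions",
    "merge_regions",
    "estimate_shift",
    "call_peaks",
]

_DEGENERATE_SIGMA = 1e-6


@dataclass
class LognormalBackground:
    """Fitted lognormal law of positive-coverage bases: ln(coverage) ~ N(mu, sigma)."""

    mu: float
    sigma: float
    n_fit: int

    @property
    def degenerate(self) -> bool:
        return self.sigma < _DEGENERATE_SIGMA

    def tail_prob(self, coverage: np.ndarray | float) -> np.ndarray | float:
        """Upper-tail probability P(X >= c) for positive coverage c."""
        if self.degenerate:
            raise ValueError(
                "degenerate background (sigma ~ 0): use a fallback quantile threshold"
            )
        c = np.asarray(coverage, dtype=float)
        with np.errstate(divide="ignore"):
            z = (np.log(c) - self.mu) / self.sigma
        return stats.norm.sf(z)


@dataclass
class PeakCallerConfig:
    alpha_position: float = 0.01     # per-position tail-probability threshold (P <= alpha enriched)
    min_region_len: int = 100        # bp, strict: regions must exceed this
    min_shift: int = 60              # bp, inclusive: fwd->rev lag must reach this
    max_merge_gap: int = 0           # bp of non-enriched bases bridged when forming regions
    fdr: float = 0.01                # region-level BH threshold (q < fdr retained)
    shift_search_max: int = 300      # bp, largest lag tried by the cross-correlation filter
    shift_flank: int = 500           # bp of context on each side of a region for the lag search

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_position <= 1.0:
            raise ValueError("alpha_position must be in (0, 1]")
        for name in ("min_region_len", "min_shift", "shift_search_max", "shift_flank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def fit_background(tracks: CoverageTrack | list[CoverageTrack],
                   min_positive: int = 1000) -> LognormalBackground:
    """Fit the lognormal background to a sample's coverage.

    Uses ln(fwd + rev) over positive-coverage bases, pooled over all
    chromosomes of the sample (the lognormal has support (0, inf), so
    zero-coverage bases are excluded and are by definition unenriched).
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    logs = []
    for tr in tracks:
        c = tr.combined
        pos = c[c > 0]
        if len(pos):
            logs.append(np.log(pos.astype(float)))
    n = sum(len(x) for x in logs)
    if n < min_positive:
        raise ValueError(f"insufficient coverage: {n} positive bases (< {min_positive})")
    x = np.concatenate(logs)
    return LognormalBackground(mu=float(x.mean()), sigma=float(x.std(ddof=1)), n_fit=n)


def score_positions(track: CoverageTrack, bg: LognormalBackground,
                    alpha: float = 0.01) -> np.ndarray:
    """Boolean enrichment mask: coverage > 0 and upper-tail probability <= alpha."""
    c = track.combined
    mask = np.zeros(len(c), dtype=bool)
    positive = c > 0
    if not positive.any():
        return mask
    # coverage is integer-valued and the tail probability is monotone
    # decreasing in it, so score unique values once and threshold
    values = np.unique(c[positive])
    pvals = np.atleast_1d(bg.tail_prob(values))
    qualifying = values[pvals <= alpha]
    if len(qualifying):
        mask = c >= qualifying.min()
    return mask


def merge_regions(mask: np.ndarray, cfg: PeakCallerConfig) -> list[tuple[int, int]]:
    """Candidate regions: maximal enriched runs, bridging gaps <= max_merge_gap,
    retained only if strictly longer than min_region_len bp."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    gaps = np.diff(idx)
    breaks = np.flatnonzero(gaps > cfg.max_merge_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    out = []
    for s, e in zip(starts, ends):
        lo, hi = int(idx[s]), int(idx[e]) + 1
        if hi - lo > cfg.min_region_len:
            out.append((lo, hi))
    return out


def estimate_shift(region: tuple[int, int], track: CoverageTrack,
                   cfg: PeakCallerConfig) -> tuple[int, bool]:
    """Forward-to-reverse lag of a region by cross-correlation.

    Over the region extended by ``shift_flank`` on each side (clipped at the
    chromosome ends), returns the lag ell in [0, shift_search_max] maximizing
    the Pearson correlation of fwd(x) with rev(x + ell) (leftmost argmax on
    ties), and whether it reaches ``min_shift``.  A zero-variance window
    yields (-1, False).
    """
    lo = max(0, region[0] - cfg.shift_flank)
    hi = min(len(track), region[1] + cfg.shift_flank)
    fwd = track.fwd[lo:hi].astype(float)
    rev = track.rev[lo:hi].astype(float)
    n = hi - lo
    best_lag, best_r = -1, -np.inf
    max_lag = min(cfg.shift_search_max, n - 2)
    for lag in range(0, max_lag + 1):
        a = fwd[: n - lag]
        b = rev[lag:]
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if r > best_r:
            best_r, best_lag = r, lag
    if best_lag < 0:
        return -1, False
    return best_lag, best_lag >= cfg.min_shift


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from scipy.stats import false_discovery_control

    return false_discovery_control(pvals, method="bh")


def call_peaks(tracks: CoverageTrack | list[CoverageTrack],
               cfg: PeakCallerConfig | None = None,
               bg: LognormalBackground | None = None) -> PeakSet:
    """Full calling pipeline for one sample.

    fit background -> score positions -> merge regions -> per-candidate min_p
    -> BH across all candidates of the sample -> retain q < fdr -> shift
    filter -> retain shift >= min_shift.  The summit is the leftmost argmax of
    combined coverage within the region.
    """
    if cfg is None:
        cfg = PeakCallerConfig()
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    if bg is None:
        bg = fit_background(tracks)

    candidates: list[tuple[CoverageTrack, tuple[int, int], float, int, float]] = []
    for tr in tracks:
        mask = score_positions(tr, bg, cfg.alpha_position)
        for lo, hi in merge_regions(mask, cfg):
            c = tr.combined[lo:hi]
            summit = lo + int(np.argmax(c))
            # min per-position p == tail prob of the max coverage (sf is monotone)
            min_p = float(np.atleast_1d(bg.tail_prob(int(c.max())))[0])
            candidates.append((tr, (lo, hi), min_p, summit, float(c.mean())))

    if not candidates:
        return PeakSet()
    qvals = _bh_adjust(np.array([c[2] for c in candidates]))

    retained = []
    for (tr, (lo, hi), min_p, summit, signal), q in zip(candidates, qvals):
        if not q < cfg.fdr:
            continue
        shift, passed = estimate_shift((lo, hi), tr, cfg)
        if not passed:
            continue
        peak = PeakRegion(chrom=tr.chrom, start=lo, end=hi, summit=summit,
                          min_p=min_p, q=float(q), shift=shift,
                          passed_shift=True, signal=signal)
        # retained-peak invariants, asserted on every call
        assert len(peak) > cfg.min_region_len
        assert peak.shift >= cfg.min_shift and peak.q < cfg.fdr
        assert peak.start <= peak.summit < peak.end
        retained.append(peak)
    return PeakSet(retained)
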