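"""Membership partitions, hypergeometric enrichment, and peak reproducibility."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulonscope.core import CoverageTrack, GeneSet, PeakRegion
from regulonscope.sets import (
    hypergeom_enrichment,
    partition_membership,
    peak_set_correlation,
)


class TestPartitionMembership:
    def test_four_way_example(self):
        part = partition_membership(GeneSet("f", {"a", "b", "c", "d"}),
                                    GeneSet("l", {"a", "b"}), GeneSet("c", {"b", "c"}))
        assert part.counts == {"both": 1, "light_only": 1, "clock_only": 1, "neither": 1}
        assert all(v == pytest.approx(25.0) for v in part.percentages.values())

    def test_empty_reference_sets_give_all_neither(self):
        part = partition_membership(GeneSet("f", {"a", "b"}), GeneSet("l"), GeneSet("c"))
        assert part.counts["neither"] == 2

    def test_focal_inside_both_gives_100_percent_both(self):
        part = partition_membership(GeneSet("f", {"a"}), GeneSet("l", {"a", "b"}),
                                    GeneSet("c", {"a"}))
        assert part.percentages["both"] == pytest.approx(100.0)

    def test_empty_focal_is_error(self):
        with pytest.raises(ValueError, match="empty focal"):
            partition_membership(GeneSet("f"), GeneSet("l"), GeneSet("c"))

    @settings(deadline=None, max_examples=60)
    @given(focal=st.sets(st.integers(0, 40), min_size=1),
           light=st.sets(st.integers(0, 40)), clock=st.sets(st.integers(0, 40)))
    def test_cells_disjoint_and_exhaustive(self, focal, light, clock):
        part = partition_membership(GeneSet("f", {str(i) for i in focal}),
                                    GeneSet("l", {str(i) for i in light}),
                                    GeneSet("c", {str(i) for i in clock}))
        cells = list(part.genes.values())
        assert sum(len(c) for c in cells) == len(focal)
        for a, b in itertools.combinations(cells, 2):
            assert not a & b
        assert sum(part.percentages.values()) == pytest.approx(100.0, abs=0.1)


def _exact_upper_tail(N, K, n, x):
    """Closed-form hypergeometric upper tail with exact rational arithmetic."""
    total = Fraction(0)
    for k in range(x, min(n, K) + 1):
        total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))
    return float(total)


class TestHypergeomEnrichment:
    def _run(self, N, K, n, x):
        assert n + K - x <= N, "inconsistent configuration"
        population = GeneSet("pop", {f"g{i}" for i in range(N)})
        study = GeneSet("s", {f"g{i}" for i in range(n)})
        term = {f"g{i}" for i in range(x)} | {f"g{i}" for i in range(n, n + K - x)}
        (res,) = hypergeom_enrichment(study, population, {"T": term}, min_term_size=0)
        assert (res.x, res.K, res.n, res.N) == (x, K, n, N)
        return res

    def test_worked_value_all_draws_hit(self):
        res = self._run(N=20, K=5, n=5, x=5)
        assert res.p == pytest.approx(1 / 15504, abs=1e-12)

    def test_zero_hits_give_p_one(self):
        assert self._run(N=20, K=5, n=5, x=0).p == 1.0

    def test_study_equals_population_forces_p_one(self):
        population = GeneSet("pop", {f"g{i}" for i in range(10)})
        results = hypergeom_enrichment(population, population,
                                       {"T": {f"g{i}" for i in range(4)}})
        assert results[0].x == results[0].K and results[0].p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_populations(self):
        """p equals enumeration over every possible same-size draw for N <= 8."""
        for N in (5, 8):
            pop = [f"g{i}" for i in range(N)]
            population = GeneSet("pop", set(pop))
            for K in (2, N // 2, N):
                term = set(pop[:K])
                for n in (1, N // 2, N):
                    for shift in range(N - n + 1):
                        study = GeneSet("s", set(pop[shift:shift + n]))
                        x = len(study.members & term)
                        (res,) = hypergeom_enrichment(study, population, {"T": term},
                                                      min_term_size=0)
                        hits = sum(1 for draw in itertools.combinations(pop, n)
                                   if len(term & set(draw)) >= x)
                        expected = hits / math.comb(N, n)
                        assert res.p == pytest.approx(expected, abs=1e-12), (N, K, n, shift)
                        assert res.p == pytest.approx(_exact_upper_tail(N, K, n, x), abs=1e-12)

    def test_study_gene_outside_population_listed(self):
        with pytest.raises(ValueError, match="absent from population.*'zz'"):
            hypergeom_enrichment(GeneSet("s", {"zz"}), GeneSet("p", {"a"}), {})

    def test_small_terms_skipped_and_bh_applied(self):
        population = GeneSet("pop", {f"g{i}" for i in range(30)})
        study = GeneSet("s", {f"g{i}" for i in range(5)})
        tm = {"tiny": {"g0"}, "big": {f"g{i}" for i in range(10)}}
        results = hypergeom_enrichment(study, population, tm)
        assert [r.term_id for r in results] == ["big"]
        assert results[0].q == pytest.approx(results[0].p)


def _make_tracks(rng, n=50_000):
    c = np.rint(rng.lognormal(2.0, 0.4, n)).astype(np.int64)
    f = rng.binomial(c, 0.5)
    return CoverageTrack("c", f, c - f)


def _peaks(intervals):
    return [PeakRegion("c", s, e, summit=(s + e) // 2, min_p=1e-6) for s, e in intervals]


class TestPeakSetCorrelation:
    def test_identical_inputs_give_r2_one(self, rng):
        tr = _make_tracks(rng)
        peaks = _peaks([(i * 1000, i * 1000 + 300) for i in range(20)])
        r2 = peak_set_correlation(peaks, peaks, {"c": tr}, {"c": tr})
        assert r2 == pytest.approx(1.0)

    def test_independent_coverage_gives_low_r2(self):
        rng = np.random.default_rng(10)
        ta, tb = _make_tracks(rng, 210_000), _make_tracks(rng, 210_000)
        peaks = _peaks([(i * 1000, i * 1000 + 300) for i in range(200)])
        r2 = peak_set_correlation(peaks, peaks, {"c": ta}, {"c": tb})
        assert r2 < 0.1

    def test_symmetric_in_arguments(self, rng):
        ta, tb = _make_tracks(rng), _make_tracks(rng)
        pa = _peaks([(0, 400), (5000, 5400), (9000, 9500)])
        pb = _peaks([(200, 600), (20_000, 20_300)])
        r_ab = peak_set_correlation(pa, pb, {"c": ta}, {"c": tb})
        r_ba = peak_set_correlation(pb, pa, {"c": tb}, {"c": ta})
        assert r_ab == pytest.approx(r_ba, abs=1e-12)

    def test_empty_union_is_error(self, rng):
        tr = _make_tracks(rng)
        with pytest.raises(ValueError, match="empty peak-interval union"):
            peak_set_correlation([], [], {"c": tr}, {"c": tr})

    def test_shared_planted_peaks_reproduce_above_087(self):
        """Two replicates sharing planted peaks but with independent background
        noise correlate at R^2 >= 0.87 (the reproducibility bound the pipeline
        reports between growth conditions)."""
        from regulonscope.simulate import SimConfig, plant_peak_truths, \
            simulate_annotation, simulate_chip_coverage
        from regulonscope.peaks import call_peaks

        cfg = SimConfig(seed=41)
        ann = simulate_annotation(cfg)
        truths = plant_peak_truths(ann, cfg)
        ta = simulate_chip_coverage(ann, truths, cfg, stream="repA")
        tb = simulate_chip_coverage(ann, truths, cfg, stream="repB")
        pa = call_peaks(list(ta.values()))
        pb = call_peaks(list(tb.values()))
        r2 = peak_set_correlation(list(pa), list(pb), ta, tb)
        assert r2 >= 0.87
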