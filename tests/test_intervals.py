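"""Interval overlap operations and binomial proportion summaries."""

import numpy as np
import pytest
from scipy import stats

from exonhancer import (
    GenomicInterval,
    IntervalSet,
    ProportionSummary,
    binomial_sem,
    est_adjacency,
    genes_with_marked_exon,
    intersect_any,
    intronic_controls,
    marked_fraction,
    p300_exon_overlap,
    simulate_intervals,
    tfbs_full_coverage,
    two_proportion_compare,
)
from exonhancer.intervals import preprocess_ccds_exons


def brute_force_any(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """O(n*m) all-pairs overlap oracle on the half-open convention."""
    out = np.zeros(len(a), dtype=bool)
    for i, x in enumerate(a):
        for y in b:
            if x.chrom == y.chrom and max(x.start, y.start) < min(x.end, y.end):
                out[i] = True
                break
    return out


def random_interval_set(rng, n, chroms=("chr1", "chr2"), span=10000, max_len=300):
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, span))
        ivs.append(
            GenomicInterval(
                str(rng.choice(chroms)), start, start + int(rng.integers(1, max_len)), name=f"i{i}"
            )
        )
    return IntervalSet(ivs)


class TestOverlapSemantics:
    def test_one_bp_overlap_counts(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 199, 300)
        assert a.overlaps(b)

    def test_half_open_abutting_never_overlaps(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 200, 300)
        assert not a.overlaps(b) and not b.overlaps(a)

    def test_different_chrom_never_overlaps(self):
        assert not GenomicInterval("chr1", 0, 10).overlaps(GenomicInterval("chr2", 0, 10))

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        a = random_interval_set(rng, 40)
        b = random_interval_set(rng, 40)
        shift = 12345
        a2 = IntervalSet([GenomicInterval(i.chrom, i.start + shift, i.end + shift) for i in a])
        b2 = IntervalSet([GenomicInterval(i.chrom, i.start + shift, i.end + shift) for i in b])
        assert np.array_equal(intersect_any(a, b), intersect_any(a2, b2))

    def test_matches_brute_force(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = random_interval_set(rng, 80)
            b = random_interval_set(rng, 80)
            assert np.array_equal(intersect_any(a, b), brute_force_any(a, b))


class TestMarkedFraction:
    def test_reported_sem_values(self):
        s = marked_fraction(*_planted(37, 358))
        assert f"{100 * s.fraction:.1f}" == "10.3" and f"{100 * s.sem:.1f}" == "1.6"

    def test_no_peaks(self):
        feats, _, _ = simulate_intervals(n_features=10, planted_fraction=0.0, n_peaks=0, seed=0)
        s = marked_fraction(feats, IntervalSet([]))
        assert s.fraction == 0 and s.sem == 0

    def test_monotone_in_peaks(self):
        feats, peaks, _ = simulate_intervals(n_features=30, planted_fraction=0.4, seed=2)
        half = IntervalSet(peaks.intervals[: len(peaks) // 2])
        assert marked_fraction(feats, half).k <= marked_fraction(feats, peaks).k

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            marked_fraction(IntervalSet([]), IntervalSet([]))


def _planted(k, n):
    feats, peaks, _ = simulate_intervals(n_features=n, planted_fraction=k / n, seed=1)
    return feats, peaks


class TestGeneLevel:
    def test_planted_gene_fraction(self):
        rng = np.random.default_rng(3)
        genes = {}
        peaks = []
        pos = 0
        for g in range(100):
            exons = []
            for e in range(3):
                exons.append(GenomicInterval("chr1", pos, pos + 100, name=f"g{g}"))
                pos += 1000
            genes[f"g{g}"] = exons
            if g < 63:
                target = exons[int(rng.integers(3))]
                peaks.append(GenomicInterval("chr1", target.start + 10, target.start + 50))
        s = genes_with_marked_exon(genes, IntervalSet(peaks))
        assert (s.k, s.n) == (63, 100)

    def test_multiple_marked_exons_count_gene_once(self):
        genes = {
            "g": [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)],
        }
        peaks = IntervalSet([GenomicInterval("chr1", 50, 550)])
        assert genes_with_marked_exon(genes, peaks).k == 1

    def test_interval_set_input_requires_names(self):
        unnamed = IntervalSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError, match="gene"):
            genes_with_marked_exon(unnamed, IntervalSet([]))


class TestIntronicControls:
    def test_contained_and_sized(self):
        introns = IntervalSet([GenomicInterval("chr1", 0, 1000)])
        out = intronic_controls(introns, [100], seed=4)
        iv = out.intervals[0]
        assert iv.length == 100 and 0 <= iv.start and iv.end <= 1000

    def test_one_control_per_target_length(self):
        introns = IntervalSet([GenomicInterval("chr1", 0, 5000), GenomicInterval("chr2", 0, 800)])
        lengths = [100, 200, 300, 700]
        assert len(intronic_controls(introns, lengths, seed=0)) == len(lengths)

    def test_no_host_long_enough_rejected(self):
        introns = IntervalSet([GenomicInterval("chr1", 0, 50)])
        with pytest.raises(ValueError, match="100"):
            intronic_controls(introns, [100], seed=0)

    def test_placement_uniform_on_single_intron(self):
        """Chi-squared goodness of fit of start positions against uniform."""
        introns = IntervalSet([GenomicInterval("chr1", 0, 1000)])
        starts = [
            intronic_controls(introns, [100], seed=s).intervals[0].start for s in range(10000)
        ]
        counts, _ = np.histogram(starts, bins=10, range=(0, 901))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestTfbsCoverage:
    def test_boundary_containment_counts(self):
        exons = IntervalSet([GenomicInterval("chr1", 100, 200)])
        clusters = IntervalSet([GenomicInterval("chr1", 100, 200, score=500)])
        assert tfbs_full_coverage(exons, clusters).k == 1

    def test_union_of_partial_clusters_does_not_count(self):
        exons = IntervalSet([GenomicInterval("chr1", 100, 200)])
        clusters = IntervalSet(
            [
                GenomicInterval("chr1", 90, 150, score=900),
                GenomicInterval("chr1", 150, 210, score=900),
            ]
        )
        assert tfbs_full_coverage(exons, clusters).k == 0

    def test_score_threshold(self):
        exons = IntervalSet([GenomicInterval("chr1", 100, 200)])
        weak = IntervalSet([GenomicInterval("chr1", 0, 300, score=499)])
        assert tfbs_full_coverage(exons, weak).k == 0


class TestP300Preprocessing:
    def test_exact_duplicates_collapse_to_one(self):
        exons = IntervalSet(
            [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 100, 200)]
        )
        assert len(preprocess_ccds_exons(exons)) == 1

    def test_overlapping_distinct_records_both_removed(self):
        exons = IntervalSet(
            [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 250)]
        )
        assert len(preprocess_ccds_exons(exons)) == 0

    def test_length_filters(self):
        exons = IntervalSet(
            [
                GenomicInterval("chr1", 0, 2),  # too short
                GenomicInterval("chr2", 0, 20000),  # too long
                GenomicInterval("chr3", 0, 150),
            ]
        )
        kept = preprocess_ccds_exons(exons)
        assert [iv.chrom for iv in kept] == ["chr3"]

    def test_planted_peak_fraction(self):
        feats, peaks, truth = simulate_intervals(
            n_features=200, planted_fraction=0.2, n_peaks=200, feature_length=150, seed=6
        )
        s = p300_exon_overlap(peaks, feats)
        assert (s.k, s.n) == (truth["n_planted"], 200)


class TestEstAdjacency:
    WINDOW_REGION = GenomicInterval("chr1", 5000, 5400)

    def test_spanning_est_excluded(self):
        ests = IntervalSet([GenomicInterval("chr1", 3000, 8000)])
        assert est_adjacency(self.WINDOW_REGION, ests, flank=1000) == 0

    def test_flank_only_est_counted(self):
        ests = IntervalSet([GenomicInterval("chr1", 4000, 4100)])
        assert est_adjacency(self.WINDOW_REGION, ests, flank=1000) == 1

    def test_outside_window_not_counted(self):
        ests = IntervalSet([GenomicInterval("chr1", 100, 200)])
        assert est_adjacency(self.WINDOW_REGION, ests, flank=1000) == 0

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            est_adjacency(self.WINDOW_REGION, IntervalSet([]), flank=-1)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        ests = random_interval_set(rng, 200, chroms=("chr1",), span=12000, max_len=4000)
        win = GenomicInterval("chr1", 4000, 6400)
        expected = sum(
            1
            for e in ests
            if max(e.start, win.start) < min(e.end, win.end)
            and not (e.start <= win.start and e.end >= win.end)
        )
        assert est_adjacency(GenomicInterval("chr1", 5000, 5400), ests, flank=1000) == expected


class TestProportionSummaries:
    @pytest.mark.parametrize(
        "k,n,pct,sem_pct",
        [(37, 358, "10.3", "1.6"), (8874, 110461, "8.0", "0.08"), (517, 813, "63.6", "1.7")],
    )
    def test_reported_sem_values(self, k, n, pct, sem_pct):
        s = ProportionSummary(k, n)
        digits = len(sem_pct.split(".")[1])
        assert f"{100 * s.fraction:.1f}" == pct
        assert f"{100 * s.sem:.{digits}f}" == sem_pct

    def test_sem_closed_form(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(1, 10**6))
            k = int(rng.integers(0, n + 1))
            p = k / n
            assert binomial_sem(k, n) == pytest.approx(np.sqrt(p * (1 - p) / n), rel=1e-12)
        assert binomial_sem(0, 10) == 0.0
        assert binomial_sem(50, 100) == pytest.approx(0.05)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_sem(5, 0)
        with pytest.raises(ValueError):
            ProportionSummary(11, 10)


class TestTwoProportionCompare:
    def test_equal_proportions_near_one(self):
        assert two_proportion_compare(30, 100, 60, 200) == pytest.approx(1.0)

    def test_cohort_counts_not_significant(self):
        assert two_proportion_compare(24, 31, 105, 147) > 0.05
        assert two_proportion_compare(14, 24, 50, 105) > 0.05
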