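"""Concordance histograms, nearest-gene assignment and classification,
each checked against exhaustive O(n*m) recomputation."""

import numpy as np
import pytest

from targetome.interval_analytics import (
    assign_nearest_gene,
    classify_genomic_region,
    distance_correlation,
    fraction_within,
    nearest_signed_distances,
    peak_centers,
    tss_anchors,
    tss_distance_distribution,
)
from targetome.io_formats import GeneModel, GenomicInterval, Peak


def _peak(chrom, start, end):
    return Peak(GenomicInterval(chrom, start, end), (start + end) // 2)


def _peak_at(center, chrom="chr1"):
    return _peak(chrom, center - 50, center + 50)


def brute_nearest_signed(query, reference):
    """Exhaustive nearest-anchor signed distances with the package tie rule."""
    out = []
    for chrom, pos in query:
        best = None
        for rchrom, rpos in reference:
            if rchrom != chrom:
                continue
            d = pos - rpos
            if best is None or abs(d) < abs(best) or (abs(d) == abs(best) and d < best):
                best = d
        out.append(np.inf if best is None else best)
    return np.array(out, dtype=float)


def _random_anchors(rng, n, span=50_000, chroms=("chr1", "chr2")):
    return [
        (str(rng.choice(chroms)), int(rng.integers(0, span))) for _ in range(n)
    ]


class TestDistanceCorrelation:
    def test_self_comparison_masses_zero_bin(self):
        peaks = [_peak_at(c) for c in (500, 2000, 9000)]
        hist = distance_correlation(peaks, peak_centers(peaks))
        nonzero = np.flatnonzero(hist.counts)
        assert len(nonzero) == 1
        lo = hist.bin_edges[nonzero[0]]
        hi = hist.bin_edges[nonzero[0] + 1]
        assert lo <= 0 < hi
        assert hist.counts.sum() == len(peaks)

    def test_rigid_shift_masses_minus_shift_bin(self):
        a = [_peak_at(c) for c in (1000, 3000, 7000)]
        b = [(p.interval.chrom, p.center + 200) for p in a]
        hist = distance_correlation(a, b)
        nonzero = np.flatnonzero(hist.counts)
        assert len(nonzero) == 1
        assert hist.bin_edges[nonzero[0]] <= -200 < hist.bin_edges[nonzero[0] + 1]

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            q = _random_anchors(rng, 200)
            r = _random_anchors(rng, 200)
            hist = distance_correlation(q, r, max_dist=10_000, bin=50)
            brute = brute_nearest_signed(q, r)
            brute = brute[np.isfinite(brute)]
            expected, _ = np.histogram(
                brute[(brute >= -10_000) & (brute < 10_000)], bins=hist.bin_edges
            )
            np.testing.assert_array_equal(hist.counts, expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            distance_correlation([("chr1", 5)], [("chr1", 5)], bin=0)
        with pytest.raises(ValueError):
            distance_correlation([("chr1", 5)], [("chr1", 5)], max_dist=-1)


class TestFractionWithin:
    def test_self_comparison_is_100_percent(self):
        peaks = [_peak_at(c) for c in (500, 1500)]
        assert fraction_within(peaks, peak_centers(peaks), 0) == 100.0

    def test_boundary_distance_counts_as_within(self):
        assert fraction_within([("chr1", 10_000)], [("chr1", 10_400)], 500) == 100.0
        assert fraction_within([("chr1", 10_000)], [("chr1", 10_501)], 500) == 0.0

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fraction_within([], [("chr1", 5)], 500)

    def test_monotone_in_d_and_saturates(self):
        rng = np.random.default_rng(9)
        q = _random_anchors(rng, 100)
        r = _random_anchors(rng, 30)
        fracs = [fraction_within(q, r, d) for d in (0, 100, 1000, 10_000, 10**7)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == 100.0

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            q = _random_anchors(rng, 150)
            r = _random_anchors(rng, 80)
            d = int(rng.integers(50, 5000))
            brute = brute_nearest_signed(q, r)
            expected = 100.0 * np.sum(np.abs(brute) <= d) / len(q)
            assert fraction_within(q, r, d) == pytest.approx(expected)


def _gene(gene_id, chrom, start, end, strand="+", exon_spans=None):
    iv = GenomicInterval(chrom, start, end, strand)
    exons = tuple(
        GenomicInterval(chrom, s, e, strand) for s, e in (exon_spans or [(start, end)])
    )
    return GeneModel(gene_id, iv, exons)


class TestNearestGene:
    def test_peak_at_tss_distance_zero(self):
        gene = _gene("g1", "chr1", 5000, 7000, "+")
        (a,) = assign_nearest_gene([_peak_at(5000)], [gene])
        assert a.gene_id == "g1"
        assert a.signed_distance == 0

    def test_upstream_of_plus_strand_is_negative(self):
        gene = _gene("g1", "chr1", 5000, 7000, "+")
        (a,) = assign_nearest_gene([_peak_at(3000)], [gene])
        assert a.signed_distance == -2000

    def test_upstream_of_minus_strand_is_negative(self):
        gene = _gene("g1", "chr1", 5000, 7001, "-")  # tss = 7000
        (a,) = assign_nearest_gene([_peak_at(9000)], [gene])
        assert a.signed_distance == -2000

    def test_tie_resolves_to_lexicographically_smallest(self):
        gb = _gene("gb", "chr1", 4000, 5001, "+")  # tss 4000
        ga = _gene("ga", "chr1", 6000, 7001, "+")  # tss 6000; peak at 5000 ties
        (a,) = assign_nearest_gene([_peak_at(5000)], [gb, ga])
        assert a.gene_id == "ga"

    def test_chromosome_without_genes(self):
        gene = _gene("g1", "chr1", 5000, 7000, "+")
        (a,) = assign_nearest_gene([_peak_at(5000, chrom="chrX")], [gene])
        assert a.gene_id is None
        assert a.category == "intergenic"

    def test_random_instances_match_exhaustive_search(self):
        rng = np.random.default_rng(5)
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 90_000))
            genes.append(
                _gene(f"g{i:03d}", str(rng.choice(["chr1", "chr2"])),
                      start, start + int(rng.integers(500, 3000)),
                      str(rng.choice(["+", "-"])))
            )
        peaks = [
            _peak_at(int(rng.integers(100, 95_000)), chrom=str(rng.choice(["chr1", "chr2"])))
            for _ in range(500)
        ]
        for a in assign_nearest_gene(peaks, genes):
            center = a.peak.center
            same_chrom = [g for g in genes if g.interval.chrom == a.peak.interval.chrom]
            best = min(abs(center - g.tss) for g in same_chrom)
            expected = min(
                (g for g in same_chrom if abs(center - g.tss) == best),
                key=lambda g: g.gene_id,
            )
            assert a.gene_id == expected.gene_id
            assert abs(a.signed_distance) == best


class TestClassification:
    gene = _gene("g1", "chr1", 5000, 9000, "+", exon_spans=[(5000, 5400), (7000, 7500)])

    def test_upstream_window_is_promoter(self):
        assert classify_genomic_region(_peak_at(4500), [self.gene]) == "promoter"

    def test_exon_outside_promoter_window(self):
        assert classify_genomic_region(_peak_at(7200), [self.gene]) == "exon"

    def test_intron_between_exons(self):
        assert classify_genomic_region(_peak_at(6000), [self.gene]) == "intron"

    def test_intergenic_far_away(self):
        assert classify_genomic_region(_peak_at(20_000), [self.gene]) == "intergenic"

    def test_promoter_precedence_over_exon(self):
        # center within both the promoter window and the first exon
        assert classify_genomic_region(_peak_at(5100), [self.gene]) == "promoter"

    def test_category_frequencies_track_genomic_fractions(self):
        """Random peak centers fall into categories at ~ the bp fraction each occupies."""
        rng = np.random.default_rng(6)
        genes = []
        for i in range(20):
            start = 2000 + i * 4000
            genes.append(
                _gene(f"g{i:02d}", "chr1", start, start + 2000, "+",
                      exon_spans=[(start, start + 500), (start + 1500, start + 2000)])
            )
        span = 90_000
        # exact per-bp truth by brute classification of every position
        cats = {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 0}
        sample = rng.integers(0, span, size=3000)
        observed = {k: 0 for k in cats}
        for pos in sample:
            observed[classify_genomic_region(_peak("chr1", int(pos), int(pos) + 1), genes)] += 1
        # promoter bp fraction: 20 genes x 1200bp / 90kb = 26.7%
        frac_prom = observed["promoter"] / len(sample)
        assert abs(frac_prom - 20 * 1200 / span) < 0.03  # ~4 binomial sds


class TestTssDistribution:
    bins = [(-10_000, -1000), (-1000, 0), (0, 1000), (1000, 10_000)]

    def _assign(self, centers, gene):
        return assign_nearest_gene([_peak_at(c) for c in centers], [gene])

    def test_all_peaks_at_tss(self):
        gene = _gene("g1", "chr1", 50_000, 52_000, "+")
        table = tss_distance_distribution(self._assign([50_000] * 5, gene), self.bins)
        row = table[(table.bin_start == 0)].iloc[0]
        assert row["count"] == 5
        assert row["percent"] == 100.0
        assert table["percent"].sum() == pytest.approx(100.0, abs=0.01)

    def test_empty_assignments_all_zero(self):
        table = tss_distance_distribution([], self.bins)
        assert (table["count"] == 0).all()
        assert (table["percent"] == 0).all()

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            tss_distance_distribution([], [(-100, 100), (50, 200)])

    def test_random_data_matches_brute_binning(self):
        gene = _gene("g1", "chr1", 50_000, 52_000, "+")
        rng = np.random.default_rng(8)
        centers = [int(c) for c in rng.integers(41_000, 59_000, size=200)]
        assignments = self._assign(centers, gene)
        table = tss_distance_distribution(assignments, self.bins)
        for _, row in table.iterrows():
            expected = sum(
                1
                for a in assignments
                if row.bin_start <= a.signed_distance < row.bin_end
            )
            assert row["count"] == expected
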