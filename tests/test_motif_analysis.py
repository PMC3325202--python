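"""PWM scanner oracle checks, enrichment Z semantics, positional bias."""

import math

import numpy as np
import pytest

from targetome.io_formats import GenomicInterval, PWM, Peak
from targetome.motif_analysis import (
    EnrichmentResult,
    MotifHit,
    Region,
    binomial_tail,
    compare_enrichment_profiles,
    enrichment_zscore,
    extract_peak_windows,
    positional_bias,
    scan_pwm,
    scan_regions,
)
from targetome.synthetic_data import nrl_like_pwm

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def oracle_score(seq: str, pwm: PWM, pos: int, strand: str) -> float:
    """Independent per-position rescoring of the similarity formula."""
    m = pwm.matrix if strand == "+" else pwm.matrix[::-1, ::-1]
    num = den = 0.0
    for i in range(len(pwm)):
        row = m[i]
        c = 2.0 + sum(f * math.log2(f) for f in row)
        num += c * row["ACGT".index(seq[pos + i])]
        den += c * max(row)
    return num / den


def _random_pwm(rng, length=9):
    counts = rng.integers(0, 20, size=(length, 4)).astype(float)
    return PWM.from_counts("rand", counts)


class TestExtractWindows:
    def _peak(self, center, chrom="chr1"):
        return Peak(GenomicInterval(chrom, center - 10, center + 10), center)

    def test_default_flank_gives_1001bp(self, small_study):
        genome = small_study["genome"]
        (region,) = extract_peak_windows([self._peak(5000)], genome, flank=500)
        assert len(region.sequence) == 1001
        assert region.start_offset == -500

    def test_chromosome_start_clips_with_bookkeeping(self, small_study):
        genome = small_study["genome"]
        with pytest.warns(UserWarning, match="clipped"):
            (region,) = extract_peak_windows([self._peak(100)], genome, flank=500)
        assert region.start_offset == -100
        assert len(region.sequence) == 601
        assert region.center_index == 100

    def test_unknown_chromosome_rejected(self, small_study):
        with pytest.raises(ValueError, match="unknown"):
            extract_peak_windows([self._peak(5000, chrom="chrZ")], small_study["genome"])

    def test_extraction_equals_substring_oracle(self, small_study):
        genome = small_study["genome"]
        rng = np.random.default_rng(1)
        for _ in range(20):
            center = int(rng.integers(600, len(genome["chr1"]) - 600))
            (region,) = extract_peak_windows([self._peak(center)], genome, flank=500)
            assert region.sequence == genome["chr1"][center - 500 : center + 501]


class TestScanPwm:
    def test_consensus_scores_exactly_one(self):
        pwm = nrl_like_pwm()
        seq = "ACGT" * 10 + pwm.consensus + "ACGT" * 10
        hits = [h for h in scan_pwm(seq, pwm, threshold=0.99) if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(1.0, abs=1e-12)

    def test_all_n_sequence_no_hits(self):
        assert scan_pwm("N" * 200, nrl_like_pwm()) == []

    def test_pwm_longer_than_sequence_empty(self):
        assert scan_pwm("ACGT", nrl_like_pwm()) == []

    def test_planted_consensus_hit_at_known_offset_matches_oracle(self):
        rng = np.random.default_rng(17)
        pwm = nrl_like_pwm()
        seq = list("".join(rng.choice(list("ACGT"), size=200)))
        center = (len(seq) - 1) // 2
        pos = center - 37
        seq[pos : pos + len(pwm)] = pwm.consensus
        seq = "".join(seq)
        hits = scan_pwm(seq, pwm, threshold=0.95)
        top = max(hits, key=lambda h: h.score)
        assert top.offset == -37
        assert top.score == pytest.approx(oracle_score(seq, pwm, pos, "+"), abs=1e-12)

    def test_every_hit_score_matches_rescoring_oracle(self):
        rng = np.random.default_rng(23)
        pwm = _random_pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        center = (len(seq) - 1) // 2
        hits = scan_pwm(seq, pwm, threshold=0.7, core_threshold=0.75)
        assert hits, "fixture should produce at least one hit"
        for h in hits:
            assert h.score == pytest.approx(
                oracle_score(seq, pwm, h.offset + center, h.strand), abs=1e-12
            )

    def test_reverse_complement_mirror_symmetry(self):
        rng = np.random.default_rng(31)
        pwm = nrl_like_pwm()
        seq = list("".join(rng.choice(list("ACGT"), size=401)))
        seq[100 : 100 + len(pwm)] = pwm.consensus
        seq[300 : 300 + len(pwm)] = revcomp(pwm.consensus)
        seq = "".join(seq)
        fwd = scan_pwm(seq, pwm, threshold=0.75)
        rev = scan_pwm(revcomp(seq), pwm, threshold=0.75)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (-(h.offset + h.length - 1), flip[h.strand], round(h.score, 10)) for h in fwd
        )
        assert mirrored == sorted((h.offset, h.strand, round(h.score, 10)) for h in rev)

    def test_substitution_away_from_max_base_never_increases_score(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            pwm = _random_pwm(rng)
            consensus = pwm.consensus
            base_score = oracle_score(consensus, pwm, 0, "+")
            for i in range(len(pwm)):
                for b in "ACGT":
                    mutated = consensus[:i] + b + consensus[i + 1 :]
                    assert oracle_score(mutated, pwm, 0, "+") <= base_score + 1e-12


class TestEnrichmentZ:
    def test_observed_equals_mean_gives_zero(self):
        r = EnrichmentResult.from_counts("m", 5, 10, expected_mean=10.0, expected_sd=2.0)
        assert r.z == 0.0
        assert not r.significant

    def test_boundary_two_sd_is_significant(self):
        r = EnrichmentResult.from_counts("m", 5, 14, expected_mean=10.0, expected_sd=2.0)
        assert r.z == pytest.approx(2.0)
        assert r.significant

    def test_just_below_two_sd_not_significant(self):
        r = EnrichmentResult.from_counts("m", 5, 13, expected_mean=10.0, expected_sd=2.0)
        assert not r.significant

    def test_zero_sd_flagged_degenerate(self):
        hi = EnrichmentResult.from_counts("m", 5, 10, expected_mean=5.0, expected_sd=0.0)
        assert np.isinf(hi.z) and hi.degenerate and hi.significant
        lo = EnrichmentResult.from_counts("m", 5, 5, expected_mean=5.0, expected_sd=0.0)
        assert lo.z == 0.0 and lo.degenerate

    def test_too_few_regions_rejected(self, small_study):
        with pytest.raises(ValueError, match=">= 10"):
            enrichment_zscore(
                [Region("r", "ACGT" * 50)] * 5, nrl_like_pwm(), small_study["genome"]
            )

    def test_planted_regions_enriched_vs_background(self, small_study):
        genome = small_study["genome"]
        truth = small_study["truth"]
        peaks = [
            Peak(s.interval, s.center, name=s.gene_id) for s in truth.planted_sites
        ]
        regions = extract_peak_windows(peaks, genome, flank=300)
        res = enrichment_zscore(regions, nrl_like_pwm(), genome, n_background=50, seed=4)
        assert res.n_regions_with_match == len(regions)
        assert res.z >= 2.0 and res.significant


class TestCompareProfiles:
    def test_identical_groups_equal_z(self, small_study):
        genome = small_study["genome"]
        truth = small_study["truth"]
        peaks = [Peak(s.interval, s.center) for s in truth.planted_sites]
        regions = extract_peak_windows(peaks, genome, flank=200)
        table = compare_enrichment_profiles(
            regions, list(regions), [nrl_like_pwm()], genome, n_background=20, seed=3
        )
        zs = table.groupby("group")["z"].first()
        assert zs["group_a"] == pytest.approx(zs["group_b"])

    def test_motif_planted_only_in_one_group(self, small_study):
        genome = small_study["genome"]
        rng = np.random.default_rng(19)
        pwm = nrl_like_pwm()

        def random_region(i, plant):
            seq = list("".join(rng.choice(list("ACGT"), size=301)))
            if plant:
                seq[140 : 140 + len(pwm)] = pwm.consensus
            return Region(f"r{i}", "".join(seq))

        group_a = [random_region(i, True) for i in range(12)]
        group_b = [random_region(i, False) for i in range(12)]
        table = compare_enrichment_profiles(
            group_a, group_b, [pwm], genome, n_background=50, seed=2
        )
        za = table[table.group == "group_a"].iloc[0]
        zb = table[table.group == "group_b"].iloc[0]
        assert za["significant"] and za["z"] >= 2.0
        assert not zb["significant"]

    def test_empty_library_empty_table(self, small_study):
        regions = [Region("r", "ACGT" * 30)] * 10
        table = compare_enrichment_profiles(
            regions, regions, [], small_study["genome"], n_background=5
        )
        assert table.empty


def brute_binomial_tail(k, n, q):
    return math.fsum(
        math.comb(n, j) * q**j * (1 - q) ** (n - j) for j in range(k, n + 1)
    )


class TestPositionalBias:
    def test_binomial_tail_matches_exact_summation(self):
        for n in (10, 100, 1000):
            q = 50 / 1001
            for k in (0, 1, n // 20, n // 4, n):
                expected = brute_binomial_tail(k, n, q)
                if expected > 1e-290:
                    assert binomial_tail(k, n, q) == pytest.approx(expected, rel=1e-10)

    def test_all_hits_in_one_window_closed_form(self):
        n = 40
        hits = [MotifHit("r", 0, "+", 1.0, 11) for _ in range(n)]
        prof = positional_bias(hits, flank=500, window=50, step=25)
        q = 50 / 1001
        # windows containing the common midpoint see k = N, so P = q^N there
        peak_val = prof.neglog10_p.max()
        assert peak_val == pytest.approx(-n * math.log10(q), rel=1e-9)
        # the maximizing window must contain the common hit midpoint (5)
        best_center = prof.window_centers[int(np.argmax(prof.neglog10_p))]
        assert best_center - 25 <= 5 < best_center + 25

    def test_uniform_expectation_window_is_unremarkable(self):
        # k = N*q exactly: the tail is heavy, -log10 P stays small
        assert -math.log10(binomial_tail(50, 1001, 50 / 1001)) <= 1.0

    def test_no_hits_rejected(self):
        with pytest.raises(ValueError, match="at least one hit"):
            positional_bias([], flank=500)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            positional_bias([MotifHit("r", 0, "+", 1.0, 8)], flank=100, window=300)

    def test_windows_tile_the_scanned_span(self):
        hits = [MotifHit("r", 0, "+", 1.0, 8)]
        prof = positional_bias(hits, flank=500, window=50, step=25)
        assert prof.window_centers[0] == -475.0
        assert prof.window_centers[-1] == 475.0
        assert len(prof.window_centers) == 39
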