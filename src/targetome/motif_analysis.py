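"""PWM scanning, motif enrichment Z-scores and positional-bias profiles.

Scanning uses an information-content-weighted matrix similarity: at each
position the score is

    sim = sum_i C_i * f_i(b_i) / sum_i C_i * max_b f_i(b)

where ``C_i = 2 + sum_b f_i(b) log2 f_i(b)`` is the per-position information
content in bits.  A "core" of the 4 contiguous positions with the highest
total information content must additionally score above its own threshold.
Both strands are scanned; positions containing N never match.  The exact
similarity scheme of the proprietary scanner the field historically used is
not public; this documented formulation preserves the matrix-similarity
concept with configurable thresholds.

Enrichment is scored against length-matched regions sampled uniformly from
the genome: Z = (observed - background mean) / background sd, with Z >= 2
called significant.  Positional bias within peak-centered windows is a
per-window upper binomial tail against uniform hit placement, reported as
-log10 P at the window mid-positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PWM, Peak

__all__ = [
    "Region",
    "MotifHit",
    "EnrichmentResult",
    "PositionalBiasProfile",
    "extract_peak_windows",
    "scan_pwm",
    "scan_regions",
    "enrichment_zscore",
    "positional_bias",
    "compare_enrichment_profiles",
    "binomial_tail",
]

_ENCODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENCODE[ord(b)] = i
    _ENCODE[ord(b.lower())] = i
_ENCODE[ord("N")] = 4
_ENCODE[ord("n")] = 4


@dataclass(frozen=True)
class Region:
    """A peak-centered sequence window.

    ``start_offset`` is the offset of the first base relative to the peak
    center (−flank for an unclipped window), so hit offsets remain
    center-anchored even when the window was clipped at a chromosome end.
    """

    region_id: str
    sequence: str
    start_offset: int = 0

    @property
    def center_index(self) -> int:
        return -self.start_offset


@dataclass(frozen=True)
class MotifHit:
    """A PWM match: offset of the hit start relative to the region center."""

    region_id: str
    offset: int
    strand: str
    score: float
    length: int


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs background-expected motif counts with a Z-score."""

    motif_id: str
    n_regions_with_match: int
    n_matches: int
    expected_mean: float
    expected_sd: float
    z: float
    significant: bool
    degenerate: bool = False  # background sd was zero

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        n_regions_with_match: int,
        n_matches: int,
        expected_mean: float,
        expected_sd: float,
    ) -> "EnrichmentResult":
        degenerate = expected_sd == 0.0
        if degenerate:
            z = np.inf if n_matches > expected_mean else 0.0
        else:
            z = (n_matches - expected_mean) / expected_sd
        return cls(
            motif_id=motif_id,
            n_regions_with_match=n_regions_with_match,
            n_matches=n_matches,
            expected_mean=expected_mean,
            expected_sd=expected_sd,
            z=float(z),
            significant=bool(z >= 2.0),
            degenerate=degenerate,
        )


@dataclass(frozen=True)
class PositionalBiasProfile:
    """-log10 binomial tail per scan window across peak-centered offsets."""

    window_centers: np.ndarray
    neglog10_p: np.ndarray
    window_width: int
    step: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_center": self.window_centers, "neglog10_p": self.neglog10_p}
        )


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def extract_peak_windows(
    peaks: Sequence[Peak], genome: dict[str, str], flank: int = 500
) -> list[Region]:
    """Extract forward-strand sequence +-flank around each peak center.

    Unclipped windows have length ``2*flank + 1``; windows running off a
    chromosome end are clipped with a warning and the offset bookkeeping is
    preserved via ``Region.start_offset``.
    """
    regions: list[Region] = []
    clipped = 0
    for i, peak in enumerate(peaks):
        chrom = peak.interval.chrom
        if chrom not in genome:
            raise ValueError(f"peak on unknown chromosome {chrom!r}")
        seq = genome[chrom]
        center = peak.center
        lo = center - flank
        hi = center + flank + 1
        if lo < 0 or hi > len(seq):
            clipped += 1
        lo_c, hi_c = max(0, lo), min(len(seq), hi)
        regions.append(
            Region(
                region_id=peak.name or f"{chrom}:{center}",
                sequence=seq[lo_c:hi_c],
                start_offset=lo_c - center,
            )
        )
    if clipped:
        warnings.warn(f"{clipped} peak window(s) clipped at chromosome ends")
    return regions


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def _encode(sequence: str) -> np.ndarray:
    enc = _ENCODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if np.any(enc < 0):
        bad = sorted(set(sequence) - set("ACGTNacgtn"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return enc


def _core_slice(pwm: PWM) -> slice:
    """The 4 contiguous positions maximizing total information content."""
    ic = pwm.information_content
    sums = np.convolve(ic, np.ones(4), mode="valid")
    start = int(np.argmax(sums))  # leftmost on ties
    return slice(start, start + 4)


def _similarity_profile(
    enc: np.ndarray, pwm: PWM
) -> tuple[np.ndarray, np.ndarray]:
    """(sim, core_sim) at every start position for one strand's matrix."""
    L = len(pwm)
    f = pwm.matrix
    ic = pwm.information_content
    denom = float(np.sum(ic * f.max(axis=1)))
    if denom <= 0:
        raise ValueError(f"PWM {pwm.motif_id} has no information content")
    w = np.concatenate([ic[:, None] * f, np.full((L, 1), -np.inf)], axis=1)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    scores = w[np.arange(L)[None, :], windows]  # (n_pos, L)
    sim = scores.sum(axis=1) / denom
    core = _core_slice(pwm)
    core_denom = float(np.sum(ic[core] * f[core].max(axis=1)))
    core_sim = scores[:, core].sum(axis=1) / core_denom
    return sim, core_sim


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold: float = 0.80,
    core_threshold: float = 0.90,
    region_id: str = "",
    center_index: int | None = None,
) -> list[MotifHit]:
    """Scan both strands of a sequence for PWM matches.

    A hit requires ``sim >= threshold`` and core-restricted similarity
    ``>= core_threshold``.  Hit offsets are the forward-strand start
    positions relative to ``center_index`` (the sequence midpoint by
    default); a PWM longer than the sequence yields no hits.
    """
    L = len(pwm)
    if L > len(sequence):
        return []
    if center_index is None:
        center_index = (len(sequence) - 1) // 2
    enc = _encode(sequence)
    hits: list[MotifHit] = []
    for strand, matrix_pwm in (("+", pwm), ("-", pwm.reverse_complement())):
        sim, core_sim = _similarity_profile(enc, matrix_pwm)
        ok = np.flatnonzero((sim >= threshold) & (core_sim >= core_threshold))
        for p in ok:
            hits.append(
                MotifHit(
                    region_id=region_id,
                    offset=int(p) - center_index,
                    strand=strand,
                    score=float(sim[p]),
                    length=L,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_regions(
    regions: Sequence[Region],
    pwm: PWM,
    threshold: float = 0.80,
    core_threshold: float = 0.90,
) -> list[MotifHit]:
    """Scan peak-centered regions; offsets are relative to each peak center."""
    hits: list[MotifHit] = []
    for region in regions:
        hits.extend(
            scan_pwm(
                region.sequence,
                pwm,
                threshold=threshold,
                core_threshold=core_threshold,
                region_id=region.region_id,
                center_index=region.center_index,
            )
        )
    return hits


def _count_matches(
    sequences: Sequence[str], pwm: PWM, threshold: float, core_threshold: float
) -> tuple[int, int]:
    """(total matches, sequences with >=1 match) over both strands."""
    total = 0
    with_match = 0
    for seq in sequences:
        n = len(scan_pwm(seq, pwm, threshold=threshold, core_threshold=core_threshold))
        total += n
        with_match += n > 0
    return total, with_match


# ---------------------------------------------------------------------------
# enrichment against sampled genomic background
# ---------------------------------------------------------------------------

def enrichment_zscore(
    regions: Sequence[Region],
    pwm: PWM,
    genome: dict[str, str],
    n_background: int = 100,
    seed: int | Sequence[int] = 0,
    threshold: float = 0.80,
    core_threshold: float = 0.90,
    min_regions: int = 10,
) -> EnrichmentResult:
    """Z-score of observed motif matches against length-matched background.

    Each of ``n_background`` replicates samples, for every input region, one
    region of identical length uniformly from the genome and counts matches
    there; Z standardizes the observed total against the replicate mean and
    sd (sd = 0 gives Z = +inf if observed exceeds the mean, else 0, and the
    result is flagged degenerate).  The significance rule is Z >= 2.
    """
    if len(regions) < min_regions:
        raise ValueError(f"enrichment needs >= {min_regions} regions, got {len(regions)}")
    lengths = [len(r.sequence) for r in regions]
    chroms = sorted(genome)
    max_len = max(len(genome[c]) for c in chroms)
    if max(lengths) > max_len:
        raise ValueError("genome chromosomes shorter than the longest region")

    observed, with_match = _count_matches(
        [r.sequence for r in regions], pwm, threshold, core_threshold
    )

    rng = np.random.default_rng(seed)
    bg_counts = np.empty(n_background)
    for rep in range(n_background):
        seqs = []
        for ell in lengths:
            feasible = [c for c in chroms if len(genome[c]) >= ell]
            weights = np.array([len(genome[c]) - ell + 1 for c in feasible], dtype=float)
            chrom = feasible[rng.choice(len(feasible), p=weights / weights.sum())]
            start = int(rng.integers(0, len(genome[chrom]) - ell + 1))
            seqs.append(genome[chrom][start : start + ell])
        bg_counts[rep], _ = _count_matches(seqs, pwm, threshold, core_threshold)

    return EnrichmentResult.from_counts(
        motif_id=pwm.motif_id,
        n_regions_with_match=with_match,
        n_matches=observed,
        expected_mean=float(bg_counts.mean()),
        expected_sd=float(bg_counts.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# positional bias
# ---------------------------------------------------------------------------

def binomial_tail(k: int, n: int, q: float) -> float:
    """Upper binomial tail P(X >= k | n, q)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, q))


def positional_bias(
    hits: Sequence[MotifHit],
    flank: int = 500,
    window: int = 50,
    step: int = 25,
) -> PositionalBiasProfile:
    """Per-window -log10 binomial tail of hit-midpoint counts vs uniform.

    With N total hits and windows of ``window`` bp tiling [-flank, +flank],
    each window's null is Binomial(N, q) with q = window / (2*flank + 1);
    the profile is -log10 of the upper tail P(X >= k) at each window's
    mid-position.  Over-represented offsets appear as peaks in the profile.
    """
    if window > 2 * flank:
        raise ValueError("window must not exceed the scanned span 2*flank")
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    n_hits = len(hits)
    if n_hits < 1:
        raise ValueError("positional bias requires at least one hit")
    midpoints = np.array([h.offset + h.length // 2 for h in hits])
    span = 2 * flank + 1
    q = window / span
    starts = np.arange(-flank, flank - window + 2, step)
    centers = starts + window / 2.0
    neglog = np.empty(len(starts))
    for i, s in enumerate(starts):
        k = int(np.sum((midpoints >= s) & (midpoints < s + window)))
        if k <= 0:
            neglog[i] = 0.0
        else:
            # log-space tail for numerical range; P in (0, 1]
            logsf = stats.binom.logsf(k - 1, n_hits, q)
            neglog[i] = max(0.0, -logsf / np.log(10.0))
    return PositionalBiasProfile(
        window_centers=centers, neglog10_p=neglog, window_width=window, step=step
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_enrichment_profiles(
    regions_a: Sequence[Region],
    regions_b: Sequence[Region],
    pwm_library: Sequence[PWM],
    genome: dict[str, str],
    n_background: int = 100,
    seed: int = 0,
    threshold: float = 0.80,
    core_threshold: float = 0.90,
    group_labels: tuple[str, str] = ("group_a", "group_b"),
    min_regions: int = 10,
) -> pd.DataFrame:
    """Per-motif enrichment Z for two region groups, ranked by Z within group.

    The same per-motif background seed is used for both groups so that
    identical groups produce identical Z values.
    """
    if len(regions_a) == 0 or len(regions_b) == 0:
        raise ValueError("both region groups must be non-empty")
    rows = []
    for mi, pwm in enumerate(pwm_library):
        for label, regions in zip(group_labels, (regions_a, regions_b)):
            res = enrichment_zscore(
                regions,
                pwm,
                genome,
                n_background=n_background,
                seed=[seed, mi],
                threshold=threshold,
                core_threshold=core_threshold,
                min_regions=min_regions,
            )
            rows.append(
                {
                    "group": label,
                    "motif_id": res.motif_id,
                    "family": pwm.family,
                    "n_regions": len(regions),
                    "n_regions_with_match": res.n_regions_with_match,
                    "n_matches": res.n_matches,
                    "expected_mean": res.expected_mean,
                    "expected_sd": res.expected_sd,
                    "z": res.z,
                    "significant": res.significant,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "group", "motif_id", "family", "n_regions", "n_regions_with_match",
                "n_matches", "expected_mean", "expected_sd", "z", "significant",
            ]
        )
    return (
        df.sort_values(["group", "z"], ascending=[True, False])
        .reset_index(drop=True)
    )
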