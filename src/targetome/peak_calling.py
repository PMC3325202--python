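"""Window-based Poisson peak callers, their intersection, and summaries.

Two documented callers stand in for the dual black-box callers of the
original workflow: both slide a fixed window over per-bp tag coverage and
test the window's treatment tag count against a Poisson background, merging
significant windows into peaks.  They differ only in the background model —
``call_peaks_global`` uses a single genome-wide rate while
``call_peaks_local`` takes the maximum of the global rate and a locally
estimated rate (guarding against local control pileups).  Keeping the peaks
found by both callers (``intersect_peak_sets``) preserves the
dual-caller-intersection structure of the analysis.

Thresholds are on raw Poisson tail probabilities; no multiple-testing
correction is applied inside the callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomicInterval, Peak

__all__ = [
    "Peak",
    "PeakSetSummary",
    "call_peaks_global",
    "call_peaks_local",
    "intersect_peak_sets",
    "summarize_peaks",
    "poisson_sf",
]

Tracks = Mapping[str, np.ndarray]


def poisson_sf(obs: int, lam: float) -> float:
    """Upper Poisson tail P(X >= obs | lam)."""
    if obs <= 0:
        return 1.0
    return float(stats.poisson.sf(obs - 1, lam))


def _as_tracks(track: Tracks | np.ndarray) -> dict[str, np.ndarray]:
    if isinstance(track, Mapping):
        return {c: np.asarray(v) for c, v in track.items()}
    return {"chr1": np.asarray(track)}


def _validate_pair(treatment: dict[str, np.ndarray], control: dict[str, np.ndarray]) -> None:
    if set(treatment) != set(control):
        raise ValueError("treatment and control cover different chromosomes")
    for chrom in treatment:
        if len(treatment[chrom]) != len(control[chrom]):
            raise ValueError(f"track length mismatch on {chrom}")
    if sum(int(v.sum()) for v in control.values()) == 0:
        raise ValueError("control track is all zero; a nonzero background is required")


def _window_sums(track: np.ndarray, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(track)
    if n < window:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = np.arange(0, n - window + 1, step)
    csum = np.concatenate([[0], np.cumsum(track)])
    return starts, csum[starts + window] - csum[starts]


def _merge_significant(
    treatment: np.ndarray,
    starts: np.ndarray,
    pvals: np.ndarray,
    sig: np.ndarray,
    window: int,
    chrom: str,
    caller: str,
) -> list[Peak]:
    """Merge overlapping/adjacent significant windows into peaks."""
    peaks: list[Peak] = []
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return peaks
    run_start = idx[0]
    prev = idx[0]
    runs = []
    for i in idx[1:]:
        # windows at consecutive starts overlap or touch when the gap between
        # window starts does not exceed the window width
        if starts[i] - starts[prev] <= window:
            prev = i
            continue
        runs.append((run_start, prev))
        run_start = prev = i
    runs.append((run_start, prev))
    for a, b in runs:
        region_start = int(starts[a])
        region_end = int(starts[b]) + window
        members = idx[(idx >= a) & (idx <= b)]
        sub = treatment[region_start:region_end]
        summit = region_start + int(np.argmax(sub))  # argmax -> leftmost tie
        pv = float(pvals[members].min())
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, region_start, region_end),
                summit=summit,
                height=float(treatment[summit]),
                # sf underflows to 0 for extreme enrichment; clamp to the
                # smallest positive float so the (0, 1] invariant holds
                pvalue=pv if pv > 0.0 else float(np.nextafter(0.0, 1.0)),
                caller=caller,
            )
        )
    return peaks


def call_peaks_global(
    treatment: Tracks | np.ndarray,
    control: Tracks | np.ndarray,
    p_threshold: float = 1e-6,
    window: int = 300,
    step: int = 50,
) -> list[Peak]:
    """Call peaks against a single genome-wide Poisson background rate.

    The expected window count is
    ``lambda = control_total * (window / genome_length) * (treatment_total /
    control_total)``, i.e. the depth-matched uniform expectation; a window is
    significant when its upper Poisson tail falls below ``p_threshold``
    (default 1e-6).  Overlapping or adjacent significant windows are merged;
    the summit is the leftmost treatment-coverage maximum in the merged
    region and the reported p-value is the minimum over merged windows.
    """
    return _call_windowed(treatment, control, p_threshold, window, step, local_flank=None)


def call_peaks_local(
    treatment: Tracks | np.ndarray,
    control: Tracks | np.ndarray,
    p_threshold: float = 1e-3,
    window: int = 300,
    step: int = 50,
    local_flank: int = 5000,
) -> list[Peak]:
    """Call peaks with lambda = max(global, local control rate in +-local_flank).

    Identical to :func:`call_peaks_global` except that each window's Poisson
    rate is the maximum of the genome-wide rate and the depth-scaled control
    rate estimated in a ``+-local_flank`` neighbourhood, which suppresses
    apparent enrichment over local control pileups.  Default threshold 1e-3.
    """
    return _call_windowed(treatment, control, p_threshold, window, step, local_flank=local_flank)


def _call_windowed(
    treatment: Tracks | np.ndarray,
    control: Tracks | np.ndarray,
    p_threshold: float,
    window: int,
    step: int,
    local_flank: int | None,
) -> list[Peak]:
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    treatment = _as_tracks(treatment)
    control = _as_tracks(control)
    _validate_pair(treatment, control)

    genome_length = sum(len(v) for v in treatment.values())
    treat_total = sum(int(v.sum()) for v in treatment.values())
    control_total = sum(int(v.sum()) for v in control.values())
    depth_ratio = treat_total / control_total
    lam_global = control_total * (window / genome_length) * depth_ratio
    caller = "global" if local_flank is None else "local"

    peaks: list[Peak] = []
    for chrom in sorted(treatment):
        t = treatment[chrom]
        c = control[chrom]
        starts, obs = _window_sums(t, window, step)
        if starts.size == 0:
            continue
        if local_flank is None:
            lam = np.full(starts.shape, lam_global)
        else:
            n = len(c)
            csum = np.concatenate([[0], np.cumsum(c)])
            lo = np.clip(starts - local_flank, 0, n)
            hi = np.clip(starts + window + local_flank, 0, n)
            local_rate = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
            lam_local = local_rate * window * depth_ratio
            lam = np.maximum(lam_global, lam_local)
        pvals = stats.poisson.sf(obs - 1, lam)
        pvals = np.where(obs > 0, pvals, 1.0)
        sig = pvals < p_threshold
        peaks.extend(_merge_significant(t, starts, pvals, sig, window, chrom, caller))
    return peaks


def intersect_peak_sets(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> list[Peak]:
    """Keep only regions supported by both callers, as merged union intervals.

    Peaks from both sets are clustered by transitive >=1 bp overlap; every
    cluster containing at least one peak from each input emits a single peak
    spanning the cluster's union interval, with summit and height taken from
    the highest-height contributor (leftmost on ties) and the minimum member
    p-value.  Peaks with no cross-set overlap are dropped.
    """
    tagged = [(p, 0) for p in peaks_a] + [(p, 1) for p in peaks_b]
    tagged.sort(key=lambda t: (t[0].interval.chrom, t[0].interval.start, t[0].interval.end, t[1]))
    out: list[Peak] = []
    cluster: list[tuple[Peak, int]] = []
    cluster_end = -1
    cluster_chrom = None

    def flush() -> None:
        labels = {lab for _, lab in cluster}
        if labels != {0, 1}:
            return
        start = min(p.interval.start for p, _ in cluster)
        end = max(p.interval.end for p, _ in cluster)
        best = max(cluster, key=lambda t: (t[0].height, -t[0].summit))[0]
        out.append(
            Peak(
                interval=GenomicInterval(cluster_chrom, start, end),
                summit=best.summit,
                height=best.height,
                pvalue=min(p.pvalue for p, _ in cluster),
                caller="intersect",
            )
        )

    for peak, label in tagged:
        iv = peak.interval
        if cluster and iv.chrom == cluster_chrom and iv.start < cluster_end:
            cluster.append((peak, label))
            cluster_end = max(cluster_end, iv.end)
        else:
            if cluster:
                flush()
            cluster = [(peak, label)]
            cluster_chrom = iv.chrom
            cluster_end = iv.end
    if cluster:
        flush()
    return out


@dataclass(frozen=True)
class PeakSetSummary:
    """Summary statistics of a peak set (counts, footprint, width, heights)."""

    n_peaks: int
    coverage_bp: int
    mean_width: float
    mean_height: float
    median_height: float
    min_height: float


def summarize_peaks(peaks: Sequence[Peak]) -> PeakSetSummary:
    """Peak count, unique-bp footprint, mean width and height statistics.

    ``coverage_bp`` counts each base once even when peaks overlap.  An empty
    set reports zeros throughout.
    """
    if not peaks:
        return PeakSetSummary(0, 0, 0.0, 0.0, 0.0, 0.0)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
    coverage = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                coverage += cur_e - cur_s
                cur_s, cur_e = s, e
        coverage += cur_e - cur_s
    widths = np.array([p.interval.length for p in peaks], dtype=float)
    heights = np.array([p.height for p in peaks], dtype=float)
    return PeakSetSummary(
        n_peaks=len(peaks),
        coverage_bp=int(coverage),
        mean_width=float(widths.mean()),
        mean_height=float(heights.mean()),
        median_height=float(np.median(heights)),
        min_height=float(heights.min()),
    )
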