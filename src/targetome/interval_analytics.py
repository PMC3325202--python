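"""Peak-set concordance, nearest-gene assignment and genomic classification.

Distances between peak sets are measured center-to-center (summits are
caller-dependent); distances to genes are peak-center-to-TSS.  Nearest-
neighbour (not all-pairs) counting is used throughout: each query peak
contributes the signed distance to its single nearest reference anchor,
with deterministic tie-breaking (smaller absolute distance, then the
downstream/negative side, then lexicographically smallest gene id).

The sign convention for anchor-to-anchor distances is ``query - reference``
(a reference sitting downstream of the query gives a negative distance);
for gene assignment the sign is strand-aware, negative upstream of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Peak

__all__ = [
    "DistanceHistogram",
    "GeneAssignment",
    "peak_centers",
    "tss_anchors",
    "nearest_signed_distances",
    "distance_correlation",
    "fraction_within",
    "assign_nearest_gene",
    "classify_genomic_region",
    "tss_distance_distribution",
]

Anchor = tuple[str, int]


def peak_centers(peaks: Sequence[Peak]) -> list[Anchor]:
    """Peak centers as (chrom, position) anchors."""
    return [(p.interval.chrom, p.center) for p in peaks]


def tss_anchors(genes: Sequence[GeneModel]) -> list[Anchor]:
    """Gene TSS positions as (chrom, position) anchors."""
    return [(g.interval.chrom, g.tss) for g in genes]


def _anchors_by_chrom(anchors: Sequence[Anchor]) -> dict[str, np.ndarray]:
    grouped: dict[str, list[int]] = {}
    for chrom, pos in anchors:
        grouped.setdefault(chrom, []).append(pos)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in grouped.items()}


def nearest_signed_distances(
    query: Sequence[Anchor], reference: Sequence[Anchor]
) -> np.ndarray:
    """Signed distance (query - reference) to the nearest reference anchor.

    Ties on absolute distance resolve to the negative side (reference
    downstream).  Queries on chromosomes without any reference anchor get
    +inf.
    """
    ref = _anchors_by_chrom(reference)
    out = np.full(len(query), np.inf)
    for i, (chrom, pos) in enumerate(query):
        positions = ref.get(chrom)
        if positions is None or positions.size == 0:
            continue
        j = int(np.searchsorted(positions, pos))
        best = None
        for k in (j - 1, j):
            if 0 <= k < positions.size:
                d = pos - int(positions[k])
                if (
                    best is None
                    or abs(d) < abs(best)
                    or (abs(d) == abs(best) and d < best)
                ):
                    best = d
        out[i] = best
    return out


@dataclass(frozen=True)
class DistanceHistogram:
    """Binned nearest-anchor signed distances of a query set to a reference."""

    bin_edges: np.ndarray
    counts: np.ndarray
    query_label: str = "query"
    reference_label: str = "reference"

    @property
    def n_binned(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def distance_correlation(
    query_peaks: Sequence[Peak] | Sequence[Anchor],
    reference_anchors: Sequence[Peak] | Sequence[Anchor],
    max_dist: int = 10_000,
    bin: int = 50,
    query_label: str = "query",
    reference_label: str = "reference",
) -> DistanceHistogram:
    """Histogram of signed nearest-reference distances for each query center.

    Accepts peaks (their centers are used) or raw (chrom, pos) anchors.
    Distances beyond +-max_dist are excluded from the counts.
    """
    if bin <= 0 or max_dist <= 0:
        raise ValueError("bin and max_dist must be > 0")
    q = _as_anchors(query_peaks)
    r = _as_anchors(reference_anchors)
    dists = nearest_signed_distances(q, r)
    dists = dists[np.isfinite(dists)]
    n_bins = int(np.ceil(2 * max_dist / bin))
    edges = -max_dist + bin * np.arange(n_bins + 1)
    counts, _ = np.histogram(dists[(dists >= edges[0]) & (dists < edges[-1])], bins=edges)
    return DistanceHistogram(edges, counts, query_label, reference_label)


def _as_anchors(items: Sequence) -> list[Anchor]:
    if len(items) and isinstance(items[0], Peak):
        return peak_centers(items)  # type: ignore[arg-type]
    return list(items)


def fraction_within(
    query_peaks: Sequence[Peak] | Sequence[Anchor],
    reference_anchors: Sequence[Peak] | Sequence[Anchor],
    d: int,
) -> float:
    """Percentage of query anchors with a reference anchor within d bp.

    Center-to-center (or center-to-TSS) distance; a distance of exactly
    ``d`` counts as within.  Raises on an empty query (the percentage is
    undefined).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    q = _as_anchors(query_peaks)
    if not q:
        raise ValueError("fraction_within is undefined for an empty query set")
    r = _as_anchors(reference_anchors)
    dists = nearest_signed_distances(q, r)
    return 100.0 * float(np.sum(np.abs(dists) <= d)) / len(q)


@dataclass(frozen=True)
class GeneAssignment:
    """A peak assigned to its nearest gene by center-to-TSS distance."""

    peak: Peak
    gene_id: str | None
    signed_distance: int | None  # negative upstream of the gene, strand-aware
    category: str  # promoter | exon | intron | intergenic


def assign_nearest_gene(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 200,
) -> list[GeneAssignment]:
    """Assign each peak to the gene with the nearest TSS on its chromosome.

    Nearest minimizes |peak center - TSS|; ties resolve to the
    lexicographically smallest gene id.  The signed distance is strand-aware
    (negative upstream of the gene).  A peak on a chromosome without genes is
    assigned gene_id None and category intergenic.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    tss_sorted: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, gl in by_chrom.items():
        gl = sorted(gl, key=lambda g: (g.tss, g.gene_id))
        tss_sorted[chrom] = (np.array([g.tss for g in gl], dtype=np.int64), gl)

    out: list[GeneAssignment] = []
    for peak in peaks:
        chrom = peak.interval.chrom
        if chrom not in tss_sorted:
            out.append(GeneAssignment(peak, None, None, "intergenic"))
            continue
        positions, gl = tss_sorted[chrom]
        center = peak.center
        j = int(np.searchsorted(positions, center))
        best_abs = None
        for k in (j - 1, j):
            if 0 <= k < positions.size:
                d = abs(center - int(positions[k]))
                if best_abs is None or d < best_abs:
                    best_abs = d
        # all genes achieving the minimal distance, then lexicographic id
        candidates = [g for g in gl if abs(center - g.tss) == best_abs]
        gene = min(candidates, key=lambda g: g.gene_id)
        d = center - gene.tss
        signed = d if gene.strand != "-" else -d
        category = classify_genomic_region(
            peak, by_chrom[chrom], promoter_up=promoter_up, promoter_down=promoter_down
        )
        out.append(GeneAssignment(peak, gene.gene_id, int(signed), category))
    return out


def classify_genomic_region(
    peak: Peak,
    genes: Sequence[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 200,
) -> str:
    """Classify a peak by its center with precedence promoter > exon > intron.

    The promoter window is ``[TSS - promoter_up, TSS + promoter_down)`` in
    gene orientation; a center inside any gene's promoter window is a
    promoter peak regardless of overlap with another gene's exon or intron.
    """
    center = peak.center
    chrom = peak.interval.chrom
    in_exon = False
    in_gene = False
    for gene in genes:
        if gene.interval.chrom != chrom:
            continue
        offset = center - gene.tss if gene.strand != "-" else gene.tss - center
        if -promoter_up <= offset < promoter_down:
            return "promoter"
        if gene.interval.contains(center):
            in_gene = True
            if any(e.contains(center) for e in gene.exons):
                in_exon = True
    if in_exon:
        return "exon"
    if in_gene:
        return "intron"
    return "intergenic"


def tss_distance_distribution(
    assignments: Sequence[GeneAssignment],
    bins: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Counts and percentages of assignments per signed TSS-distance bin.

    ``bins`` are disjoint half-open ``[lo, hi)`` intervals expected to cover
    the distances of interest; overlapping bins are an error.  Percentages
    are of assignments with a gene and sum to 100 when every distance falls
    in some bin.
    """
    ordered = sorted(bins, key=lambda b: b[0])
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping bins [{lo1},{hi1}) and [{lo2},{hi2})")
    for lo, hi in bins:
        if hi <= lo:
            raise ValueError(f"empty bin [{lo},{hi})")
    dists = [a.signed_distance for a in assignments if a.signed_distance is not None]
    total = len(dists)
    rows = []
    for lo, hi in bins:
        count = sum(1 for d in dists if lo <= d < hi)
        rows.append(
            {
                "bin_start": lo,
                "bin_end": hi,
                "count": count,
                "percent": 100.0 * count / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "count", "percent"])
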