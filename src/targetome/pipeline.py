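"""Top-level integration: co-occupancy, disease loci and the pipeline runner.

``run_pipeline`` executes the full analysis on a synthesized study: peak
calling with two callers on two platforms, per-platform intersection,
cross-platform concordance, nearest-gene assignment, knockout-expression
integration into a direct-target table, co-occupancy splitting against a
second factor's peaks, per-group motif enrichment with positional-bias
profiling, and a disease-locus report.  Every intermediate is written to
disk and the whole run is a deterministic function of the configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression_integration import (
    TargetRecord,
    compute_fold_changes,
    define_direct_targets,
)
from .interval_analytics import (
    assign_nearest_gene,
    fraction_within,
    nearest_signed_distances,
    peak_centers,
)
from .io_formats import (
    GeneModel,
    GenomicInterval,
    Peak,
    write_bed,
    write_expression,
    write_fasta,
    write_gtf,
    write_loci,
    write_pwm_library,
)
from .motif_analysis import (
    compare_enrichment_profiles,
    extract_peak_windows,
    positional_bias,
    scan_regions,
)
from .peak_calling import (
    call_peaks_global,
    call_peaks_local,
    intersect_peak_sets,
    summarize_peaks,
)
from .synthetic_data import (
    PLATFORMS,
    SimulationConfig,
    TruthSet,
    default_pwm_library,
    generate_disease_loci,
    generate_genome_and_genes,
    nrl_like_pwm,
    plant_sites_and_simulate_tags,
    simulate_expression,
)

__all__ = [
    "CooccupancySplit",
    "LocusReport",
    "PipelineConfig",
    "PipelineError",
    "split_by_cooccupancy",
    "map_disease_loci",
    "run_pipeline",
]


@dataclass(frozen=True)
class CooccupancySplit:
    """Partition of a peak set by proximity to a second factor's peaks."""

    cobound: tuple[Peak, ...]
    solo: tuple[Peak, ...]
    d: int

    def __post_init__(self) -> None:
        n = len(self.cobound) + len(self.solo)
        ids = {id(p) for p in self.cobound} | {id(p) for p in self.solo}
        if len(ids) != n:
            raise ValueError("cobound and solo must partition the input")

    @property
    def cobound_fraction(self) -> float:
        total = len(self.cobound) + len(self.solo)
        return 100.0 * len(self.cobound) / total if total else 0.0


def split_by_cooccupancy(
    peaks: Sequence[Peak],
    cofactor_peaks: Sequence[Peak] | Sequence[tuple[str, int]],
    d: int = 500,
) -> CooccupancySplit:
    """Split peaks into co-bound vs solo by center-to-center distance <= d.

    A peak is co-bound when the nearest co-factor peak center lies within
    ``d`` bp (inclusive), the rule used to define joint cis-regulatory
    modules.  An empty co-factor set leaves every peak solo.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if not peaks:
        return CooccupancySplit((), (), d)
    if len(cofactor_peaks) == 0:
        return CooccupancySplit((), tuple(peaks), d)
    anchors = (
        peak_centers(cofactor_peaks)  # type: ignore[arg-type]
        if isinstance(cofactor_peaks[0], Peak)
        else list(cofactor_peaks)
    )
    dists = nearest_signed_distances(peak_centers(peaks), anchors)
    cobound = tuple(p for p, dd in zip(peaks, dists) if abs(dd) <= d)
    solo = tuple(p for p, dd in zip(peaks, dists) if not abs(dd) <= d)
    return CooccupancySplit(cobound, solo, d)


@dataclass(frozen=True)
class LocusReport:
    """Genes and target genes within one disease locus.

    ``fold_enrichment`` follows the printed convention of dividing the total
    gene count in the locus by the target-gene count (note this is the
    inverse of the usual enrichment ratio; see ``map_disease_loci`` for the
    conventional alternative).
    """

    locus_id: str
    interval: GenomicInterval
    total_genes: int
    target_genes: int
    fold_enrichment: float

    def __post_init__(self) -> None:
        if self.target_genes > self.total_genes:
            raise ValueError("target_genes cannot exceed total_genes")


def map_disease_loci(
    target_gene_ids: set[str],
    genes: Sequence[GeneModel],
    loci: pd.DataFrame,
    include_empty: bool = False,
    conventional_ratio: bool = False,
) -> list[LocusReport]:
    """Count genes and target genes per locus by TSS containment.

    ``fold_enrichment = total_genes / target_genes`` as printed in the
    source table; with ``conventional_ratio=True`` it is instead the
    target fraction in the locus over the genome-wide target fraction.
    Loci containing no target genes are omitted unless ``include_empty``.
    """
    reports: list[LocusReport] = []
    n_all = len(genes)
    n_targets_all = len(target_gene_ids & {g.gene_id for g in genes})
    for row in loci.itertuples(index=False):
        total = 0
        targets = 0
        for g in genes:
            if g.interval.chrom == row.chrom and row.start <= g.tss < row.end:
                total += 1
                targets += g.gene_id in target_gene_ids
        if targets == 0 and not include_empty:
            continue
        if targets == 0:
            fe = float("nan")
        elif conventional_ratio:
            genome_rate = n_targets_all / n_all if n_all else float("nan")
            fe = (targets / total) / genome_rate if genome_rate else float("nan")
        else:
            fe = total / targets
        reports.append(
            LocusReport(
                locus_id=str(row.locus_id),
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                total_genes=total,
                target_genes=targets,
                fold_enrichment=fe,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails, naming the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration: simulation plus analysis parameters."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    p_threshold_global: float = 1e-6
    p_threshold_local: float = 1e-3
    window: int = 300
    step: int = 50
    local_flank: int = 5000
    flank: int = 500
    cooccupancy_d: int = 500
    fc_threshold: float = 1.5
    n_background: int = 100
    scan_threshold: float = 0.80
    core_threshold: float = 0.90
    motif_min_regions: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (payload.pop("simulation", {}) or {}).items()
        })
        return cls(simulation=sim, **payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _match_metrics(
    peaks: Sequence[Peak], sites: Sequence, d: int = 500
) -> tuple[float, float]:
    """(recall, precision) of peak centers against planted-site centers."""
    site_anchors = [(s.interval.chrom, s.center) for s in sites]
    if not sites:
        return (float("nan"), float("nan") if peaks else float("nan"))
    if not peaks:
        return 0.0, float("nan")
    pk_anchors = peak_centers(peaks)
    d_peaks = nearest_signed_distances(pk_anchors, site_anchors)
    d_sites = nearest_signed_distances(site_anchors, pk_anchors)
    recall = float(np.mean(np.abs(d_sites) <= d))
    precision = float(np.mean(np.abs(d_peaks) <= d))
    return recall, precision


def _cobound_accuracy(
    split: CooccupancySplit, truth: TruthSet, d: int = 500
) -> float:
    """Fraction of truth-matched peaks whose co-bound call matches the truth flag."""
    site_anchors = [(s.interval.chrom, s.center) for s in truth.planted_sites]
    flags = [s.cofactor for s in truth.planted_sites]
    correct = 0
    total = 0
    for predicted, peaks in ((True, split.cobound), (False, split.solo)):
        if not peaks:
            continue
        dists = nearest_signed_distances(peak_centers(peaks), site_anchors)
        for peak, dd in zip(peaks, dists):
            if not np.isfinite(dd) or abs(dd) > d:
                continue
            # index of matched site
            idx = min(
                range(len(site_anchors)),
                key=lambda i: abs(peak.center - site_anchors[i][1])
                if site_anchors[i][0] == peak.interval.chrom
                else np.inf,
            )
            total += 1
            correct += flags[idx] == predicted
    return correct / total if total else float("nan")


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return run

    return wrap


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full synthetic-study analysis; write all intermediates.

    Returns a report bundle: a dict holding the in-memory results, the
    recovery metrics against the simulation truth, and the paths of every
    written file.  The same configuration produces byte-identical output
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    paths: dict[str, str] = {}

    def _write(name: str, fname: str, writer, *args) -> None:
        p = outdir / fname
        writer(*args, p)
        paths[name] = str(p)

    # --- synthesis -------------------------------------------------------
    synth = _stage("synthesize")(lambda: _synthesize(sim))
    genome, genes, truth, coverage, expr, loci, pwm_library = synth()
    _write("genome", "genome.fa", write_fasta, genome)
    _write("genes", "genes.gtf", write_gtf, genes)
    _write("expression", "expression.tsv", write_expression, expr)
    _write("loci", "disease_loci.tsv", write_loci, loci)
    _write("pwms", "pwm_library.txt", write_pwm_library, pwm_library)
    truth.to_json(outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    cofactor_peaks = [
        Peak(iv, summit=iv.center, height=1.0, name=f"cofactor_{i + 1}")
        for i, iv in enumerate(truth.cofactor_peak_truth)
    ]
    _write("cofactor_peaks", "cofactor_peaks.bed", write_bed, cofactor_peaks)

    # --- peak calling per platform --------------------------------------
    call = _stage("peak_calling")(_call_platform)
    intersected: dict[str, list[Peak]] = {}
    summaries = []
    for platform in PLATFORMS:
        by_caller, inter = call(coverage[platform], config)
        intersected[platform] = inter
        for caller, pk in [*by_caller.items(), ("intersect", inter)]:
            _write(f"peaks_{platform}_{caller}", f"peaks_{platform}_{caller}.bed", write_bed, pk)
            s = summarize_peaks(pk)
            summaries.append({"platform": platform, "caller": caller, **dataclasses.asdict(s)})
    summary_df = pd.DataFrame(summaries)
    _write("peak_summaries", "peak_summaries.tsv",
           lambda df, p: df.to_csv(p, sep="\t", index=False), summary_df)

    # --- concordance -----------------------------------------------------
    conc = _stage("concordance")(_concordance)
    concordance = conc(intersected, config)
    _write("concordance", "concordance.tsv",
           lambda d, p: pd.DataFrame([d]).to_csv(p, sep="\t", index=False), concordance)

    # --- nearest gene + expression integration --------------------------
    integrate = _stage("expression_integration")(_integrate)
    assignments, expr_records, target_records = integrate(intersected, genes, expr, config)
    assign_df = pd.DataFrame(
        [
            {
                "chrom": a.peak.interval.chrom,
                "peak_center": a.peak.center,
                "gene_id": a.gene_id,
                "signed_distance": a.signed_distance,
                "category": a.category,
            }
            for a in assignments
        ]
    )
    _write("assignments", "assignments.tsv",
           lambda df, p: df.to_csv(p, sep="\t", index=False), assign_df)
    targets_df = pd.DataFrame([dataclasses.asdict(t) for t in target_records])
    _write("targets", "direct_targets.tsv",
           lambda df, p: df.to_csv(p, sep="\t", index=False), targets_df)

    # --- co-occupancy ----------------------------------------------------
    cosplit = _stage("cooccupancy")(
        lambda: {
            platform: split_by_cooccupancy(
                intersected[platform], cofactor_peaks, d=config.cooccupancy_d
            )
            for platform in PLATFORMS
        }
    )()
    co_rows = [
        {
            "platform": platform,
            "n_cobound": len(s.cobound),
            "n_solo": len(s.solo),
            "cobound_percent": s.cobound_fraction,
        }
        for platform, s in cosplit.items()
    ]
    _write("cooccupancy", "cooccupancy.tsv",
           lambda rows, p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False), co_rows)

    # --- motif enrichment + positional bias (deeper platform's split) ----
    motif_platform = PLATFORMS[1]
    motifs = _stage("motif_analysis")(_motifs)
    ztable, bias_profile = motifs(
        cosplit[motif_platform], intersected[motif_platform], genome, pwm_library, config
    )
    if ztable is not None:
        _write("motif_z", "motif_enrichment.tsv",
               lambda df, p: df.to_csv(p, sep="\t", index=False), ztable)
    if bias_profile is not None:
        _write("positional_bias", "positional_bias.tsv",
               lambda prof, p: prof.to_frame().to_csv(p, sep="\t", index=False), bias_profile)

    # --- disease loci ----------------------------------------------------
    direct_ids = {t.gene_id for t in target_records if t.is_direct_target}
    locus_reports = _stage("disease_loci")(map_disease_loci)(direct_ids, genes, loci)
    locus_df = pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "total_genes": r.total_genes,
                "target_genes": r.target_genes,
                "fold_enrichment": r.fold_enrichment,
            }
            for r in locus_reports
        ],
        columns=["locus_id", "chrom", "start", "end", "total_genes",
                 "target_genes", "fold_enrichment"],
    )
    _write("locus_report", "locus_report.tsv",
           lambda df, p: df.to_csv(p, sep="\t", index=False), locus_df)

    # --- recovery metrics vs truth --------------------------------------
    metrics: dict[str, float] = {}
    for platform in PLATFORMS:
        rec, prec = _match_metrics(intersected[platform], truth.planted_sites)
        metrics[f"site_recall_{platform}"] = rec
        metrics[f"site_precision_{platform}"] = prec
        metrics[f"cobound_accuracy_{platform}"] = _cobound_accuracy(
            cosplit[platform], truth, d=config.cooccupancy_d
        )
    recovered = direct_ids
    truth_targets = truth.target_gene_ids
    metrics["target_recall"] = (
        len(recovered & truth_targets) / len(truth_targets) if truth_targets else float("nan")
    )
    metrics["target_precision"] = (
        len(recovered & truth_targets) / len(recovered) if recovered else float("nan")
    )
    metrics.update(concordance)

    manifest = {
        "package_version": __version__,
        "seed": sim.seed,
        "config": config.to_dict(),
        "paths": {k: Path(v).name for k, v in sorted(paths.items())},
        "metrics": {k: metrics[k] for k in sorted(metrics)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    paths["manifest"] = str(outdir / "manifest.json")

    return {
        "genes": genes,
        "truth": truth,
        "intersected": intersected,
        "assignments": assignments,
        "expression_records": expr_records,
        "target_records": target_records,
        "cooccupancy": cosplit,
        "motif_table": ztable,
        "positional_bias": bias_profile,
        "locus_reports": locus_reports,
        "metrics": metrics,
        "paths": paths,
    }


def _synthesize(sim: SimulationConfig):
    genome, genes = generate_genome_and_genes(sim)
    pwm = nrl_like_pwm()
    truth, coverage, genome = plant_sites_and_simulate_tags(genome, genes, pwm, sim)
    expr = simulate_expression(truth, genes, sim)
    loci = generate_disease_loci(genes, sim)
    return genome, genes, truth, coverage, expr, loci, default_pwm_library()


def _call_platform(tracks, config: PipelineConfig):
    by_caller = {
        "global": call_peaks_global(
            tracks["treatment"], tracks["control"],
            p_threshold=config.p_threshold_global,
            window=config.window, step=config.step,
        ),
        "local": call_peaks_local(
            tracks["treatment"], tracks["control"],
            p_threshold=config.p_threshold_local,
            window=config.window, step=config.step,
            local_flank=config.local_flank,
        ),
    }
    inter = intersect_peak_sets(by_caller["global"], by_caller["local"])
    return by_caller, inter


def _concordance(intersected: dict[str, list[Peak]], config: PipelineConfig) -> dict:
    a, b = (intersected[p] for p in PLATFORMS)
    out: dict[str, float] = {}
    out["fraction_a_within_500_of_b"] = (
        fraction_within(a, peak_centers(b), 500) if a and b else float("nan")
    )
    out["fraction_b_within_500_of_a"] = (
        fraction_within(b, peak_centers(a), 500) if a and b else float("nan")
    )
    return out


def _integrate(intersected, genes, expr, config: PipelineConfig):
    # the paper-style combined analysis: peak-gene associations pooled
    # across platforms
    all_assignments = []
    for platform in PLATFORMS:
        all_assignments.extend(assign_nearest_gene(intersected[platform], genes))
    expr_records = compute_fold_changes(expr, threshold=config.fc_threshold)
    target_records = define_direct_targets(all_assignments, expr_records)
    return all_assignments, expr_records, target_records


def _motifs(split: CooccupancySplit, peaks, genome, pwm_library, config: PipelineConfig):
    if (
        len(split.cobound) < config.motif_min_regions
        or len(split.solo) < config.motif_min_regions
    ):
        ztable = None
    else:
        regions_co = extract_peak_windows(list(split.cobound), genome, flank=config.flank)
        regions_solo = extract_peak_windows(list(split.solo), genome, flank=config.flank)
        ztable = compare_enrichment_profiles(
            regions_co,
            regions_solo,
            pwm_library,
            genome,
            n_background=config.n_background,
            seed=config.simulation.seed,
            threshold=config.scan_threshold,
            core_threshold=config.core_threshold,
            group_labels=("cobound", "solo"),
            min_regions=config.motif_min_regions,
        )
    bias_profile = None
    if peaks and pwm_library:
        regions = extract_peak_windows(list(peaks), genome, flank=config.flank)
        hits = scan_regions(
            regions, pwm_library[0],
            threshold=config.scan_threshold, core_threshold=config.core_threshold,
        )
        if hits:
            bias_profile = positional_bias(hits, flank=config.flank)
    return ztable, bias_profile
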