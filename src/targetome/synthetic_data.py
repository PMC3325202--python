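"""Synthetic ChIP-seq study generator with known ground truth.

Emulates the study design that the rest of the package analyses: a small
uniform-composition genome with non-overlapping genes; a transcription
factor's binding sites planted near the TSSs of chosen target genes (the
PWM consensus is written into the genome); per-bp ChIP tag coverage for an
immunoprecipitated treatment over an IgG-like Poisson background on two
sequencing platforms of different depth; a WT-vs-knockout expression matrix
in which bound, responsive target genes carry a planted fold change of at
least 1.5; a second factor's peak set co-occurring with a designated subset
of the sites; and disease loci each spanning a known number of genes.

Everything is a pure function of ``(config, seed)``: the same configuration
reproduces byte-identical artifacts.  Distinct random substreams are derived
per stage so that, e.g., regenerating the expression matrix does not perturb
the coverage tracks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GenomicInterval,
    Peak,
    PWM,
    write_bed,
    write_expression,
    write_fasta,
    write_gtf,
    write_loci,
    write_pwm_library,
)

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "TruthSet",
    "generate_genome_and_genes",
    "plant_sites_and_simulate_tags",
    "simulate_expression",
    "generate_disease_loci",
    "nrl_like_pwm",
    "default_pwm_library",
    "write_all",
]

PLATFORMS = ("platform_a", "platform_b")

# fixed per-stage stream ids so artifacts are independent across stages
_STREAM_GENOME = 1
_STREAM_SITES = 2
_STREAM_TAGS = 3
_STREAM_EXPR = 4
_STREAM_LOCI = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Depths are per-platform pairs (platform_a, platform_b) in mean tags per
    kb; platform B defaults deeper, mirroring a deeper sequencing library on
    the second platform.  ``site_enrichment`` sets the expected summit
    amplitude of a planted site as a multiple of the local background rate;
    per-site strengths vary uniformly over ``site_strength_range``.
    """

    seed: int = 0
    genome_length: int = 600_000
    n_chroms: int = 2
    n_genes: int = 80
    n_target_genes: int = 24
    n_bound_only: int = 8
    down_fraction: float = 0.7
    site_offset_sd: float = 100.0
    depth_treatment: tuple[float, float] = (530.0, 630.0)
    depth_control: tuple[float, float] = (530.0, 630.0)
    fragment_sd: float = 100.0
    site_enrichment: float = 30.0
    site_strength_range: tuple[float, float] = (0.5, 1.5)
    effect_log2fc: float = 1.0
    expr_noise_sd: float = 0.2
    n_replicates: int = 3
    cofactor_fraction: float = 0.6
    cofactor_jitter_sd: float = 100.0
    cofactor_peak_width: int = 300
    gene_length_range: tuple[int, int] = (1000, 3000)
    min_gene_gap: int = 2000
    exon_count_range: tuple[int, int] = (2, 5)
    n_loci: int = 6

    def __post_init__(self) -> None:
        if self.n_target_genes + self.n_bound_only > self.n_genes:
            raise ValueError("n_target_genes + n_bound_only must be <= n_genes")
        for name in ("genome_length", "n_chroms", "n_genes", "n_target_genes",
                     "n_bound_only", "n_replicates", "n_loci"):
            if getattr(self, name) <= 0 and name not in ("n_target_genes", "n_bound_only"):
                raise ValueError(f"{name} must be > 0")
        if self.n_target_genes < 0 or self.n_bound_only < 0:
            raise ValueError("gene counts must be >= 0")
        if self.effect_log2fc < np.log2(1.5):
            raise ValueError("effect_log2fc must be >= log2(1.5)")
        if not 0.0 <= self.cofactor_fraction <= 1.0:
            raise ValueError("cofactor_fraction must be in [0, 1]")
        if not 0.0 <= self.down_fraction <= 1.0:
            raise ValueError("down_fraction must be in [0, 1]")
        if min(self.depth_treatment) <= 0 or min(self.depth_control) <= 0:
            raise ValueError("depths must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class PlantedSite:
    interval: GenomicInterval
    gene_id: str
    direction: str  # down | up | none
    cofactor: bool
    strength: float = 1.0

    @property
    def center(self) -> int:
        return self.interval.center


@dataclass
class TruthSet:
    """Ground truth of a simulated study, serializable to JSON."""

    planted_sites: list[PlantedSite]
    target_gene_ids: set[str]
    cofactor_peak_truth: list[GenomicInterval]

    def __post_init__(self) -> None:
        directions = {s.direction for s in self.planted_sites}
        if not directions <= {"down", "up", "none"}:
            raise ValueError(f"unknown planted-site directions {directions}")

    @property
    def direction_by_gene(self) -> dict[str, str]:
        return {s.gene_id: s.direction for s in self.planted_sites}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_sites": [
                {
                    "chrom": s.interval.chrom,
                    "start": s.interval.start,
                    "end": s.interval.end,
                    "gene_id": s.gene_id,
                    "direction": s.direction,
                    "cofactor": s.cofactor,
                    "strength": s.strength,
                }
                for s in self.planted_sites
            ],
            "target_gene_ids": sorted(self.target_gene_ids),
            "cofactor_peak_truth": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
                for iv in self.cofactor_peak_truth
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        sites = [
            PlantedSite(
                interval=GenomicInterval(d["chrom"], d["start"], d["end"]),
                gene_id=d["gene_id"],
                direction=d["direction"],
                cofactor=d["cofactor"],
                strength=d.get("strength", 1.0),
            )
            for d in payload["planted_sites"]
        ]
        cof = [
            GenomicInterval(d["chrom"], d["start"], d["end"])
            for d in payload["cofactor_peak_truth"]
        ]
        return cls(sites, set(payload["target_gene_ids"]), cof)


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def _chrom_lengths(config: SimulationConfig) -> dict[str, int]:
    base = config.genome_length // config.n_chroms
    lengths = {f"chr{i + 1}": base for i in range(config.n_chroms)}
    lengths[f"chr{config.n_chroms}"] += config.genome_length - base * config.n_chroms
    return lengths


def generate_genome_and_genes(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Uniform-ACGT genome plus non-overlapping gene models with 2-5 exons.

    Genes are spread over chromosomes proportionally to length and placed
    with a minimum intergenic gap; an error suggests a larger genome if the
    requested density cannot be met.
    """
    rng = config.rng(_STREAM_GENOME)
    lengths = _chrom_lengths(config)
    sequences = {
        chrom: "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
        for chrom, n in lengths.items()
    }

    # apportion genes to chromosomes proportional to length
    chroms = list(lengths)
    per_chrom = {c: (config.n_genes * lengths[c]) // config.genome_length for c in chroms}
    i = 0
    while sum(per_chrom.values()) < config.n_genes:
        per_chrom[chroms[i % len(chroms)]] += 1
        i += 1

    genes: list[GeneModel] = []
    gene_no = 0
    lo, hi = config.gene_length_range
    kmin, kmax = config.exon_count_range
    for chrom in chroms:
        n = per_chrom[chrom]
        if n == 0:
            continue
        gene_lens = rng.integers(lo, hi + 1, size=n)
        needed = int(gene_lens.sum()) + config.min_gene_gap * (n + 1)
        slack = lengths[chrom] - needed
        if slack < 0:
            raise ValueError(
                f"cannot place {n} genes on {chrom} ({lengths[chrom]} bp) without "
                "overlap at the requested density; use a larger genome"
            )
        # distribute the slack over the n+1 gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=n))
        pos = config.min_gene_gap
        prev_cut = 0
        for gi in range(n):
            pos += int(cuts[gi]) - prev_cut
            prev_cut = int(cuts[gi])
            start = pos
            end = start + int(gene_lens[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            gene_id = f"gene{gene_no:04d}"
            k = int(rng.integers(kmin, kmax + 1))
            # 2k sorted distinct cut points -> k alternating exon segments
            offsets = np.sort(rng.choice(np.arange(1, end - start), size=2 * k - 1, replace=False))
            bounds = np.concatenate([[0], offsets, [end - start]])
            exons = tuple(
                GenomicInterval(chrom, start + int(bounds[2 * j]), start + int(bounds[2 * j + 1]), strand)
                for j in range(k)
                if bounds[2 * j + 1] > bounds[2 * j]
            )
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), exons)
            )
            pos = end + config.min_gene_gap
    return sequences, genes


# ---------------------------------------------------------------------------
# planted sites + two-platform tag coverage
# ---------------------------------------------------------------------------

def plant_sites_and_simulate_tags(
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    pwm: PWM,
    config: SimulationConfig,
) -> tuple[TruthSet, dict[str, dict[str, dict[str, np.ndarray]]], dict[str, str]]:
    """Plant binding sites near target TSSs and simulate two-platform coverage.

    The PWM consensus is written into the genome at an offset drawn from
    Normal(0, site_offset_sd) around each chosen gene's TSS (resampled up to
    100 times if it would run off the chromosome).  For each platform,
    control coverage is i.i.d. Poisson background at ``depth_control``;
    treatment coverage is the same background plus a site-centered
    Gaussian-kernel tag pileup whose summit amplitude is
    ``site_enrichment x background-rate x per-site strength``.

    Returns ``(truth, coverage, genome_with_sites)`` where coverage is
    ``{platform: {"treatment"|"control": {chrom: int array}}}``.  The genome
    with the consensus written in is returned rather than mutated in place.
    """
    if len(pwm) >= 4 * config.site_offset_sd:
        raise ValueError("PWM length must be small relative to the site offset window")
    rng_sites = config.rng(_STREAM_SITES)
    rng_tags = config.rng(_STREAM_TAGS)

    n_sites = config.n_target_genes + config.n_bound_only
    gene_ids = sorted(g.gene_id for g in genes)
    by_id = {g.gene_id: g for g in genes}
    chosen = list(rng_sites.choice(gene_ids, size=n_sites, replace=False)) if n_sites else []
    target_ids = chosen[: config.n_target_genes]
    n_down = int(round(config.down_fraction * len(target_ids)))
    directions = {gid: ("down" if i < n_down else "up") for i, gid in enumerate(target_ids)}
    for gid in chosen[config.n_target_genes:]:
        directions[gid] = "none"

    consensus = pwm.consensus
    L = len(consensus)
    seq_arrays = {c: np.frombuffer(s.encode(), dtype="S1").copy() for c, s in genome.items()}
    lo_s, hi_s = config.site_strength_range
    strengths = lo_s + (hi_s - lo_s) * rng_sites.random(n_sites)

    sites: list[PlantedSite] = []
    for i, gid in enumerate(chosen):
        gene = by_id[gid]
        chrom_len = len(genome[gene.interval.chrom])
        start = None
        for _ in range(100):
            offset = int(round(rng_sites.normal(0.0, config.site_offset_sd)))
            cand = gene.tss + offset - L // 2
            if 0 <= cand and cand + L <= chrom_len:
                start = cand
                break
        if start is None:
            raise ValueError(
                f"planted site for {gid} repeatedly ran off chromosome "
                f"{gene.interval.chrom}; enlarge the genome or reduce site_offset_sd"
            )
        seq_arrays[gene.interval.chrom][start : start + L] = np.frombuffer(
            consensus.encode(), dtype="S1"
        )
        sites.append(
            PlantedSite(
                interval=GenomicInterval(gene.interval.chrom, start, start + L),
                gene_id=gid,
                direction=directions[gid],
                cofactor=False,
                strength=float(strengths[i]),
            )
        )

    # designate exactly round(fraction * n) sites as co-factor co-bound
    n_cof = int(round(config.cofactor_fraction * len(sites)))
    cof_idx = set(rng_sites.choice(len(sites), size=n_cof, replace=False)) if n_cof else set()
    cof_peaks: list[GenomicInterval] = []
    half_w = config.cofactor_peak_width // 2
    final_sites: list[PlantedSite] = []
    for i, site in enumerate(sites):
        is_cof = i in cof_idx
        final_sites.append(dataclasses.replace(site, cofactor=is_cof))
        if is_cof:
            chrom_len = len(genome[site.interval.chrom])
            c = site.center + int(round(rng_sites.normal(0.0, config.cofactor_jitter_sd)))
            c = int(np.clip(c, half_w, chrom_len - half_w - 1))
            cof_peaks.append(GenomicInterval(site.interval.chrom, c - half_w, c + half_w))
    sites = final_sites

    coverage: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for pi, platform in enumerate(PLATFORMS):
        bg_treat = config.depth_treatment[pi] / 1000.0
        bg_ctrl = config.depth_control[pi] / 1000.0
        treat: dict[str, np.ndarray] = {}
        ctrl: dict[str, np.ndarray] = {}
        for chrom, seq in genome.items():
            n = len(seq)
            mean_t = np.full(n, bg_treat)
            for site in sites:
                if site.interval.chrom != chrom:
                    continue
                amp = config.site_enrichment * bg_treat * site.strength
                span = int(4 * config.fragment_sd)
                x0 = max(0, site.center - span)
                x1 = min(n, site.center + span + 1)
                x = np.arange(x0, x1)
                mean_t[x0:x1] += amp * np.exp(
                    -0.5 * ((x - site.center) / config.fragment_sd) ** 2
                )
            treat[chrom] = rng_tags.poisson(mean_t).astype(np.int64)
            ctrl[chrom] = rng_tags.poisson(np.full(n, bg_ctrl)).astype(np.int64)
        coverage[platform] = {"treatment": treat, "control": ctrl}

    truth = TruthSet(
        planted_sites=sites,
        target_gene_ids=set(target_ids),
        cofactor_peak_truth=cof_peaks,
    )
    genome_with_sites = {c: arr.tobytes().decode() for c, arr in seq_arrays.items()}
    return truth, coverage, genome_with_sites


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    truth: TruthSet, genes: Sequence[GeneModel], config: SimulationConfig
) -> pd.DataFrame:
    """WT/KO expression matrix with planted fold changes for target genes.

    Per gene, baseline log2 expression is Normal(8, 1); knockout replicates
    of down-targets are shifted by -effect_log2fc and of up-targets by
    +effect_log2fc; each replicate receives Normal(0, expr_noise_sd) noise on
    the log2 scale.  Values are returned linear-scale.
    """
    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = config.rng(_STREAM_EXPR)
    gene_ids = [g.gene_id for g in genes]
    direction = truth.direction_by_gene
    baseline = rng.normal(8.0, 1.0, size=len(gene_ids))
    shift = np.array(
        [
            -config.effect_log2fc if direction.get(g) == "down"
            else config.effect_log2fc if direction.get(g) == "up"
            else 0.0
            for g in gene_ids
        ]
    )
    cols: dict[str, np.ndarray] = {}
    for r in range(config.n_replicates):
        noise = rng.normal(0.0, config.expr_noise_sd, size=len(gene_ids)) if config.expr_noise_sd else 0.0
        cols[f"WT_{r + 1}"] = 2.0 ** (baseline + noise)
    for r in range(config.n_replicates):
        noise = rng.normal(0.0, config.expr_noise_sd, size=len(gene_ids)) if config.expr_noise_sd else 0.0
        cols[f"KO_{r + 1}"] = 2.0 ** (baseline + shift + noise)
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))


# ---------------------------------------------------------------------------
# disease loci
# ---------------------------------------------------------------------------

def generate_disease_loci(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> pd.DataFrame:
    """Pairwise-disjoint genomic loci, each spanning >= 1 gene.

    Each locus covers a run of consecutive genes on one chromosome plus a
    margin; the table records locus id, interval and the total gene count
    within (by TSS containment).
    """
    if not genes:
        raise ValueError("need at least one gene to build loci")
    rng = config.rng(_STREAM_LOCI)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    chroms = sorted(by_chrom)
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    margin = max(1, config.min_gene_gap // 4)
    attempts = 0
    while len(rows) < config.n_loci and attempts < 200:
        attempts += 1
        chrom = chroms[(len(rows) + attempts) % len(chroms)]
        gl = by_chrom[chrom]
        run = int(rng.integers(1, min(8, len(gl)) + 1))
        i0 = int(rng.integers(0, len(gl) - run + 1))
        block = gl[i0 : i0 + run]
        start = max(0, block[0].interval.start - margin)
        end = block[-1].interval.end + margin
        if any(start < e and s < end for s, e in taken[chrom]):
            continue
        taken[chrom].append((start, end))
        n_in = sum(1 for g in gl if start <= g.tss < end)
        rows.append(
            {
                "locus_id": f"locus{len(rows) + 1:02d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_genes": n_in,
            }
        )
    return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end", "n_genes"])


# ---------------------------------------------------------------------------
# default PWM library (planted motif + decoys)
# ---------------------------------------------------------------------------

def _counts_from_consensus(consensus: str, major: float = 12.0, minor: float = 1.0) -> np.ndarray:
    counts = np.full((len(consensus), 4), minor)
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = major
    return counts


def nrl_like_pwm() -> PWM:
    """A bZIP-like extended AP-1 half-site motif used for planting."""
    return PWM.from_counts("NRL_like", _counts_from_consensus("TGCTGACTCAG"), family="bZIP")


def default_pwm_library() -> list[PWM]:
    """Planted motif plus photoreceptor-flavoured decoys (CRX, SP1, ESRRB-like)."""
    return [
        nrl_like_pwm(),
        PWM.from_counts("CRX_like", _counts_from_consensus("CTAATCCC"), family="homeodomain"),
        PWM.from_counts("SP1_like", _counts_from_consensus("GGGGCGGGG"), family="zinc_finger"),
        PWM.from_counts("ESRRB_like", _counts_from_consensus("TCAAGGTCA"), family="nuclear_receptor"),
    ]


# ---------------------------------------------------------------------------
# one-call materialization
# ---------------------------------------------------------------------------

def write_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every artifact and serialize it under ``outdir``.

    Writes FASTA genome (with planted sites), GTF annotation, truth-site and
    co-factor BED, per-platform coverage wiggles, expression TSV, locus TSV,
    the PWM library and the truth JSON.  Returns a name -> path mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = generate_genome_and_genes(config)
    pwm = nrl_like_pwm()
    truth, coverage, genome = plant_sites_and_simulate_tags(genome, genes, pwm, config)
    expr = simulate_expression(truth, genes, config)
    loci = generate_disease_loci(genes, config)

    paths: dict[str, Path] = {}

    def _p(name: str, fname: str) -> Path:
        paths[name] = outdir / fname
        return paths[name]

    write_fasta(genome, _p("genome", "genome.fa"))
    write_gtf(genes, _p("genes", "genes.gtf"))
    site_peaks = [
        Peak(s.interval, summit=s.center, height=1.0, name=s.gene_id)
        for s in truth.planted_sites
    ]
    write_bed(site_peaks, _p("truth_sites", "truth_sites.bed"))
    cof_peaks = [
        Peak(iv, summit=iv.center, height=1.0, name=f"cofactor_{i + 1}")
        for i, iv in enumerate(truth.cofactor_peak_truth)
    ]
    write_bed(cof_peaks, _p("cofactor_peaks", "cofactor_peaks.bed"))
    from .io_formats import write_coverage

    for platform, tracks in coverage.items():
        for cond in ("treatment", "control"):
            write_coverage(tracks[cond], _p(f"{platform}_{cond}", f"{platform}_{cond}.wig"))
    write_expression(expr, _p("expression", "expression.tsv"))
    write_loci(loci, _p("loci", "disease_loci.tsv"))
    write_pwm_library(default_pwm_library(), _p("pwms", "pwm_library.txt"))
    truth.to_json(_p("truth", "truth.json"))
    return paths
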