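# Methods

This note documents the models and procedures implemented in `targetome`,
the defaults chosen where the underlying workflow left details open, and
what the synthetic benchmark does and does not demonstrate.

## Coordinates and formats

All coordinates are 0-based half-open internally. BED is native; GTF is
converted on read/write (1-based inclusive on disk). Peaks are BED6+1 with
the summit offset in column 7 and the summit tag count ("height") in the
score column. Whether heights should be depth-normalized is left to the
caller — raw summit counts are stored, since that is how peak heights are
conventionally displayed in browser tracks. PWMs use a JASPAR-style text
dialect; counts receive a pseudocount of 0.01 per cell before per-position
normalization so all frequencies are strictly positive (configurable).

## Peak calling

Both callers slide a `window` = 300 bp window with `step` = 50 bp across
per-bp tag coverage and score the treatment tag sum `x_w` against a Poisson
null, merging overlapping/adjacent significant windows. The window/step
defaults were chosen so that typical merged peaks are a few hundred bp wide,
matching the width scale usually reported for point-source TF ChIP-seq.

- **Global caller** (default p < 10⁻⁶):
  λ_global = C·(w/G)·(T/C) = T·w/G, where T and C are the total treatment
  and control tag counts and G the genome length — the depth-matched uniform
  expectation. A window is significant when P(X ≥ x_w | λ) falls below the
  threshold (upper Poisson tail, exact `scipy.stats.poisson.sf`).
- **Local caller** (default p < 10⁻³):
  λ = max(λ_global, λ_local), with λ_local the control rate in ±5 kb around
  the window, depth-scaled by T/C. This suppresses apparent enrichment over
  local control pileups and reduces exactly to the global caller under a
  uniform control.

The two callers stand in for the two independent black-box callers of the
original dual-caller design: they share the window machinery but differ in
the background model, which preserves the structural point — only regions
supported by two differently-parameterized background models survive.
Summits are the leftmost treatment maximum in the merged region; the peak
p-value is the minimum over merged windows, clamped to the smallest positive
float when the tail underflows. No multiple-testing correction is applied
inside the callers; thresholds are on raw Poisson tails, as is conventional
for this style of caller. Tightening the threshold can only remove windows,
so peak sets are monotone in p.

**Intersection** clusters the union of both callers' peaks by transitive
≥1 bp overlap and emits, for every cluster containing peaks from both
callers, the union interval with summit/height from the higher-height
contributor. Any-overlap (≥1 bp) was chosen over a minimum-overlap
fraction; with window-merged peaks of similar provenance the two rules
rarely differ.

## Interval analytics

Distances between peak sets are **center-to-center** — summits are
caller-dependent, centers are not — and distances to genes are
center-to-TSS. All concordance statistics are nearest-neighbour per query
peak (each query contributes its single nearest reference anchor), because
per-peak percentages ("x% of peaks within 500 bp") imply one match per
query. Sign convention: query − reference for anchor distances; strand-aware
(negative = upstream) for gene distances. Ties break deterministically:
smaller absolute distance, then the downstream/negative side, then the
lexicographically smallest gene id.

Genomic classification uses the peak center with precedence
promoter > exon > intron > intergenic and a promoter window of
[TSS−1000, +200) in gene orientation — a common default; the window is
configurable.

## Expression integration

Fold changes are ratios of **linear-scale condition means** (a log2-mean
alternative is available); direction is down when WT/KO ≥ 1.5 and up when
KO/WT ≥ 1.5, with the boundary counting as changed ("at least 1.5-fold").
A zero mean on one side is an infinite change; all-zero genes are flagged
and left unchanged. Fold change is the only criterion by default, matching
the stated rule of the workflow being reproduced; an optional Welch t-test
gate (off by default) is provided for noisy designs. A direct target is a
gene with ≥1 assigned peak and a changed direction; down-targets form the
factor-activated class and up-targets the factor-repressed class.

## Motif analysis

**Scanning.** Similarity at position p on strand s is
`sim = Σᵢ Cᵢ·f_i(bᵢ) / Σᵢ Cᵢ·f_i^max` with per-position information content
`Cᵢ = 2 + Σ_b f_i(b) log₂ f_i(b)` (bits) — high-information positions
dominate the score, so the consensus of a near-degenerate matrix scores
exactly 1. A hit additionally requires the 4 contiguous positions of
maximal total information (the "core") to reach their own threshold
(defaults 0.80 overall / 0.90 core). Both strands are scanned via the
reverse-complement matrix; windows containing N never match. The similarity
scheme of the proprietary scanner historically used for this analysis is
not public; this documented formulation preserves the published
matrix-similarity concept, and numerical equivalence with that scanner is
explicitly not claimed.

**Enrichment Z.** The observed total match count over a region set is
standardized against `n_background` = 100 replicates, each sampling one
uniformly-placed genomic region per input region with identical length
(seeded). Z ≥ 2 is the significance rule, boundary inclusive. A zero
background sd is flagged degenerate (Z = +∞ if observed exceeds the mean,
else 0). Length-matched uniform sampling was chosen over dinucleotide
shuffling for transparency and testability; on the uniform-composition
synthetic genome the two coincide in expectation.

**Positional bias.** With N total hits in ±flank around peak centers, each
window (50 bp, step 25 bp) is scored by the upper binomial tail
P(X ≥ k | N, q), q = window/(2·flank+1), reported as −log₁₀ P at the window
midpoint (computed in log space; hit position = midpoint of the match).
Windows overlap, so neighbouring values are correlated; the profile is a
visualization statistic, and under uniform placement its maximum exceeds the
Bonferroni bound −log₁₀(0.05/n_windows) in well under 10% of replicates.

**Family aggregation** is not performed by default; motifs carry an
optional family label and the Z-table reports per-motif counts.

## Co-occupancy and disease loci

A peak is co-bound when the nearest co-factor peak center lies within
d = 500 bp, inclusive. Locus reports count genes by TSS containment;
`fold_enrichment = total_genes / target_genes` exactly as the convention of
the table being reproduced prints it (note this is the inverse of the usual
enrichment ratio — a *smaller* value means a target-denser locus); a
conventional rate-ratio alternative is available behind a flag. Loci with
zero targets are omitted by default.

## Synthetic study design

The generator emulates the study conditions end to end and is fully
deterministic in (config, seed), with independent substreams per stage.

- **Genome/genes:** i.i.d. uniform ACGT; default 600 kb over 2 chromosomes;
  80 non-overlapping genes of 1–3 kb with 2–5 exons and ≥2 kb intergenic
  gaps (so a site is unambiguous about its gene).
- **Sites:** 24 responsive targets (70% down, 30% up, echoing the observed
  down-heavy ratio for an activator) plus 8 bound-but-unresponsive genes;
  the motif consensus is written into the genome at Normal(0, 100 bp)
  offsets from the TSS.
- **Coverage:** control is per-bp Poisson background; treatment adds a
  Gaussian-kernel pileup (sd 100 bp ≈ fragment-size smearing) with summit
  amplitude 30× background scaled by a per-site strength in U(0.5, 1.5).
  Platform depths default to 530 and 630 tags/kb — the 5.3 : 6.3 ratio of
  the two sequencing libraries in the study being emulated, platform B
  deeper.
- **Expression:** per-gene baseline log2 ~ N(8,1); knockout replicates of
  targets shifted by ∓1 log2 unit (2-fold, above the 1.5-fold criterion);
  N(0, 0.2) per-replicate log2 noise; 3 replicates per condition.
- **Co-factor:** exactly round(0.6 · n_sites) sites carry a co-factor peak
  jittered by Normal(0, 100 bp), in the range of the co-occupancy fractions
  reported for the emulated factor pair.
- **Loci:** 6 disjoint intervals each spanning a run of consecutive genes.

At these conditions both platforms detect essentially every planted site
(the weakest site's window excess is an order of magnitude above the 10⁻⁶
detection limit), so the cross-platform concordance inequality — the
shallower platform's peaks at least as concordant with the deeper set as
vice versa — holds weakly, usually as a tie near 100%. A strict asymmetry
of the kind seen with real data (where the deeper library reports roughly
twice the peaks) would require planting sites below the shallow platform's
detection limit, which the recovery guarantees deliberately exclude.
More generally, the generator omits mappability structure, GC bias,
duplicated reads, sequence-composition background and fragment-model
asymmetries, so passing recovery tests demonstrate correctness of the
analysis logic under the stated model, not caller performance on real
libraries.

## Numerical choices and degenerate inputs

Poisson and binomial tails come from `scipy.stats` (log-space where small);
the brute-force summation oracles in the test suite agree to 1e-10 relative
error. Peak p-values are clamped to the smallest positive float on
underflow. All tie-breaks (summits, nearest anchors, gene ids, core
position) are leftmost/lexicographic for determinism. Empty inputs are
either well-defined (empty peak set → zero summary; empty co-factor set →
all solo) or rejected with a named error (empty query for a percentage,
all-zero control, <10 regions for enrichment). Problem sizes in the test
suite (600 kb genome, 10 seeds, 100 background replicates, 50–100
calibration replicates) were chosen so the full suite demonstrates every
property at comfortable statistical margins while remaining quick to run.

## Known limitations

- The emulated callers are not MACS/NGS-Analyzer; only the dual-caller
  intersection structure and Poisson-background logic are preserved.
- Motif similarity scores are not comparable to proprietary scanner scores;
  thresholds were set for the bundled matrices and are configurable.
- Single-TSS gene models; no multi-isoform handling or enhancer–gene
  linkage beyond nearest-TSS.
- Expression significance is fold-change-only by default; replicate-level
  modelling (e.g. moderated tests) is out of scope.
- The locus analysis takes gene-to-locus membership as given input; ortholog
  mapping between species is not performed.
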