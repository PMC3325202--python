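# targetome

Reusable analysis pipeline for defining a transcription factor's **direct
targetome** from ChIP-seq and knockout expression data, modelled on the
workflow used to map the rod-photoreceptor regulator NRL: peaks are called
from two sequencing platforms with two independent callers, only regions
supported by both callers are kept, peaks are assigned to the nearest gene
TSS, and genes that are both peak-associated and changed at least 1.5-fold
in the knockout are called direct targets. Peak regions are then profiled
for transcription-factor binding-site (TFBS) enrichment and positional bias,
split by co-occupancy with a second factor (e.g. CRX), and intersected with
disease loci.

A bundled synthetic-data generator produces genomes, annotations, planted
binding sites, two-platform tag coverage, WT/KO expression matrices,
co-factor peaks and disease loci with known ground truth, so every stage is
testable offline with recovery metrics.

## Methods at a glance

- **Peak calling.** Sliding windows (300 bp, step 50 bp) over per-bp tag
  coverage are tested against a Poisson background: the *global* caller uses
  λ = T·w/G (T = total treatment tags, w = window, G = genome length;
  p < 10⁻⁶), the *local* caller uses λ = max(λ_global, λ_local) with
  λ_local estimated from control tags in ±5 kb (p < 10⁻³). Significant
  windows merge into peaks with summit, height and minimum p-value; the
  per-platform peak set is the intersection of both callers (union interval
  of each overlapping cluster).
- **Concordance and annotation.** Signed nearest-anchor distances
  (center-to-center or center-to-TSS), within-*d* percentages, and
  promoter/exon/intron/intergenic classification with promoter =
  [TSS−1000, TSS+200) in gene orientation.
- **Direct targets.** Linear-scale condition means; a gene is changed when
  max(WT,KO)/min(WT,KO) ≥ 1.5 (boundary inclusive); direct target ⇔ peak
  AND changed.
- **Motif analysis.** Matrix similarity
  `sim = Σᵢ Cᵢ f_i(bᵢ) / Σᵢ Cᵢ f_i^max` with per-position information
  content `Cᵢ = 2 + Σ_b f_i(b) log₂ f_i(b)` and a 4-position maximal-
  information core; enrichment Z against 100 length-matched genomic
  background samples (Z ≥ 2 significant); positional bias as the per-window
  −log₁₀ upper binomial tail of hit counts against uniform placement in
  ±500 bp around peak centers.
- **Co-occupancy and loci.** Peaks within 500 bp (center-to-center) of a
  second factor's peak are "co-bound"; disease-locus reports count genes by
  TSS containment with fold enrichment = total genes / target genes.

## Worked example

```sh
targetome run --seed 1 --outdir run1
```

runs the full pipeline on the default synthetic study (600 kb genome,
80 genes, 24 expression-responsive targets + 8 bound-but-unresponsive genes,
two platforms at 530 / 630 tags per kb) and prints the recovery metrics
computed against the generator's truth:

```
cobound_accuracy_platform_a	1.0000
cobound_accuracy_platform_b	1.0000
fraction_a_within_500_of_b	100.0000
fraction_b_within_500_of_a	100.0000
site_precision_platform_a	1.0000
site_precision_platform_b	1.0000
site_recall_platform_a	1.0000
site_recall_platform_b	1.0000
target_precision	1.0000
target_recall	1.0000
```

Every planted binding site is recovered by the intersected dual-caller peak
sets on both platforms (recall/precision 1.0), the direct-target table
exactly matches the planted responsive genes, and the co-occupancy split
agrees with the planted co-factor flags. `run1/` contains the peak BEDs,
peak summaries, assignments, direct-target table, motif Z-table (in which
the planted motif ranks first with Z ≈ 12.7 in the co-bound group and the
decoys stay below 2), the positional-bias profile (maximal −log₁₀ P at
offset 0), the disease-locus report and a JSON manifest. The same seed
reproduces the bundle byte-for-byte.

The same steps are available as a library (`targetome.peak_calling`,
`targetome.interval_analytics`, `targetome.expression_integration`,
`targetome.motif_analysis`, `targetome.pipeline`) and as individual CLI
commands (`targetome call-peaks`, `concord`, `annotate`, `integrate`,
`cooccupancy`, `motifs scan|enrich|bias`, `loci`).

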