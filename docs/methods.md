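# Methods

## Problem and approach

Human long non-coding RNAs are mostly not sequence-conserved in mouse, so
functional conservation has to be inferred from context rather than
alignment. The screen operationalizes "same function, different sequence"
as the conjunction of three observable signatures, evaluated on gene-level
annotations and TPM-like expression matrices from paired human/mouse
(chimeric-liver) samples:

1. **Syntenic placement.** A lncRNA locus is represented by the union
   interval of its transcripts (0-based half-open coordinates
   everywhere internally; GTF's 1-based inclusive convention is converted
   at the boundary). For an intergenic lncRNA, its flank frame is the
   nearest coding gene with `end <= lnc.start` and the nearest with
   `start >= lnc.end`; lncRNAs overlapping a coding gene are excluded
   (they are not intergenic, and "flanked by" would be ambiguous), and
   chromosome-edge lncRNAs lack a frame. Two lncRNAs match when the human
   frame maps onto the mouse frame through the coding-gene ortholog
   table. By default the frame is treated as an unordered set
   (inversion-tolerant, since local inversions are common in otherwise
   conserved blocks); `flank_mode="ordered"` requires
   upstream→upstream. One-to-many orthologs are honoured by trying every
   combination. When several lncRNAs of each species share one frame,
   all cross pairs are emitted — disambiguation is left to the later
   stages, which score each lncRNA individually.

2. **Consistent regulation.** Per condition, differential expression of
   each lncRNA against the reference condition uses Welch's
   unequal-variance t test on `log2(TPM + pseudocount)`; the reported
   effect is `log2((mean_trt + c)/(mean_ref + c))` on the raw scale with
   pseudocount `c = 1` (bounds fold changes of near-zero genes). The
   significance rule is strict: `|log2FC| > 0.5` **and** `p < 0.05`, raw
   p — multiple-testing control is deliberately deferred to the
   enrichment stage, where a test family is well defined. A pair is
   "similarly regulated" when ≥ 1 shared condition has both members
   significant in the same direction and no shared condition has them
   significant in opposite directions (the veto is configurable off).
   The test is pluggable; Welch-on-logs was chosen because inputs are
   normalized abundances, not counts, and group sizes are small.

3. **Shared functional association.** Guilt-by-association: each lncRNA
   is correlated (Spearman by default — robust to monotone-nonlinear
   relations across heterogeneous conditions; Pearson selectable) with
   every coding gene in the expressed universe (nonzero in ≥ half of
   samples — enrichment is sensitive to the universe, so the rule is
   explicit and configurable). The top `N = 500` genes by |coefficient|
   (ties broken by gene id for determinism) form the query for
   hypergeometric over-representation against each pathway, with
   Benjamini–Hochberg adjustment within the lncRNA's pathway family. A
   pair passes when the two species' significant pathway sets
   (`adjusted p < 0.05`) share ≥ `min_shared_pathways = 1` members and
   the Jaccard index clears `jaccard_threshold` (0 by default — the
   shared-count rule governs; both numbers are recorded in provenance so
   stringency is auditable).

**Rescue scoring.** The functional-equivalence assay compares
KD-vs-control and rescue-vs-KD. Per comparison, the DE gene set (same
strict significance rule) is tested for pathway over-representation as in
stage 3; a pathway's direction is the sign of the mean log2FC over its
significant members. *Rescued* = enriched in both comparisons with
opposite directions; the headline percentage is over KD-enriched pathways
only. "Differential pathway" is interpreted as over-representation of DE
genes (not a ranked-list statistic) — the largest single interpretive
choice in the package, made to share one enrichment machinery across
stages. Gene-level calls mirror this: *unaffected* (not significant in
KD), *rescued* (significant in both with opposite signs), else
*not_rescued*. When no pathway is KD-enriched the percentage is reported
as undefined with an explicit flag, never silently 0. Sign reversal is
required, but a return-to-within-tolerance-of-control is not — reversal
is what the transcriptome-level assay can support robustly at small n.

## Synthetic data generator

The generator emulates the study design: two collinear pseudo-genomes of
8 chromosomes × 250 coding genes (2,000 orthologous coding pairs), six
conditions (chow reference; fast, refeed, PPARα, PPARγ, FXR agonist) × 3
replicates, with the same sample ids in both compartments (the chimeric
liver gives paired measurements).

- **Geometry.** Coding genes sit on a fixed grid; lncRNAs occupy
  inter-coding slots. True pairs take the same slot in both species,
  syntenic decoy pairs likewise, co-regulated decoys take non-matching
  slots, and plain decoys take slots left empty in the other species.
  Slot assignments are disjoint by construction, so no unintended frame
  match can occur; infeasible geometry (more lncRNAs than slots) is an
  error.
- **Expression.** log2 abundance = baseline ~ U(4, 9) (TPM ≈ 16–512,
  i.e. well-expressed liver genes; keeps pseudocount shrinkage of
  empirical log2FC below the recovery-bias bound) + condition terms +
  N(0, 0.3) residual, exponentiated. True (and co-regulated-decoy)
  lncRNAs carry planted ±2.0 log2 shifts in 1–3 treatment conditions,
  identical across species. Coding genes share their condition response
  (sd 0.5) with their ortholog — the humanized-liver premise that both
  compartments see the same physiology, and the signal behind the
  ortholog-recovery benchmark. Member genes of a true pair's pathway are
  driven by their regulating lncRNA instead: they inherit its condition
  shifts at coupling 0.5 and track its residual with gain
  ρ/√(1−ρ²), which yields a within-condition lncRNA–member correlation
  of exactly ρ = `latent_corr` = 0.8 while leaving the lncRNA's own
  variance at the noise level (an external shared factor would inflate
  the lncRNA's variance and mask its planted fold changes at n = 3).
- **Rescue design.** Control/KD/rescue × 5 replicates over the mouse
  coding genes; KD shifts all members of each perturbed pathway by ±2.0
  (random sign per pathway); the rescue group returns a
  `rescue_fraction` subset to baseline and leaves the rest at KD level;
  the truth records both sets.
- **Determinism.** One global seed; every generator and the pipeline
  derive salted substreams from it, so identical configuration gives
  byte-identical outputs.

The noise model is log-normal on abundances, not negative-binomial
counts, because the pipeline consumes TPM-like values; a count-emitting
mode would be the natural extension for raw-count workflows. What the
generator does **not** emulate: read-level sampling noise and
length/GC biases, batch structure, cell-type mixture within compartments,
correlated pathway overlap (planted pathways are disjoint), and isoform
structure (loci are single intervals). Passing the planted-truth tests
therefore demonstrates the pipeline's logic and calibration under clean,
strong-effect conditions — not performance on real sequencing data, where
effect sizes, annotation quality and pathway redundancy are all less
favourable.

## Numerical and design notes

- Coordinates: 0-based half-open internally; converters only in the io
  layer. Nearest-flank ties (identical boundary coordinate) break
  lexicographically by gene id.
- Degenerate DE inputs: genes constant in both groups with equal means
  get p = 1; constant-profile genes yield undefined (NaN) correlations
  and are excluded from ranking; an all-undefined correlation vector is
  an error.
- BH adjustment is computed per enrichment family
  (per lncRNA, per comparison), matching how adjusted p-values are
  reported per panel in practice.
- Percent rescued uses `round`-free floating arithmetic; the discovery
  rate is reported to one decimal (e.g. 59 of 2419 → 2.4).
- Problem sizes in the tests and the acceptance script (2,000-gene
  universes, 3–10 replicates, 5–10 seeds per property) were chosen as
  the smallest sizes at which the statistical assertions are stable;
  they run in seconds on one CPU.

## Known limitations

- The screen operates at the gene/locus level; transcript-isoform
  structure is collapsed, so isoform-specific conservation is invisible.
- "Similarly regulated" requires one shared significant condition; with
  many conditions and no multiplicity control at stage 2, permissive
  thresholds admit chance agreements — the default strict thresholds and
  the opposite-direction veto are the guard rails.
- Enrichment-set agreement depends on the pathway database's granularity
  and redundancy; overlapping pathways inflate both shared counts and
  Jaccard.
- Cis-acting lncRNAs whose function is tied to their locus rather than a
  diffusible product can pass the screen but fail a trans rescue — the
  rescue scorer cannot distinguish "not conserved" from "acts in cis".
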