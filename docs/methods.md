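# Methods

## Data model and conventions

All genomic intervals are 0-based half-open internally; GTF input/output is
converted at the boundary (1-based inclusive per the GTF standard).  A read is
a sequence of sorted, non-overlapping genomic blocks; it is *gapped* iff it has
two or more blocks.  Blocks are derived from the CIGAR such that only
reference skips (`N`) split blocks — deletions (`D`) consume reference inside a
block and never create junctions, because junctions are meant to carry the
splicing signal, not indel structure.  Unmapped, secondary and supplementary
records are skipped; duplicates are not detected or removed.

## GNSSR

GNSSR(j, s) = [c(j,s)/G(s)] / [g(gene,s)/T(s)].  Design choices:

- The gene-expression normalizer is the union-mode gene count over total
  mapped reads.  TPM-style length normalization would cancel in between-sample
  comparisons of the same junction and is not implemented.
- A junction's host gene is the unique gene whose span contains both flanks;
  junctions matching zero or multiple genes are flagged and excluded.
- If the host gene has zero assigned reads in a sample the record is kept but
  flagged undefined and skipped by group averaging (it carries no usage
  information, not a zero).
- Group means average over the *observed junction universe*: junctions never
  seen in any sample of the experiment are excluded; junctions seen somewhere
  contribute 0 in samples where they are absent.  This keeps group means
  comparable across samples without conditioning on per-sample detection.
- An optional output scale factor (default 1) only affects readability;
  absolute GNSSR magnitudes are convention-dependent, so analyses should rely
  on ratios, signs and significance patterns.

Union-mode counting assigns a read to a gene iff every block overlaps that
gene's exons and no block overlaps a different gene; reads hitting zero genes
or more than one are tallied as `no_feature`/`ambiguous` and excluded.  Only
union mode is implemented.

## Compartment partition and gene change

`mito_pct` is computed over all primary mapped records.  The per-gene change
summary is a CPM + pseudocount surrogate (pseudocount 0.5 CPM keeps l2fc
finite at zero counts; the t-test runs on log2(CPM+0.5); BH across the gene
set).  It is *not* a negative-binomial Wald test and makes no dispersion
assumptions beyond equal variance on the log scale — adequate for the designed
effect sizes here, under-powered and miscalibrated for low counts in general.

## Precursor index

Border pairs are adjacent transcript couples on the mitochondrial chromosome
in genomic order.  The circular-origin pair is excluded by default because
linear aligners cannot produce origin-wrapping alignments; a flag adds it for
data that contain them.  Only ungapped reads are eligible spanners (the
normalization is defined in terms of ungapped reads, and spliced reads are
mature by definition).  For near-abutting neighbors each side of the rule is
measured against its own boundary, so a read lying entirely within the gap
counts for neither; a read spanning a very short unit entirely may count for
two pairs and does, once per pair.  The minimum overlap defaults to 6 nt.
Normalization scale 1e6 was chosen for readable magnitudes only.

## qPCR

rq = 2^−(Ct_target − Ct_reference), no efficiency correction.  Technical
replicates are averaged on the Ct scale (geometric mean on the quantity
scale).  No-RT mock records are accepted and never quantified; a (sample,
target) is flagged when its mock Ct comes within 5 cycles of the RT Ct, a
contamination heuristic that does not auto-exclude.  Ct sanity bounds are
(0, 60) cycles.

## Statistics

"Student's t-test" is the pooled-variance form (Welch behind a flag), two-sided
throughout.  Degenerate inputs are resolved by rule: both groups constant and
equal → t=0, p=1; both constant and unequal → p=0 with a degenerate flag.  BH
adjustment is the standard step-up, order-preserving, clipped at 1; adjusted
values are not claimed idempotent under re-adjustment.

## Synthetic data generator

The generator emulates a two-condition, quadruplicate, single-end bulk RNA-seq
design at desk scale:

- **Nuclear gene**: 9 exons × 200 nt with 300 nt introns on a linear
  chromosome; a full-length isoform using all 8 junctions and a 3'-only
  isoform starting at the anchor exon (exon 5) using only the 4 downstream
  junctions.  Default mixture 0.8/0.2 in `con` vs 0.5/0.5 in `ldl`, producing
  the reciprocal upstream/downstream usage shift.
- **Mitochondrial chromosome**: circular, 7 single-exon units in fixed order
  (rRNA-like, tRNA-like, protein-coding, tRNA-like with a 3 nt gap, three
  protein-coding), abutting or near-abutting, flanked by transcript-free
  spacers so no read wraps the origin.  Default mito read fraction 4.5% in
  `con` and 11.2% in `ldl` (the emulated study's partition), giving every
  mitochondrial gene an ~2.5-fold CPM increase.
- **Reads**: length 50 nt (post-trimming scale; must not exceed the shortest
  mature unit), 50,000 per sample by default as the desk-scale stand-in for
  hundreds of millions.  Each read draws compartment ~ Bernoulli(mito
  fraction); nuclear reads draw an isoform and a uniform start on the spliced
  transcript (blocks by projection through the exon map); mitochondrial reads
  are precursor-derived with probability `precursor_fraction` (uniform on the
  mito genome, may span borders) or mature (unit proportional to length,
  uniform within the unit, never spanning a border).  Default precursor
  fraction 0.05 in both conditions — a realistic minor precursor pool
  consistent with a null processing comparison.
- Placement is uniform: no fragment-length, GC or positional bias, no
  sequencing errors, no multimappers, plus strand only.  The statistics under
  test are ratio-based and bias-agnostic at this scale, so passing tests
  demonstrate correctness of the estimators and their calibration under the
  stated sampling model — not robustness to real-library biases, soft-clipped
  alignments or ambiguous multimapping.
- Determinism: every random stream is seeded from (seed, purpose, condition,
  replicate) via hashed seed sequences, so identical configs give identical
  outputs across platforms.

Each sample is stored as column arrays from which count tables (junctions,
genes, totals, border spans) are computed vectorized; the same reads can be
materialised to coordinate-sorted SAM and re-parsed, and both routes produce
identical tables (enforced by tests).  Calibration studies use the array route
for speed.

Closed-form oracles used in testing: expected junction count of isoform *i* is
n_i (R−1)/(L_i−R+1); expected raw border count for a pair with gap *g* is
N_precursor (R − 2·min_overlap + 1 − g)/(L_mito − R + 1).

## Problem sizes

Defaults: 4+4 samples × 50,000 reads for effect-recovery analyses; 200
simulated experiments at 20,000 reads/sample for the junction-test null
calibration; 200,000 reads/sample at 11.2% mito fraction for the precursor
linearity study (at shallower depth the per-border counts are single-digit and
the regression is dominated by Poisson noise); 10,000 replicates for t-test
type-I calibration; 200 simulated plates at n=6/group, Ct noise SD 0.2, for
qPCR fold recovery (a single plate's recovered fold has ~8% sampling error at
this noise level, so accuracy is assessed on the average over plates while the
per-plate significance test is checked directly).

## Known limitations

- The gene-change summary is a surrogate, not a count model; see above.
- GNSSR's gene normalizer (g/T) responds to compartment-composition changes:
  a large shift in mitochondrial content changes every nuclear gene's relative
  expression and therefore scales GNSSR globally.  Group *contrasts* within a
  gene remain interpretable; absolute levels across designs are not.
- Strandedness is carried through the data model but counting is unstranded.
- No paired-end support; no multimapper handling beyond skipping secondary
  records.
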