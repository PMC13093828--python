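# Methods

`stressreg` re-implements, as a tested desk-scale pipeline, the
computational analyses used to characterise the regulation of a
stress-responsive yeast gene (the CLN3 homolog BTN1, systematic name
YJL059W) and its convergent neighbour (BIT61): an expression-compendium
variance screen with co-clustering consensus and gene-set enrichment,
upstream-ORF annotation of the 5' leader, 5' RACE read processing with TSS
calling and TMM/CPM normalisation, and the small quantitation calculations
(2^-ddCt, survival fractions, petite percentages). This note records the
models, parameter choices and numerical conventions, and what the synthetic
data do and do not establish.

## Expression screen

Datasets are gene x condition matrices of (by default) log2 expression
ratios. QC rejects a dataset when it has fewer than `min_genes = 4000`
genes, when any gene's most extreme pair of conditions differs by more than
`max_abs_fold = 100` on the linear scale, or when the query gene is absent
or entirely missing. The query profile is normalised per condition as
query − mean(housekeeping genes) on the log2 scale (equivalently, query
divided by the geometric mean of ACT1 and PDA1 on the linear scale); this
form is symmetric in the two housekeeping genes and invariant to adding a
per-condition constant to every gene, which is what a loading/scanning
normalisation should cancel. Conditions where the query or all housekeeping
genes are missing are dropped rather than imputed, because variances
computed over imputed constants are biased downward. Datasets are ranked by
the sample variance (ddof = 1) of the relative profile, ties broken
lexicographically on dataset id so output is deterministic; the top
`top_n = 15` are kept. Replicate columns sharing a header label are averaged
at load time. The control column is the first column unless one is labelled
"control"/"0 min" or overridden in the config.

Open choices resolved here: the source archives mix log2 ratios and linear
ratios, so the scale is an explicit config flag (`value_scale`), and the
fold filter always evaluates on the linear scale; variance is computed on
normalised log2 values, not linear ratios, because the screen's effect model
is additive in log space.

## Co-clustering and enrichment

Genes are clustered per dataset with k-means, k = 16, on replicate-averaged
log2 values without standardisation. K-means is implemented in-package
(Lloyd's algorithm, k-means++ seeding, Euclidean distance, best of
`n_init = 10` restarts, `max_iter = 300`, relative inertia tolerance 1e-4,
empty clusters repaired by reseeding with the globally farthest point) so
that results are a deterministic function of the seed (default 1) and do not
drift with library versions; scikit-learn is used only as an independent
check in tests. Genes missing in more than half the conditions are dropped;
remaining gaps are imputed with the gene's row mean.

The consensus set collects genes co-clustering with the query in at least
`min_support = 4` of the kept datasets. Enrichment of a gene set against a
GMT collection uses the one-sided hypergeometric tail
P(X >= k | N, K, n) with the background taken as the union of genes present
in the data (the tested universe, not the whole genome) and
Benjamini–Hochberg correction across the terms of one collection. Terms
with zero overlap are reported with p = 1 rather than omitted.

## uORF annotation

Coordinates are HGVS-like `c.` positions: c.1 is the A of the main start
codon, c.-1 the base immediately upstream, no position zero. A uORF "at
−N" has the A of its ATG at c.-N and is in frame with the main ORF iff N is
divisible by 3. The scanner reports every ATG whose A lies in
[−window, −3] (default window 192 bp), most distal first, whether or not
the uORF terminates before the main ORF (`terminated_before_main` is an
attribute, not a filter). Stop-codon search proceeds codon-by-codon in the
uORF's frame and ends at c.-1; read-through into the main ORF is not
followed. Start-codon knockouts convert ATG→AAG, i.e. the T at c.-(N−1)
becomes A, reported as `c.-(N-1)T>A`, matching the mutagenesis convention
used for such strains.

The stop-run probability is the exact binomial tail
P(X >= m | n, p_stop) with p_stop the mass of {TAA, TAG, TGA} under either
a uniform codon model (p_stop = 3/64) or an independent-base composition
model. The "about 2%" figure sometimes quoted for three stops in eight
codons depends on the codon model assumed, which is why both models are
exposed rather than a single number asserted.

## 5' RACE processing and TSS calling

The implemented read model is the "traditional" (poly-dA tailing) chemistry:
cDNA is primed at a gene-specific position, tailed with dATP, and amplified
from a QT-style anchor primer (35-base anchor + poly-dT). A read in anchor
orientation is anchor, then a poly-T run, then the transcript's
sense-strand sequence starting at its 5' end. Processing:

1. **Anchor filter** — a read is kept iff it contains, exactly, at least the
   terminal 8 bases of the anchor (the longest matching suffix is located
   and removed). The template-switching chemistry appears only in the
   fragment-size arithmetic below.
2. **Tail stripping** — the maximal homopolymer run at the junction is
   removed; runs shorter than 5 leave the junction ambiguous and the read
   is dropped. A transcript whose first base equals the tail base would be
   shortened by one — a genuine artifact of this chemistry; the synthetic
   locus plants non-T bases at its TSS positions so noise-free recovery is
   exact, and the noisy-read tests only require modal positions within 1 nt.
3. **Alignment** — exhaustive scan of both strands of the (≤10 kb) locus,
   vectorised over all offsets; a unique best hit with at most 1 mismatch is
   required, ties and worse hits are dropped and tallied in a QC report.
   This replaces a general-purpose aligner at desk scale and makes the
   mapping criterion explicit.
4. **TSS table** — each sense-strand alignment contributes one count at
   (5'-end locus coordinate − ORF start), expressed in the no-zero `c.`
   convention.
5. **Normalisation** — TMM scale factors follow the published edgeR
   defaults exactly: reference sample by the 75th-percentile rule, M and A
   values on rows non-zero in both samples, two-sided trimming of 30% on M
   and 5% on A, inverse-variance weighting, factors rescaled to geometric
   mean 1. Counts are then scaled by effective library size, converted to
   per-sample percentages, and reported as log10(percentage); zero counts
   are missing (NaN), not floored, since log10(0) is undefined. Note that
   weighted TMM is exactly invariant under a common depth rescaling of all
   libraries but only approximately (the weights rebalance) when a single
   library is rescaled; the test suite asserts both at the appropriate
   tolerance, matching edgeR's behaviour.

End arithmetic is exact integer work: a template-switching fragment of
length L with the gene-specific primer at transcript position p and a
36-bp TSO implies a 5' end at −(L − 36 − p) (0 maps to +1 under the no-zero
convention); a 3' end extending e nt past a gene's stop codon reaches
max(0, e − g) nt into the convergent neighbour across a g-nt intergenic
gap; two convergent transcripts overlap by max(0, e_a + e_b − g). The
formula gives 105 for the pair (88, 68, 51) even though a printed range
tops out at 103; the formula is implemented and the discrepancy documented
rather than matched.

## Quantitation

Relative expression uses plain 2^-ddCt with amplification efficiency fixed
at 2 (no standard-curve correction): dCt = mean Ct(target) − mean
Ct(reference) within each sample, ddCt = dCt(test) − dCt(calibrator). Two
reference genes are handled by computing the ratio against each separately
(as such tables are reported), not by averaging references. The uncertainty
is the replicate standard deviations (ddof = 1) of the four groups combined
in quadrature on the Ct scale, reported as the symmetrised half-width of
2^−(ddCt ± sd); this equals (after Bessel correction) the spread of ddCt
over the full factorial of replicate combinations. Survival fractions are
colony counts per plated volume relative to the t = 0 plating
(0.05 ml at t = 0 vs 0.075 ml at 24 h by default); petite percentages are
100 · white/total.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (spec, seed) — reruns are
byte-identical — and every artifact ships a JSON TruthRecord sufficient to
score any downstream stage.

- **Compendium** (default: 15 datasets × 4500 genes × 8 conditions): a
  30-gene module including the query shares a random 0/1 stress pattern
  scaled by a 3.0 log2 effect in 5 of the 15 datasets; housekeeping rows
  have sd 0.05; everything else is N(0, 0.5) log2 noise. This captures the
  additive co-regulation structure the screen and clustering exploit, but
  not two-channel microarray physics, intensity-dependent bias, or
  missing-value structure of real arrays — so recovery results bound
  algorithmic correctness, not field performance.
- **Locus** (250-bp leader, 300-bp ORFs, 51-bp intergenic): ATGs are
  planted at −27, −66, −80, −96, −180 with the published stop structure
  (uORF-27: −18 TAG, −9 TAA, −3 TAA; uORF-66's frame: six stops beginning
  −60 TGA, −45 TAG; uORF-80: −71 TAG, −68 TAA; uORF-180: −168, −162 TAA);
  background ATGs in the window and unplanted in-frame stops are removed by
  rejection resampling, so planted annotation is exact by construction.
  Two consequences of the constraints are worth noting: the ATG at −27
  together with the A at the −24 TSS forces a third uORF-80-frame stop at
  −26, and the sixth uORF-66-frame stop (whose published position is not
  printed) is planted at −30. The generated sequence is synthetic — it
  reproduces the published coordinates, not the genomic sequence.
- **RACE reads** (default 20,000 × 100 nt): anchor + poly-T (run 5–30) +
  sense insert from a TSS drawn from the mixture over −24/−29/−32/−39,
  truncated to read length, with optional uniform substitution noise.
  No quality-score model or PCR bias is simulated.
- **qPCR**: Ct = gene baseline − log2(fold) + N(0, sd) per replicate.

## Problem sizes and determinism

Default sizes (15 × 4500 compendium, 20,000 reads, 1000-sequence oracle
sweeps) run the full suite in well under a minute each on a single core.
Every stochastic component takes an explicit seed with no global default;
`scripts/acceptance.py --seed N --out f.json` threads one seed through all
generators and recomputes every reported quantity from scratch.

## Known limitations

- The screen reproduces the method, not the original archive results: the
  public microarray compendium is not downloaded, and archive-specific
  dialects beyond plain TSV are out of scope.
- Enrichment is a plain hypergeometric/BH test against a supplied GMT; no
  GO graph propagation, and no web-service parity.
- The aligner is an exhaustive-scan locus aligner (≤1 mismatch, unique
  best); it is not suitable for genome-scale mapping.
- ANOVA over survival time courses and heatmap rendering are out of scope;
  the normalised log10-percentage matrix is the heatmap's data product.
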