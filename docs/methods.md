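# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Read disambiguation

Each read pair aligned to both the human and mouse references is assigned
by comparing one scalar per genome. The comparison key is the **summed
alignment score (AS) over mates** when every aligned genome carries AS
tags, otherwise summed MAPQ; `key="mapq"` forces the MAPQ comparison. A
genome with no alignment contributes −∞; an unaligned single mate
contributes 0 to its genome's sum. Ties are ambiguous. The comparison is
**per pair, not per mate**: mate-level evidence is aggregated before the
decision, which avoids splitting a pair across genomes. Assignment depends
only on the comparison key, so it is invariant to input order, and
swapping the two genomes exactly swaps graft and host counts.

## Gene-set filtering

Sets are kept when the fraction of members with a mouse ortholog is
≥ 0.80 and the size is within [15, 400], all boundaries inclusive. Genes
absent from the ortholog map count as non-orthologous. Size and fraction
are measured on the **full GMT membership** by default, since filtering
precedes scoring; `restrict_to=` measures them after intersection with an
expression matrix instead. Symbols are compared case-sensitively after
whitespace stripping; no alias resolution is attempted — the ortholog map
is an explicit input precisely because homology sources differ.

## ssGSEA

The implementation uses the integral (sum-of-differences) form of the
enrichment statistic — the defining choice of the single-sample variant —
rather than the maximum-deviation form of two-group GSEA. Parameters:

* `alpha` (rank-weight exponent): default **0.25**. Not derivable from the
  analysis description itself; 0.25 is the single-sample convention. Fully
  configurable and recorded in every profile's JSON sidecar.
* `normalize`: default on; all scores are divided by the global
  (max − min) of the unnormalized matrix. With non-constant scores the
  normalized matrix has span exactly 1.
* Ties are broken by gene name, which makes scoring deterministic;
  average-rank tie handling was considered and rejected because exact
  reproducibility across runs and platforms matters more here than tie
  symmetry (ties are measure-zero on continuous data).

Because the statistic is a function of within-sample ranks only, any
strictly increasing per-sample transform leaves unnormalized scores
bit-identical (the rank permutation is equal, hence the floating-point
computation is identical). This is verified directly on the distorted
synthetic cohort, and is the operational sense in which gene-set features
are robust to platform differences while individual gene values are not.

Sets with empty intersection against the expression matrix are dropped
with a warning (not an error) at matrix level, matching batch usage; the
single-sample scorer treats the same condition as an error.

## Classification

A random forest (default 500 trees, impurity importances) is trained on
the samples × gene-sets profile with a **stratified 70–30 split** (each
class contributes `round(0.7·n)` training samples, clamped so both halves
are non-empty). Importances from the full-feature fit are linearly
rescaled so the maximum equals 100; features with scaled importance
**strictly greater than 8** are kept. "Scaled importance" has no meaning
without a declared ceiling, so both the ceiling (100) and the threshold
(8) are explicit configuration, persisted in the model manifest. The
pruned forest is refit on the **same training indices** — a fresh split
would leak the old test set into training — and held-out accuracy is
measured once on the untouched test set. The binary tumor-type model is
the identical workflow with two classes.

Forest size, split fraction and threshold defaults are recorded in every
model manifest so that silent defaults cannot diverge from reported
results. Determinism: identical (data, config, seed) gives identical
splits, importances, selected features and probabilities.

## DE thresholds and signature algebra

Genes with total count < 10 are excluded; significance requires adjusted
p < 0.05 **and** |log2FC| > 1, both strict, so a gene at exactly 1.0 or
0.05 is not significant ("greater than |1|" admits only the strict
reading). The shared signature is the intersection over foreground
contrasts of each contrast's up ∪ down calls — direction-agnostic, since
a gene consistently differential but direction-flipped is still shared; a
direction-consistent mode is available by flag. Exclusive signatures are
the direction-consistent foreground intersections minus every gene
differential in any background contrast.

The overlap of a signature with a peak-derived bound-gene list is scored
with the upper-tail hypergeometric probability of at least the observed
overlap. The universe defaults to all genes surviving the count filter of
the first foreground table; it is configurable because the appropriate
universe depends on how the bound-gene list was derived.

## Interval engine

Coordinates are 0-based half-open everywhere (BED native); a gene's TSS is
`start` on `+` and `end − 1` on `−`. Union merge coalesces overlapping
**and touching** intervals per chromosome. Annotation is a total function
returning exactly one of five categories by priority promoter > exon >
intron > downstream > distal intergenic, with ≥ 1 shared base counting as
overlap; the promoter window spans 3 kb upstream to 3 kb downstream of
the TSS in transcription orientation, and "downstream" is a 3 kb window
past the 3′ end (all configurable — ±3 kb is the common annotation-tool
default, adopted here because the windows are otherwise unspecified).
5′/3′ UTRs are deliberately folded into "exon": the downstream analyses
only distinguish promoters, gene bodies and distal regions.

Region enrichment uses a shuffle null: each query peak is re-placed
uniformly on **its own chromosome with its own length**, `n_shuffles`
(default 1000, always logged) times. No exclusion zones are applied — the
simplest null consistent with catalog-enrichment practice; a
universe-restricted mode can be layered by shuffling within a provided
subset genome. The z-score uses the null mean/SD (reported as missing when
the null is degenerate, e.g. a genome-wide catalog), and the empirical
p-value uses the add-one rule `(1 + #{null ≥ obs})/(n_shuffles + 1)`, so
p is never 0 and its floor is 1/(n_shuffles+1). BH correction is applied
across catalog labels. Null placements are drawn once per run and shared
across labels, which makes labels comparable under a single seed.

## Synthetic generators: what they emulate, and what they do not

* **Cohort**: per-gene baselines are Normal(6, 2) on log2 scale (chosen to
  resemble log microarray intensities); each subgroup's marker-set member
  genes are shifted by +delta (default 2.0, a strong subgroup program);
  i.i.d. Normal(0, 0.5) noise; samples alternate between two platform
  distortions (identity, and slope 1.4 / intercept 2 / power 1.15 applied
  through the odd extension so it is strictly increasing everywhere).
  Study conditions used throughout testing: 4 subgroups × 40 samples,
  2000 genes, 200 gene sets of 30 genes with 4 marker sets per subgroup.
  Deliberately *not* emulated: gene–gene correlation beyond marker blocks,
  heteroskedastic noise, batch effects that are non-monotone within a
  sample, class imbalance, and label noise. Passing tests therefore show
  the workflow recovers clean planted structure — they do not bound
  performance on real cohorts, where published models of this type report
  held-out accuracies near 0.95 on >1000-profile corpora.
* **Xenograft**: true-origin pairs favor their genome by a Normal gap
  (mean 15, SD 3, clipped at 1), ambiguous pairs tie exactly. Clipping
  guarantees perfect separability — the generator tests the decision rule,
  not the aligner.
* **DE tables**: planted genes receive |log2FC| ≥ 1.5 and padj < 0.049;
  every null gene is forced to fail at least one threshold (half by small
  fold change, half by padj ≥ 0.05). Adjusted p-values are drawn directly
  rather than via a fitted count model, since DE fitting is upstream of
  this pipeline.
* **Genome**: genes are packed round-robin across chromosomes with ≥ 12 kb
  margins (so adjacent promoter/downstream windows cannot collide), three
  exons each, alternating strands. `plant_peaks` proposes positions near
  the relevant feature and accepts only candidates whose annotation
  round-trips to the requested category, so planted truth is correct by
  construction.

## Problem sizes and numerical checks

Test and acceptance runs use the study conditions above (160-sample
cohort), 1000 read pairs, 2000-gene DE tables, 200-interval merge
fixtures, and 200 repetitions × 999 shuffles for the type-I calibration of
the enrichment test — sizes chosen so the full suite completes in well
under a minute while keeping binomial error on calibrated rates a few
percent. The ssGSEA and hypergeometric implementations are held to 1e−12
against naive direct-summation oracles; the union merge is held exactly
equal to a per-base boolean-array oracle. In the type-I check, both query
and catalog are redrawn each repetition, which smooths the discreteness of
overlap counts; the empirical test is mildly conservative (rejection rates
slightly below nominal 0.05) as expected from the add-one rule on a
discrete statistic.

## Known limitations

* The classifier validates against planted synthetic structure only; the
  published corpus-scale accuracies (and feature counts) depend on
  external controlled-access training data and are out of scope.
* Per-pair (not per-read) disambiguation is a choice, not a published
  convention; pair-level aggregation is documented above and configurable
  ones could be added behind the same interface.
* The shuffle null ignores mappability/blacklist structure; on real
  genomes an exclusion-aware null would be less liberal near repetitive
  regions.
* Gene symbols are matched exactly; real MSigDB/ortholog inputs need
  upstream symbol harmonization.
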