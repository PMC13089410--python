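# Methods

## Overview

`lofburden` implements a gene-level loss-of-function (LoF) burden framework
for inbred plant panels. The chain is: rule-based LoF calling from annotated
variants and structural deletions; collapsing of independent LoF alleles
into a binary gene burden per accession; mixed-model association of burdens
against expression (or scalar) phenotypes; an empirical rank null from
frequency-preserving permutations; a candidate-filtering cascade with a
signed association network; and random-forest prediction of gene
dispensability from per-gene features. A synthetic-study generator with
full ground truth makes every stage testable end to end.

## LoF calling rules

A variant disrupts a transcript when one of the following holds:

* **Annotation rule.** The variant carries a HIGH-impact annotation of one
  of the six disruptive classes (stop gained, stop lost, start lost,
  frameshift, splice donor, splice acceptor). Annotations are taken at face
  value; small-indel frame arithmetic is not re-derived.
* **Deletion frameshift.** A structural deletion overlaps the spliced CDS
  in `o` bases with `o > 0` and `o mod 3 != 0`. Overlap is summed across
  CDS exons only; intronic overlap never counts.
* **Deletion extent.** `o / L > 0.10` for spliced CDS length `L`. "More
  than 10%" is read strictly: a deletion removing exactly 10% is tolerated.

Two vetoes then apply:

* **Terminal exemption.** A variant whose entire CDS footprint lies in the
  first or last 5% of the spliced CDS (windows `[1, ceil(0.05 L)]` and
  `[floor(0.95 L)+1, L]`, boundary bases exempt) is assumed rescuable by an
  alternative start/stop codon. The exemption applies to deletions as well
  as small variants. Splice-site variants have no CDS footprint and are
  never exempt.
* **All-gene-models requirement.** A variant is a gene knockout only when
  every transcript of the gene receives a non-exempt LoF verdict. This is a
  deliberate false-positive guard: a variant sparing one isoform is not a
  true knockout.

Coordinates are handled internally as 0-based half-open intervals; GFF3
(1-based inclusive) and VCF (1-based) are converted at the file boundary,
so all overlap arithmetic lives in one convention.

Carrier coding is dominant: an accession carries a LoF allele when its
genotype contains at least one alternate allele, appropriate for selfed
homozygous lines where heterozygotes are rare sequencing artefacts.
Missing genotypes count as functional and are tallied per variant.
Multi-allelic sites are decomposed per alternate allele.

## Burden matrices

The uncollapsed matrix has one binary column per gene-disrupting variant;
collapsing ORs each gene's columns, so burden 1 means "carries at least one
LoF allele of this gene". Collapsing is idempotent and the collapsed
frequency dominates every member allele's frequency. The minor-allele
frequency filter retains columns with `min(f, 1-f) >= 0.05` (the boundary
is inclusive because only frequencies *below* the threshold are excluded).
Gene genomic position is the midpoint of the gene span, used for distance
filtering and Manhattan tables.

## Association models

Four models are available for phenotype `y` and burden marker `x`:

* `glm`: `y = xb + e`
* `glm_pc`: `y = xb + Cg + e` with the top five genetic principal components
* `emmax`: `y = xb + u + e`, `u ~ N(0, s2g K)`
* `emmax_pc`: both covariates and the random genetic effect

`K` is the centered genomic relationship matrix `ZZ'/m` from column-centered
genotypes; principal components are its leading eigenvectors.

The mixed models use the EMMAX approximation: variance components are
estimated once per phenotype by REML under the null model (no marker) and
the resulting covariance `s2g K + s2e I` is held fixed for every marker
test. REML maximizes the profiled restricted likelihood in one dimension,
`log10(delta)` with `delta = s2e/s2g`, over `[-5, 5]`: a 100-point grid
seeds a bounded Brent refinement (tolerance 1e-8), and the better of grid
and refined optimum is kept. A boundary optimum is flagged (heritability
indistinguishable from 0 or 1). Heritability is reported trace-normalized,
`h2 = s2g (tr K / n) / (s2g (tr K / n) + s2e)`, which makes it invariant to
the scaling of `K`.

Per-marker tests are generalized least squares in the eigenbasis of `K`
with the residual scale re-estimated per marker (t reference with
`n - q - 1` degrees of freedom, `q` covariate columns including the
intercept). Re-estimating the scale means the test reduces *exactly* to
the ordinary t-test when `K = I`, a limit the tests assert; it also matches
an explicit covariance-solve oracle to better than 1e-8 relative error.
Markers constant in the analyzed accessions yield p = NaN with a warning.
All inputs are intersected on shared accession ids before fitting.

Expression preprocessing follows the convention for transcript matrices:
log2 transform, then per gene replace non-finite values with the lowest
finite transformed value among accessions (all-zero genes go to a floor of
0 with a warning). The optional rank-based inverse normal transformation
maps average-tie ranks through `Phi^-1(r/(n+1))`; no Blom-type offset is
applied, since the plain quantile convention is the simplest consistent
with rank preservation, and the offset choice is exposed nowhere else.

## Permutation rank null

For each of 101 replicates, every burden column is shuffled independently
across accessions, preserving its allele frequency exactly. Each permuted
matrix is rescanned reusing the null variance components (the EMMAX null
does not involve the markers, so this is exact under the approximation).
The observed p-value of each (marker, phenotype) pair is ranked among the
first 100 permutation p-values with the conservative tie rule
`rank = 1 + #{sims < obs} + #{sims == obs}`; rank 1 means the observed
signal beat every permutation. The 101st replicate, ranked the same way
against the first 100, gives a matched null rank matrix that is uniform on
{1..101} by exchangeability — the calibration check the test suite runs on
10,100 pairs. Rank enrichment divides the observed rank frequencies by the
null frequencies (unit ratio under the null). Ranking by |beta| instead of
p is available as a switch.

Per-column shuffles deliberately break marker–marker correlation as well as
marker–kinship correlation; this matches the stated per-gene shuffling
procedure even though it does not preserve linkage structure. Seeding is
counter-style — each (permutation, column) pair derives its own stream from
the master seed — so any single permutation is reproducible in isolation.

## Candidate filtering and network

Association hits pass, in order: Benjamini–Hochberg FDR <= 0.05 (applied
globally across all tests in the run; per-phenotype scope is a
configuration choice), removal of same-chromosome pairs with gene midpoints
within 1,000 kb (midpoint-to-midpoint, `<=` removal; cross-chromosome pairs
always pass), removal of pairs where either gene's annotation contains
"hypothetical" (case-insensitive substring), and retention of rank-1 pairs
only. The first three filters commute — they test independent predicates —
and per-stage drop counts are reported. Survivors form a directed network,
LoF gene to expression gene, edge sign from the beta coefficient and weight
`-log10(adjusted p)`; self-loops are excluded with a warning. Diagnostics
include the positive/negative association ratio, Spearman coexpression per
pair, and the Jaccard index of binarized tissue-expression profiles
(expressed when mean expression exceeds 0 by default; both empty profiles
define Jaccard 0).

## Random-forest dispensability

Per-gene features (LoF frequency, tissue breadth, histone-mark means
min-max normalized to [0,1] and averaged over the gene region, sequence
scalars) predict a binary label: pan-genome dispensability or LoF tolerance
(tolerant iff population LoF frequency > 0). Training uses stratified
10-fold cross-validation with balanced training sets — the majority class
is randomly downsampled to the minority size in each training fold, the
held-out fold is untouched — and forests of 500 trees (other
hyperparameters at library defaults, recorded in the report). Every gene is
held out exactly once; out-of-fold scores are pooled into a single ROC
rather than averaging per-fold AUCs. Feature importance is the Mean
Decrease in Gini averaged across folds. Cross-species application trains on
all of one species' data after balancing and scores the second species'
genes, aligned by feature name. The default pan-genome label map counts
only core genes as indispensable; the softcore-with-core alternative is a
preset.

## Synthetic-study generator

The generator emulates the statistical structure of a natural inbred
diploid panel rather than any particular genome:

* **Population.** Balding–Nichols-style: ancestral allele frequencies
  uniform on (0.05, 0.95); each of `n_subpops` subpopulations draws its own
  frequency from a beta distribution with divergence parameter
  `fst_like_divergence` (default 0.15, two subpopulations — modest
  continental structure). Accessions are fully homozygous, coded 0/2.
* **Gene models.** Non-overlapping genes over five chromosomes, 2–3 CDS
  exons, spliced CDS 300–1503 bp (multiples of 3), 20–40 kb spacing so
  within-chromosome distances exercise the 1,000 kb linkage filter; 5% of
  genes are labelled "hypothetical". Multiple transcripts of a gene share
  CDS intervals; alternative gene models are exercised through annotation
  coverage (variants annotated on a subset of transcripts) rather than exon
  structure.
* **LoF alleles.** Per-gene allele counts from a configurable distribution
  (default 0–3, mean ≈ 1.35, giving per-gene allelic heterogeneity);
  per-allele frequencies beta(0.6, 6) clipped to (0, 0.5] — a rare-shifted
  spectrum with most mass below 0.1, a modeling choice, since only the
  shape (most LoF alleles rare, a tail of common ones) is constrained by
  observation. Variant classes follow configurable proportions dominated by
  frameshifts (44.6%) and premature stops (25.0%). True LoF small variants
  are placed in the CDS interior (class labels are annotation strings;
  positions are not class-faithful, which is irrelevant to the rules under
  test); splice variants sit in introns; deletions are engineered to
  trigger exactly one rule. Decoys — MODERATE-impact annotations,
  terminal-5% HIGH variants, in-frame sub-10% deletions, and
  partial-transcript annotations — are emitted and excluded from the truth
  burden, so the caller must actively reject them.
* **Expression.** `y = sum(x * beta * sd_e) + u + e` with
  `u ~ N(0, s2g K*)` for the trace-normalized realized kinship `K*`,
  `s2g = h2`, `s2e = 1 - h2`; effect sizes are in residual-SD units so the
  heritability bookkeeping stays exact. Planted effects (default: 10
  effects of 2 residual SDs, 70% positive) choose causal genes with burden
  frequency in [0.05, 0.45] and targets on a different chromosome, neither
  hypothetical — so planted pairs are removable only by a statistical
  failure, not by construction.
* **Feature tables.** Class-conditional Gaussian features with a mean shift
  of `signal` standard deviations on the informative columns; label
  imbalance preserved exactly.

What the generator does *not* emulate: linkage disequilibrium decay and
recombination maps (permutation breaking of LD is therefore untestable
here), sequencing error and missingness patterns, batch structure in
expression, compensatory mutations, and real epigenomic track
autocorrelation. Passing tests demonstrate the pipeline's internal
correctness and calibration under the stated generative model, not
robustness to those real-data complications.

### Default study sizes

The bundled reference study is 300 accessions, 400 genes, 1,000 SNPs for
kinship, 100 expression phenotypes, 10 planted effects at h2 = 0.3. The
allelic-heterogeneity fixture uses 5 causal genes with 4 disjoint alleles
at frequency 0.02 each (burden 0.08) and an effect of 1 residual SD — the
regime where single alleles are underpowered but the collapsed burden is
not. Replicate counts (100 for the power comparison, 20 seeds per
heritability level, 10,100 pairs for rank uniformity) were chosen to give
stable Monte-Carlo estimates at desk scale.

## Numerical choices and degenerate inputs

* Kinship matrices are symmetrized and eigenvalues clipped at zero after a
  PSD check (tolerance 1e-6 relative to the largest eigenvalue); the
  centered GRM is singular by construction (rows sum to 0), which the
  eigenbasis formulation handles without inversion.
* The Cholesky draw of the polygenic background adds a 1e-8 jitter to the
  singular kinship.
* Markers with residualized variance below 1e-12 are reported as p = NaN.
* p-values are floored at the smallest positive double, never 0.
* A constant phenotype makes the rank-normal transform undefined and
  raises; an all-tie rank vector cannot be normalized.
* Collapsing a matrix already at gene level is the identity.
* BH adjustment goes through the standard step-up implementation; the test
  suite compares it (and Spearman, Jaccard, AUC, INT) against brute-force
  definitions on 1,000 random instances each.

## Known limitations

* The EMMAX approximation shares variance components across markers; for
  markers explaining a large variance fraction, exact per-marker refits
  (not implemented) would differ.
* Degrees-of-freedom and missing-data conventions differ slightly among
  mixed-model implementations; p-values may differ in the third decimal
  from other EMMAX codes.
* Compensatory-mutation rescue, re-annotation of small indels, and
  protein-structure-based effect prediction are out of scope.
* Only deletions among structural variants are classified; duplications
  and inversions are not.
* GO enrichment and coexpression-module detection are external analyses
  and not reimplemented.
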