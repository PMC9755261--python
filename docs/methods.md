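# Methods

This note documents the models and procedures implemented in `lncregnet`,
the parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinate model and I/O

All coordinates are 0-based half-open internally; GTF I/O (1-based
inclusive) converts at the boundary, so a single convention flows through
every stage and interval length is always `end - start`.  The published
DE-lncRNA table shipped in `datasets.py` satisfies `End - Start = Length`
exactly under this arithmetic, which is adopted as the operative convention
for those records.  bedGraph is the required coverage format (plain text,
dependency-free); unknown Cuffcompare class codes are preserved on input and
only interpreted by the discovery filter.

## Discovery cascade

Five per-transcript filters in fixed order: class code ∈ {i, x, u, o};
expression support (FPKM ≥ 0.5 for ≥ 2 exons, ≥ 2.0 for single-exon, met in
≥ 2 samples — boundaries inclusive); no exonic overlap (any bp,
strand-agnostic by default) with annotated small RNAs; spliced length
(exon sum, not genomic span) strictly > 200 bp; and the intersection of
three non-coding verdicts.  The class-code, length and coding filters are
independent per-transcript predicates, so the survivor set is invariant to
their order (property-tested).  Class code maps to category as u→lincRNA,
i→intronic, x→antisense, o→sense.

Coding-potential verdicts are inputs; the built-in stand-in
(`orf_heuristic_evidence`) flags a transcript as coding when its spliced
forward-strand sequence contains a complete ATG→stop open reading frame of
≥ 100 codons.  ORFs that run off the transcript end without a stop are not
counted; the heuristic is marked as such in its output and is not a
substitute for dedicated coding-potential engines on real data.

## Differential expression

Fold change uses condition means with pseudocount ε = 0.01 FPKM
(configurable): log2((x̄_treated + ε)/(x̄_control + ε)).  The pseudocount
bounds the measurable |log2FC| for transcripts that vanish in one
condition; planted effects beyond ~|5| are recovered with the correct sign
but compressed magnitude, which is inherent to ratio estimation on
near-zero means.  Direction calls use inclusive thresholds (q ≤ 0.05,
log2FC ≥ 1 / ≤ −1).  Upstream q-values are consumed as a column; when
absent, a Welch t-test on log2 FPKM with Benjamini–Hochberg correction is
offered and labelled a stand-in — it is not the negative-binomial machinery
of count-based callers and is underpowered at three replicates.

## Cis and trans target inference

Cis neighbors are genes whose edge-to-edge distance from the lncRNA is
≤ 100 kb (inclusive at exactly 100,000 bp, measured from interval edges,
not midpoints).  Correlation is Pearson's r across all samples; the
pass threshold |r| ≥ 0.8 is a package default exposed as a flag — reported
cis pairs in the source study span |r| 0.56–0.97 and no cutoff is stated,
so the default deliberately sits inside that range.

The trans branch is a deliberately simplified co-expression network:
unsigned adjacency |r|^β on log2(FPKM + 0.01) with β = 6, average-linkage
hierarchical clustering of 1 − a, a static cut, minimum module size 10, and
a first-principal-axis module summary (the eigengene analog).  The static
cut height defaults to 0.8: with β = 6 a true pairwise correlation of 0.9
gives dissimilarity 1 − 0.9⁶ ≈ 0.47 before sampling noise, and at 12
samples observed member-pair dissimilarities spread up to ≈ 0.8, so a much
lower cut would shatter genuine modules into singletons.  Full WGCNA
(soft-threshold selection by scale-free fit, TOM, dynamic tree cut) is out
of scope.

The lncRNA–module association p-value comes from ≥ 10,000 sample-label
permutations of the lncRNA vector (two-sided on |r|), avoiding
distributional assumptions at small n.  One honest limitation: with a
2 genotypes × 2 conditions × 3 replicates design, roughly 1/220 of
permutations preserve the condition-block alignment and yield near-identical
correlations, so the permutation p has a structural floor near 10⁻³
regardless of the permutation count.  Parametric figures quoted elsewhere
(e.g. p < 10⁻⁴ from network software) are not comparable at this sample
size.  Enrichment is a one-sided hypergeometric upper tail per term with
BH correction across terms, over the universe of supplied expressed
transcripts.

## Chromatin accessibility

For each query interval the observed mean per-base coverage is compared
with n = 50 random regions of identical length (configurable upward for
more stable p-values).  Null starts are uniform over all valid
(chromosome, start) pairs — chromosomes weighted by capacity — excluding
only the query interval itself; null regions may overlap other features,
including other accessible loci, which occasionally lifts the empirical p
one notch above its 1/51 floor.  The primary statistic is the
plus-one-corrected one-sided empirical rank p (never 0, uniform under the
null — verified by simulation); a z-score and a one-sample t-test of the
null means against the observed value are reported for star-style display.
Adding a constant to the whole track changes neither z nor the empirical p.

## In-silico mutagenesis

The predictor contract is minimal: a deterministic map from a fixed-length
sequence over {A,C,G,T,N} to a bounded scalar read as accessibility at the
window's center (its TSS).  The full-scale TSS extraction length (196,698
nt) is exposed as a constant; desk-scale analyses here use windows of
6,001–10,001 nt, mutagenesis windows of 300–500 nt and strides of 20–25,
which preserve the method's structure at a size a laptop can sweep.

The region scan replaces each window position's contents with uniform
random nucleotides (one draw by default; a `replicates` option averages
several for variance reduction) and records ISMS = |f(modified) −
f(reference)|, with f(reference) computed once.  Per-offset RNG streams are
derived from (seed, offset), so coarser strides subsample — never
reshuffle — the stride-1 profile.  z-scores standardize the profile by its
own mean and SD; offsets with z ≥ 3 merge into maximal runs reported as
peaks.  The threshold direction (high ISMS = significant) resolves an
ambiguity in how the rule is usually printed; the opposite reading would
mark the uninformative bulk of the profile and discard the peaks.  The
single-base scan substitutes all three alternatives at every position and
reports the signed extrema (gain = max Δf, loss = min Δf; gain ≥ loss by
construction).

## Motif scanning

Log2-odds scoring with a probability floor of 1e−4 before the log (so a
zero matrix entry costs ≈ −11.3 bits rather than −∞); `N` contributes the
background-expected score 0.  Exact p-values discretize per-position scores
into bins of 1e−3 log-odds units and convolve the four-valued per-position
histograms into the full null distribution (shift-add, O(4·L·range));
p(score) is the tail at the binned score.  Agreement with exhaustive 4^L
enumeration is exact for the same binning (oracle-tested for L ≤ 6); the
discretization error is bounded by half a bin per position.  P-values are
per-position/per-strand with no multiple-testing across positions — the
stringent 1e−10 threshold is applied raw, matching common TFBS-mining
practice.  The minus strand is scored with the reverse-complement matrix on
the forward sequence under the same background; the background defaults to
the scanned sequence's own composition and is overridable.  Note that an
information-rich motif must be ≥ 18 positions long for even its consensus
to clear p ≤ 1e−10 against a uniform background ((1/4)¹⁸ ≈ 1.5e−11) —
shorter motifs cannot produce hits at that confidence, which is a property
of the threshold, not a bug.

## miRNA target mimicry

Expectation scoring follows the target-prediction convention: per aligned
miRNA position, Watson–Crick 0, G:U wobble 0.5, mismatch 1.0, gap 2.0, all
doubled within the seed (miRNA positions 2–13); the seed definition and
multiplier are a documented reconstruction (only the thresholds —
expectation ≤ 5, fewer than four mismatches — are fixed by convention) and
are exposed as parameters.  The alignment is a banded DP (at most two
unpaired bases per strand) over the miRNA versus the reversed site; ties in
expectation break toward fewer mismatches; G:U pairs are scored but not
counted as mismatches.  A vectorized screen evaluates every site offset at
five site lengths and keeps the best per offset.  The unpairing-energy
(UPE) filter of structure-aware tools requires RNA secondary-structure
prediction and is intentionally not evaluated; the field is emitted as
not-evaluated so downstream consumers can see the gap.

## Synthetic data generator

The generator emulates the statistical structure of a two-genotype
(tolerant/sensitive) salt-stress transcriptome study at desk scale: 2
chromosomes × 100 kb, 200 transcripts (30 true lncRNAs across the four
categories, 110 protein-coding, 20 other-class, and 10 decoys per failure
mode), 2 conditions × 3 biological replicates per genotype.  Planted
differential lncRNAs carry the published fold-change set (2 up + 2 down
tolerant, 6 up + 3 down sensitive) as default effect sizes.  FPKM noise is
log-normal multiplicative (σ = 0.2 on the natural-log scale, configurable;
σ = 0 gives exact planted effects).  Baseline abundances are log-uniform on
[5, 60] FPKM.

The co-expression module (default 50 members, target pairwise r = 0.96) is
induced by a single latent factor: member log2 expression adds
c·(√r·L_s + √(1−r)·ε) with c = 3, which makes the target pairwise
correlation exact in expectation and analytically invertible
(Monte-Carlo-verified to ±0.05).  The latent profile is the z-scored
condition response of the driver lncRNA plus a small continuous per-sample
component (σ = 0.005 log2 units) shared by the driver — modelling shared
regulation beyond the binary contrast and keeping profiles free of exact
ties.  Accessible chromatin is planted as +10 coverage over a gamma(2, 0.5)
background (mean 1.0) at the differential lncRNA loci.  Two
near-consensus 18-mer PWMs are planted into those loci (driving the toy
predictor); three 21-nt miRNAs get perfect antiparallel complements written
into lncRNA exons.  All randomness flows from one seed through named
generator streams; outputs are byte-identical per seed.

The **toy predictor** scores a window as the squashed sum of motif-match
log-odds within a receptive field of the center, where a match must reach
90% of the motif's maximum score; squash(x) = 1/(1 + e^(−x/10)) maps to
(0, 1) with baseline 0.5 for a motif-free window.  Destroying a planted
consensus strictly decreases the score.  It satisfies the predictor
contract and stands in for any trained sequence-to-accessibility model; it
sees only exact-ish motif content on the forward strand, so passing tests
demonstrate the mutagenesis machinery, not biological realism.

What the generator does **not** emulate: read-level noise (no FASTQ),
realistic genome composition or annotation density, correlated
between-replicate structure, batch effects, dispersion–mean trends in
expression, degenerate motif instances, or RNA structure.  Truth-recovery
results on it are exact-by-construction checks of the pipeline's logic, not
evidence about performance on real libraries.

## Problem sizes

Defaults throughout are chosen so the full test suite and the acceptance
script each run in well under a minute of CPU: simulations use the 2×100 kb
genome, mutagenesis sweeps 6 kb sequences at stride 20, Monte-Carlo checks
use 10–40 seeds, permutation tests 500–10,000 shuffles, and the uniformity
calibrations 500 simulated tracks.  Every size is a parameter, and the
methods scale to chromosome-size inputs at proportional cost.

## Known limitations

- q-values for differential calling are trusted inputs; the Welch stand-in
  is honest but weak at n = 3.
- The module-detection stage is a static-cut simplification; overlapping or
  nested modules are not modelled.
- The permutation association test's resolution is bounded by the sample
  design (see above).
- The mimicry screen reports no UPE, so its output is a superset of what a
  structure-aware screen would pass.
- The discovery cascade's exactness claims hold at zero noise; with noise,
  boundary transcripts (e.g. FPKM hovering at a threshold) can flip filter
  outcomes, as they would in any thresholded pipeline.
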