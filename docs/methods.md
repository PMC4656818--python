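# Methods

This note documents the statistical procedures, the synthetic-data models
behind the tests, the numerical conventions, and the limitations a user
should know before trusting a result.

## Z-ratio differential expression

**Procedure.** Raw gene × sample intensities are (1) globally normalized —
each array is rescaled by `mean(array totals) / array total`, so all arrays
share the mean total while within-array structure is preserved; (2) log10
transformed after clipping at a floor (default 1.0 intensity unit, serving
as the low-signal filter); (3) Z-scored per array (column mean 0, SD 1).
For groups A (case) and B (control), per gene:

- `d(g) = z̄_A(g) − z̄_B(g)` (mean over replicate arrays; the mean, not the
  median, defines a group's z-value),
- `Z-ratio(g) = d(g) / SD_genes(d)` — the denominator is the standard
  deviation of `d` over *all* genes, so the Z-ratio expresses each change in
  units of the platform-typical change and the vector has unit SD by
  construction,
- Z-test: `t(g) = d(g) / sqrt(s²_A/n_A + s²_B/n_B)` referred two-sided to
  the standard normal (a reproducibility test across biological replicates),
- q-values by Benjamini–Hochberg step-up.

A gene is called up/down when `(|Z-ratio| ≥ 1.5 OR p < 0.05) AND q < 0.05`;
the three gates are independent flags on `ZRatioModel.fit`.

**Conventions.** Per-array Z-scoring uses the sample SD (ddof=1, the
spreadsheet STDEV convention of the lineage this statistic comes from:
log10 {10,100,1000} → z = {−1,0,+1}); the cross-gene SD in the Z-ratio
denominator is also ddof=1.  A degenerate all-zero `d` vector returns zero
Z-ratios rather than dividing by zero; a gene with zero pooled SE gets
p = 1 when the group means agree and p = 0 otherwise.

**Assumptions and limitations.**

- Referring the replicate Z-test to the standard normal is the method's
  historical choice, not a calibrated one: with 3 replicates per group the
  statistic is approximately t with ~4 degrees of freedom, so null p-values
  are anticonservative (P(p < 0.05) ≈ 0.12) and *not* uniform.  The FDR
  gate absorbs much of this in calling, but the p-values themselves should
  not be read as calibrated tail probabilities at these replicate counts.
- The Z-ratio null calibration (≈13.4% of null genes beyond |1.5|, the
  two-sided normal tail) holds because the statistic is standardized across
  genes; it is what makes 1.5 a meaningful default threshold.
- When a large fraction of genes carries very large shifts, per-array
  Z-scoring itself is perturbed: the affected arrays' SDs inflate, the two
  groups' z-scales diverge, and baseline-dependent systematic differences
  leak into every gene.  In the planted-recovery tests (5% of genes shifted
  by 3 standardized units, i.e. 1000-fold) this costs a few points of
  specificity and makes sensitivity saturate — and even recede slightly —
  at the largest effects.  Real studies sit far from this regime, but it is
  why the recovery property tests allow a 0.02 saturation tolerance.

## Signed Venn partitioning

Each dataset contributes a signed set (gene → ±1).  Every gene in the union
belongs to exactly one region keyed by (the subset of datasets containing
it, category), with category `up` when every containing set has +1, `down`
when every one has −1, and `contra` when any pair disagrees (for 3–4 sets,
one disagreeing pair suffices).  Cross-omics overlap folds identifiers to
lower case before matching (gene-symbol case differs between array and
proteomics conventions; no alias/ortholog mapping is attempted) and labels
shared identifiers concordant/discordant by polarity agreement.

## Pathway over-representation

For a list of n genes in a universe of N, a pathway with K members in the
universe and O in the list: `E = nK/N`, `R = O/E`, and
`p = P(X ≥ O), X ~ Hypergeom(N, K, n)` (upper tail).  A pathway is reported
only when O ≥ 2 (configurable) and flagged significant when `R > 1 and
p < 0.05` — raw p by design, mirroring the minimum-population-of-two and
raw-hypergeometric convention of this analysis style; an optional BH flag
adjusts across pathways.  The universe is the measured platform restricted
to the annotation file; whether to prefer a whole-genome background is left
to the caller via the `universe` argument.

The polarity score of a pathway is `100·U/(U+D) − 100·D/(U+D)` where U and
D count pathway members among the up- and down-regulated lists; the
denominator is the *populated* members (not all members) so a purely
up-regulated pathway scores +100 regardless of its size, and an unpopulated
pathway scores 0.  A pathway significant in both the up-only and the
down-only enrichment runs is classed `bimodal`.

## iTRAQ quantification

Inputs are peptide-level reporter-ion intensities for channels 114/115
(two pooled control samples) and 116/117 (two case samples).  Per peptide:
`r_ctrl = i114/i115`, `r116 = i116/mean(i114,i115)`,
`r117 = i117/mean(i114,i115)`; peptides with a zero denominator are skipped
with a warning.  Protein values are the **median** of peptide ratios (robust
to single outlier spectra; the roll-up statistic of the upstream vendor
pipeline is unpublished, so a documented robust choice is used), with
`min_peptides` defaulting to 1 — a single compliant spectrum may quantify a
protein.  QC: a protein is trusted only when `0.8 < r_ctrl < 1.2`, strict
inequalities (exactly 0.8 or 1.2 fails); failing proteins stay in the QC
report but are never called.  Differential calls (mode `any`, the default):
up if `r116 > 1.2 or r117 > 1.2`, down if `r116 < 0.8 or r117 < 0.8`;
channels breaching in opposite directions yield `unchanged` with a conflict
flag.  Mode `both` requires both case channels concordantly outside the
limits.  `116:(114:115)` is read as the case channel over the mean of the
two control channels.  Note the (0.8, 1.2) window is asymmetric on the
ratio scale; swapping the control labels maps `r_ctrl → 1/r_ctrl` and can
change QC status near the boundaries — the documented, not symmetrized,
behavior.

## Latent semantic indexing

Documents (one per gene: its concatenated literature text) are tokenized
(lowercase, split on whitespace and hyphens, punctuation stripped, a small
overridable English stop-word list).  The term × document matrix carries
log-entropy weights: local `ln(1+tf)`, global
`1 + Σ_j p_ij ln p_ij / ln n` with `p_ij = tf_ij/gf_i` — a term spread
uniformly over all documents is muted (weight ~0), a term unique to one
document keeps weight 1.  A rank-k truncated SVD `W ≈ U_k S_k V_kᵀ`
represents documents as columns of `S_k V_kᵀ`; a keyword query is weighted
like a document and folded in as `U_kᵀ q`.  Cosine similarity classifies
associations: > 0.2 explicit, 0.1–0.2 implicit (exactly 0.2 goes to
implicit), < 0.1 none.

k defaults to `min(300, rank)` and matters: at full rank the decomposition
is exact, so only explicit (shared-term) associations survive; implicit
associations emerge only in reduced-rank spaces, and on small corpora a k
around half the document count works well.  Two caveats of reduced rank:
(1) a document whose retained latent norm is near zero has an unstable
direction, so isolated unrelated documents can show spurious moderate
cosines; (2) scores are corpus-dependent, so the 0.2/0.1 thresholds are
conventions, not probabilities.

Word-cloud support: noun phrases are dismantled into individual words
(whitespace/hyphen split, lowercased) and counted; a word table carries the
occurrence count, its z-score across the listed words (population SD), and
the latent cosine between the word's term vector and the centroid of all
document vectors.  Differential word tables subtract z and cosine between
two datasets over their common words.  These are documented, testable
stand-ins for the interface of the proprietary tools used in this analysis
style; they are not reimplementations of those tools' scores.

## Synthetic data models

- **Expression**: gene baselines `b_g ~ N(2.5, 1.0)` in log10 units; each
  array adds `N(0, 0.3)` replicate noise — 0.3 log10 (~2-fold SD) is the
  between-animal biological scale for brain tissue, deliberately larger
  than pure technical array noise since the emulated replicates are
  individual animals.  A planted gene's case arrays shift by
  `±effect × sqrt(1.0² + 0.3²)` log10 units, i.e. `effect` is in
  standardized per-array log-intensity (z) units; planted genes are half
  up, half down (ties to up).  Intensities are `10^(log10 value)`, hence
  strictly positive.
- **iTRAQ**: per-protein abundance `10^N(4, 0.5)`, per-peptide ionization
  factor `10^N(0, 0.2)`, and independent multiplicative log-normal channel
  noise with the requested CV (`σ = sqrt(ln(1+cv²))`); planted proteins
  multiply channels 116/117 by the fold.  `control_cv=0` gives exact unit
  ratios.
- **Pathways**: non-planted pathways draw members uniformly from the
  universe (the hypergeometric null by construction); planted pathways
  include DE genes at `enrichment_factor ×` the background rate.
- **Corpus**: each gene has a private filler vocabulary (8 words × 3), so
  unlinked genes are exactly orthogonal to every keyword context.  Explicit
  links add the keyword (×6) plus its 5-word context vocabulary (×2);
  implicit links add only the context vocabulary (×2).  For each linked
  keyword, 4 background "abstract" documents co-mention the keyword with
  its context — without them implicit associations would be exactly zero at
  every rank, because an isolated low-rank block is reconstructed exactly
  by the SVD.  Under these doses implicit-link cosines land around 0.17
  (inside the implicit band) and explicit links near 1.

What the generators do *not* emulate: probe-level effects, background
correction, intensity-dependent (heteroskedastic) array noise,
peptide-misassignment or ratio compression in iTRAQ, overlapping pathway
correlation structure, and natural-language grammar (documents are bags of
tokens).  Passing recovery tests therefore demonstrate the correctness of
the statistics under their own assumptions, not robustness to those
real-data artifacts.

All generators are fully determined by their seed (single `default_rng`
per call) and record their planted truth.

## Problem sizes in tests

The test and acceptance runs use 1000–2000 genes with 3 replicates per
group, 400 proteins × 3 peptides, 20-pathway collections over a few hundred
genes, and 20-gene corpora over 20 seeds — sizes at which every stage's
behavior (calibration, recovery, oracle agreement) is already stable and
the whole suite runs in seconds.

## Design choices where the design was open

- The Z-ratio denominator (SD across genes of the mean-z differences) and
  the and/or gate structure are fixed to the published thresholds but every
  constant is a parameter, never hard-coded downstream.
- Enrichment reports raw hypergeometric p by default (BH optional) to match
  the convention of the analysis style it reproduces.
- Peptide→protein roll-up by median; control channels summarized by their
  mean in the case-ratio denominators.
- The pipeline writes TSV/JSON only, with a manifest of SHA-256 checksums;
  rerunning with the same seed and config is byte-identical.
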