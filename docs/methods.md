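# Methods

## Model and procedure

The package identifies candidate immunosuppressive clonal hematopoietic
(CH) mutations in tumor-infiltrating immune (TII) cells from a cohort of
matched tumor / normal-blood exomes. The underlying model: a somatic
mutation arising in a hematopoietic stem/progenitor clone is carried by a
fraction *f* of blood cells, so at a site of depth *n* the observed alt
read count is approximately Binomial(*n*, VAF), where the expected VAF of a
heterozygous somatic variant is *f*/2. Because TII cells are
blood-derived, the same variant appears in the tumor sample at a VAF set by
immune infiltration. The dual window 2% < VAF < 25% **in both samples**
therefore selects clonally expanded somatic variants that are present in
TII cells while excluding sequencing noise and circulating-tumor-DNA
contamination (below 2%) and heterozygous germline variants (around 50%).
It is implemented with strict inequalities, since the thresholds are stated
as "greater than 2%" and "less than 25%".

Downstream filters encode the passenger-exclusion logic: a truly functional
CH variant should recur across unrelated patients (sample fraction > 5%,
strict), be rare in the general population (frequency < 10⁻⁴, strict; a
variant absent from the reference, frequency 0, passes), not sit in a gene
family that hypermutates naturally during immune response (immunoglobulin,
T-cell receptor, histocompatibility antigen and Ig-like receptor loci), be
predicted damaging by both SIFT and PolyPhen — with truncating, frameshift
and splice-site variants auto-classified as deleterious, since the
predictors do not score them — and lie in a gene expressed by at least one
immune cell in a tumor-microenvironment single-cell atlas.

## Statistics

* **VAF**: alt/(ref+alt) of the variant's two alleles, an exact rational of
  the two MAF count fields. The alternative (alt/total site depth) differs
  only at multi-allelic sites, which are out of scope.
* **Binomial proportion CI**: Wilson score interval by default
  (well-behaved at boundary counts; the bound is pinned to exactly 0/1 at
  zero/full alt counts where the closed form is analytically at the
  boundary). Wald and Clopper–Pearson are available via `ci_method`.
* **Welch *t*** with Satterthwaite degrees of freedom, two-sided, from the
  defining formulas (see `diff_expression`); groups need ≥ 2 observations
  and at least one nonzero variance.
* **Benjamini–Hochberg** step-up adjustment, computed by the
  cumulative-minimum pass over sorted p values; genes with zero variance in
  both groups are untestable and are excluded from the correction rather
  than diluting it (their count is logged).
* **Reported percentages** are rounded half-to-even at the requested
  precision (`report_percent`).

These four statistics are implemented in-package from their formulas;
statsmodels/scipy serve only as independent cross-checks in the test suite.

## Funnel accounting

Per-sample MAF rows collapse to one funnel unit per distinct variant
(keyed on chromosome, position, ref, alt) from the protein-altering stage
onward, so stage counts tally "different mutations" rather than
observations. The three per-variant filters (recurrence, rarity,
hypermutable exclusion) commute; the report applies them in the order
recurrence → rarity → hypermutable → deleteriousness → expression. A
variant "passes" the CH window per sample independently: a sample carries
the CH variant iff its own VAF pair lies in the window, and the sample
fraction is the number of such samples over the cohort size.

Two expression ratios exist for a gene: immune-expressing cells over all
expressing cells (the ratio the candidate table prints) and
immune-expressing cells over all immune cells. `summarize_gene_expression`
reports both; the candidate table uses the former.

The final literature-curation step of candidate selection rests on reviewed
experimental evidence and is not computable; the pipeline's computational
endpoint is the candidate set with its differential-expression and pathway
evidence. An optional user-supplied allowlist can stand in for curation.

## Synthetic cohort

The generator emulates the statistical structure of the study data rather
than reads or callers:

* **Depth**: Poisson around `depth_mean` (default 200×), floored at 16 and
  capped at 725 — the observed exome depth range. The Poisson choice is a
  stand-in; per-variant depth distributions of real exomes are not modeled.
* **Alt reads**: Binomial(depth, true VAF); no substitution-error model
  beyond the explicit noise variants.
* **Cohort**: 1,064 samples by default, matching the study scale. Planted
  CH variants draw true VAFs uniformly inside (0.05, 0.20) in each sample
  type and carrier fractions in (0.06, 0.12) — above the 5% recurrence
  threshold, which planted variants must pass by construction; the
  `passenger:sample_fraction` variant sits at 2%, so the cohort straddles
  the threshold. Germline variants have true VAF 0.5; noise variants
  < 1.5%, with half (configurable) additionally failing the quality gate.
* **Quality fields**: LOD uniform on (4.01, 75.10) and base quality on
  (10, 40) for passing calls — inside the observed ranges — and below the
  thresholds for the failing noise calls; no caller is modeled.
* **Passenger somatics**: each is built to fail exactly one named filter
  (recurrence 2%, population frequency 0.05, hypermutable TRBV gene,
  SIFT-tolerated, or zero immune-cell expression) and to pass all others.
* **Single cells**: 1,500 cells by default (a down-scaled microenvironment;
  the real atlas has ~100k), with fixed type proportions (40% T-cell, 25%
  myeloid, 10% B-cell, 5% NK, 20% non-immune). Variant genes express with
  T-cell-skewed per-type Bernoulli probabilities so the pooled immune
  composition lands near the observed ~55% T-cell / ~35% myeloid split;
  counts for expressing cells are 1 + Poisson(1).
* **Bulk expression**: log-scale Gaussian values (baseline uniform on
  (2, 10), unit noise SD) so the *t*-test assumptions hold by construction;
  each planted variant shifts a disjoint set of 5 background genes by
  `de_effect_size` (default 1 SD) in its carrier samples, and those genes
  map to the "Immune System" top-level pathway.
* **Determinism**: one RNG stream per output table, all spawned from the
  master seed, so regenerating one table's noise does not perturb another;
  a fixed seed yields byte-identical bundles.

What passing tests on this cohort do **not** show: robustness to real
caller artifacts, mapping bias, contamination, depth heterogeneity between
sample types, non-Gaussian expression, batch effects, or cell-type
misannotation. The generator exercises the thresholds and the bookkeeping,
not the sequencing physics.

## Problem sizes and numerical choices

The default test/acceptance configurations use 1,064 samples, ~30 variants,
120–165 genes, 1,500 cells and 2,000-replicate calibration simulations —
small enough to run in seconds while keeping every threshold exercised on
both sides. Oracle-equivalence checks run 1,000 random instances at 1e-9
tolerance. Ties in the BH adjustment share one adjusted value (stable
sort); the CH-window reason codes resolve in the fixed order below-lower
(blood, tumor) then germline-range (blood, tumor); degenerate inputs
(zero depth, empty tables, zero passing samples, all-zero expression pools)
raise domain errors or return explicit absent values as documented on each
function.

## Known limitations

* The funnel consumes SIFT/PolyPhen calls and population frequencies as
  annotations; it does not compute them.
* Pathway evidence is a tabulation against a supplied gene → top-level
  pathway map, not an over-representation test against a pathway database.
* Single-carrier candidates report no VAF SD (the moment is undefined at
  n = 1).
* Multi-allelic decomposition, VCF input and indel normalization are out of
  scope; input is the MAF dialect documented in `variant_io`.
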