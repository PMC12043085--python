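# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data experiments do and do not establish.

## Germline variant triage

A candidate germline call passes the hard filter iff all of: population
allele frequency < `rarity_max_af` (default 0.01, strict inequality), read
depth ≥ `min_depth` (10), alternate reads ≥ `min_alt_reads` (4), VAF ≥
`min_germline_vaf` (0.40 — lower fractions are treated as probable somatic or
artifactual), consequence in {missense, nonsense, frameshift, indel, splice
site}, not in a repetitive region, not duplicated by a somatic call in the
same patient, and ACMG tier not benign/likely benign. Filtering is pure
flagging: rows are never dropped, so audits can recover why a variant failed.

### Overrepresentation screen

The cohort-versus-population comparison is realized as a one-sided exact
binomial upper tail: for a variant with population allele frequency *p*
observed with allele count *k* (het = 1, hom = 2) in a cohort of *n*
genotyped patients, the p-value is P(X ≥ k) for X ~ Binomial(2n, p). A
Poisson approximation is available behind `overrep_test: poisson`. A
population frequency of exactly 0 is floored at 1/(2 ·
`reference_cohort_size`) (default 63,026) so the tail stays defined; the
floor is the standard one-allele pseudo-count.

Benjamini–Hochberg step-up control runs at `fdr_alpha` (0.05) over the
family of *filtered VUS that were observed in the cohort*. P/LP variants are
selected unconditionally and excluded from the family. Two consequences of
this family definition are worth knowing:

- Selection is monotone in alpha (tightening the FDR never adds variants).
- Because unobserved variants cannot enter the family, the family is
  conditioned on observation. For very rare variants this conditioning makes
  the realized false-discovery proportion somewhat leakier than the nominal
  level in the worst case; the calibration experiment (below) measures the
  realized FDP under the default generator and finds it well inside 2×
  nominal. Screening decisions on real cohorts should still treat q-values
  near the threshold with caution.

### hcD classification

Rules, any of which makes a carrier high-confidence deleterious:
(a) any selected P/LP variant; (b) a heterozygous selected VUS in a
dominant-trait gene (AD, or AD_AR); (c) biallelic selected variants in a
recessive-capable gene (AR, AD_AR, XL): homozygous, or ≥ 2 distinct
heterozygous variants in the same gene. WES is unphased, so rule (c)'s
two-het branch is a *presumed* compound heterozygote; the rule tag records
which branch fired. X-linked hemizygous calls should be encoded as `hom` so
males flow through rule (c) — the biological convention for hemizygosity.

### Burden statistics

Cohort summary reports: carrier count and combined burden (carriers /
cohort), hcD rate, per-carrier variant count distribution (median, range),
the simplified expected probability (sum of the selected variants' population
allele frequencies), and Pearson's χ² (no Yates correction, matching the
usual reporting of χ² on large tables) on carriers-vs-controls. Percentages
are printed as half-up integers but stored with numerator and denominator so
they always recompute exactly.

## Somatic landscape

Driver SNV/indel calls are kept when the gene is on the driver panel, the
pathogenicity annotation is P/LP, and the consequence is protein-altering.
The shipped 30-gene panel is a stub assembled from recurrently mutated T
cell neoplasm and lymphoid clonal-hematopoiesis drivers; real analyses
should supply the full panel as an input table.

Gene-level copy number is the overlap-length-weighted mean of segment log₂
over the gene interval (0-based half-open coordinates throughout). Calls:
gain at weighted log₂ ≥ +0.3, loss at ≤ −0.3 — roughly a one-copy change at
moderate tumor purity; both cutoffs are configurable because no universal
threshold exists. A gene is excluded from calling when blacklist intervals
(hypervariable regions, common population CNVs) cover ≥ 50% of its length
(configurable); blacklists are expected pre-merged — self-overlapping
blacklist intervals would double-count coverage. A gene with no overlapping
segment is reported neutral with missing log₂ and a `no_coverage` flag
rather than silently dropped.

## TCR repertoire

Only productive rearrangements (in frame, no stop codon) are analyzed.
Depth normalization is rarefaction to exactly `downsample_templates` = 5,420
templates, drawn uniformly without replacement from the template multiset
via a single multivariate-hypergeometric draw — per-clone sampled counts are
bounded by the originals and totals are exact, and the draw is
bit-reproducible given a seed. The rarefaction unit is *templates*; a
unique-clonotype mode (`downsample_unique`) exists for sensitivity analyses
since "clones" is ambiguous between the two readings. Samples below the
rarefaction depth raise an explicit insufficient-depth signal and are
excluded from normalized comparisons (mirroring cohorts where a subset of
samples survives normalization).

Diversity: inverse Simpson 1/Σpᵢ² (bounds [1, richness] are property-tested),
unique clonotype count, mean clone size. Expansion classes from template
count: nonexpanded (1), normal (2–5), pathological (>5), hyperexpanded
(>10); hyperexpanded is nested inside pathological and both flags are
reported. Specificity annotation is exact CDR3 amino-acid string equality
against the reference; V/J genes are deliberately not part of the matching
key. A clonotype matching several condition categories counts once per
category and is flagged ambiguous.

## Expression scoring

`module_score` is the binned-control gene-set score: genes are ranked by
dataset-wide mean expression and cut into `n_bins` = 24 equal-size rank bins
(deterministic first-occurrence tie-break); each set gene contributes
`n_ctrl` = 100 control genes drawn uniformly without replacement from its
bin (capped at bin size, seeded); the per-cell score is the set-gene mean
minus the pooled-control mean. The defaults are the conventional ones for
this score family. The score is invariant to adding a constant to the whole
matrix and equivariant under cell permutation; tests verify both, plus
agreement with an independent dense recomputation when controls are whole
bins, and rank agreement with the scanpy implementation as a cross-check.
Input is assumed log-normalized; scores on scaled (z-scored) data are
accepted but shift the interpretation of the percentile threshold.

Bulk samples use a geometric mean over the set genes, exp(mean(log(x +
pseudocount))). Signature construction intersects an internally derived
up-regulated list with the union of external up-regulated lists,
order-stable and deduplicated; an empty intersection warns rather than
fails. High/low calls cut strictly above the empirical `score_percentile`
(0.90) quantile computed over *all cells pooled* (matching thresholds
applied to one combined embedding); a per-group option exists. Ties at the
threshold are low; constant scores yield all-low with a warning.
Coexpression reports per-group proportions with stored counts and an r×2 χ²
per flag; degenerate flags (all high or all low) yield NaN statistics
rather than an error.

The shipped 15-gene TCR-signaling and 9-gene STAT3-activation sets are
reconstructions assembled from TCR-complex/signalosome members and canonical
STAT3 targets respectively; neither is a published list, and both are plain
configuration (`gene_sets` in the YAML) meant to be replaced.

## Clinical phenotyping

An analyte is low iff strictly below the lower normal bound; missing
analytes yield absent flags (never false) and are excluded from
denominators, so every proportion is over the patients actually assessed.
Hypogammaglobulinemia = any Ig isotype below bound. Lymphocytopenia bound
defaults to 1.0 ×10⁹/L (standard clinical bound; the study convention only
fixes the ≤ 4.0 "low/normal" ceiling, so the lower bound is configurable).
The immune-defect composite is lymphocytopenia OR hypogammaglobulinemia —
the only explicitly stated composite; whether subset deficits should count
is genuinely open, so the composite is kept minimal and the per-subset flags
are reported alongside. Hypogammaglobulinemia with any acquired-cause
history flag (prior hemato-lymphoid neoplasm, anti-B-cell or other
immunosuppressive therapy, chemotherapy, Good syndrome/CVID-like condition,
transplant) is an acquired candidate; with none, unexplained. Reported
percentages are half-up integers with stored counts.

## Synthetic cohort generator

What it emulates, per stage, with defaults chosen as the study conditions:

- **Germline** (n = 92 patients, 60-gene panel): planted variants appear
  heterozygous per patient with probability 2·AF·enrichment (default 8
  variants at AF 10⁻⁴, 50× enrichment), nulls at 2·AF (40 variants at AF
  5·10⁻⁴); depth ~ NegBin(mean 80, dispersion 0.2), het VAF ~ Beta(20, 20).
  Unobserved variants are absent from the table, as in real calling.
- **Somatic**: STAT3 mutation rate 0.46, non-STAT3 driver rate 0.49,
  burden capped at 4 — the cohort-scale driver rates.
- **Repertoire**: 10,000 clonotypes, Zipf(2.5) clone sizes truncated at 10
  templates, 5 planted hyperexpanded clones (sizes log-uniform 50–2,000), a
  4% planted reference-match fraction split infection/autoimmunity/tumor
  surveillance (0.02/0.01/0.01). Truncating the background at the
  hyperexpansion bound makes the planted clones the exact truth set. The
  generated specificity reference holds 2,000 clonotypes — a scaled-down
  stand-in for an 80k-entry reference, which only changes the absolute match
  fraction, not the matching logic under test.
- **Expression**: 3 groups × 300 cells × 500 genes; per-gene baselines
  uniform on [0, 4] (so expression bins have structure), noise SD 1.0, +δ
  (default 1.0) on the score genes in the designated group.
- **Clinical** (n = 201): analytes lognormal with the mean set so the target
  fraction falls below the lower bound exactly by construction (σ = 0.4);
  patient-level hypogammaglobulinemia at 0.32 with acquired-cause flags at
  0.61 among the affected — the cohort-scale clinical rates.

All randomness flows from `numpy.random.default_rng` (PCG64) keyed on
(seed, CRC-32 of the stage name), so outputs are bit-reproducible across
platforms and processes.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: linkage between variants, relatedness,
batch effects and ancestry stratification in allele frequencies, sequencing
artifacts correlated with repetitive regions, V/J-specific PCR bias in
repertoires, dropout and library-size variation in single-cell counts, and
correlated multi-analyte failure patterns in clinical labs. The experiments
establish that the implementations recover planted effects under their own
stated model, not that the thresholds are clinically optimal.

## Calibration experiments (defaults used by tests and the acceptance script)

- **Screen FDR/recall**: 200 replicate 92-patient cohorts; pooled FDP among
  selected VUS ≤ 2× nominal, and recall ≥ 0.8 of planted variants, counted
  over planted variants present in the cohort (an unobserved variant is
  unrecoverable by any screen).
- **Rarefaction**: two clones 8,000/2,000 rarefied to 5,420 over 500 seeds;
  the mean sampled share must sit within 3 SE of the hypergeometric
  expectation (0.8).
- **Shift recovery**: 20 replicates at δ = 1.0; the shifted group must have
  the strictly highest fraction of 90th-percentile-high cells in ≥ 19.
- **Determinism**: simulate + full pipeline twice at one seed; the
  serialized summaries must be byte-identical.

Problem sizes were chosen so the full suite runs in well under a minute on
one CPU while keeping Monte-Carlo error far from each experiment's acceptance margin.

## Numerical and degenerate-input choices

- BH q-values use the standard reverse cumulative-minimum step-up form,
  clipped at 1; ties share the q of the highest tied rank.
- χ² on a table with a zero marginal raises with a pointer to Fisher's
  exact test instead of returning NaN.
- Rarefaction at exactly the repertoire's depth is the identity (no draw).
- Half-up percent rounding (not banker's) matches clinical reporting of
  integer percentages.
- Interval semantics are 0-based half-open everywhere (BED convention);
  malformed intervals are row-level errors carrying the source line number.

## Known limitations

- The observed-only BH family (above) is the procedure as practiced on real
  cohorts, not an oracle-optimal test; a family over all panel variants
  would be more conservative.
- Compound heterozygosity is presumed, not phased.
- Gene-level CN calling ignores purity/ploidy and segment uncertainty; the
  ±0.3 default is a convention, not an estimate.
- The specificity match is exact string equality; near-matches (single
  mismatches, motif-level similarity) are out of scope.
- Expression scoring assumes a dense, moderately sized matrix (the analysis
  scale here); very large sparse atlases would want a sparse-aware path.
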