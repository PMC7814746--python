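# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the synthetic-data generator's assumptions, and the
numerical and design choices made where the design was genuinely open.

## Data model

A cohort is a sites × samples pair of matrices: beta values
β = m / (m + u) from methylated (m) and unmethylated (u) read counts, and
the coverage m + u.  β is missing exactly where coverage is zero; the
beta/count identity is preserved by every transformation and asserted by
`MethylationMatrix.check_consistency`.  Coverage files use 1-based inclusive
positions; BED inputs are 0-based half-open; conversion happens exactly
once, at read time.  Missing values are excluded pairwise in every
downstream statistic — there is no imputation anywhere in the inference
path (the panel classifier mean-imputes features, see below, but no test
statistic does).

Site inclusion follows the cohort filter: a CpG is kept when covered at
≥ `min_coverage` (default 5) reads in ≥ `min_sample_fraction` (default 0.9)
of samples, both comparisons inclusive, restricted to autosomes 1–22
('chr'-prefixed or bare naming auto-detected; mixed naming is an error).
Opposite-strand calls at adjacent positions are *not* merged by default; an
optional documented merge (`merge_strand_calls`) sums counts of pos/pos+1
pairs onto the lower position.

## Differential methylation

Per CpG, the two survivor groups are compared with an independent two-sided
t test on beta values — Welch's unequal-variance form by default (Student's
available via `equal_var=True`); the selection rule is the raw
dual cutoff *p* < 0.01 and |Δβ| ≥ 0.1, with Δβ defined as STS mean minus
LTS mean.  No multiple-testing correction enters selection; a
Benjamini–Hochberg column is emitted for users.  A site is testable with
≥ 2 non-missing betas per group; zero-variance ties yield t = 0, p = 1.

The global comparison and all other two-group location tests use the
Wilcoxon rank-sum: exact enumeration when the combined n ≤ 20 and the data
are untied, otherwise the tie-corrected normal approximation without
continuity correction (so two identical groups give p = 1 exactly).

Region calling is single-linkage chaining of significant CpGs on one
chromosome with inter-site gap ≤ `max_gap`; runs with ≥ `min_sites`
(default 6, i.e. "> 5") members become regions.  `max_gap` (default
5 kb) is a pipeline parameter, reported in output headers, not a value
taken from any publication.  The dominant direction is the majority Δβ
sign, ties broken by the summed Δβ.  Cross-cohort concordance matches each
site of one cohort to its nearest significant site of the other on the same
chromosome within `max_distance` (ties to the smaller position);
`max_distance=0` gives the exact-shared-site mode and 1000 the
1-kb-proximal mode — both are provided because both conventions are in use.

## Regulatory landscape and features

Within marked genomic space the precedence is: H3K4me3 ⇒ promoter;
H3K4me1 ∧ H3K27ac (no H3K4me3) ⇒ active enhancer; H3K4me1 alone ⇒ poised
enhancer.  Peak files are merged per mark (bookended intervals joined)
before classification.  The four-way genomic feature of a CpG is promoter
(H3K4me3 overlap **or** strand-aware TSS proximity, default window
TSS−2000/+500 — the union is used because the available descriptions
support either reading, and the choice is flagged in output) > enhancer
(active or poised) > body (inside a gene span) > intergenic.  Enrichment of
a differential set over its background is fold change of feature fractions
with a two-sided hypergeometric test (the original analysis names no test;
hypergeometric is the natural finite-population choice).

## Extreme-phenotype selection

Band membership uses the LTS *group mean* (not per-sample extremes):
fully-unmethylated sites have LTS mean β ∈ [0, 0.1] and Δβ ≥ +0.1;
fully-methylated sites have LTS mean β ∈ [0.9, 1] and Δβ ≤ −0.1.  Band
edges are inclusive and guarded by a 1e-9 epsilon against float
subtraction artifacts.  No significance test applies at this stage;
significance enters later through survival association.  Against a
normal-tissue baseline (mean over the normal samples), a
fully-unmethylated-set site whose normal mean is within the low band is a
de novo gain; a fully-methylated-set site whose normal mean is within the
high band is a shared loss; sites missing from the normal matrix are
reported as uncovered, mirroring the coverage attrition seen between tumor
and normal sequencing runs.

## SSIGN scoring and survivor groups

The default point table — pT1=0, pT2=1, pT3a–pT4=2; pNx/pN0=0, pN1/pN2=2;
pM0=0, pM1=4; size <5 cm=0, ≥5 cm=2; grade 1–2=0, grade 3=1, grade 4=3;
necrosis=2 — is configurable; it is the assignment consistent with the
published cohort compositions (the primary source's point table for pT3
sub-stages is not reprinted there).  Strict survivor criteria: STS = died
of disease in < 6 y (scores 0–1) or < 3.2 y (scores 2–3); LTS = alive
> 10 y (0–1) or > 6.9 y (2–3).  Relaxed criteria: death < 7.5 / < 4.5 y
and survival > 8.5 / > 5.5 y for the same strata.  Scores above 3 are
always excluded by study design.  Patients dying of other causes are
censored at death and can qualify as LTS only when the censoring time
exceeds the alive cutoff — the sources are silent here; this is the
package's decision and is visible per sample in the labeled output.

Cohort comparison: continuous variables by Wilcoxon rank-sum; categorical
by Pearson χ² without correction (default), Yates-corrected χ² (2×2 only;
multi-level Yates requests fall back to Pearson with a note, since the
correction is not unambiguously defined there), or two-sided Fisher exact.
Multi-level χ² keeps every *declared* level in the degrees of freedom
(df = levels − 1 for two groups) while zero-expected cells contribute
nothing to the statistic — the convention under which the published grade
comparison (p = 0.962) reproduces.

## Phyloepigenetic analysis

Sample distances are Euclidean over a declared CpG set with
pairwise-complete missing handling, rescaled by (declared set size /
complete sites) inside the square root so sparsely covered samples are not
artificially close; the rescaling is recorded in output metadata.  Trees
are neighbor joining (scikit-bio's implementation; negative branch lengths
clamped to zero with the deficit moved to the sibling branch) — the
standard method for distance-based sample trees; a hierarchical-clustering
dendrogram can be produced through the stratification stage instead.
Within-group distance lists (n(n−1)/2 per group) are compared by rank-sum;
that p-value is descriptive because pairwise distances are not independent.

## Survival, expression, and score screens

Survival association dichotomizes each CpG at its median beta — samples at
exactly the median go to the low arm, deterministically — then applies a
two-sided log-rank test and a Cox proportional-hazards fit (tiny ridge
penalty 1e-6 for stability on small arms) for the high-arm hazard ratio.
HR > 1 means hypermethylation is unfavorable, so the favorable state is
"hypo".  Expression uses Pearson correlation (the stated choice for
methylation–expression); the SSIGN score screen uses Spearman with midrank
ties since the score is ordinal.  Raw p cutoffs (0.05 / 0.01) match the
screening design; BH columns accompany all screens.

## Panel selection

Greedy forward search: at step k every unchosen candidate is evaluated by
fitting a CART classifier (Gini impurity, max depth k, min leaf size 2,
fixed random state) on the chosen sites plus the candidate and scoring the
AUROC of its class probabilities; the best candidate joins the panel, ties
broken toward the larger between-class |Δβ| and then genomic order, so
selection is deterministic.  The search stops when AUROC reaches 1 or at
`max_k` (default 10).  AUROC is the Mann–Whitney probability that a random
positive outranks a random negative with ties counted ½.

Resubstitution AUROC is the default mode because that is the figure the
original small-cohort analysis reports; it is optimistic, and the package
makes the caveat measurable: `mode="loo"` scores leave-one-out predictions
instead, and on label-free noise the LOO AUROC sits near 0.5 while
resubstitution inflates (this contrast is asserted in the test suite).
Candidates constant across samples are skipped with a note; the classifier
mean-imputes missing betas per site (screens never do).

All-comer stratification clusters samples by Ward-linkage agglomerative
clustering on panel-site betas, cut at k = 3 (configurable), clusters
ordered by ascending mean beta so labels read hypo / intermediate / hyper;
SSIGN scores across clusters are compared by Kruskal–Wallis, and an
optional binary stage grouping (I/II vs III/IV) is tested against the
clusters by Pearson χ².

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not real genomes.  Defaults are the study conditions of the discovery
design: 22 LTS vs 14 STS, mean coverage 30×, 77 % of planted effects
hypermethylated in STS, exponential survival with group medians 9.5 y
(LTS) and 2.5 y (STS) under 25-y administrative censoring, and a desk-scale
5000 CpGs.

* **Baseline methylation**: per-site π from a three-component mixture,
  weights 0.45/0.10/0.45 for Beta(2,18) / Beta(5,5) / Beta(18,2) — the
  bimodal landscape in which most CpGs sit near 0 or 1.
* **Coverage**: negative binomial (size = `coverage_dispersion`, default 5;
  heavy-tailed like real RRBS depth), floored at 1 read.
* **Counts**: beta-binomial — a per-sample/site methylation probability
  from Beta(μs, (1−μ)s) with concentration s = `methylation_precision`
  (default 30; the per-group beta variance is not specified anywhere, so it
  is an explicit knob rather than an assertion), then binomial methylated
  counts.
* **Planted effects**: the STS group mean is shifted ±`effect_delta` on the
  probability scale.  Sites are drawn preferentially where the full shift
  fits inside [0,1], keeping the planted |Δβ| directly interpretable
  against the 0.1 cutoff; clipping remains the fallback when a
  configuration leaves too few feasible sites, and a site whose shift fully
  clips away is excluded from the truth table.
* **Pathology**: covariate combinations drawn per group from the published
  SSIGN score distributions, constructed so every sample scores 0–3.
* **Expression**: planted CpG–gene pairs with signed linear coupling plus
  Gaussian noise; all other genes are noise.
* **Normal tissue**: companion samples drawn around the baseline π with the
  same coverage model and a site-subsampling rate (default 0.8) emulating
  tumor/normal coverage attrition.

One integer seed drives everything; every quantity draws from its own named
substream (`default_rng([seed, stream_id])`), so adding a field never
shifts other draws and identical config + seed is bitwise identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (bisulfite conversion error,
mapping bias), hydroxymethylation, spatial correlation of methylation along
the genome (sites are exchangeable given their baseline class, so region
calling is exercised on constructed inputs, not on emergent clustered
signal), realistic linkage between pathology and methylation, and
per-cohort sequencing-depth differences beyond the single coverage knob.

## Numerical choices and degenerate inputs

Inclusive thresholds throughout ("at least", "or more"); float-sensitive
band edges carry a 1e-9 epsilon.  Empty cohorts round-trip as valid empty
files.  Fully tied rank-sum inputs return p = 1.  χ² on empty tables
returns p = 1 with df 0.  Constant screening vectors are flagged, not
dropped silently.  Pipeline runs write to fresh directories and never
overwrite earlier outputs; reports contain no wall-clock content, so a
fixed seed and config reproduce the report byte-for-byte.

## Problem sizes

The test suite and the acceptance script run cohorts of 200–5000 CpGs and
20–40 samples; these sizes give the calibration checks (binomial 3-SD
bands, ≥ 80 % recovery, HR within 15 %) comfortable resolution while the
whole suite completes in well under a minute of compute.

## Known limitations

The beta-value t test is a deliberate re-implementation of the original
design, not a counts-aware model (beta-binomial regression and smoothed DMR
callers are out of scope).  Resubstitution AUROC on small cohorts
overstates generalization — use `mode="loo"`.  The SSIGN point table's pT3
sub-stage values are a reconstruction consistent with published summaries;
users with the primary scoring reference should verify before clinical
interpretation.  The strand-merge option assumes simple pos/pos+1 pairing
and does not chain.
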