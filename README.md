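# methylpipe

DNA-methylation stratification of **low-risk clear cell renal cell carcinoma
(ccRCC)** survivor groups from reduced representation bisulfite sequencing
(RRBS) data.

Patients whose tumors score 0–3 on the Mayo SSIGN algorithm (Stage, SIze,
Grade, Necrosis) have a favorable prognosis, yet a substantial minority
recur and die early.  This package implements, as a tested and reusable
pipeline, an analysis that separates these **short-term survivors (STS)**
from **long-term survivors (LTS)** by their tumor methylomes:

1. **Ingestion & filtering** — per-sample bismark-style coverage files are
   assembled into a sites × samples matrix of beta values
   (β = methylated reads / total reads) and filtered to autosomal CpGs with
   ≥ 5× coverage in ≥ 90 % of samples.
2. **Differential methylation** — a global per-sample comparison (Wilcoxon
   rank-sum on mean β), then per-CpG two-sided t tests with the dual cutoff
   *p* < 0.01 **and** |Δβ<sub>(STS−LTS)</sub>| ≥ 0.1; significant runs of
   CpGs (> 5 within a locus) are chained into differentially methylated
   regions, and cross-cohort sign concordance is quantified.
3. **Regulatory annotation** — histone-mark peaks (H3K4me3, H3K4me1,
   H3K27ac) define promoters, active enhancers and poised enhancers; each
   CpG gets one of four genomic features (promoter > enhancer > body >
   intergenic) and differential sites are tested for feature enrichment
   (hypergeometric).
4. **Extreme-phenotype CpGs** — sites essentially unmethylated in LTS
   (mean β ∈ [0, 0.1]) that gain ≥ 10 % methylation in STS, and fully
   methylated sites (β ∈ [0.9, 1]) that lose ≥ 10 %, compared against a
   normal-kidney baseline to label de novo gains.
5. **Clinical scoring** — SSIGN point sums, score-stratified survival
   inclusion criteria (strict and relaxed variants) assigning STS / LTS /
   excluded, and Table-1-style cohort comparison statistics (Wilcoxon,
   Pearson/Yates χ², Fisher).
6. **Phyloepigenetic analysis** — pairwise-complete Euclidean distances
   over a CpG set, neighbor-joining trees, and intra-group distance
   comparisons.
7. **Panel selection** — per-CpG survival association (median split,
   log-rank + Cox HR), methylation–expression Pearson correlation,
   Spearman correlation with SSIGN score, and greedy **stepwise recursive
   partitioning** (CART) that accumulates CpGs until the resubstitution
   AUROC reaches 1.0; Ward clustering stratifies all-comer cohorts.

A first-class synthetic-cohort generator (`methylpipe.simulate`) emulates
the statistical structure this analysis assumes — bimodal per-CpG baseline
methylation, beta-binomial counts at RRBS-like overdispersed coverage,
planted group effects, methylation-linked survival, SSIGN-consistent
pathology, and methylation-correlated expression — so every stage is
testable without any data download.

## Worked example

```python
import methylpipe as mp

cfg = mp.SimulationConfig(n_sites=2000, frac_dm=0.05, effect_delta=0.15, seed=7)
cohort = mp.generate_cohort(cfg)
groups = cohort.samples.set_index("sample_id")["group"]

res = mp.global_methylation_test(cohort.methylation, groups)
print(f"global methylation: median beta LTS={res.median_lts:.3f} "
      f"STS={res.median_sts:.3f} ({res.direction}), Wilcoxon p={res.p_value:.2g}")

dm, _ = mp.test_dmcpgs(cohort.methylation, groups, p_cutoff=0.01, delta_cutoff=0.1)
sig = dm[dm["significant"]]
print(f"DMCpGs: {len(sig)} of {len(dm)} tested "
      f"({(sig['direction'] == 'hyper').sum()} hyper / "
      f"{(sig['direction'] == 'hypo').sum()} hypo in STS)")

truth = cohort.truth_dm_sites.index
print(f"planted sites recovered: {truth.isin(sig.index).mean():.1%} of {len(truth)}")

d = mp.euclidean_distances(cohort.methylation, sig.index)
dists, p = mp.intra_group_distances(d, groups)
print(f"intra-group connections: LTS={len(dists['LTS'])} STS={len(dists['STS'])}, "
      f"Wilcoxon p={p:.2g}")

model = mp.stepwise_panel_selection(cohort.methylation.beta, groups, list(sig.index))
print(f"panel: {model.ordered_sites}, AUROC trace = {model.cumulative_auc}")
```

prints:

```text
global methylation: median beta LTS=0.510 STS=0.514 (hyper), Wilcoxon p=5.5e-06
DMCpGs: 95 of 1999 tested (72 hyper / 23 hypo in STS)
planted sites recovered: 92.0% of 100
intra-group connections: LTS=231 STS=91, Wilcoxon p=1.1e-43
panel: ['chr4:472272'], AUROC trace = [1.0]
```

Reading the output: the 22-vs-14 cohort carries a planted hypermethylation
skew, so the STS group's per-sample mean β is slightly but systematically
higher; 95 CpGs pass the dual cutoff, dominated by hypermethylation (72/95)
as the generator planted 77 % of effects upward; the 22 LTS samples
contribute C(22,2) = 231 within-group distances and the 14 STS samples
C(14,2) = 91; on this clean synthetic cohort a single strongly separating
CpG already yields a resubstitution AUROC of 1.0 (resubstitution on small
cohorts is optimistic — a leave-one-out mode is available, see
`docs/methods.md`).

The full stage sequence, with every intermediate artifact written to a run
directory, is one call (or `methylpipe run` on the command line):

```python
report = mp.run_discovery(mp.PipelineConfig(seed=7))
```

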