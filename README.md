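# sexmeta

Sex-stratified cross-study meta-analysis of case/control transcriptomics
data, built for the setting where disease-associated expression changes
differ between males and females — e.g. post-mortem *substantia nigra*
cohorts in Parkinson's disease, where male and female patients show
partly distinct molecular alterations.

The package takes a collection of independent cohorts (log-scale
expression matrices plus clinical annotations), analyzes each sex
separately, integrates the per-cohort statistics into per-sex
cross-study records, and classifies genes as **female-specific**,
**male-specific**, **candidate sex-dimorphic** (opposite direction of
change in the two sexes), or **shared**.  Downstream modules provide
Fisher over-representation analysis of the resulting gene lists and a
permutation-standardized transcription-factor regulon activity score.
A bundled synthetic multi-cohort generator with planted effect classes
makes the entire pipeline testable end to end without any data
download.

## Method

**Per-cohort differential expression.**  For each cohort *d* and sex
*s*, gene-wise linear models `expression ~ condition (+ age + batch +
subject)` are fit on the samples of that sex only, yielding a log2 fold
change (patients minus controls), a two-sided p-value and the mean
expression per gene.  Optional empirical-Bayes variance moderation is
available for small cohorts.

**Weighted integration.**  Cohorts are weighted by their effective
sample size for the sex,

    w_{d,s} = sqrt( n_{d,s} / sum_delta n_{delta,s} ),
    n_{d,s} = min(|patients_{d,s}|, |controls_{d,s}|),

so that the squared weights sum to one.  Per gene, a consensus
direction of change is chosen by a weighted vote over the per-cohort
LFC signs; the p-values of the direction-consistent cohorts are then
combined by the weighted inverse-normal (Stouffer) statistic

    S = sum_d w_d * Phi^{-1}(1 - p_d) / sqrt(sum_d w_d^2),

reported as the upper normal tail of *S*.  Each gene also carries a
cross-study LFC (weighted mean over consistent cohorts), a
**consistency score** (weighted fraction of measuring cohorts that
agree with the consensus; genes need >= 60% for a significance claim)
and a **reliability score** (weighted fraction of cohorts measuring the
gene at all; genes below 2/3 are excluded).  False-discovery rates are
Benjamini–Hochberg, adjusted once over the pooled male + female
p-values.

**Sex-specificity classification.**  Because the male and female
analyses differ in detection power, sexes are compared on *ranks*
rather than raw significance.  Per sex, each gene gets a pi-value
`pi = -log10(p) * |LFC|` (with `p - eps` substituted at `p = 1`), and
the specificity index is the difference of rank ratios

    Spe_g = rank_ratio(pi_F,g) - rank_ratio(pi_M,g),

with rank 1 = strongest signal.  A gene is *female-specific* if it is a
female DEG (FDR < 0.05, consistency >= 0.6) and `Spe < -tau` (default
tau = 0.2), i.e. the male analysis is not approaching significance;
*male-specific* symmetrically; *candidate sex-dimorphic* if the two
sexes' LFCs have opposite signs with |LFC| >= 0.25 in both and at least
one sex significant; *shared* if significant in both sexes with equal
sign.

## Worked example

```python
import sexmeta as sm

# six synthetic cohorts, 40 samples per sex x condition cell, noise SD 0.5,
# 50 planted genes in each of four effect classes (|log2 effect| = 1)
config = sm.recovery_config(seed=1)
datasets, truth = sm.generate_cohorts(config)

tables = sm.run_sex_meta_analysis(datasets)          # DE + integration + pooled FDR
classified = sm.classify_genes(tables["F"], tables["M"])
print(classified["label"].value_counts().to_string())

labels = classified["label"].reindex(truth.genes).fillna("unclassified")
confusion, summary = sm.truth_confusion(labels, truth)
print(summary.round(3).to_string())
```

prints

```
label
unclassified           1009
shared                   51
candidate_dimorphic      50
female_specific          45
male_specific            45

                 n_true  n_predicted  sensitivity    fdr
shared             50.0         51.0         1.00  0.020
female_specific    50.0         45.0         0.84  0.067
male_specific      50.0         45.0         0.84  0.067
dimorphic          50.0         50.0         1.00  0.000
```

All 50 planted dimorphic genes are recovered with no false positives;
84% of the planted sex-specific genes are recovered at a false-discovery
below 7% (the remainder fall short of the rank-ratio margin because the
null sex happens to rank them moderately well).  The same analysis is
available from the shell:

```sh
sexmeta simulate --preset recovery --seed 1 --out cohorts/
sexmeta run-all --cohorts cohorts/ --out run/
cat run/summary.json
```

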