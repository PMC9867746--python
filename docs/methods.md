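# Methods

This note documents the statistical model behind `sexmeta`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Model and assumptions

The pipeline targets collections of independent case/control cohorts
measured on heterogeneous platforms.  Within each cohort the analysis
is sex-stratified: males and females are modelled separately throughout
(patients and controls are compared within each sex), because the two
sexes are often unevenly represented and imperfectly age-matched, and
pooling them into a single interaction model would force a shared
variance structure across strata of very different size.

Assumptions, per cohort:

* expression is on a log2 scale with approximately Gaussian residuals
  after covariate adjustment (microarray intensities, vsn/voom-style
  transformed counts);
* samples are exchangeable within (sex, condition) cells up to the
  modelled covariates (age, batch, subject blocks);
* cohorts are independent of one another (duplicate subjects across
  cohorts must be removed upstream).

Pre-processing (background correction, normalization, outlier removal,
count modelling) is out of scope; the pipeline consumes processed
matrices.

## Per-cohort differential expression

Gene-wise ordinary least squares, `expression ~ condition (+ age +
batch + subject)`, fit on one sex's samples; the condition coefficient
is the log2 fold change and its t-test gives a two-sided p-value.
Covariates: age enters centered and linear; batch and subject enter as
categorical blocking factors.  Subject blocking supports paired
designs; when condition is constant within every subject the design is
singular and the fit refuses (a within-subject correlation model is out
of scope for a generic least-squares engine).

`moderated=True` applies empirical-Bayes variance moderation: per-gene
variances are shrunk toward a scaled-F prior fitted by moment matching
on the log residual variances (digamma/trigamma inversion), and the
t-test gains the prior degrees of freedom.  Default off: at the cohort
sizes of the bundled study conditions moderation is unnecessary, and
the unmoderated test is exactly calibrated.

Genes with zero residual variance get `p = NaN` with a warning (their
LFC is still reported); downstream they are excluded from combination
on a per-cohort basis.

## Cross-study integration

Cohort weights follow the square-root effective-sample-size rule

    w_{d,s} = sqrt(n_{d,s} / sum_delta n_{delta,s}),
    n_{d,s} = min(#patients, #controls)  for sex s,

so sum_d w^2 = 1.  The minimum of the two group sizes reflects that a
cohort's detection power is limited by its smaller group.

Per gene and sex:

1. **Consensus direction** — weighted vote over per-cohort LFC signs;
   zero LFCs vote for neither side.  An exact tie breaks toward "+"
   and is flagged.  The tie-break deliberately consults the *signs
   only*: any magnitude-aware rule (e.g. the sign of the mean LFC)
   selects the stronger-looking side of tied genes into the p-value
   combination and measurably inflates the null (observed ~0.07
   instead of 0.05 at 6 equal-weight cohorts, where 31% of null genes
   tie 3–3).
2. **Combined p** — weighted inverse-normal over the cohorts whose LFC
   sign matches the consensus, renormalized by sqrt(sum w^2) over that
   subset so the statistic is standard normal under the null.
   *Sidedness* is configurable:
   * `two_sided` (default): each consistent cohort contributes
     z = Phi^{-1}(1 - p_two).  Because a cohort's two-sided p is
     independent of its effect sign under the null, conditioning on
     sign agreement leaves the combined statistic exactly N(0, 1) and
     the combined p uniform — the all-null simulation confirms the
     p < 0.05 fraction sits inside the 3-SD binomial band per sex.
   * `one_sided`: each consistent p is halved first.  This makes the
     single-study identity (combined p = p/2) hold, but since cohorts
     are *selected* by sign agreement, summing the resulting
     half-normal quantiles is anti-conservative under the null (~0.5
     of null genes reach p < 0.05 at 6 cohorts); it is retained as an
     option, not a default.
3. **Cross-study LFC** — weighted mean of the consistent LFCs; its
   sign equals the consensus direction by construction.
4. **Consistency score** Cst — weighted fraction of measuring cohorts
   agreeing with the consensus.  A gene needs Cst >= 0.6 in a sex for
   any significance claim in that sex.
5. **Reliability score** R — weighted fraction of all cohorts
   measuring the gene (platform coverage).  Genes with R strictly
   below 2/3 in a sex are removed from that sex's analysis; R = 2/3
   exactly is retained.
6. **FDR** — Benjamini–Hochberg, one pass over the concatenated male +
   female combined p-values, mapped back per sex.  Pooling keeps the
   two sexes' significance claims on a common adjustment scale.

### Male-subsampling robustness

Because male cohorts are typically larger, the male analysis can be
re-run on female-sized male subsamples (per cohort, drawn without
replacement per condition; cohorts with more females than males are
used in full and flagged).  Concordance with the full male analysis is
summarized by sign-agreement rates (all genes, and genes significant in
the full analysis) and the Spearman correlation of cross-study LFCs.

## Sex-specificity classification

Raw FDR values are not comparable across sexes when detection power
differs, so sexes are compared through ranks of the pi-value

    pi_{s,g} = -log10(p_hat_{s,g}) * |LFC_{s,g}|,
    p_hat = p - eps  if p = 1, else p        (eps = 1e-12),

using the *nominal* combined p (FDR only gates significance).  The
epsilon only prevents pi from collapsing to 0 at p = 1, avoiding
spurious rank ties; any value much smaller than 1 behaves identically.
Rank 1 is the largest pi (strongest signal); the rank ratio divides by
the number of ranked genes; ties get average ranks.  Rankings are
computed over the genes that pass the reliability filter in **both**
sexes, so the two sexes' rank ratios refer to the same universe and the
specificity index

    Spe_g = rank_ratio(pi_F,g) - rank_ratio(pi_M,g)  in (-1, 1)

is exactly antisymmetric under swapping the sexes (negative = stronger
in females).

Decision rules, mutually exclusive, with defaults FDR < 0.05,
|LFC| >= 0.25 (inclusive), tau = 0.2:

1. *candidate dimorphic*: opposite LFC signs, both |LFC| >= 0.25, and
   at least one sex a DEG (FDR < 0.05 with Cst >= 0.6 in that sex);
2. *shared*: DEG in both sexes with equal LFC sign (excluded from all
   sex-related lists);
3. *female-specific*: female DEG and Spe < -tau; *male-specific*
   symmetrically (Spe > +tau);
4. otherwise *unclassified* (including genes missing stats or
   reliability in either sex).

The consistency gate belongs to the per-sex significance claim, not to
classification membership: a gene that is genuinely null in one sex
shows an even split of per-cohort signs there (Cst near 0.5) in about a
third of cases, and demanding Cst >= 0.6 in *both* sexes would
therefore disqualify a large share of true sex-specific genes for a
reason that carries no evidence against them.

The margin tau operationalizes "not approaching significance in the
other sex" as a rank-ratio gap.  It trades sensitivity against
specificity: larger tau demands that the other sex's signal rank
clearly in the bulk of its ranking.  With tau = 0.2 the expected
sensitivity for well-separated planted effects is ~0.85 at the bundled
study conditions; the dominant loss mechanism is a truly-null sex
ranking a gene moderately well by chance.

## Enrichment and regulons

*Over-representation*: one-sided hypergeometric tail per gene set, BH
within each collection separately.  The background is the set of genes
passing the reliability filter — not the whole genome — so coverage
differences between platforms do not masquerade as enrichment.  The
reported gene ratio is overlap / (number of list genes annotated by any
set of that collection).

*Regulon activity*: for each TF with at least 5 scored targets, the raw
activity in a sex is the mean over targets of (edge sign x signed
target statistic), where the statistic is sign(LFC) * -log10(p) and
inhibitory edges flip the sign.  The reported activity is the z-score
of the raw value against a permutation null (default 1000 draws of
equally many statistics from the sex's gene universe).  Permutation
index matrices are shared across TFs of equal regulon size and across
sexes, so identical per-sex inputs give exactly identical activities.
This is a deliberately transparent statistic with the same monotone
semantics as regulon-enrichment tools (coherently up-regulated
activating targets => positive activity); it does not reproduce any
external tool's scale.

*Network filter*: activation edges survive iff source and target LFC
signs agree, inhibition edges iff they differ; edges with a missing or
zero LFC at either endpoint are dropped, as are edges reported with
both signs (ambiguous duplicates).

## Probe handling

Multi-gene probes are removed when (a) they map 5 or more genes, (b)
another probe maps a strict subset of their genes, or (c) they partially
overlap another multi-gene probe (shared gene, neither set nested).
All three rules are marked against the same input and removed in one
sweep, which makes the filter idempotent and leaves every surviving
multi-gene probe minimal.  Per gene, dataset and sex context, the probe
with the highest mean expression (pooled over that sex's samples across
the datasets measuring the probe) is selected, with lexicographic
tie-break; genes whose selection differs between the sex contexts in
any dataset are excluded from all reports, since their male and female
statistics would describe different measurements.

## Synthetic cohorts

The generator emulates the structure that drives the integration
statistics: several cohorts with configurable per-(sex, condition)
sample counts, per-gene baselines uniform on log2 [4, 12], additive
per-sex condition effects by planted class (null / shared /
female-specific / male-specific / dimorphic), optional linear age and
two-level batch effects, i.i.d. Gaussian noise, and gene-wise
missingness per cohort (whole genes absent, as with platform coverage —
this is what exercises the reliability score).  One RNG substream per
cohort index is spawned from the master seed, so collections are
bit-reproducible and appending cohorts never perturbs earlier ones.

It does **not** emulate: probe-level artifacts, count-distributed
RNA-seq data, gene–gene correlation, cell-type composition shifts, or
platform-specific mean-variance trends.  Passing tests therefore
demonstrate the correctness and calibration of the statistical
machinery under its stated assumptions, not robustness to those real
data phenomena.

Canonical study conditions used by the tests and the acceptance script:

* **null collection** — 6 cohorts, G = 2000, 20 samples per (sex,
  condition) cell, no effects: verifies per-cohort p uniformity (KS)
  and the binomial calibration of the combined p per sex.
* **recovery collection** — 6 cohorts, 40 samples per cell, noise SD
  0.5, 50 genes per non-null class with |log2 effect| = 1 (dimorphic:
  -1/+1), 10% missing genes per cohort, G = 1200.  The gene universe is
  kept compact so the planted classes occupy a realistic fraction of
  the ranked lists while the run stays desk-scale (a few seconds).
* **study-like collection** — 12 cohorts with heterogeneous,
  male-skewed counts and 0–25% missing genes, mirroring a typical
  multi-repository collection.

## Numerical conventions

* Combined p floored at the smallest positive double; normal quantiles
  clipped to |z| <= 37.5 (beyond which the tail underflows).
* p-values entering Phi^{-1} are clipped into [1e-310, 1].
* Consensus ties break toward "+" and are flagged (`tie` column).
* Probe-selection ties break lexicographically by probe id.
* BH is delegated to `statsmodels.stats.multitest.multipletests`.
* Degenerate inputs: genes whose consistent cohorts all lack p-values
  are dropped with a warning; empty DEG lists yield all-1 enrichment
  p-values with a warning.

## Limitations

* Fixed-effects combination only; no between-cohort heterogeneity
  model (no random effects, I2 or Q).
* The generic linear-model DE engine does not reproduce any specific
  published package's moderation or trend details.
* The rank-ratio margin tau is a declared operationalization of "not
  approaching significance"; results for borderline genes depend on it
  and it is surfaced in the configuration and the output.
* The regulon activity score shares semantics but not scale with
  external regulon-inference software.
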