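# Methods

## Differential expression

Counts are normalised to counts per million (CPM) within each sample.
The fold change of a feature is

    FC = (mean case CPM + c) / (mean control CPM + c)

with pseudocount c = 1 (configurable); the pseudocount keeps
zero-expression features finite, at FC = 1. Significance comes from a
two-sided Welch t-test on log2(CPM + 1). Calls follow the screening
convention of small-cohort EV transcriptomics studies: *up* requires
FC strictly above 1.4 and p ≤ 0.05 (inclusive), *down* requires FC
strictly below 0.7 and p ≤ 0.05, everything else is *ns*. The p-values
are raw by default — matching the single-test convention such screens
use — with an optional Benjamini–Hochberg switch (`bh_correction`).

The Welch test is a deliberately transparent substitute for count-model
engines (edgeR-style negative-binomial fits): the classification
contract is "thresholds plus a p-value source", and the p-value source
is pluggable. On log-scale data with n = 5 per group the Welch p agrees
with the exact 252-split permutation distribution to within a few
hundredths in the decision region (verified in the test suite); it does
not model count overdispersion, so very-low-count features are noisier
than a negative-binomial treatment would make them.

Degenerate features (zero within-group variance in both groups) get
p = 1 when the group means are equal and p = 0 otherwise.

Summary percentages are 100·n/n_annotated rounded **half-up** to one
decimal. Half-up is the convention a reader applies to printed tables;
note that published tables are not always internally consistent at the
last digit, and this package makes no attempt to reproduce any one
table's rounding quirks.

## Triplet screen

Candidates are all (lncRNA, miRNA, mRNA) triplets such that the
(miRNA, mRNA) pair appears in the mRNA interaction table, the
(miRNA, lncRNA) pair appears in the lncRNA interaction table, and all
three members are differentially expressed. DE *direction* is not a
screen criterion: the expected pattern (miRNA up, partners down) is an
emergent property of sponge regulation and is observed, not enforced.

Each candidate is tested with three correlations computed over **all
samples pooled** (both groups): lncRNA–mRNA must satisfy r > 0.3 with
p < 0.05 (both strict), and each miRNA–partner pair must satisfy
r < −0.3 with p < 0.05. Pooling is deliberate: with n = 5 per group a
within-group correlation would need |r| > 0.878 to reach p < 0.05, so
group-wise screening at these thresholds would be near-vacuous; pooled
correlations capture the case/control axis plus within-group
covariation, which is exactly the signal a sponge mechanism produces.
A `per_group` flag additionally requires the criteria within each group
for users with larger cohorts.

Pearson (product-moment) correlation on log2(CPM+1) is the default;
the p-value is the two-sided tail of t = r·√((n−2)/(1−r²)) with n−2
degrees of freedom, with the limit convention p = 0 at |r| = 1.
Spearman (the same computation on average ranks) is selectable for
heavy-tailed data. Zero-variance features cannot be correlated; the
affected candidate is excluded and logged rather than failing the run.
No multiple-testing correction is applied across the correlation tests
by default (the thresholds are interpreted as per-test screening rules);
a BH switch spanning all 3·k tests is available.

An optional pre-filter (`top_k_mirna`) restricts candidates to the k
miRNAs with the most distinct DE-lncRNA partners (ties broken
lexicographically); it is off by default because no principled default
k exists.

## Network

Passed triplets are merged into a typed graph: sponge edges
lncRNA→miRNA and target edges miRNA→mRNA, deduplicated. Node attributes
are RNA kind and DE direction; hub ranking sorts nodes of one kind by
degree (incident edge count), ties lexicographic. Exports — SIF,
GraphML, attribute TSV — are deterministic: edges in lexicographic
(source, target) order, nodes sorted by id, so identical networks give
byte-identical files and diffs are meaningful.

## Synthetic data generator

The generator emulates a small two-group circulating-EV study. For each
planted triplet *t* and sample *s* a latent miRNA activity

    a_ts ~ Normal(mu_group, 1),   mu_case = mu_control + group_shift

drives the three planted log-expressions (natural log):

    miRNA :  baseline + a_ts + eps
    mRNA  :  baseline − beta_mrna · a_ts + eps
    lncRNA:  baseline − beta_lncrna · a_ts + eps

with eps ~ Normal(0, noise_sd) and per-feature baselines from
Normal(baseline_log_mean, baseline_log_sd). Non-planted features are
independent log-normal noise with no group effect. Each layer's
log-expressions are exponentiated, scaled to an expected `library_size`
per sample, and Poisson-sampled into counts. One mechanism (the shifted
latent activity) therefore produces both the DE pattern (miRNA up,
partners down) and the correlation signature the screen tests for.
Interaction tables contain every planted (miRNA, mRNA) and
(miRNA, lncRNA) pair plus `decoy_interactions` unique non-planted
pairs, split evenly between the two tables. All randomness flows from
one seeded generator; identical parameters give bit-identical output.

Defaults: 5 samples per group, 20 planted triplets,
beta_mrna = beta_lncrna = 1.5, group_shift = 2 (natural-log scale, i.e.
~e² ≈ 7.4-fold latent enrichment), noise_sd = 0.3, baseline log-mean 4
(sd 1), library size 10⁶, 200 decoys. Feature universes default to
2,000 lncRNAs / 1,500 miRNAs / 8,000 mRNAs — the relative sizes of
annotated universes in human EV transcriptomics, with miRNA at full
scale and the other layers scaled down to keep a full run around a
hundred milliseconds. The miRNA universe size matters beyond realism:
planted miRNAs are strongly enriched in cases, and in a small universe
they dominate the case libraries so that CPM renormalisation drags
every other miRNA's fold change down (a compositional artifact);
at ~1,500 features the planted mass stays a modest fraction of the
library.

What the generator does **not** emulate: count overdispersion beyond
Poisson (no negative-binomial dispersion), batch or library-preparation
effects, shared miRNAs across triplets, correlated decoys, or any
clinical covariate structure. Passing tests on this generator therefore
demonstrate the pipeline's logic and statistics, not robustness to
real-data artifacts such as overdispersion-driven false positives.

## Recovery characteristics and a known power ceiling

Under the default simulation the screen recovers planted triplets with
mean precision ≈ 1.0 over seeds. Mean recall sits near 0.6, and this is
a property of the *design being simulated*, not of the implementation:
with per-sample latent sd fixed at 1 and group_shift = 2 the
per-feature effect size is d ≈ 2, for which a 5-vs-5 Welch test at
α = 0.05 has power ≈ 0.72–0.79; a triplet is recalled only if **all
three** members are called DE, and Monte-Carlo on the noiseless latent
model puts that joint probability at ≈ 0.66. The correlation stage
loses essentially nothing (measured 0 over 10 seeds). Recall losses are
therefore concentrated entirely in the DE stage and shrink only with
larger cohorts or stronger shifts.

## Numerical and interface choices

- Percent rounding: decimal half-up at one decimal (floating-point-safe
  via exact decimal division).
- Correlation: computed from centred sums; |r| clipped to [−1, 1];
  |r| ≥ 1 − 1e−14 treated as exact for the p = 0 convention.
- Hypergeometric tail: `scipy`'s log-space survival function,
  P[X ≥ k] = sf(k − 1); exact to 1e−12 against enumeration for N ≤ 12.
- Welch on degenerate (constant) features: handled explicitly rather
  than propagating NaN.
- Group labels are fixed to the {Lean, MetS} vocabulary internally;
  readers accept an alias map for other studies.
- Interaction tables deduplicate on (miRNA, target), first source kept;
  conflicting target kinds for one id are an input error, not a merge.
- Thresholds are strict exactly where stated (FC bounds, correlation r
  and p) and inclusive for the DE alpha — the two stages deliberately
  use different p conventions (≤ vs <) to match screening practice.

## Limitations

The DE engine is a t-test, not a count model; the screen inherits the
usual caveats of correlation-based ceRNA inference (pooled correlations
conflate group and within-group signal; no MRE-level sequence evidence);
interaction tables are taken as given, so database coverage and bias
propagate directly into the candidate set.
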