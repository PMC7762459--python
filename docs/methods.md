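# Methods

This note records the models implemented in `omicdriver`, the choices
made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Module network

The analytic core is a two-level model of tumor expression. Genes are
partitioned into co-expression modules; within a module, tumor samples
are partitioned into blocks of similar expression; and candidate
regulators are scored by how well their molecular profiles predict the
sample partition.

**Scoring.** A configuration is scored by the product over
(module, sample-block) cells of the Normal–Gamma marginal likelihood of
the cell's values: each cell is modeled as i.i.d. Normal with unknown
mean and precision integrated against a conjugate Normal–Gamma prior
(μ₀ = 0, λ₀ = 0.1, α₀ = 0.1, β₀ = 0.1). These are standard weakly
informative conjugate choices for row-standardized data (mean 0, SD 1);
μ₀ must be 0 for standardized rows, and the sampler enforces this. The
score is exchangeable within cells, which the tests exploit.

**Sampling.** Each sweep resamples every gene's module assignment, then
every sample's block within every module, each proportional to
exp(Δ log score) times a Chinese-restaurant prior (concentration 1.0 for
both levels), so module and block counts adapt to the data rather than
being fixed. Per chain the best-scoring sweep is reported and the
per-sweep log-score trace retained. Defaults: 10 chains × 100 sweeps;
chains are independently seeded from one seed sequence, making every run
bit-reproducible. The sweep kernel is compiled with numba; a plain-numpy
scorer (`partition_log_score`) provides the reference path that the
enumeration oracle test checks against.

**Consensus.** Genes whose co-clustering frequency across the chains'
best sweeps reaches 0.8 are linked; connected components with ≥ 5 genes
become consensus modules, all other genes stay unassigned (module 0).
This mirrors the "tight cluster" idea: only structure stable across
chains survives.

**Regulation programs.** Each consensus module's mean profile over tumor
samples is recursively bisected (depth ≤ 3, leaves ≥ 5 samples) at the
exact 1-D two-means cut (prefix-sum search over the sorted values;
boundary ties broken at the first optimal cut). Regulator profiles never
define the splits — splits come from the module mean alone — which
prevents a regulator from generating the partition it is then scored
against. At each internal node every regulator receives
score = 2σ(z) − 1 with z = |mean difference| / pooled SD between the two
child sample blocks; this "fuzzy" (graded) assignment maps z = 0
(constant profile) to exactly 0 and strong separation toward 1.
Significance is an empirical p-value against 100 random relabelings of
the node's samples into blocks of the same sizes (with the +1
correction, so the smallest attainable p is 1/101).

**Driver selection.** score(r, m) sums node weight (fraction of module
samples at the node) × node score over nodes where r's empirical
p ≤ 0.05. Drivers are the union of (a) per module, the top
⌈0.01 R⌉ regulators by score(·, m), and (b) the top ⌈0.1 R⌉ by summed
score, R the number of candidates; ceilings keep small candidate sets
selecting at least one, and boundary ties are all included. Zero-score
regulators are never selected by either rule: a "driver" that regulates
no module is a contradiction, and at score 0 the boundary-tie rule would
otherwise admit the entire candidate list.

## Candidate regulators

Per platform: mutation candidates by recurrence (≥ 2% of tumors, or a
user-supplied significance list — covariate-aware background models are
out of scope); CNV amplification/deletion candidates by state frequency
(state ≥ +1 / ≤ −1 in ≥ 10% of tumors, rules applied independently);
methylation candidates by a BIC-selected 1–3 component Gaussian mixture
on tumor beta values (a component with weight ≥ 0.1 whose mean deviates
from the normal mean by ≥ 0.1) that must also be transcriptionally
predictive (negative Spearman beta–expression correlation at BH
q < 0.05); miRNA candidates by significantly negative Spearman
correlation with annotated targets (BH q < 0.05); TF and
literature-curated genes enter by list membership with their expression
rows as profiles. All FDR control routes through one shared
Benjamini–Hochberg implementation. Welch's unequal-variance *t* is used
for differential expression; genes with zero variance in both groups are
flagged degenerate with p = 1.

## COCA subtyping

Level one: each platform's driver-feature matrix is clustered 100 times
on 80% sample subsamples (NMF with nndsvd initialization for
non-negative matrices, k-means on standardized features otherwise); the
consensus matrix holds co-clustering frequencies among co-sampled pairs;
k ∈ 2..6 is chosen by the cophenetic correlation between 1 − consensus
and its average-linkage dendrogram, and labels come from the dendrogram
cut. Level two: the one-hot matrix of per-platform memberships (samples
missing a platform get an all-zero block) is consensus clustered the
same way; k ∈ 2..8 is the largest whose relative delta-area of the
consensus CDF exceeds 0.025 — the convention of the consensus-clustering
literature. The construction sorts platforms by name, making the result
invariant to platform order and within-platform label permutation.

Survival: Kaplan–Meier estimation and the k-sample log-rank test
delegate to lifelines (verified against R `survival::survdiff` to seven
digits). Note the log-rank chi-square approximation is mildly
anticonservative at moderate sizes: at n = 50 per group with exponential
times its true level is ≈ 0.054 at nominal 0.05 (measured at 10,000
replicates). Clinical association uses Fisher's exact test for
categorical variables (exact 2×2; Monte-Carlo over fixed-margin tables
otherwise) and one-way ANOVA for continuous ones, BH-adjusted.

## Enhancer and chromatin analysis

All interval logic is 0-based half-open on fixed 50-bp windows. Quantile
normalization replaces each track's values by the mean order statistic
at the matching rank (average ranks for ties), making the sorted vectors
of all tracks identical. "Mark present" defaults to the top quartile of
a track's nonzero values (scale-free; an absolute threshold is
configurable). Strong enhancer = both H3K4me1 and H3K27ac marks outside
promoters; weak = H3K4me1 only. Differential status per window:
gain if (tumor + ε)/(normal + ε) ≥ 2 with ε = 1, loss symmetrically,
inclusive at the boundary; adjacent same-label windows merge into
regions. Promoters default to TSS ± 2 kb when no external promoter set
is supplied. Regulatory domains follow the basal-plus-extension rule:
basal 5 kb upstream / 1 kb downstream of the TSS (strand-oriented),
extended outward from the basal edges by up to 20 kb per side but
clipped at the nearest neighboring gene's basal domain and at
coordinate 0; region–gene association requires ≥ 1 bp overlap with the
extended domain. Driver-expression explanation is a rule table:
down-regulation is genome-explained by mutation, hypermethylation or
deletion and enhancer-explained by domain enhancer loss; up-regulation
by mutation or amplification, and by enhancer gain; the two categories
are reported separately along with their overlap.

## Downstream statistics

ssGSEA ranks a sample's genes by expression (ties broken by gene name
for determinism) and integrates a weighted running sum: in-set genes add
|x|^w normalized over the set (w = 0.75, the cited method family's
convention), out-of-set genes subtract 1/(N − n_set); the enrichment
score is the sum of the running sum over all positions. Weights use the
expression values themselves, so at w = 0 the score is rank-only and
invariant to monotone transforms, while at w > 0 it is not. E2F/TP53
subgrouping standardizes the E2F1 and E2F2 rows, averages them, splits
at the cohort median and crosses with TP53 mutation status. Mutual
exclusivity tests the observed co-occurrence count against
Binomial(n, f_A f_B) — the product-of-marginals null — one-sided toward
fewer co-occurrences; a margin-conditioned permutation alternative is
available behind a flag. Over-representation is the one-sided
hypergeometric upper tail with BH adjustment. Wilcoxon rank-sum tests
use the exact distribution when both groups have ≤ 8 untied values.

## Synthetic cohorts

`generate_cohort` emulates a tumor/normal multi-omics study. Expression
is log2-scale: gene g in sample j follows
baseline_g + effect × Σ_r a_r(j) + N(0, noise_sd), where the planted
regulators r of g's module have signed activations a_r ∈ {−1, 0, +1}
over tumors and 0 in normals. Each module carries one program direction:
all its regulators push it the same way, realized per platform as
mutation (binary indicator in 30% of tumors), CNV (state ±2 in 30%,
dosage reflected in the regulator's own expression), methylation
(hypermethylation 0.2 → 0.8 silencing a down-module, or methylation loss
0.8 → 0.2 activating an up-module, always with the regulator's own
transcript following so the alteration is transcriptionally predictive),
miRNA (repressor gained in 40% of tumors for down-modules, lost for
up-modules, with planted target annotations plus decoys), or TF
expression (own transcript shifted in 40% of tumors). The stated
platform mix is realized exactly over the planted regulators
(largest-remainder quotas, randomly permuted). Background realism:
1% per-gene-per-tumor mutation noise, ±1 CNV states in 3% of tumors,
logit-normal beta values around 0.2, decoy TF/literature entries.
Methylation is generated on the logit scale and inverse-transformed, so
beta never leaves (0, 1). Survival times are exponential with
per-subtype rate baseline × HR; a Bernoulli(censor_rate) coin censors a
subject uniformly before its event — a simple random-censoring scheme
that keeps the expected censoring fraction exact and the log-rank null
intact. One global seed spawns an independent stream per generation
stage, so stages can be regenerated independently and every output is
bit-reproducible.

Signal tracks share a log-normal baseline (median 10, σ = 0.5) between
tumor and normal; gains multiply the tumor by the fold, losses divide,
and each track gets independent multiplicative log-normal noise of the
stated coefficient of variation. Gains and losses are planted only on
windows whose baseline is at least half the track median: a "lost
enhancer" at near-zero signal is not an enhancer, and the pseudocount of
the fold-change call deliberately damps such windows.

What the generator does *not* emulate: real marginal distributions,
cohort sizes, mutation spectra, batch effects, probe-level methylation
structure, linked alterations between platforms, or read-level ChIP-seq
noise. Passing the planted-truth benchmarks therefore demonstrates the
machinery's correctness and its behaviour under the stated
signal-to-noise regimes, not performance on any real cohort.

## Benchmark study conditions

The acceptance benchmarks fix the following problem sizes (chosen to
exercise the full pipeline within desk-scale runtimes):

- module recovery: 200 genes, 5 modules × 30 genes, 60 tumors /
  30 normals, effect 2, noise 1; 10 chains × 100 sweeps; 10 cohorts.
- driver recovery: 200 genes, 8 modules × 20 genes, one planted
  regulator per module, mix balanced over mutation/CNV/methylation/miRNA,
  effect 2, noise 1; 10 cohorts; single-platform comparison runs reuse
  the same candidates and seeds. One regulator per module reflects the
  selection rule's behaviour at desk-scale candidate pools, where the
  per-module top-1% quantile admits exactly ⌈0.01 R⌉ = 1 regulator per
  module (at cohort-scale pools of thousands of candidates the same rule
  admits dozens).
- COCA: 120 samples, 4 subtypes, 4 platforms each seeing a two-way
  merge of the subtypes at SNR 3; 10 replicates.
- survival: 1000 null replicates at n = 50 per group for the log-rank
  level; exact two-subject product-limit check.
- enhancers: 2000 windows, 100 gains + 100 losses at fold 4,
  noise CV 0.1; 5 replicates.

## Known limitations

- The module sampler's cell model assumes independent Normal cells;
  correlated residuals (batch structure) will inflate module counts.
- Regulator scoring is marginal per regulator: two highly collinear
  candidate profiles share credit, and the per-module quantile then
  admits only one of them.
- The consensus-CDF delta-area criterion can under-select k when
  subclasses are heavily unbalanced.
- The Monte-Carlo Fisher test for r×c tables has simulation error
  ~1/√n_mc; increase `n_mc` for small p-values.
- MethylMix-style candidate calling here is a simplification (Gaussian
  mixture on beta, BIC); it does not model probe-level structure.
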