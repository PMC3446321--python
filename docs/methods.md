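# Methods

## The model

mexplorer identifies transcription factors (TFs) whose regulatory targets are
informative about a biological process.  The inputs are (i) a gene x TF matrix
of categorical regulatory evidence and (ii) a partition of the gene universe
into named process classes plus a baseline class.

Evidence is a closed nine-level vocabulary per (gene, TF) cell:
`not_regulated` (baseline), `up`/`down` (differential expression in the TF
deletion strain), `TFBS` (a promoter binding site), `NDTFBS` (a binding site
in nucleosome-depleted chromatin), and the four composites
`up+TFBS`, `down+TFBS`, `up+NDTFBS`, `down+NDTFBS`.  Treating deletion
response and binding as equally informative lines of evidence, and flagging
their (rare) agreement separately, is a modeling assumption, not a data
property.

For each TF independently, the response class of gene *i* is modeled by
baseline-category multinomial logistic regression.  With response classes
c = 1..C (class C the baseline) and the TF's K observed non-baseline evidence
levels dummy-coded with `not_regulated` as reference:

    H1:  log(p_ic / p_iC) = beta_{0,c} + sum_k beta_{k,c} x_{i,k}
    H0:  log(p_ic / p_iC) = beta_{0,c}

Both are maximum-likelihood fits of the standard multinomial log-likelihood
l = sum_i sum_c y_{i,c} log p_{i,c} and compared by the likelihood-ratio test

    LR = -2 (l0 - l1)  ~  chi-square on (C-1) K degrees of freedom.

Per-TF p-values are corrected across the screen with Benjamini-Yekutieli
(BY) FDR, which is valid under the arbitrary dependence created by shared
genes and overlapping target sets; the default significance cut-off is
q <= 0.05.

### Fitting: closed form, not iteration

The single predictor is categorical, so the alternative model is exactly
saturated in the evidence-level dimension: the (K+1)(C-1) coefficients are a
smooth reparameterization of the (K+1) level-conditional class distributions.
The supremum of the likelihood is therefore the log-likelihood of the
observed (level x class) cross-tabulation,

    l1 = sum_{l,c} n_{lc} log(n_{lc} / n_{l.}),

with 0 log 0 = 0.  This identity holds *including* the quasi-separated case
(an evidence level observed in only some response classes): coefficients
diverge but the likelihood supremum is still the cross-tab value, so the LR
statistic is well-defined.  The default fit uses this closed form; divergent
coefficients are clamped at |beta| <= 30 for reporting and the level is
flagged.  An aggregated Newton-Raphson solver (`method="newton"`,
convergence when the log-likelihood improves by < 1e-8, cap 500 iterations,
step-halving) is kept as an independent route and agrees with the closed
form to ~1e-9 in practice; the suite also cross-checks both against
statsmodels' MNLogit.  All log-likelihood comparisons use an absolute
tolerance of 1e-6.

Null-model quantities are closed-form: fitted probabilities are the class
frequencies n_c/N, l0 = sum_c n_c log(n_c/N), intercepts log(n_c/n_C).
The null fit is computed once per screen — it does not depend on the TF.

TFs whose column is entirely `not_regulated` (K = 0) carry no information
and are reported untested rather than p = 1; BY's m counts only performed
tests.  Ties rank by ascending p then lexicographic TF id everywhere.

### Coefficient summaries

Positive slopes mark evidence levels over-represented in a class relative to
baseline genes.  Process (phase) specificity of a TF is the unit-scaled
positive coefficient mass per response class, s_c = sum_k max(beta_{k,c}, 0)
normalized to sum to one; evidence contribution is the transpose
(s_k = sum_c max(beta_{k,c}, 0)).  Capped coefficients enter these sums as
capped, which bounds the influence of separated levels.

### Composite scores

Two screens on different process definitions are combined by min-max scaling
-log10 p to [0, 1] within each run (p floored at 1e-300) and summing.
Min-max scaling is used because it makes runs of different sizes and p-value
ranges commensurable; divide-by-max is available via `scaling="maxdiv"`.
The log base is immaterial to the ordering under min-max scaling.  A TF
absent from (or untested in) a run scores 0 in it.

## Preprocessing

Nucleosome-depleted binding sites are called per (gene, TF) site set: a
one-sided lower-tail one-sample t-test of the site's normalized occupancy
observations against the genome-wide average, BH-FDR across sites, depleted
at adjusted p <= 0.05.  The lower tail operationalizes "occupancy below the
genome average"; BH (rather than BY) is used for this preprocessing filter.
When several binding sites fall in one promoter their observations are
pooled into one per-(gene, TF) test.  Sites with fewer than two observations
are untestable and left not-depleted with a warning.

Evidence merging is the exact cross-product of expression call x binding
call x depletion call; contradictory inputs (a gene both up and down for one
TF) are rejected.  Genes named in a process list but absent from the matrix
are dropped with a logged count: the model cannot use genes that have no
evidence row.

## Companion statistics

**Fisher overlap.**  2x2 collapses (any evidence vs none; any process class
vs baseline) are tested one-sided with the exact hypergeometric upper tail,
the direction implied by asking whether targets are *over*-represented among
process genes; two-sided is available by flag.

**Ordered enrichment.**  For a gene list ranked strongest-first (smaller
score = stronger; the canonical score is a product of differential-expression
p-values, so ascending order), every prefix length n is tested against each
functional category with the hypergeometric upper tail P(X >= k_n), and the
minimum over prefixes is reported with the prefix attaining it.  The scan
minimum is deliberately left uncorrected for the number of prefixes —
mirroring the ranked-list enrichment convention it reimplements — and is
therefore anti-conservative; this is documented rather than adjusted, and
BH-FDR (configurable to BY) runs across categories.  Categories whose gene
set is a subset of another category's are pruned first (equal sets keep the
lexicographically smaller id), leaving an antichain.

**Viability error model.**  Culture viability (CFU/ml divided by cells/ml)
is log-transformed (zeros floored at half the smallest positive value,
flagged) and each (tested strain, time-point) is assessed on the
cross-section of that time-point with nested Gaussian linear models
H1: v ~ i + c + b + m vs H0: v ~ i + c + b, where i is the intercept, c a
pooled negative-control indicator, b the batch indicator(s), m the
tested-strain indicator.  All negative-control strains share one indicator
(a per-strain encoding would leave controls unpenalized relative to the
strains they calibrate).  No longitudinal correlation across time-points is
modeled; each cross-section is independent.  The LR statistic uses the
closed form N log(RSS0/RSS1) and chi-square with df = 1; if the null model
already fits to round-off the statistic is zero.  With a single batch the b
term is dropped and flagged.  The grid of tests is BH-FDR corrected
(configurable), and strains below raw viability 0.005 are flagged inviable.

## Synthetic data

The generator emulates the structural features of a genome-scale yeast
regulator compendium, which is what makes desk-scale testing meaningful:

- ~7% of cells carry non-baseline evidence (sparsity 0.07 by default);
- the evidence mixture puts 84% of non-baseline mass on expression-only
  classes (split evenly up/down), 1.5% on the four composite classes, and
  the remainder on binding-only classes (TFBS 8.5%, NDTFBS 6%);
- the default response has six phase-like classes of sizes 82/30/13/19/30/18
  over 2000 genes (~9.6% of the universe, matching the proportion and size
  range of curated cell-cycle phase lists against a 6253-gene genome);
- 5 of 100 TFs are planted: their per-gene target probability is multiplied
  by an odds factor (default 8) inside two designated process classes,
  assigned round-robin.

What it does **not** emulate: correlated TF target sets (paralogous
regulators), class-dependent evidence-type composition, gene-length or
expression-level ascertainment biases, and any real promoter structure.
Passing the planted-recovery benchmark therefore demonstrates statistical
correctness and ranking behaviour of the screen, not performance on real
regulatory genomics data.

Viability tables mirror the quiescence time-course design: eight sampling
days (0.3, 2, then weekly to day 42), triplicates, two batches with tested
strains split between batches and wildtype/controls in both, log-normal
noise (default log-SD 0.2, i.e. ~20% of the mean) around a declining
trajectory starting near 0.9 with an e-folding time of ~25 days after
day 2, and a batch effect of log-SD 0.1.  Planted fold changes multiply the
mean at chosen (strain, day) cells.

A single integer seed drives one `numpy` generator per fixture, so all
fixtures are bit-reproducible; the small fixtures committed under
`tests/data/` are synthetic, regenerated and byte-compared in the suite
(provenance in `tests/data/fixture_spec.yaml`).

## Benchmark protocol

Rankings are scored with rank-based AUC (midranks for ties; untested TFs
tied last so that all methods are compared on the identical TF universe).
The robustness harness redraws gene subsets at 30/50/70/90% of the universe,
100 replicates each by default, reruns the screen per subset, and reports
mean AUC with a percentile 95% interval; subsets that empty a response class
are redrawn (attempt cap 100).  The false-positive check permutes the
response assignment over genes — preserving class sizes — and counts
q <= 0.05 calls for both the multinomial screen and the Fisher baseline.

Problem sizes used throughout the suite and the acceptance script (2000
genes, 100 TFs, 100 subsampling replicates, 1000 calibration replicates,
50 shuffle replicates) are the package's chosen desk-scale defaults; the
protocol accepts any matrix/response/gold triple, including a full
genome-scale compendium, unchanged.

## Numerical choices and limitations

- LR p-values rely on chi-square asymptotics; with very small classes or
  very sparse evidence levels the statistic's null distribution is discrete
  and the p-values conservative or anti-conservative cell by cell.  The
  calibration test runs at the default universe size (N = 2000), where the
  approximation passes a KS uniformity check over 1000 null replicates.
- The BY correction is applied over tested TFs only; changing which TFs are
  testable (e.g. by subsampling genes) changes m.
- Coefficient capping at 30 affects only reported coefficients and the
  share summaries, never likelihoods or p-values.
- `ordered_enrichment` evaluates every prefix (not a coarser grid); with
  L-length lists and many categories this is O(L x categories) vectorized
  hypergeometric tails.
- Robustness CIs are percentile intervals over replicates, not analytic.
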