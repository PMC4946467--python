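# Methods

This note records the models, defaults and numerical choices behind
`liverseq`, and what the synthetic-data tests do and do not establish.

## Study design assumed

Samples carry (donor, group, timepoint, batch) metadata with groups
PRE / DBD / DCD and timepoints pre / 0h / 3h / 6h. The PRE group exists
only at the `pre` timepoint; every (donor, timepoint) pair is unique.
Analyses start from a gene × sample integer count matrix; read mapping
and quantification are upstream of this package.

Two branches mirror the two scientific questions:

* **perfusion** — unpaired 0h-vs-PRE contrasts for DBD and DCD;
  TMM-normalized CPM; FDR ≤ 0.001; inconsistency tolerance 0.
* **cold-storage** — donor-paired 3h/6h-vs-0h contrasts within each
  group; log2 → batch adjustment → back-transform; FDR ≤ 0.25;
  tolerance 1.

Batch adjustment is applied only in the cold-storage branch and TMM only
in the perfusion branch (the perfusion batches are too small for stable
batch-parameter estimation).

## Preprocessing

**Expression filter.** A gene is kept when its number of samples with a
nonzero count strictly exceeds the number of subjects in the branch's
sample set. The filter runs before any normalization or adjustment
(order not otherwise determined; filtering first keeps all later stages
on one gene universe). It is idempotent.

**Log transform.** `log2(count + pc)` with pseudocount 1.0 (zero maps to
zero). Configurable.

**Batch adjustment.** Parametric empirical-Bayes location/scale
adjustment on the log2 scale: standardize each gene by its grand mean and
pooled variance; estimate per-batch location γ̂ and scale δ̂² per gene;
shrink γ̂ toward a normal prior and δ̂² toward an inverse-gamma prior
(moment-matched hyperparameters, iterative joint solution); remove the
shrunken effects; restore the grand location/scale. Two implementation
details are deliberate:

* a final per-gene recentering pins the output grand mean exactly to the
  input's — EB shrinkage otherwise leaves a small location residue;
* a single-batch input is returned unchanged with an identity model.

Every batch needs at least two samples. The implementation is
cross-checked in the tests against scanpy's independent implementation of
the same model.

**Back-transform.** The cold-storage branch adjusts on the log2 scale but
the count model needs count-scale input, a reconciliation the analysis
recipe leaves open. We invert the log (`2^x − pc`), clip at zero, and
round to integers for the NB fit; CPM for the consistency stage is
computed from the unrounded back-transformed values.

**TMM.** Trimmed mean of M-values with the method's standard constants:
30% two-sided trim on M, 5% on A, genes with a zero in either sample
excluded, inverse-delta-method precision weights, factors centered to
geometric mean 1. The reference sample is the one whose 75th-percentile
count fraction is closest to the across-sample mean. Factors match an
independently coded brute-force implementation to 6 decimals on random
matrices.

**CPM.** `count / (L_j · f_j) · 10⁶` with f ≡ 1 when factors are absent.

## Differential expression

Per-gene NB GLM with log link and offsets `log(L_j f_j)`:
`Var = μ + φ μ²`. Fitting is IRLS, vectorized across genes (shared
design matrix; the per-iteration weighted least squares batches into one
stacked p×p solve): max 50 iterations, relative deviance tolerance 1e-8,
step-halving on deviance increase, linear predictor clipped to ±40.
All-zero genes get a degenerate converged fit and p = 1. φ = 0 reduces to
the Poisson GLM (p-values agree to < 1e-3 at φ = 1e-8).

**Dispersions.** The common φ maximizes the summed Cox–Reid adjusted
profile likelihood (APL = profile log-likelihood − ½ log det X'WX),
optimized on log10 φ ∈ [−6, 1.5]. Tagwise values maximize
`APL_g + prior_n · mean_g(APL)` on a 21-point log2 grid spanning ±8
doublings around the common value, with quadratic interpolation at the
grid maximum; `prior_n = prior_df / residual_df`, prior df 10 by default.
Bit-compatibility with any particular DE tool is not a goal; correctness
is established by simulation (Poisson truth → median φ̂ < 0.01; φ = 0.2
truth recovered within [0.1, 0.4]; null p-values uniform).

**Testing.** Likelihood-ratio χ² between nested fits with df = rank
difference; a negative deviance difference beyond tolerance raises (fit
failure); df = 0 (identical designs) returns p = 1. BH adjustment is the
standard step-up (statsmodels behind the package surface; tests compare
against a brute-force transcription of the definition).

**Paired designs.** Donor indicator columns absorb per-(gene, donor)
biological state. Omitting them does not inflate the type-I error here —
because both timepoints share the donor, the absorbed extra dispersion
*overestimates* the within-pair variance and the test becomes severely
conservative; either way calibration requires the donor terms, which is
what the tests assert.

## Consistency index

Per-subject log2 fold changes are computed on CPM + 1 (the analysis
recipe names no scale; CPM after the branch's own normalization keeps the
statistic units-free). Paired: `log2((cpm_t + 1)/(cpm_0 + 1))` per donor.
Unpaired: subject's log2 CPM minus the mean log2 CPM of the baseline
samples. The gene's direction is the sign of the mean per-subject log2FC
(ties break to "up" and are flagged); a subject is consistent when its
log2FC *signed in that direction* strictly exceeds 0.5 — an absolute-value
reading would count opposite-direction subjects, contradicting the
same-direction requirement. The index is the consistent fraction, and
the pass threshold is `(n − tolerance)/n`: 1.0 at tolerance 0, 0.90 for
n = 10 / tolerance 1, 0.83 for n = 6 / tolerance 1. A gene is called when
q ≤ FDR threshold **and** c ≥ threshold. Direction comes from the
consistency stage itself, keeping the statistic self-contained; the GLM
coefficient sign is available in the DE table for cross-checking.

The source analysis describes the perfusion criterion both as "a
consistency index of exactly 0" and as a threshold of 1.0; these coincide
only if the former counts *inconsistent* subjects. We standardize on the
consistent fraction with the tolerance expressed in subjects.

## Enrichment

Ontology terms form a rooted DAG (child → parent is_a edges). Annotations
propagate by the true-path rule (a term's gene set is its direct
annotations plus all descendants', de-duplicated). Each term gets a
one-sided upper-tail hypergeometric p (`P[X ≥ k]`, X ~ Hypergeom(N, K, n)),
identical to the one-sided Fisher exact test. Terms with k < 5 observed
study genes are removed *before* BH (the alternative order is exposed as
a flag). Reporting keeps leaf terms only: significant terms (q < 0.001)
with no significant descendant.

The universe is the expression-filtered gene list. The analysis recipe's
sentence naming the DE genes as the reference set is read as a wording
slip (a study set tested against itself yields p ≡ 1); the literal
reading remains available behind `study_as_universe=True` for audit.

## Energetics

Metabolite summaries are per (group, timepoint, metabolite) means, SDs
and counts; empty cells are absent, not zero. Group comparisons default
to the two-sided Welch t-test (the published p-values name no test;
Mann–Whitney is available side by side). The ATP–AST association is the
Pearson correlation of post-perfusion ATP against recipient peak AST over
transplanted donors, with the t-transform p-value on n − 2 df. Note the
published pair (r = −0.683, R² = 0.467) agrees only to one unit in the
last printed digit — both numbers were evidently rounded from one
unrounded estimate.

## Synthetic data

`simulate_counts` draws NB counts with mean

    μ_gj = L_j · q_g · 2^(effect_gj + γ_b(j) + b_gd(j) + ε_gj)

* `q_g`: log-normal relative abundances (σ = 1.6), normalized;
* `L_j`: log-normal library sizes, default mean 16.5 M, log-sd 0.4;
* `effect_gj`: planted signed log2 effects (default 10% of genes,
  |effect| ~ |N(2, 0.5)|) applied to the DE group's post-perfusion
  samples, sign-flipped for donors flagged inconsistent;
* `γ_b`: per-batch location shifts (sd 0.5 log2); `ε_gj`: within-batch
  log2 noise whose scale is the batch's δ_b (log-normal, log-sd 0.25)
  times 0.15 — the location/scale structure the adjustment step removes;
* `b_gd`: per-(gene, donor) biological state, sd 0.4 log2, shared across
  a donor's timepoints. Residual NB dispersion is log-normal around 0.01.

This split matters: between-donor contrasts see biological plus counting
noise (effective BCV ≈ 0.32, a standard human-tissue value), while
within-donor (paired) contrasts see only the residual dispersion — the
reason paired designs gain power, and the regime in which the null
cold-storage data produce zero called genes. Donor counts, timepoints and
batch count default to the study layout (4 PRE, 10 DBD, 6 DCD, 0/3/6 h,
4 batches). The magnitudes of library-size spread and dispersion are
field conventions, not estimates from the study (none are published).

The ontology generator builds a random rooted DAG with a guaranteed
diamond motif and Poisson-distributed gene annotations. The energetics
generator draws log-normal metabolite trajectories around declining-ATP /
rising-hypoxanthine group profiles (DCD sharply lower at 0 h) and draws
log peak AST against the *standardized pooled* log ATP so the sample
correlation across both donor groups targets ρ (default −0.683): in a
pooled transplant cohort the group contrast itself carries part of the
correlation.

What the generator does not emulate: gene–gene correlation, GC/length
biases, isoform structure, outlier samples, and annotation bias in the
ontology. Passing recovery tests therefore demonstrate internal
correctness of the pipeline under its own model class, not performance on
arbitrary real data.

## Problem sizes and tolerances

Calibration and recovery suites run at 2,000 genes with the study's donor
layout: KS < 0.05 on 2,000 null p-values; mean realized FDP < 0.10 at
q ≤ 0.05 over 20 replicates with 10% planted |log2FC| = 2; enrichment
null at ≈ 5% ± 2.5 points; perfusion recovery ≥ 80% with zero flipped-donor
admissions over 10 replicates; cold-storage null with zero calls in
≥ 9/10 seeds. Oracle-equivalence suites use ≥ 100 random small instances
per statistic. Numerical tolerances: IRLS deviance 1e-8; TMM vs oracle
1e-6; exact combinatorial identities 1e-9 relative.

## Known limitations

* Dispersion estimation uses a fixed prior df (10) rather than estimating
  the prior from the data.
* The batch model assumes no batch–condition confounding; the generator
  assigns batches per donor, so storage timepoints are never split across
  batches.
* The cold-storage back-transform-and-round step makes the NB input
  approximate at very low counts (values below 1 CPM-equivalent clip to
  zero).
* Non-parametric batch-adjustment priors, quasi-likelihood F-tests and
  conditional (parent-child decorrelated) enrichment are out of scope.
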