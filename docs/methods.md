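# Methods

This note documents the statistical model behind each pipeline stage, the
tunable parameters and their defaults, the design of the synthetic cohort
generator, and the numerical conventions that make runs reproducible.

## The immune-checkpoint panel

The analysis is anchored to a fixed 31-gene panel of checkpoint molecules,
each annotated on two orthogonal axes: role (17 ligands, 14 receptors) and
signalling class (12 costimulatory, 19 coinhibitory). The registry is
packaged data (`icpattern.registry`); its partition invariants are asserted
at load time and in tests. Gene symbols are the join key throughout the
package; no probe-to-symbol mapping is attempted, and duplicate expression
rows are collapsed by keeping the row with the largest mean (the common
microarray convention).

## Batch integration

Expression of gene *g* in sample *j* of batch *i* is modelled as
x_gij = α_g + γ_ig + δ_ig ε_gij, the standard location/scale batch model.
Parametric empirical Bayes shrinks the per-(gene, batch) estimates — normal
prior for γ, inverse-gamma for δ² with method-of-moments hyperparameters —
iterated to relative tolerance 1e-4 (max 100 iterations). Settings:

* `mode` — `location_scale` (default) or `location_only`.
* `parametric` — `True` (EB shrinkage) or `False` (raw per-batch
  estimates). With shrinkage off, location-only correction equalizes
  per-gene batch means to machine precision and the corrector is exactly
  idempotent. With shrinkage on, re-application moves the output by ~1%
  RMS — the shrunk estimate deliberately under-corrects, so exact
  idempotence is impossible; tests pin both behaviors.
* Per-batch variances use ddof = 0 so the pooled and within-batch scales
  agree (this is what makes the shrinkage-off path exactly idempotent).

No covariate-preservation term is fit: the integration step is unsupervised.
A single batch yields the identity transform with a warning; a batch with
one sample is an error. Genes constant within every batch pass through
unchanged and are flagged. The implementation is cross-checked against an
independent parametric-ComBat implementation (scanpy's) in the test suite.

## Consensus clustering and k-selection

Patients are clustered on the z-scored panel genes with PAM k-medoids under
the 1 − Pearson-correlation distance between sample profiles. Genes are
z-scored first so the distance reflects relative profile shape rather than
per-gene baselines (the analogue of the median-centering conventionally
applied before consensus clustering). PAM uses the deterministic greedy
BUILD initialization followed by alternating assignment/medoid-update; all
consensus variability therefore comes from item resampling, and with
`item_fraction = 1` the consensus matrix is exactly 0/1-valued.

Consensus entries are co-clustered counts divided by co-sampled counts over
`n_resamples` subsampling runs (defaults: 1000 resamples at 80% of samples,
drawn without replacement). Final assignments cut an average-linkage
hierarchical tree of 1 − M at k. The number of clusters is chosen by
minimum PAC — the fraction of off-diagonal consensus entries inside the
ambiguity interval (0.1, 0.9] — over a default grid k = 2…6, ties breaking
toward smaller k; the relative change in area under the consensus CDF
(delta-area) is reported alongside. A forced k is accepted for both
clustering passes (the signature-gene pass uses k = 2 by default). Cluster
labels are canonicalized A, B, C, … in decreasing mean expression over the
clustering genes, so "A" is always the immune-hot pattern.

## ssGSEA and ESTIMATE-style scores

For one sample and one gene set S, genes are ranked within the sample
(average ranks on ties) and the ranked list is walked from the top:

ES = Σ_i [P_in^w(i) − P_out(i)],  P_in^w(i) = Σ_{j≤i, j∈S} r_j^α / Σ_{j∈S} r_j^α,
P_out(i) = #{j≤i, j∉S} / (N − |S|).

The weight exponent defaults to α = 0.25 (the canonical ssGSEA value; the
choice is exposed because nothing in the analysis pins it). Scores depend
only on within-sample ranks and are therefore invariant to any strictly
monotone transform of a sample's values — asserted by metamorphic tests.
Edge cases: sets with no overlap are dropped with a warning; a set covering
the whole matrix has an empty out-of-set walk and scores from the in-set
walk alone. Optional min-max normalization rescales each set's scores to
[0, 1] across samples.

Stromal and immune summary scores are the unnormalized ssGSEA scores of two
user-supplied signatures, and their sum is the combined score (an exact
identity, tested). The published 141-gene ESTIMATE signatures are *not*
bundled — signature content is an input; equation-level behavior is the
contract. The synthetic generator emits its own stromal/immune sets.

Associations between scores use Spearman correlation (Pearson on average
ranks, t-approximation p) or distance correlation (double-centered
Euclidean distance matrices, permutation p with a seeded null; 999
permutations by default, via pingouin with a brute-force double-centering
oracle in tests).

## Signature derivation and the ICscore

Differential expression between every unordered pair of patterns uses Welch
t on log-scale expression (Wilcoxon rank-sum as an option) with
Benjamini–Hochberg adjustment within each contrast at FDR 0.05. The
signature is the intersection of significant genes across all contrasts.
The variance-moderated linear-model test often used for this step is
deliberately replaced by Welch/Wilcoxon: the pipeline's contract is the
intersection-and-score procedure, not the moderation machinery.

Signature genes are z-scored (training mean/sd stored for held-out scoring)
and the two leading principal components extracted. The score formula
"Σᵢ(PC1ᵢ + PC2ᵢ)" is read as the sum over signature genes of each gene's
contribution to the two component coordinates, which telescopes to the
sample's PC1 + PC2 coordinates; this identity is asserted against a
brute-force eigendecomposition. PCA sign indeterminacy is resolved by
orienting each component so its loading sum is ≤ 0: higher mean signature
expression then drives the score down, making the low-ICscore group the
immune-hot one and keeping low/high labels stable across runs. Whether to
z-score, and any univariate prognostic pre-filter before the PCA, are
config-exposed (defaults: z-score on, no pre-filter).

The survival-optimal cutpoint maximizes the absolute standardized two-group
log-rank statistic |O − E|/√V over midpoints between consecutive unique
scores whose induced groups each hold at least `minprop` (default 0.1) of
samples; exact ties break toward the candidate nearest the median score.
The exhaustive scan *is* the estimator; an independent scan with a second
log-rank implementation is the test oracle.

## Survival statistics

Kaplan–Meier product-limit curves with Greenwood variance; censorings at an
event time count as at-risk for that time's events. The k-group log-rank
test aggregates per-event-time O/E and the full hypergeometric covariance,
with the statistic from the first k − 1 groups. Cox models are fit by
partial likelihood (statsmodels PHReg) with Efron tie handling by default
(Breslow optional; the two agree exactly on tie-free data, tested). Wald
95% intervals are reported on the hazard-ratio scale. Constant covariates
and rank-deficient designs are errors; |β| > 20 or non-finite coefficients
are flagged as non-convergence (monotone-likelihood separation). The
univariate per-gene screen combines a continuous-expression Cox fit with a
median-split log-rank p and labels direction from the sign of β.

Contingency tables: 2×2 uses the two-sided Fisher exact test by the
point-probability method (sum of table probabilities ≤ the observed one —
conventions differ, hence documented) with a Haldane–Anscombe +0.5 odds
ratio when a cell is zero (the exact p always comes from the uncorrected
table); larger tables use Pearson χ².

## Genomics

TMB is the per-sample count of nonsynonymous MAF records (Missense,
Nonsense, Frame_Shift_Del/Ins, In_Frame_Del/Ins, Splice_Site,
Translation_Start_Site, Nonstop); a capture size in Mb converts to a
per-megabase rate on request (raw counts by default, since no capture size
is part of the inputs). Mutation frequency counts a sample once per gene
regardless of hit multiplicity. Co-occurrence tests every gene pair's
mutated/wild-type 2×2 with Fisher exact p, BH adjustment across all pairs,
and labels co-occurring/exclusive by the odds-ratio direction at the FDR
threshold. CNV input is collapsed to {−1, 0, +1} at read time (GISTIC ±2
merged with ±1) and summarized as per-gene gain/loss frequencies.

## The synthetic cohort generator

`simulate_cohort` emits a fully linked cohort that is a pure function of
(config, seed). Defaults are the study conditions for every test and for
the acceptance script:

* **Samples** — 80 per pattern (A hot, B intermediate, C cold), 3 batches
  assigned independently of pattern.
* **Latent immune axis** — z ~ N(μ_pattern, 0.3²) with μ = +1, 0, −1;
  drives infiltration, survival and TMB.
* **Panel expression** — gene baselines N(5, 1) in log2 units; pattern
  shifts ±1.5 (A/C) on every panel gene, with 2 genes reversed (the
  CD276/VTCN1-like minority). Pattern B sits between A and C on every gene
  but with its own per-gene profile (weight of magnitude 0.5–0.9, random
  sign). A purely level-intermediate B would be invisible to the
  scale-invariant correlation distance — profile heterogeneity is also what
  real intermediate patterns show.
* **Background** — 2000 genes, of which 300 form a signature block tracking
  the axis (effect 1.0, 80% positively — the majority direction is what
  gives the loading-sum sign rule its meaning); the rest are null.
* **Immune sets** — 28 sets × 30 dedicated genes, per-set abundance
  multiplier U(0.4, 1.2) on the axis; separate stromal (effect 0.4) and
  immune (0.8) summary signatures.
* **Batch effects** — additive per-(gene,batch) shifts N(0, 0.4²) and
  log-normal scale factors (σ = 0.15): exactly the model the corrector
  fits, so correction is identifiable.
* **Survival** — exponential event times with hazard λ₀ exp(−log(2)·z),
  λ₀ = 0.02/month (median overall survival ≈ 3 years for an average
  patient, a realistic gastric-cancer figure); independent uniform
  censoring calibrated by bisection to a 30% marginal censor fraction.
* **Mutations** — per-sample nonsynonymous counts Poisson(12/8/5) for
  A/B/C (hot tumors carry more mutations, so TMB ends up anti-correlated
  with the ICscore), spread over a 100-gene panel, plus three driver genes
  with pattern-dependent hit probabilities (ARID1A 0.57/0.35/0.17, PIK3CA
  0.41/0.25/0.10, TP53 0.36/0.40/0.42) and Poisson(1) silent passengers
  that must not count toward TMB.
* **Clinical categoricals** — MSI-H enriched in pattern A (0.50/0.25/0.08),
  with stage and N-stage drifting adverse toward pattern C.

What the generator does **not** emulate: realistic marginal distributions,
gene–gene correlation beyond the planted blocks, cohort-specific platform
effects, informative censoring, or subclonal mutation structure. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under its own model assumptions — not that the biological conclusions
transfer to any real cohort.

## Determinism and problem sizes

One global seed fans out to named substreams (CRC-keyed SeedSequence), so
adding a stage never perturbs earlier stages' randomness, and a fixed
config + seed reproduces every output file bit-identically (golden-file
tested). The test suite runs consensus clustering at 60–150 resamples and
the calibration studies at 100–1000 simulations; the acceptance script uses
the full 1000-resample default. All sizes are configuration, not contract.

## Known limitations

* Consensus clustering supports only the PAM base clusterer and item (not
  gene) resampling.
* The Cox layer has no time-varying covariates, stratification, or
  proportional-hazards diagnostics.
* CNV handling is summary-level only ({−1, 0, +1} calls); no segment data.
* Cross-cohort symbol harmonization is assumed done upstream: matching is
  exact-symbol.
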