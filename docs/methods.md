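# Methods

This note documents the models, defaults and numerical choices behind
`cmsig`, and what the synthetic experiments do and do not establish.

## The translation pipeline

The package's object of study is a *translation*: a genome-wide subtype
classifier is distilled into a small panel of directly measurable features
whose linear combination predicts survival. The stages, with their
assumptions:

**Functional spectra (ssGSEA).** For sample *j*, genes are ranked by
expression descending (rank 1 = highest; ties broken by lexicographic gene
id, so the transform is deterministic). For a gene set *S* the score is

ES(S, j) = Σᵢ [ Pin(i) − Pout(i) ],

summed over all list positions *i*, where Pin is the cumulative sum of
in-set weights wᵢ ∝ (G − i + 1)ᵅ normalized to 1, and Pout is the
unweighted cumulative fraction of out-of-set genes. This is the
integrated running-sum dialect (not the maximum deviation), with α = 0.25
by default. At α = 0 the score depends only on ranks and is invariant to
any strictly monotone transform of a sample's expression. Set members
missing from the matrix are dropped per set; sets reduced below 2
overlapping members, or covering every gene (empty complement), are
dropped with a warning. Normalization (divide all scores by the global
max − min) is on for classifier input and off for immune infiltration,
where scores are only compared within a cell type across groups.

**Subtype classifier and deep features.** A fully connected ReLU network
(input → 128 → 32 → 10 → 4) is trained with softmax cross-entropy and Adam
(lr 10⁻³, batch 64, ≤300 epochs) on CMS-labeled samples; unlabeled
(NOLBL) samples are excluded from the loss but can still be embedded. An
internal stratified validation split (20%) drives early stopping
(patience 25) with best-weight restoration, and the reported held-out
accuracy. All stochastic steps (init, shuffling, split) flow from one
seed; training is exactly reproducible. The last hidden layer's
activations are the K = 10 deep features.

Two deliberate choices here:

- *Initialization at the prior predictor.* The output bias is initialized
  to the log class frequencies and the final layer's weights are scaled
  down tenfold, so the untrained network starts as (approximately) the
  class-prior predictor. This is the standard remedy for networks that
  otherwise begin far from the natural baseline: with no signal in the
  inputs the early-stopped model then predicts the majority class, and its
  held-out accuracy equals the largest class prior rather than an
  arbitrary value below it.
- *Uniform loss weights by default.* Inverse-frequency class weighting is
  implemented (`class_weight="balanced"`) but off by default. With
  inverse-frequency weights a no-signal classifier's argmax is not the
  majority class, which makes the null behaviour of the pipeline
  unpredictable; uniform weighting keeps the no-signal baseline exactly at
  the majority prior. On the synthetic cohorts the labeled classes are
  imbalanced (45% vs 12%) yet easily separable, so weighting does not
  change the signal regime.

**Distillation.** For each deep feature, candidate raw features are ranked
by |Pearson r| (ties by feature id), the top `n_top = 10` kept — the sign
of r is recorded, not used for slating; a `per_sign` switch slates 10 per
sign instead — then re-ranked by MAD (unscaled median absolute deviation,
computed on the training cohort only) and the top `n_keep = 3` retained.
The union over the K deep features is deduplicated by first occurrence, so
the panel has at most K·n_keep members. Zero-variance features are flagged
and never enter candidacy.

**Risk model.** Signature features are screened one at a time by
univariate Cox (Wald p < 0.05; no multiple-testing correction by default,
Benjamini–Hochberg optionally available upstream). Survivors enter a
multivariate Cox fit with Efron tie handling via lifelines (its default
Newton–Raphson convergence criteria; the fit agrees with a dense
grid-search maximization of the Efron partial likelihood to 10⁻³ on toy
data). Features are z-scored with training-cohort parameters stored on the
model, so validation cohorts are scored without refitting. The risk score
is RSᵢ = Σⱼ βⱼ zᵢⱼ. The high/low cutoff is the maximum-Youden threshold of
the time-dependent ROC at a fixed horizon (default 60 months), with
ties broken toward the smaller threshold (the larger high-risk group);
"high" includes the boundary (RS ≥ c*).

**Time-dependent ROC.** Cumulative-case / dynamic-control with inverse
probability of censoring weights: cases are subjects with an observed
event by the horizon (weight 1/G(tᵢ⁻)), controls subjects at risk past it
(weight 1/G(T)), where G is the Kaplan–Meier estimator of the censoring
distribution. The AUC is the trapezoidal integral; with no censoring
before the horizon the curve reduces to the plain ROC against the
event-by-horizon indicator. A constant score yields a single threshold
with J = 0 (the degenerate cutoff) rather than an error.

**Downstream statistics.** Subtype enrichment collapses to a 2×2
(high/low × target/other, unlabeled excluded) and reports the
cross-product odds ratio — Haldane–Anscombe +0.5 on every cell when any
cell is zero — and the one-sided hypergeometric tail p. Group comparisons
use the Wilcoxon rank-sum test (exact enumeration when both groups ≤ 8
with no ties; tie-corrected normal approximation without continuity
correction otherwise, so that exactly symmetric data gives p = 1) and the
chi-square/Fisher router (Pearson chi-square without continuity correction
when all expected counts ≥ 5, Fisher's exact otherwise, 2×2 only).
Correlation maps report Pearson r with two-sided t-based p and BH q per
pair; both raw and adjusted p are kept, since conventions differ on which
to star.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_samples / n_genes | 600 / 2000 | discovery-cohort scale, desk-size gene space |
| subtype proportions | 0.15, 0.45, 0.14, 0.26 | labeled CMS distribution of the discovery cohort |
| program size / effect δ / noise σ | 100 genes / 2.0 / 1.0 | comfortable but not trivial recovery (log-scale shift of 2 sd) |
| baseline means | Uniform(2, 12) | log-expression dynamic range |
| hazard log-multipliers γ | 0, −0.2, 0, ln 2.5 | CMS4 carries a 2.5-fold hazard; CMS2 mildly protective |
| baseline hazard / censoring | 0.015 per month / Uniform(0, 120) ∧ 120 months | ≈55% event fraction over a 10-year window |
| gene sets | 5 per program (≥80% program genes, 50 members), 20 background, 28 disjoint immune sets (10 genes; two embedded in the CMS1 block) | classifier input plus immune engine |
| radiomic arm | 21 features, 16 linked (λ = 1.5, noise sd 1.0), 5 pure noise | linked feature = λ·standardized program activity + noise |
| label masking | 10% → NOLBL | unlabeled fraction of real cohorts |

Expression is baseline + δ·1[gene ∈ program(subtype)] + N(0, σ²); survival
is exponential (chosen over Weibull for analytic transparency — the
planted log-hazards are the recovery targets); programs are disjoint so
recovery metrics are unambiguous, although real subtype programs overlap.
One seed drives a hierarchy of spawned generators, so adding the radiomic
arm never perturbs the expression draws.

A consequence worth knowing: the *marginal* CMS4-vs-rest hazard ratio
converges to ≈3.0, not 2.5, because the reference group is a hazard
mixture in which the protective CMS2 stratum accrues disproportionate
person-time. The tests check consistency against the analytically
integrated mixture value and a Cox-free exponential rate-ratio estimator,
not against the naive per-stratum 2.5.

What the generator does **not** emulate: real gene names or chromosomal
structure, overlapping programs, microarray noise models, batch effects,
covariate-dependent censoring, or non-proportional hazards. Passing
recovery tests therefore shows the pipeline is correct and sensitive under
its own assumptions — not that it would achieve any particular accuracy on
clinical cohorts.

## Numerical choices and degenerate inputs

- All ties in ranking steps break lexicographically by identifier;
  selection is invariant to sample order.
- Pearson correlations are clipped to [−1, 1]; zero-variance columns get
  r = 0 and a flag, and are excluded from candidacy/testing. Correlation
  with fewer than 3 samples is an error.
- Missing expression values are errors, never imputed; probe-to-gene
  collapse (keep the probe with maximum mean expression) is available but
  off by default.
- Cox fits require more events than features; apparent separation
  (|β| > 50) is an error naming the feature. Replication of every record
  leaves the Breslow partial-likelihood maximizer exactly unchanged but
  shifts the Efron one slightly — the Efron fit remains the exact
  maximizer of the duplicated likelihood.
- Serialized artifacts (classifier, risk model) are JSON bundles with
  base64 arrays; loading checks a format version and fails loudly on
  truncation. Round-trips are bit-exact for integers and ≤10⁻¹² for reals.
- Survival time units are always declared (`months` throughout the
  synthetic study); horizons (24/36/60) are in the declared unit.

## Problem sizes used by the test suite

Recovery properties run on 20 seeded default cohorts (n = 600, G = 2000,
δ = 2, σ = 1); null calibration uses a δ = 0, null-hazard cohort for the
classifier and screen checks, and 20 smaller null cohorts (n = 200,
G = 800) for the immune-contrast calibration. Oracle-equivalence suites
use 200 random ssGSEA instances (≤50 genes), 50 concordance instances of
30 records, exhaustive hypergeometric margins to 40, and a 12-record Cox
toy against a coarse-to-fine grid search.

## Known limitations

- The immune-null calibration check ("no cell type significant after BH in
  ≥95% of null seeds") sits exactly on the calibration boundary: under a
  perfect null the per-seed probability of zero BH rejections is exactly
  0.95, so any finite batch of seeds passes only with moderate
  probability. The pooled null p-values are verifiably uniform (5.0%
  below 0.05 across 560 contrasts).
- Deep features are post-ReLU activations; an occasional unit is inactive
  for most samples, which is why subtype association is asserted for ≥8 of
  10 features rather than all 10.
- The distillation is a ranking heuristic, not an optimality claim; no
  stability selection or sparse-regression alternative is provided.
- No competing risks, proportional-hazards diagnostics, or nomograms;
  the log-rank and Cox machinery assume proportional hazards, which the
  exponential generator satisfies by construction.
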