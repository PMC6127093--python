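# Methods

This note documents the statistical procedures peersway implements, the
generative model behind its synthetic cohorts, the numerical choices that
were genuinely open, and what the test suite does and does not establish.

## Task and scores

A session consists of interleaved *test* and *post-test* blocks of 8 faces.
In a test trial the participant rates a face's trustworthiness on an integer
1–8 scale and then sees the peer group's modal rating — in reality a fictive
value derived from their own rating: equal to it (agreement), offset by ±2
(moderate disagreement) or ±3 (strong disagreement), or withheld
(no-feedback control).  Each face returns once in the matching post-test
block, in permuted order, for a second rating.

Because a ±3 offset from a rating of 7 or 8 would leave the scale, feedback
conditions cannot be bound to trial positions in advance.  The scheduler
therefore assigns conditions adaptively: when a test rating arrives, a
condition is drawn uniformly among the conditions that (a) still have quota
and (b) keep the fictive rating inside [1, 8].  If every remaining-quota
condition is infeasible for the rating at hand, the feasible condition with
the largest remaining quota is assigned (keeping realized counts as close to
quota as possible) and the event is counted.  With ratings concentrated in
the middle of the scale — the empirically realistic regime — this fallback
essentially never fires and per-condition counts are met exactly (the suite
checks this across seeds); a pathological rating stream pinned to one scale
end could force small quota violations, which is the price of never showing
an off-scale peer rating.

The **social-influence score** for a disagreement condition is the mean of
(post − test) over that condition's face pairs, multiplied by −1 for
negative-valence conditions, so a positive score always means adjustment
towards the peer rating.  Agreement and no-feedback conditions keep the raw
mean change.  Outlier screening runs in two non-iterative stages: first on
the overall disagreement score (the unweighted mean of the four condition
scores — the aggregation is our choice; with equal trial counts per
condition it equals the pooled-trial mean), then, among survivors, on the
no-feedback mean change, each with a sample-mean ± 2 SD criterion.  A
degenerate zero-SD sample excludes nobody.  The no-feedback change also
feeds a one-sample t-test against zero: under an intact rating criterion it
should be indistinguishable from zero.

## PVD questionnaire

Perceived Infectability (items 2, 5, 6, 8, 10, 12, 14) and Germ Aversion
(items 1, 3, 4, 7, 9, 11, 13, 15) are scored as item means after
reverse-keying items 3, 5, 11, 12, 13, 14 (`r → L + 1 − r`; Likert maximum
L = 7 by default and configurable, since administrations vary).
Internal consistency is Cronbach's
α = (k/(k−1))(1 − Σ item variances / variance of sums), on raw scores
(hence invariant to per-item offsets and a common rescaling, but not to
per-item rescaling).  When a subscale is unreliable, `maximize_alpha`
prunes greedily: at each step it removes the single item whose removal most
increases α (ties to the lowest item index), stopping at a target α
(default 0.7), when no removal helps, or at 2 items.  On cohorts where four
GA items are uncorrelated noise, this recovers the 4-item subscale
{1, 3, 7, 13} used as the "maximized" GA score.

## EEG preprocessing

Epochs are −200…+1000 ms tensors (trials × 64 channels × samples) in µV.
The pipeline order is: average reference (channel mean removed per sample),
baseline correction (per-trial/channel mean over [−200, 0) ms), rejection of
any trial with |amplitude| > 100 µV, then interpolation of channels that
exceed the threshold in more than 25 % of all epochs.  Interpolation is an
inverse-distance-weighted mean of the k = 4 nearest montage neighbors —
deliberately simpler than spherical splines, exact for spatially constant
fields and adequate for the package's simulation-driven use.  Continuous
filtering and ocular ICA are out of scope: inputs are assumed band-limited.

## Decoding

At every sample, the 64 channel voltages form the feature vector of an
L2-regularized logistic classifier (unit regularization; features
z-standardized with training-fold statistics only, which makes the AUC
time-courses invariant to positive rescaling of the data).  Folds come from
stratified 10-fold cross-validation, drawn once per subject per contrast
and reused at every timepoint.  Out-of-fold class probabilities are
summarized by ROC-AUC computed as the Mann–Whitney rank statistic with
midrank tie handling; 0.5 is chance.  The solver is an in-package damped
Newton (IRLS) iteration — it matches scikit-learn's estimates to < 1e-5 (a
test asserts this) and avoids per-call overhead that dominates at tens of
thousands of tiny fits per subject.

Temporal generalization applies the entire trained pipeline from training
time t (fold scaler + logistic weights) to features from every test time
t′.  Because folds are fixed, the matrix diagonal equals the canonical
time-course exactly; this identity is asserted, not approximated.

The probabilistic classifier family is an explicit choice: linear models
are the default for EEG multivariate analysis, and the ROC summary requires
graded class probabilities.  Whether folds should be redrawn per timepoint
is a genuinely open design point; fixing them is what makes the diagonal
identity and cross-timepoint comparability exact.

## Cluster-mass permutation inference

Group decoding test: one-tailed one-sample t-tests of subject AUC against
0.5 at each timepoint; clusters are maximal runs of **at least two**
adjacent samples with p < 0.05 (a single supra-threshold sample never forms
a cluster); each cluster's mass is the sum of the group-mean AUC over the
run.  The null distribution flips the sign of (AUC − 0.5) independently per
subject — the standard exchangeable null for a one-sample test — and
records the maximum cluster mass per permutation.  `*p` is the proportion
of permutations whose maximum mass meets or exceeds the observed mass,
floored at 1/n_perm; the default significance threshold is *p < 0.01 with
1000 permutations.  Summing raw AUC (rather than AUC − 0.5) makes long
mediocre clusters outweigh short strong ones; both the literal sum
(default) and a `centered` option are exposed.

Correlation clusters: Pearson r between subjects' per-timepoint AUC and a
behavioral or questionnaire score; observed clusters are runs of ≥ 2
samples with r ≥ 0.40 (positive tail only), massed by Σr; the null shuffles
the score vector across subjects (10 000 permutations, *p < 0.05 by
default).  Both procedures resample summary time-series only — classifiers
are never re-run inside the permutation loop.

On null data, both procedures hold their family-wise error near the nominal
5 % (checked on 200 replicates in the acceptance suite).  The plain
proportion-of-permutations estimator (without adding the identity
permutation) is mildly liberal at finite n_perm; this follows the stated
`*p` definition.

## Mixed models and Bayes factors

Social-influence scores enter a long table with four rows per participant;
disagreement valence and strength are deviation-coded (−0.5/+0.5) so main
effects remain interpretable under interactions.  The random-intercept
model is fitted by maximum likelihood with the likelihood profiled over
ψ = σ²_b/σ²_e: for fixed ψ the per-group covariance is σ²_e(I + ψ11ᵀ),
inverted in closed form by Sherman–Morrison, giving GLS fixed effects and
the ML residual variance directly; a 1-D grid-plus-Brent search over
ψ ∈ [0, 10³] finds the optimum, including the ψ = 0 boundary (where the fit
reduces to OLS — asserted to 1e-6).  The fit agrees with statsmodels'
MixedLM (ML) to 1e-5 on well-conditioned problems; the in-package
implementation exists because boundary fits on 17-subject cohorts are a
routine, not exceptional, case here and must never fail.

t-statistics use the inner–outer df convention: terms constant within
participants are tested on n_groups − 1 − n_between df, within-varying terms
on n_obs − n_groups − n_within df.

Model comparison uses BF₁₀ = exp((BIC_base − BIC_alt)/2) with
BIC = −2ℓ + k log n_obs and k counting fixed effects plus the two variance
components.  This is a deliberate approximation to default-prior (JZS)
Bayes factors, whose exact mixed-model form requires bespoke quadrature:
the supported conclusions are model *orderings* (which covariate
specification wins), not BF magnitudes.  The *type-1* model adds a
between-subject covariate as a main effect; *type-2* crosses it with both
within-subject factors.

The **combination index** is z(mean AUC over the two processing-stage
windows, 200–400 and 400–900 ms) + z(PVD subscale score), per subject; it
has sample mean zero and is invariant to positive affine rescaling of
either input.

## Synthetic cohorts

A latent trait v ~ N(0, 1) per subject drives three observable layers:

* **Behavior** — reliance weight w = logistic(a + bv) with a = −1.7,
  b = 0.8 (mean w ≈ 0.15, so mean social-influence scores land around
  0.3–0.5 points, the realistic range for this task family).  Test ratings
  are round(clip(N(4.2, 1.2²))) — anchored at the observed
  slightly-untrustworthy bias; post-test ratings move a fraction w toward
  the fictive rating before N(0, 0.7²) noise, rounding and clipping.
* **Questionnaire** — item j = midpoint + 1.2(λⱼv + ε), ε ~ N(0, 1),
  thresholded to 1…7; λ = 1.45 for PI items and 0.8 for GA items
  (reverse-keyed items generated with inverted sign).  These loadings were
  calibrated once so that PI α ≈ 0.90 and GA α ≈ 0.8 at realistic n.
* **EEG** — each feedback-locked epoch is
  Σₖ ampₖ(condition) · g · spatialₖ ⊗ temporalₖ(t) + noise, with a
  fronto-central component with a Gaussian profile peaking at 300 ms
  (support 200–400 ms) and an occipito-parietal/right-frontal sustained
  plateau over 400–900 ms.  Amplitudes: 0 for agreement, 0.22 for moderate
  and 0.33 for strong disagreement (in units of the noise SD), times the
  subject gain g = 1 + 0.4v + N(0, 0.2²).  Noise is spatially correlated
  (squared-exponential over the montage, 5 cm length scale) and AR(1) in
  time (25 ms time constant).  These magnitudes were calibrated once so
  that group peak decoding AUC lands near 0.60–0.66 — the sensitivity scale
  typical of this paradigm — and left alone thereafter.

What the generator reproduces: the two-stage spatiotemporal structure, the
strength-scaled condition differences, a signal-free baseline and
agreement class, and positive trait links to both behavior and neural gain.
What it does not: biophysical volume conduction, ocular and muscle
artifacts, non-stationary noise, learning or fatigue across blocks, and
any item-level PVD structure beyond a single factor.  Passing recovery
tests therefore demonstrates that the *pipeline* recovers planted structure
at realistic signal-to-noise, not that real data contain such structure.

## Problem sizes in the shipped checks

The test suite and reproduction script scale the designs so the whole
chain runs comfortably on one CPU: parameter-recovery replicates use 17
subjects, 240 trials (the lab design's condition proportions at half
length) and 50 Hz epochs with 300–500 permutations; the reproduction
script's headline cohort uses the full 480-trial lab design at 100 Hz with
1000–2000 permutations; calibration studies use 200 null replicates of a
17 × 100 AUC matrix.  All inference code is rate-agnostic and runs
unchanged at 500 Hz / 600 samples.

## Known limitations

* The amplitude-rejection rule is fully automatic; no manual review stage.
* Bad-channel interpolation is inverse-distance, not spherical-spline.
* Cluster inference is temporal only (no channel-adjacency clustering, no
  TFCE).
* BF magnitudes inherit the BIC approximation's implicit unit-information
  prior; only orderings are interpretable.
* The adaptive quota scheduler guarantees on-scale fictive ratings, at the
  cost of exact quota conservation only for realistic rating streams.
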