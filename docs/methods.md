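# Methods

This note documents the models implemented in `seropanel`, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions a maintainer should know about.

## Signal model and quantification

The quantitative readout of a spot is its signal-to-noise ratio,
SNR = median foreground / median background. Per-protein values are the
arithmetic mean over the protein's duplicate spots (the mean is symmetric
in the duplicates and unbiased for the latent spot value; duplicates on
real arrays are nearly identical, so the choice of combiner is minor).
One samples × proteins matrix is produced per detection channel (IgG,
IgM); screening and modelling default to IgG, the conventional seromics
readout, with IgM retained through I/O.

Cross-array normalization defaults to quantile normalization within a
phase and channel: every sample's sorted values are mapped onto the
cross-sample mean quantile profile, with tied values receiving the mean
of the profile entries they span, so within-sample rank order is
preserved exactly. Median scaling (divide each sample by its median,
multiply by the median of sample medians) is available for sensitivity
analysis, and the method used is recorded in the matrix provenance.
Two caveats of quantile normalization worth keeping in mind:

* it is not exactly invariant to rescaling a single array — the reference
  profile averages all samples, so rescaling one array by *c* perturbs
  every output by up to |c−1|·max(array)/S (S = number of samples);
* it is compositional: if a sizeable fraction of proteins is genuinely
  elevated in one group, forcing all samples onto a common profile
  attenuates those effects. With 7 informative proteins on a 100-protein
  array the attenuation is small; at 7 of 40 it measurably erodes
  realized fold changes.

## Screening statistics

The seropositivity threshold for a protein is control mean + 2 × sample
SD; a case is positive strictly above it (ties count negative), and the
positive ratio is the positive fraction among cases. Zero control
variance is degenerate (threshold collapses to the mean); it is computed
with a warning rather than refused. Sensitivity-at-specificity scans the
observed values as candidate thresholds and returns the sensitivity at
the smallest threshold whose specificity reaches the floor (default
90%).

The two-sample test is Welch's *t* (group variances are not assumed
equal), and fold change is the ratio of arithmetic group means on the
normalized linear scale. The discovery filter requires *p* ≤ 0.05,
FC ≥ 1.2, positive ratio ≥ 10%; the test-phase filter requires *p* < 0.05
(strict), FC ≥ 1.2, sensitivity > 15% (strict) at ≥ 90% specificity, run
separately against healthy and cirrhotic controls with each hit labelled
healthy-only / cirrhotic-only / both. The asymmetry between ≤ and < is
deliberate and preserved. No multiple-testing correction enters either
filter; a Benjamini–Hochberg q-value column is reported for information
only, since the joint FC and positivity constraints already suppress the
null pass rate far below α·(number of proteins).

## Panel selection

Samples are assigned to 10 near-equal folds (sizes differ by at most
one; 576 samples give six folds of 58 and four of 57), stratified by
group by default. Per fold, the training 90% is re-screened — by default
HCC vs pooled (healthy + cirrhotic) controls with the test-phase
criteria, matching the classifier's target contrast; the two-comparison
filter and a plain *t*-test are config options — and the surviving
candidates enter a bidirectional stepwise logistic regression scored by
AIC (BIC and forward-only are options), starting from the intercept-only
model, ties broken by ascending protein ID. Marker values are
standardized with training-set mean/SD before fitting, and a negligible
ridge penalty (λ = 1e−8·n) bounds coefficients under perfect separation
without materially biasing them. The consensus panel is the set of
markers selected in every fold; a consensus logistic fit on the full
cohort supplies the reported coefficients.

Note on stepwise parsimony: with AIC, a pure-noise candidate clears the
admission bar (one-df likelihood-ratio > 2) with probability ≈ 0.16, so
with ten noise candidates the intercept-only model survives only ~18% of
null datasets; the all-fold intersection is what actually suppresses
false inclusions in the consensus. BIC's log(n) penalty makes single-fit
null selections themselves rare.

## Committee classifier

Member networks are fully connected feedforward networks: *n* inputs
(the panel), hidden layer sized by *N*ₕ = (4*n*² + 3)/(*n*² − 8) rounded
half-up (7 → 5; defined for *n* ≥ 3), logistic hidden activation, and a
2-node softmax output whose HCC-node probability is the member's output.
Training is full-batch gradient backpropagation on cross-entropy
(learning rate 0.05, at most 500 epochs), with the held-out verification
fold used only for early stopping (patience 20, best-epoch weights
restored) — never for weight updates. These hyper-parameters are
conventions of this implementation, exposed on `NetworkSpec`.

The committee trains one member per fold of each of 50 independent
random 10-fold plans (500 members; a plan leaving any fold single-class
is re-drawn and logged). Standardization parameters are fitted once on
the training phase and frozen. The committee vote is the arithmetic mean
of all members' outputs; classification calls HCC strictly above the
0.5 threshold, ties to control. Out-of-fold votes (each sample averaged
over the members whose verification fold contained it) are used for
honest training-phase evaluation. Blind prediction applies the frozen
committee to a new cohort and refuses any sample ID seen in training.
Models serialize to JSON losslessly, so blind predictions reproduce
bit-for-bit after a round trip.

## Evaluation

AUC is the Mann–Whitney pair-counting probability (ties ½). The AFP
detector calls positive strictly above 400 ng/mL; the AFP-negative
subgroup is AFP < 20 ng/mL (strict). The AFP+ANN combination — not
uniquely determined by convention — is a logistic model over
(log1p(AFP), vote), standardized, fitted on the training phase and
applied frozen; log1p tames AFP's heavy tail. An OR-rule (positive iff
either detector positive) is available for sensitivity analysis.
Stratified reports cover case strata (all, AFP−, HBsAg±, BCLC 0/A, B, C)
against each control comparison; empty strata yield rows with counts and
NA metrics so table shapes are stable.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
starting at spot medians (no image simulation):

* background medians are gamma-distributed (shape 4, scale 50) —
  right-skewed and strictly positive, like scanner intensities;
* latent log-SNR is normal: protein baseline (mean 0.3, SD 0.2 across
  proteins) + sample effect (SD 0.5) + spot noise (SD 0.05), and
  foreground = background × exp(latent), so the observed ratio recovers
  the latent SNR;
* a minority of informative proteins gains a log-scale shift
  `effect_size` in HCC and `effect_size × cirrhosis_leak` in cirrhotic
  samples, in the IgG channel only by default (which channel the
  focused-array analysis used is not knowable; both are generated);
* serum AFP in HCC is a two-component log-normal mixture
  (weight 0.385 on LN(ln 1000, 1.2), rest LN(ln 15, 0.8)), giving
  ≈ 30% above the 400 ng/mL cutoff and ≈ 40% below 20 ng/mL — a single
  component cannot produce both an AFP-high and an AFP-negative
  subpopulation; controls draw from low log-normals;
* HBsAg is positive in 70% of HCC (85% of cirrhotic, 2% of healthy) and
  BCLC stages follow (0, A, B, C) = (0.06, 0.44, 0.26, 0.24);
* defaults: 282 HCC / 130 cirrhotic / 164 healthy (test phase), 100
  printed proteins, 7 informative at effect 0.35 (standardized d ≈ 0.7
  per marker, fold change ≈ 1.4; seven independent such markers imply an
  oracle panel AUC Φ(0.7·√7/√2) ≈ 0.90, the scale reported for real
  HCC autoantibody panels), cirrhosis leak 0.3 (so the cirrhotic
  contrast is harder than the healthy one).

Per-sample RNG streams derive from (master seed, group, index), so
enlarging one group never perturbs existing samples, and the printed
array structure (baselines, informative set) has its own `array_seed` so
phases profiled on the same arrays share it. Replicate scans of one
sample share its latent vector and differ only by per-protein array
noise whose SD is solved in closed form from the jointly log-normal
correlation identity to hit a target linear-scale Pearson r (0.95 by
default).

What the generator does **not** emulate: spatial artefacts and gridding
errors, batch/site effects, antibody cross-reactivity, correlated marker
modules (informative effects are independent given the group), and
covariate-dependent effects (stage and HBsAg do not modulate marker
shifts). Passing tests therefore demonstrate correctness and
recoverability of the algorithms under the stated model, not performance
on real serum data, whose headline AUCs are not reproducible from
published information.

## Problem sizes used in the checks

The simulation-backed checks run at desk scale: the null filter rate
uses 200 proteins × 50/group × 100 seeds; panel recovery plants 7
markers at log-effect 0.5 (FC ≈ 1.65, comfortably above the 1.2 filter
cutoff, as a recoverability study requires) on a 100-protein array with
250 HCC vs 125 + 125 controls over 20 seeds; the committee-vs-oracle
comparison trains 50-member committees (10 folds × 5 repeats) on
independent Gaussian markers over 10 seeds. The bundled quickstart
config uses a larger planted effect (0.7) at 60/30/60 scale so the
filter → consensus funnel stays populated in a demonstration-sized
cohort.

## Known limitations

* The per-fold differential screen inside cross-validation is re-run on
  training data only, but all folds come from one cohort; consensus
  membership is still an in-cohort statistic, which is why the blind
  validation phase exists.
* Stepwise selection inherits the usual instabilities near the filter
  cutoffs; markers whose true fold change sits at the 1.2 boundary pass
  each fold with ~50% power and rarely survive the all-fold
  intersection.
* The committee is deliberately faithful to the described procedure
  (plain gradient descent, fixed small architecture); it is not a
  competitive modern classifier and no hyper-parameter search is
  performed.
* GPR parsing covers only the simplified tab-delimited dialect defined
  here, not the full GenePix format.
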