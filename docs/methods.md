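# Methods

`hepasafe` predicts a patient-specific *safe resection volume* (mL) for
right hemi-hepatectomy from 23 preoperative features, using a residual
regression network trained with an asymmetric loss, and evaluates
predictors with safety-oriented cross-validated metrics. This note records
the model, the defaults and why they are set as they are, what the
synthetic cohorts do and do not emulate, and the numerical choices.

## Clinical scores

Three liver-function scores are computed from the labs and fed to the
model as features:

* **MELD** `= 3.78 ln(TB) + 11.2 ln(INR) + 9.57 ln(Cr) + 6.43` with TB and
  Cr in mg/dL. The bare formula is the default; the conventional clamp of
  each input to ≥ 1 is available via `clamp=True` (with it, the score
  floors at 6.43).
* **ALBI** `= 0.66 log10(TB µmol/L) − 0.085 · albumin(g/L)`, on the
  original unit convention. Records store TB in mg/dL and albumin in g/dL
  (the units labs report in this setting); conversion (×17.1, ×10) happens
  inside `derive_scores`.
* **APRI** `= (AST/40 × 100) / PLT(10⁹/L)`, reference AST 40 U/L (upper
  normal limit).

**PHLF** is defined by the 50-50 criteria: PT < 50 % *and* serum bilirubin
> 50 µmol/L on postoperative day 5, both inequalities strict, so boundary
values classify as no-PHLF.

Volumetry ratios, for a right hemi-hepatectomy where the left hemi-liver
is the remnant: `FLR% = 100·Lt/(Lt+Rt)` and `RLWR% = 100·Lt/(weight·1000)`
(1 mL liver ≈ 1 g).

## Feature vector

The canonical input is 23 features: age, sex (male=1), BMI, ASA class
(integer 1–3), five comorbidity flags, nine labs (WBC, neutrophils, PLT,
INR, PT%, TB, AST, ALT, Cr, HS-CRP), the three derived scores, and the
left-lobe volume. Diagnosis is collected but excluded. Right-lobe volume,
FLR% and RLWR% are deliberately left out: together with the left-lobe
volume they nearly determine the resected volume in a right
hemi-hepatectomy, so including them leaks the label. The list is a
configuration item (`feature_names`) so other subsets can be evaluated.

## Weighted liver loss

Under-predicting the safe volume risks leaving diseased tissue behind;
over-predicting errs toward a conservative margin. The loss therefore
weights squared errors asymmetrically:

    L = (1/N) Σᵢ (wᵢ·SEᵢ + SEᵢ),  SEᵢ = (ŷᵢ − yᵢ)²,
    wᵢ = under_penalty if ŷᵢ < yᵢ else over_penalty

Ties take the over branch; the same convention defines "over-predicted" in
the evaluation metrics. Defaults are `under_penalty=10`, `over_penalty=1`
— values expressing a strong clinical asymmetry; they are configuration,
not estimates. An optional term `log_coeff·log(1 + eᵢ)` for over-predicted
samples (default coefficient 0) additionally penalizes very large
over-predictions.

A useful way to think about the loss: with penalties (u, o) the population
minimizer of `Σ (w+1)(ŷ−y)²` at a given x is the **expectile** of y | x at
level `(u+1)/((u+1)+(o+1))` — 11/13 ≈ 0.85 at the defaults — which sits
above the conditional mean whenever the residual distribution has spread.
This is precisely the mechanism by which the trained model over-predicts
more often than an MSE-trained twin.

## Network and training

Architecture (input 23 → output 1): affine + ReLU to width 64; residual
block (64); expand to 128 + ReLU; residual block (128); shrink to 64 +
ReLU; residual block (64); shrink to 32; residual block (32); shrink to
16; affine to 1. A residual block of width d is two affine d→d maps with a
ReLU between them, an identity skip added to the second map's output, and
a final ReLU. Widths are configurable; the defaults above give ≈ 72k
parameters. Implementation is plain NumPy with hand-derived backprop
(verified against finite differences in the test suite) — the problem
sizes make GPU frameworks unnecessary.

Training defaults: full-batch Adam, learning rate 1e-3, 500 epochs,
z-scored inputs *and* targets using training-fold statistics only (no fold
leakage; predictions are mapped back to mL). Two regularizers are part of
the default configuration and matter a great deal at this sample size:

* **Dropout 0.2** after each stage-level ReLU. With ~50 patients and tens
  of thousands of parameters, unregularized Adam drives the training loss
  to exactly zero within ~100 epochs; once the model interpolates its
  training targets, the choice of loss function no longer influences the
  fitted regression and the asymmetric loss is inert. Dropout keeps
  training residuals alive throughout, so the loss keeps pulling the fit
  toward its upper expectile. Masks are drawn per epoch at the *unit*
  level, shared across the batch — this preserves exact invariance of
  full-batch training to sample order. With dropout on, the MSE-trained
  network's training loss plateaus near the synthetic task's irreducible
  noise level (≈ 0.6 of target variance) instead of 0, i.e. it estimates
  rather than memorizes.
* **Decoupled weight decay 3e-3** on weights only. Biases are exempt, as
  is conventional; decaying the output bias would also directly fight the
  upward shift the asymmetric loss is designed to produce.

Divergence (non-finite loss) raises an error naming the epoch. Training is
deterministic under a fixed seed and single-threaded BLAS; `epochs=0`
returns the initialized network untouched.

The supervision target is the *actually resected volume*. In the synthetic
cohorts, PHLF patients' recorded resections are known over-resections; a
sensitivity switch could cap their labels at the generator truth, but the
default keeps the realistic (biased) labels.

## Synthetic cohorts

The generator emulates the published summary structure of a 52-patient
right-hemi-hepatectomy cohort: per-group (PHLF n=6 / non-PHLF n=46)
medians and ranges for each lab and volumetric variable, PHLF prevalence
6/52, and comorbidity/sex/ASA/diagnosis prevalences from the published
counts (for HBV the running-text counts, 4/6 and 8/46, which are the ones
consistent with the published univariate odds ratio).

Each continuous variable is drawn from a log-normal truncated to the
printed (low, high) range. The log-scale spread is set so the printed
range covers the central 99 % of the untruncated distribution, and the
location is solved (Brent's method on the truncated CDF) so the *truncated*
median equals the printed median exactly — the truncated median is
monotone in the location, so the root is unique. Calibration therefore
holds by construction for every sampled variable; the test suite verifies
sample medians within 5 % at n = 20 000 and ≥ 99 % of samples in range.
Two required fields lack published rows: body weight (median ≈ 65–67 kg,
backed out of the published Lt-volume and RLWR medians) and albumin
(normal clinical range, medians 3.9/4.1 g/dL).

APRI, ALBI and MELD are *derived* from the drawn labs, never sampled, so
they are internally consistent and carry realistic correlation with their
inputs. A corollary: their medians (and those of FLR%/RLWR%) are *not*
calibrated to the printed score medians — medians do not compose through
nonlinear formulas, and score agreement with the published rows is
qualitative only. Beyond score derivation, labs are sampled independently
within group; no published covariance exists to emulate. The generator
also does not emulate longitudinal labs, measurement error in CT
volumetry, or site effects — passing tests say nothing about those.

Ground-truth label rule (a stand-in for the surgical record):

    required_flr = clip(0.40 + 0.05·L, 0.05, 0.90)
    L = (z_APRI + z_MELD − z_PLT)/3      (fixed documented constants)
    true_safe  = (Lt + Rt) · (1 − required_flr)

with z-constants (centers 0.5, 0, 225; scales 0.5, 4, 70) chosen near the
non-PHLF medians and spreads, so a typical patient needs ≈ 40 % remnant
and worse liver function monotonically lowers the safe volume. Non-PHLF
patients' recorded resection is `true_safe + N(0, 30 mL)`; PHLF patients
were over-resected by construction: `true_safe·1.10 + |N(0, 30)|`. The
base 0.40 and slope 0.05 give resected volumes centred near the published
right-lobe volumes; noise 30 mL reflects the volumetry-vs-specimen
discrepancy one expects clinically.

## Evaluation

Shuffled K-fold cross-validation (default K=5; at n=52 the fold sizes are
11, 11, 10, 10, 10; every sample is validated exactly once). Per fold:

* **P** = 100 · #{ŷ ≥ y}/n — percentage predicted at or above the
  reference (the "safe side");
* **U** (**O**) = mean |ŷ − y| over under- (over-)predicted cases, in mL.

An empty under/over set reports 0 with an explicit emptiness flag rather
than NaN, keeping cross-fold averaging stable. Metrics are averaged across
folds (the pooled-over-all-validation-predictions variant is also
reported). The identity `n·MAE = under_count·U + over_count·O` holds
exactly per fold and is asserted in tests.

`compare_models` repeats the whole K-fold procedure over several seeds
(reshuffling folds and reseeding models) and runs a one-way ANOVA per
metric across models, with the per-seed mean as the unit of replication —
chosen because fold-level values within a run are not independent. Paired
per-seed sign tests back the pairwise claims; no distributional assumption
is made about per-seed metric differences.

The univariate odds-ratio utility implements the cross-product OR with a
Wald log-scale 95 % CI, a Haldane 0.5 correction flag for zero cells, and
an orientation flag returning the reciprocal (the published table reports
exposure-oriented ORs below 1).

## Numerical choices

* Tie ŷ = y goes to the over branch everywhere (loss weight and P metric).
* The MAE subgradient at 0 is taken as 0; the Huber comparator uses δ=1 on
  the standardized scale.
* Lab draws use inverse-CDF sampling of the truncated normal on the log
  scale (no rejection loops), so cohorts are deterministic under a seed
  and two seeds differ with probability ~1.
* Checkpoints are versioned JSON (self-describing header + parameter
  payload); shape mismatches on load are rejected.
* Cohort CSVs are read with round-trip float precision so
  write→read is the identity on records.

## Limitations

* The headline comparisons hold on synthetic cohorts whose label rule is
  an explicit stand-in; nothing here validates the method on real surgical
  outcomes.
* The expectile shift the loss produces depends on the model *estimating*
  rather than interpolating; with regularization disabled the asymmetric
  and symmetric losses become indistinguishable at this sample size.
* The 23-feature list is one consistent resolution of an under-specified
  design space; alternates can be passed via `feature_names`.
* ANOVA across models uses per-seed means as replicates; other choices of
  replication unit would change the F statistics.
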