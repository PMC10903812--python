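# Methods

## The model

`cmrsurv` implements a multi-input neural proportional-hazards model for
time-to-first major arrhythmic event (MAE) in dilated cardiomyopathy at
desk scale. Each patient contributes four imaging families — a 4D cine
short-axis hypervideo (H×W×slices×phases), three 3D cine long-axis
videos, a 3D LGE short-axis hyperimage and three 2D LGE long-axis
images — plus a baseline clinical covariate vector. A three-branch
network maps these to a single unbounded scalar x, the log-relative
hazard in

    h(t | x) = h0(t) · exp(x).

Training maximizes the Cox partial likelihood, so the network never sees
absolute event rates, only the ordering of failures within risk sets.
After training, the cumulative baseline hazard H0(t) is estimated by the
Breslow step-function estimator on the fitted scores and each patient's
survival curve is S(t | x) = exp(−H0(t)·eˣ). Discrimination is reported
as Harrell's C per split and as AUROC for the binary outcome "event
within τ" at τ = 12, 24, 36, 60 and 96 months, scored by 1 − Ŝ(τ | x).

## Input homogenization

Slice and frame counts vary per patient (retrospective acquisitions), so
bundles are padded — never resampled — to cohort-wide maxima: zeros
("null" frames/slices) appended at the high end of each axis, with binary
validity masks recording which entries are real. The three long-axis
planes are appended as three extra slice positions after the short-axis
stack, giving one fixed-shape tensor per modality. Conventions we fixed
where the choice was genuinely open: null value 0.0; origin-anchored
placement (keeps spatial correspondence trivial); slices ordered
base→apex; time origin at the first stored frame; RGB→gray by unweighted
channel mean (sources are grayscale stored as RGB, so conventions
coincide); intensities divided by 255 with no histogram processing. All
conventions are recorded in the container sidecar. Padded entries are
passed to the network as zeros without recurrent masking; masks are
retained in the container so masking can be added later.

PNG/AVI are ingest formats only; the canonical on-disk form is a
compressed array container with a JSON sidecar. Video I/O is a
self-contained uncompressed RIFF/AVI reader-writer (8-bit palettized or
24-bit BI_RGB), which makes encode/decode round trips bit-exact and keeps
tests independent of any codec stack.

## Network architecture

Cine branch: slices (plus the three long-axis planes) are folded into
channels and a two-layer ConvLSTM (8 then 16 filters, 3×3 kernels) runs
over the phase axis; the final hidden state summarizes motion. The
alternative — 3D-kernel ConvLSTM over (slice, H, W) — is noted as a
possible variant but not implemented at desk scale. LGE branch: two 3×3
conv layers (8, 16 filters). The two maps are concatenated into a shared
two-layer conv trunk (16, 16) with 2×2 max-pooling, globally average
pooled and projected to a width-8 embedding. Covariate branch: two dense
blocks of width 8. The width-8 image and covariate embeddings are
concatenated (width 16) and a dense head ends in a single linearly
activated node — x. After every learned layer: batch normalization, an
L2 activity penalty (1e-4, applied uniformly to every layer) and dropout
(0.2). Every such number lives in `NetworkConfig`, not in code.

The network core is a compact numpy implementation with hand-written
backward passes (im2col convolutions, full backpropagation through time
in the ConvLSTM), sized for cohorts of tens to hundreds of patients; an
exact finite-difference gradient audit is part of the test suite.
Training is full-batch Adam: with full batches the partial likelihood's
risk sets are exact rather than within-minibatch approximations, and runs
are bit-reproducible given the seed. The default step size is 1e-2: with
only 30 full-batch updates in the two-stage protocol, smaller steps leave
the image branches essentially at initialization (training curves confirm
this), so the default is chosen for the protocol's short budget rather
than for long-horizon training.

## Survival conventions

The source description states no tie rule, so we declare one: Breslow
ties everywhere (loss, baseline), for internal consistency between the
training target and the baseline estimator. Risk sets use t_j ≥ t_i. The
loss is averaged over events so learning-rate semantics are independent
of cohort size. Harrell's C counts pairs (t_i < t_j, event_i = 1) plus
tied-time pairs with exactly one event; tied scores count ½. Its standard
error is the Hanley–McNeil (Noether-type) pair-statistic estimator with
group sizes taken as the numbers of subjects appearing on the earlier
and later side of comparable pairs; the primary interval is C ± 1.96·se,
and a C ± SD interval is also exposed because some reports print that
convention. Horizon AUROC excludes subjects censored event-free before
the horizon; no inverse-probability-of-censoring weighting (out of
scope, as is competing-risk modelling).

## Split and training protocol

30% of patients (nearest-integer rounding) form the test set; 30% of the
remainder the validation set — 154 patients split 76/32/46. Stage 1
trains 5 epochs on the training split, monitoring validation; stage 2
continues 25 epochs on train+validation, monitoring the held-out test
split. Monitoring is logging only: no early stopping or selection ever
reads the monitored split, which avoids institutionalizing test-set
leakage while still producing the full 30-epoch learning curves. The
covariate encoder (5 standardized continuous — NT-proBNP on the log
scale, the conventional transform for a right-skewed natriuretic
peptide — 11 binary, smoker and NYHA one-hot; train-split medians/modes
for imputation) is refit at the stage boundary: train-only statistics in
stage 1, train+validation in stage 2, both SHA-fingerprinted so leakage
audits are mechanical.

## The synthetic cohort generator

The generator emulates the *statistical* structure of a DCM imaging
cohort, not its anatomy. Cine studies: an annular "myocardium" whose
inner radius follows r(t) = r0·(1 − a·sin²(πt/T)); the amplitude a is
the contractility surrogate and 1 − a raises the true log-risk. LGE
studies: the same annulus with a hyperintense arc spanning the angular
fraction ℓ of the ring — the scar surrogate. Covariates are drawn from
distributions matched to published DCM cohort statistics (age ~ N(48, 13)
years, 70% male, NT-proBNP log-normal with median 923 pg/l, NYHA
frequencies 56/9/32/3%, ...). Event times follow a Weibull
proportional-hazards model with inverse-transform sampling on the true
log-risk η = β_amp·((1−a)−c̄) + β_scar·(ℓ−c̄) + β_covᵀz (contributions
centred at their generator means so the baseline rate describes a
typical patient), uniform loss-to-follow-up censoring on (0, 120]
months, and administrative censoring at 96 months. The default monthly
baseline rate 0.006 yields roughly one third observed events — higher
than the ~15% of a real DCM cohort, a deliberate choice so desk-scale
cohorts contain enough events to fit survival models — while censor_max
= 120 reproduces a median follow-up near 60 months. Non-MAE censoring
reasons (death/transplant/LVAD/lost) are drawn with fixed proportions.

The `strong_signal` configuration (β_amp = β_scar = 5, covariate effects
0.5/1.5/1.0 on standardized age/log NT-proBNP/NYHA) was sized
analytically so the generating mechanism's own pairwise concordance,
E[σ(|Δη|)] under proportional hazards, is about 0.9 — the ceiling any
fitted model is measured against.

What the generator does **not** emulate: MR physics, anatomical
variability, registration error, segmentation ambiguity, informative
censoring, or covariate-imaging correlation beyond the shared hazard.
Passing tests therefore demonstrate that the pipeline recovers a known
risk signal from heterogeneous multimodal input at realistic sample
sizes — not that it would attain comparable discrimination on clinical
data.

## Problem sizes

The package targets desk scale by design: 16×16 pixels, 4–6 slices,
8–10 phases, cohorts of 60 (end-to-end image runs) to 400 patients
(covariate-only recovery, ground-truth concordance), and the 5+25-epoch
protocol. The end-to-end check trains the full three-branch network on a
60-patient strong-signal cohort and asserts test-split concordance above
0.65 — well below the ~0.9 generative ceiling, reflecting that an
18-patient test split is a noisy instrument.

## Numerical choices and degenerate inputs

Partial likelihood uses log-sum-exp over suffix risk sets; zero events
is a defined error, as are undefined concordance (no comparable pairs)
and undefined horizon AUROC (no positives or no negatives at τ), which
the evaluation report propagates as named nulls. All-tied risk scores
stratify every patient to "high" with a warning. The log-rank statistic
uses the variance pseudo-inverse, so co-linear group margins cannot
crash the test. Batch normalization: momentum 0.9, eps 1e-5; inference
uses running moments, making reports regenerable bit-identically from a
checkpointed model.

## Known limitations

No competing risks (cause-specific hazard only), no IPCW metrics, no
recurrent masking of padded frames, no DICOM ingestion or segmentation,
no hyperparameter search. The two-stage protocol's stage-2 monitoring of
the test split is reproduced as logging only; the original wording could
be read as validating on test, which we deliberately do not do.
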