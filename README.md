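# cmrsurv

Neural Cox survival modelling for cardiac magnetic resonance at desk
scale: from heterogeneous cine/LGE image stacks plus clinical covariates
to per-patient survival curves for major arrhythmic events (MAE) in
dilated cardiomyopathy.

## Who this is for

Researchers prototyping image-based arrhythmic-risk models who need the
full pipeline — ingest, homogenization, a multi-input network, the Cox
survival machinery and censoring-aware evaluation — in a form that is
small, fully deterministic, and testable without any patient data: a
bundled synthetic cohort generator provides imaging-survival cohorts
with known ground-truth risk.

## The model

Each patient i contributes a 4D cine short-axis hypervideo, three 3D
cine long-axis videos, a 3D LGE short-axis hyperimage, three 2D LGE
long-axis images, and a covariate vector z_i (age, sex, anthropometrics,
risk factors, familial history, creatinine, NT-proBNP, NYHA class,
rhythm). A three-branch network — ConvLSTM over the cardiac cycle for
cine, a CNN for LGE, dense blocks for covariates, merged through width-8
embeddings — emits one scalar x_i, the log-relative hazard of the
proportional-hazards model

    h(t | x_i) = h0(t) · exp(x_i),

trained by the negative log Cox partial likelihood (Breslow ties).
The Breslow estimator of the cumulative baseline hazard H0(t) then gives
patient-specific curves S(t | x_i) = exp(−H0(t)·e^{x_i}). Evaluation:
Harrell's C (with standard error and 95% CI) per split, AUROC for
"event within τ" at τ = 12–96 months from 1 − Ŝ(τ | x), Kaplan–Meier
curves, K-sample log-rank tests, and median-risk stratification.
Cohorts follow a 70/30 train+validation/test split (154 patients →
76/32/46) and a two-stage 5 + 25 epoch protocol. See `docs/methods.md`
for conventions and design choices.

## Worked example

```python
from cmrsurv import SimParams, generate_cohort
from cmrsurv.pipeline import SplitSpec, run_two_stage_training, evaluate_report

params = SimParams.strong_signal(n=60, seed=7)   # 16x16, 4-6 slices, 8-10 phases
bundles, covariates, followup, truth = generate_cohort(params)

result = run_two_stage_training(bundles, covariates, followup,
                                SplitSpec(seed=7), seed=7)
report = evaluate_report(result, bundles, covariates, followup)

log = result.log
print(f"train loss epoch 1 -> 30: "
      f"{log.train_loss.iloc[0]:.3f} -> {log.train_loss.iloc[29]:.3f}")
for split in ("train", "validation", "test"):
    c = report["splits"][split]["concordance"]
    print(f"{split:>10}: C = {c['harrell_c']:.3f} "
          f"(95% CI {c['ci_low']:.3f}-{c['ci_high']:.3f})")
```

prints

```
train loss epoch 1 -> 30: 3.353 -> 2.677
     train: C = 0.908 (95% CI 0.789-1.000)
validation: C = 0.905 (95% CI 0.714-1.000)
      test: C = 0.789 (95% CI 0.599-0.979)
```

The training loss (mean negative log partial likelihood) falls over the
30-epoch protocol; concordance on the 18-patient held-out test split is
0.79 against the cohort's generative ceiling of ≈0.9 — the network has
recovered most of the planted motion/scar/covariate risk signal from
pixels. `report` also carries per-patient survival curves, horizon
AUROCs, Kaplan–Meier curves and log-rank tests, and
`result.log` is the 30-row learning curve.

A CLI wraps the same flow: `cmrsurv simulate`, `cmrsurv run --seed 7
--out results/`.

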