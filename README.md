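# crcal — calibration of competing-risk prediction models

Clinical prediction models for time-to-event outcomes often face *competing
risks*: events whose occurrence precludes the event of interest (a patient
who dies of non-cardiovascular causes can no longer die of cardiovascular
ones).  In that setting the quantity a model predicts is the cumulative
incidence function, F₁(t₀ | **X**) — the probability of the primary event
before a horizon t₀, accounting for the competing event — and standard
calibration tools for binary or ordinary survival outcomes do not apply.

`crcal` assesses the **calibration** of any such model — the agreement
between predicted and observed risk — graphically and numerically:

1. Take each subject's predicted risk Î = F₁(t₀ | **X**) from the model
   under assessment (Fine-Gray, cause-specific hazards, a random survival
   forest — anything that outputs a cumulative incidence).
2. Fit a *secondary* Fine-Gray subdistribution hazard model regressing the
   primary event on a restricted cubic spline (default 3 knots, at the
   10th/50th/90th percentiles) in log(−log(1 − Î)), the complementary
   log-log of the predicted risk.
3. The secondary model's predicted incidence at t₀, Îˢ, is the *smoothed
   observed risk* at each predicted risk.  Plotting Îˢ against Î gives the
   calibration curve; deviations from the diagonal are miscalibration.
4. Summarize with the integrated calibration index and its companions over
   the sample: **ICI** = mean |Îˢ − Î|, **E50** / **E90** = median / 90th
   percentile of |Îˢ − Î|, and **Emax** = max |Îˢ − Î|.

The Fine-Gray engine is fit by inverse-probability-of-censoring-weighted
risk-set expansion (subjects with a competing event remain at risk with
weight G(s−)/G(Tᵢ−), G the reverse Kaplan-Meier censoring survival) and a
weighted Cox partial likelihood with a Breslow baseline.  The package also
ships the competing-risk simulator and the six Monte Carlo study designs
used to validate the method, a decile-binned comparator, and Kaplan-Meier /
Aalen-Johansen estimators.

## Worked example

```python
import numpy as np
from crcal import generate, fine_gray, predict_cif, calibration_curve
from crcal.simulate import DGPConfig

data = generate(DGPConfig(n=4000, p=0.5, beta1=1.0, beta2=0.25, seed=7))
fit = fine_gray(data, ["x"])                       # model under assessment
t0 = float(np.median(data.time))
preds = predict_cif(fit, data.covariate_matrix(["x"]), t0)

result = calibration_curve(data, preds, n_knots=3)
m = result.metrics
print(f"ICI={m.ici:.4f}  E50={m.e50:.4f}  E90={m.e90:.4f}  Emax={m.emax:.4f}")
```

prints

```
ICI=0.0021  E50=0.0022  E90=0.0034  Emax=0.0050
```

The predictions were produced by a correctly specified model on its own
sample, so the smoothed observed risk differs from the predicted risk by
only ~0.2 percentage points on average — essentially perfect calibration.
Refitting with a quadratic data-generating process while the model keeps
only the linear term (`examples/03_detect_misspecification.py`) inflates
the ICI about a hundredfold, which is how the metric flags
mis-specification.  The `examples/` directory walks through simulation and
fitting, calibration assessment, mis-specification detection, and a small
Monte Carlo study.

A thin CLI mirrors the library for shell use:

```sh
crcal simulate --n 2000 --p 0.5 --beta1 1 --censoring 0.2 --seed 1 --out cohort.csv
crcal calibrate --data cohort_with_preds.csv --pred-col pred --time 1.0 \
      --metrics-out metrics.json --curve-out curve.csv
crcal study --name quadratic --scale desk --seed 1 --out study_out/
```

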