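# breathdx

Breath-VOC and capnogram analysis for non-invasive asthma screening.

Exhaled breath carries volatile organic compounds (VOCs — isoprene, acetone,
ethanol, …) whose abundances shift with airway inflammation, and the CO₂
capnogram changes shape with airway obstruction: healthy breaths show a
square/trapezoid waveform with a flat end-tidal plateau, obstructed airways
a rising "shark-fin". `breathdx` is a toolkit for researchers working with
multi-channel breath-sensor records (13 waveforms per exhalation: CO₂, total
and named VOC channels, flow, temperature, humidity, pressure) who want to

- **simulate** labeled cohorts with realistic class structure when device
  data cannot be shared,
- **preprocess** the waveforms: standardization, end-tidal plateau
  detection, scalar breath features (VOC maximum, VOC plateau width, CO₂
  end-tidal level/slope, upstroke angle, …) and PCA,
- **deconvolve** composite VOC profiles into Gaussian components ("orders")
  and quantify asthmatic-vs-control differences, and
- **classify** subjects with an attention/capsule neural network trained
  under a leakage-safe, subject-level protocol.

## The model

A VOC profile is modeled as a sum of Gaussian orders plus baseline,

```
y(t) = Σₒ Aₒ · exp(−(t − μₒ)² / (2σₒ²)) + c + ε,
```

fit by bounded nonlinear least squares with incremental residual-peeling
initialization. Each order is summarized by amplitude A, mean μ, SD σ and
FWHM = 2√(2 ln 2)·σ ≈ 2.3548·σ; groups are compared per order/metric by the
percent difference 100·(A − NA)/NA of class means.

The classifier (ADENA — an asthma-diagnosis network) stacks, for a 1-D
input x:

1. convolution blocks  `x' = ReLU(w * x + b)`;
2. squeeze-and-excitation channel gating — squeeze `z_c = mean over
   positions of channel c`, excitation gates `E = σ(W₂ · δ(W₁ z))` applied
   multiplicatively per channel;
3. a residual-attention mask `RA = M(E) ⊙ E` (variant `(1 + M(E)) ⊙ E`
   available);
4. capsule-style dynamic routing by agreement with the squash
   nonlinearity `v = (‖s‖²/(1+‖s‖²)) · s/‖s‖`;
5. a stochastic-depth-wrapped dense layer, spatial dropout (training only),
   spatial average pooling, and a sigmoid head giving P(asthmatic) ∈ (0, 1).

Training minimizes the combined objective

```
L = L_focal + L_BCE,   L_focal = −(1 − p_t)^γ · log p_t   (γ = 2 default),
```

with Adam. The network runs on a small in-repo reverse-mode autodiff engine
(`breathdx.nn.autodiff`, numpy float64); every block's analytic gradient is
verified against central differences in the test suite.

Evaluation: MSE, F1, accuracy, ROC/AUC (rank statistic, ties ½), a 60/30/10
train/validation/test split, stratified subject-level 5-fold
cross-validation (triplicate measurements of one subject never straddle a
fold boundary), hyperparameter grid search, and a comparison harness over
standard sklearn baselines (SVM, kNN, logistic regression, MLP, decision
tree, naive Bayes).

## Worked example

```python
import numpy as np
from breathdx.synthcohort import CohortSpec, generate_cohort
from breathdx.pipeline import deconvolve_cohort
from breathdx.traineval import TrainConfig, cross_validate

spec = CohortSpec(n_asthmatic=20, n_control=25, age_group="adult", seed=3)
records = generate_cohort(spec)          # 45 subjects x 3 replicates

_, comparison = deconvolve_cohort(records, seed=0)
print(comparison.percent_differences.round(2))

reports = cross_validate(
    records, k=5,
    train_config=TrainConfig(learning_rate=5e-4, epochs=30, batch_size=4, seed=0),
)
print("5-fold accuracy:", round(float(np.mean([r.accuracy for r in reports])), 3))
print("5-fold AUC:     ", round(float(np.mean([r.auc for r in reports])), 3))
```

Output:

```
   amplitude   mean      sd    fwhm
0    1459.22  33.65  502.08  502.08
1     204.91   7.45  -13.80  -13.80
2      19.42   9.71   44.09   44.09
5-fold accuracy: 1.0
5-fold AUC:      1.0
```

The percent-difference table has one row per Gaussian order: on this noisy
45-subject cohort the asthmatic group shows the expected strongly elevated
order-0/order-1 amplitudes and a moderate (~20%) order-2 amplitude excess;
the tiny sub-noise components inflate the order-0 SD/FWHM contrast. The
classifier separates the two groups perfectly on held-out subjects — the
table-derived class profiles differ strongly, so a clean simulation is an
easy classification problem.

The same stages are scriptable from a shell:

```
breathdx simulate --n-asthmatic 20 --n-control 25 --age-group adult --seed 3 --out cohort/
breathdx validate --data cohort/
breathdx deconvolve --data cohort/ --out reports/
breathdx cv --data cohort/ --out reports/ --k 5
breathdx run --out full_run/        # simulate -> ... -> evaluate, one manifest
```

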