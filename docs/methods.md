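# Methods

## Scope and data model

`breathdx` operates on per-subject exhalation records: 13 time-sampled
waveform channels (`co2`, `voc_total`, `isoprene`, `acetone`, `ethanol`,
`nox_proxy`, `flow`, `temperature`, `humidity`, `pressure`, `voc_aux1..3`),
a binary asthma label, an adult/pediatric age-group tag, and triplicate
measurements per subject. Real breath-sensor data of this kind are
proprietary, so the package ships a simulator whose defaults encode the
class structure reported for such cohorts; all downstream stages are
developed and tested against it.

## Synthetic cohorts (`synthcohort`)

**VOC profiles.** The composite `voc_total` trace is a sum of three Gaussian
components on a pseudo retention axis spanning 0–40 retention units,
`y(t) = Σₒ Aₒ exp(−(t−μₒ)²/2σₒ²) + baseline + noise`. The default
class-conditional (A, μ, σ) triplets are the published adult and pediatric
deconvolution-table values (`breathdx.tables`), taken verbatim — including
their oddities (a pediatric asthmatic amplitude of 6.02e-10, an SD of
42.11). Named VOC channels carry single orders with fixed response factors
(isoprene ← order 0, acetone ← order 1, ethanol ← order 2); the aux channels
are scaled copies of `voc_total`.

**Capnograms.** Breath cycles of period 4 s at 25 Hz (defaults; 300 samples
= 3 cycles per record), phase fractions 10% upstroke / 50% expiration / 10%
downstroke / 30% inspiratory baseline. Controls produce a trapezoid whose
alveolar plateau sits exactly at the configured end-tidal level (5.0% CO₂);
asthmatics produce a shark-fin: the upstroke reaches only 30% of the
end-tidal level and the expiratory limb rises concavely
(`0.35u + 0.65(1−e^{−4u})/(1−e^{−4})`), reaching the end-tidal level (5.4%)
only at the final expiratory sample, with terminal slope ≈ 0.03 %CO₂/sample
— above the plateau detector's default tolerance by construction, so no
flat plateau exists. An `obstruction ∈ [0,1]` parameter interpolates the two
shapes.

**Other channels.** Flow is one bell per breath peaking at the
class-conditional peak expiratory flow (adult 450 vs 320 L/min, pediatric
250 vs 180); airway temperature is offset +0.5 °C and humidity −3 %RH for
asthmatics (direction from the inflammation physiology, magnitudes chosen
once as plausible); pressure oscillates breath-synchronously around
101.3 kPa with slightly larger swing under obstruction.

**Variability and noise.** Between-subject biological variability jitters
each subject's component parameters (amplitude CV 0.15, mean jitter SD 0.3
retention units, SD CV 0.10, lognormal/normal); within-subject replicate
variation is additive i.i.d. Gaussian sensor noise with SD =
`noise_scale ×` (clean channel dynamic range), `noise_scale = 0.05` by
default. These were fixed once as what a breath-sensing practitioner would
call realistic; they are parameters of `EffectProfile`, not tuning knobs.

**Effect dial.** `scale_effect(profile, s)` linearly interpolates every
asthmatic generating parameter toward the control value; `s = 0` makes the
classes identically distributed (used for null calibration), `s = 1` is the
table-derived difference.

**Determinism.** One integer seed feeds a `SeedSequence` tree (subject →
replicate), so a `CohortSpec` maps to a byte-identical cohort. Long-format
CSV + JSON sidecar round-trips losslessly (1e-9 relative) via `%.17g`.

**What the simulator does not model:** sensor chemistry, drift,
cross-sensitivity, breath-to-breath autocorrelation, missing data, or a
FeNO channel (the emulated platform does not measure FeNO). Consequently a
perfect classifier score on clean simulations demonstrates pipeline
correctness and protocol hygiene, not clinical performance.

## Preprocessing (`signalprep`)

Standardization is per-feature z-scoring; constant columns map to zeros
with a warning rather than aborting (synthetic edge cases shouldn't kill
pipelines), and the transform is idempotent.

End-tidal plateau detection smooths with a centered 5-sample moving
average, then finds runs where the absolute smoothed first difference stays
within `slope_tol` (default 0.01 units/sample) **and** the level is at least
half the smoothed maximum — the level gate stops the zero-CO₂ inspiratory
baseline from qualifying. The longest run ≥ `min_length` wins (ties: the
latest, i.e. terminal run); no run means no plateau, which is itself the
shark-fin signature.

Scalar features per record: VOC maximum; VOC plateau width (time spent at
≥ 50% of maximum — exactly the FWHM in seconds for a single noiseless
Gaussian); CO₂ plateau slope and end-tidal level (from the detector, with a
terminal-region fallback when no plateau exists); upstroke angle
(arctan of the maximum smoothed rise in %CO₂/s); mean and max of every
other channel. Replicates aggregate by the median — robust to one bad
exhalation. PCA (scikit-learn, full SVD) keeps the smallest number of
components reaching a cumulative explained-variance target (default 0.95,
fixed k overridable); for classification each kept score is weighted by its
explained-variance ratio so more informative components enter the model
with larger magnitude. Whether to feed the classifier raw waveform samples
or scalar features was genuinely open; scalar features are the default
(robust at small n), and `ADENA.forward` accepts raw `(B, C, L)` maps too.

## Deconvolution (`deconv`)

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trf) on
`n` Gaussians + constant baseline. Bounds: amplitudes ≥ 0, means within the
span ± 10%, SD ∈ [dt, span] (prevents degenerate spikes). Initialization is
incremental residual peeling: fit k−1 components, place component k at the
argmax of the residual with a half-max-width SD estimate, refit all — this
reliably digs out components orders of magnitude smaller than the dominant
peaks (the adult order-0 amplitude is 7.5e-6 of the signal maximum and is
still recovered to machine precision on noiseless input). Up to 5 jittered
restarts on failure; a fit that never converges returns
`converged=False` rather than raising. Emitted components are sorted by
mean and satisfy FWHM = 2√(2 ln 2)·σ exactly.

Group comparison averages each metric over subjects per class and reports
`100·(A − NA)/NA`; a zero control mean flags the cell as undefined (NaN),
never silently zero. FWHM cells average per-component FWHM values and are
cross-checked against the FWHM of the class-mean SD. Two table quirks are
handled explicitly rather than corrected: (i) the published tables' FWHM
columns are rounded, so components built from printed rows may carry a
verbatim FWHM that differs from 2.3548·σ in the third decimal —
`audit_table_fwhm` reports every cell violating the relation beyond 1%
(three pediatric cells fail: control order 0, asthmatic order 2, control
order 2); (ii) the pediatric asthmatic rows are not monotone in mean, so
table-derived comparisons keep the printed row order while fitted results
stay mean-sorted.

## Classifier (`nn`)

A minimal reverse-mode autodiff engine (float64 numpy) underlies the
network; analytic gradients of every op and block are pinned against
central differences at 1e-4 relative tolerance in the tests.

Architecture defaults (all overridable in `ModelConfig`): two stride-1
convolution blocks (16 and 32 filters, kernel 5, ReLU, same-padding);
squeeze-and-excitation with reduction 4; a 1×1-conv bottleneck attention
mask with the literal multiplicative form `M(E)⊙E` as default and the
residual `(1+M(E))⊙E` variant selectable; positions-as-capsules dynamic
routing into 8 capsules of dimension 8 with 3 routing iterations (logits
zero-initialized, coupling softmax over output capsules, squash, agreement
reinforcement — gradients flow through the unrolled loop); one
stochastic-depth-wrapped residual 1×1-conv dense layer (survival 0.8:
Bernoulli gate in training, deterministic scaling in eval); spatial dropout
(rate 0.2, whole channels, inverted scaling, training only); spatial
average pooling; a 32-unit hidden dense layer and a sigmoid output.

Two published ambiguities are kept as explicit config switches. The
excitation activations: the conventional gating `sigmoid(W₂·relu(W₁z))` is
the default because multiplicative gates must be bounded, while
`activation_order="relu_outer"` gives `relu(W₂·sigmoid(W₁z))`. The
attention form: `mask_product` vs `residual_mask` (intent unresolved in the
literature this follows; both are tested). The dense head consumes flattened
capsule outputs (fully-connected classification) rather than capsule norms;
dropout precedes pooling.

Loss: `L = L_focal + L_BCE` averaged over the batch, focal
`−(1−p_t)^γ log p_t` with γ = 2 by default (γ is exposed; γ = 0 collapses
the loss to exactly twice the binary cross-entropy). Probabilities are
clamped at ε = 1e-7 inside the logs.

## Training and evaluation protocol (`traineval`)

All splitting is subject-level: the 60/30/10 train/validation/test split
(largest-remainder apportionment gives exact sizes, stratified within one
subject per portion) and stratified k-fold CV (round-robin per class; 45
subjects → five folds of 9) partition subjects, never replicate rows, so a
memorizing model scores at chance on held-out folds — a property the tests
assert directly. How the 60/30/10 split interacts with 5-fold CV was left
open in the source protocol; here CV serves model/hyperparameter selection
on the train+validation pool and the untouched 10% yields the final report.

Training is Adam (β = 0.9/0.999) on the combined loss, seeded shuffling,
non-finite loss aborts with a diagnostic. Grid search scores each
(learning rate, epochs, batch size) combination by k-fold mean F1, ties
broken by lower mean MSE then fewer epochs; the default grids are the
historically explored values (5e-3, 1e-3, 1e-4, 1e-1, 1e-2; 200/500/1000
epochs; batch 2/4) plus the ultimately selected 5e-4.

Metrics: MSE `(1/N)Σ(y−p)²`; F1 from confusion counts with the TP = 0 → 0
convention; accuracy `(TP+TN)/total`; AUC via the Mann–Whitney rank
statistic with ties counted ½ (verified against brute-force pairwise
comparison and scikit-learn on every fixture); classification threshold
0.5, AUC threshold-free. Reference classifiers (SVM, kNN, logistic
regression, MLP, decision tree, naive Bayes) run with library defaults
under the identical fold protocol, failures recorded per model.

## Benchmark problem sizes and numerical choices

The packaged benchmarks (tests and `scripts/acceptance.py`) use sizes
chosen for a single-CPU desk run: a 200-subject cohort (100/100, adult
profile, 5% noise) for the classifier benchmark, trained per fold with the
selected learning rate 5e-4 and batch size 4 for 30 epochs — on the
low-dimensional PCA-weighted feature representation the loss plateaus well
within that budget; 100 three-component mixtures (parameters jittered
around the adult asthmatic table values: amplitude CV 0.1, mean SD 0.3, SD
CV 0.05; noise 1% of signal maximum) for deconvolution recovery, scoring
each true component against the nearest-mean fitted component so the
deliberately sub-noise order-0 amplitude (SNR ≈ 1e-6) does not poison the
matching; the median relative parameter error lands near 1.4%. The
null-effect calibration reuses the same machinery with the effect dial at
zero and checks the cross-validated AUC stays within 0.5 ± 0.1.

Headline device-cohort numbers (98.7% accuracy, AUC 0.98 and the
accompanying baseline table) belong to a proprietary clinical dataset and
are deliberately not claimed; the synthetic benchmark is a property-based
stand-in: near-perfect separation when the class structure is present,
chance when it is removed.

## Known limitations

- The simulator's independence assumptions (i.i.d. noise, independent
  channels given class) make the classification task easier than real
  breath data; performance numbers on it are upper bounds.
- Deconvolution of components below the noise floor is impossible in
  principle; such components are reported as fitted but their parameters
  are meaningless (the recovery benchmark's matching rule acknowledges
  this).
- The autodiff engine is intentionally minimal (no GPU, no broadcasting
  matmul beyond numpy semantics, stride-1 convolutions only); it is sized
  for the small models this package trains.
- `percent_difference` is asymmetric and explodes as the control mean
  approaches zero — values like the pediatric 11,838% are faithful
  arithmetic, not robust effect sizes; `fold_ratio` is provided alongside.
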