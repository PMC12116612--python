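# Methods

`semgcobb` models the prediction of radiographic scoliosis severity (Cobb
angle) and secondary clinical outcomes from paraspinal surface-EMG
recordings collected during isometric Schroth exercise holds.  Because no
patient-level dataset accompanies the study design it implements, the
package ships a synthetic cohort generator that reproduces the design and
the published cohort statistics, so the full pipeline — signal
conditioning, feature extraction, the TCN-LSTM hybrid and its baselines,
and the evaluation protocol — is exercised and tested end to end.

## Study design emulated

143 adolescent idiopathic scoliosis patients (age 10–18), four exercise
holds of ~20 s each, eight muscles (bilateral erector spinae, multifidus,
rectus abdominis, external oblique) sampled at 1,000 Hz, measured at
weeks 0, 8, 16 and 24 of a Schroth programme: 16 recordings per patient,
2,288 in total, 572 per measurement week.  Outcome labels: thoracic and
lumbar Cobb angles (weeks 0 and 24 only — radiographs are not taken at
intermediate visits), trunk rotation angles (ART-T/L), the SRS-22
quality-of-life score, and the Biering-Sørensen endurance time (BST),
the latter four at all visits.

## Signal model

Each channel of a synthetic recording is

    x(t) = s(t) + a_lf(t) + a_hf(t)

where `s` is Gaussian noise shaped to the 20–400 Hz analysis band and
scaled so that its band-passed RMS equals the channel's amplitude target
(with 3% log-normal per-recording jitter), `a_lf` is a sub-20 Hz tone
(default 10 µV RMS) standing in for motion/respiration artifact, and
`a_hf` a >400 Hz tone (4 µV RMS) for high-frequency contamination.  The
generator makes no attempt at motor-unit realism: RMS and PMSI semantics
are what the downstream pipeline consumes, and amplitude-modulated
band-limited noise carries them exactly.  Consequences: waveform-level
features (firing statistics, spectral shifts with fatigue) carry no
information here, so a model that passes the benchmarks has demonstrated
amplitude/asymmetry learning, not EMG waveform decoding.

### Amplitude targets and the asymmetry–Cobb coupling

For each bilateral pair the convex-side RMS target exceeds the
concave-side level by a ratio

    r = 1 + gain · Cobb_region · Λ,   Λ = 1 + s·u,  u ~ N(0,1) truncated ±2.5

with `Cobb_region` the latent regional Cobb angle at that week (the
paraspinal pairs follow the lumbar curve — the electrodes sit at L4–L5 —
and the abdominal pairs the thoracic curve).  `Λ` is a patient-level
multiplicative noise; `r` is clipped to [0.2, 3.5].  The PMSI
(= RMS_convex / RMS_concave) of a filtered recording therefore tracks
the regional Cobb angle: this is the learnable signal of the cohort.

The published erector spinae statistics (concave 25.56 ± 7.83 µV, convex
38.57 ± 7.43 µV, PMSI 1.37 ± 0.19) are *jointly infeasible* as population
moments: E[convex] = E[concave]·E[PMSI] + Cov(concave, PMSI), and the
covariance required (3.55 µV) exceeds its Cauchy–Schwarz bound
(7.83 × 0.19 = 1.49).  The generator therefore reproduces the three means
exactly and lets the erector spinae PMSI spread land near 0.5.
Concretely, a deterministic internal Monte-Carlo calibration (80,000
latent draws, fixed internal seed) (i) solves the erector spinae gain so
the clipped baseline ratio has mean 1.37, and (ii) couples the concave
level to the ratio through the ratio's normal scores with weight α chosen
so E[level · r] = 38.57 µV; the level marginal stays exactly
N(25.56, 7.83²).  The erector spinae Λ-noise scale is fixed at s = 1.3 —
large, because the required covariance needs a wide ratio spread — which
makes the erector spinae pair a *noisy* Cobb proxy.  The three unprinted
pairs use free level constants (multifidus 20 ± 5 µV, rectus abdominis
10 ± 2.5 µV, external oblique 13 ± 3 µV, baseline mean ratios 1.30/1.25/
1.25) and a small noise scale s = 0.18, so they carry a clean asymmetry
signal; together the cohort's PMSI panel supports test R² well above the
benchmark thresholds (a ridge regression on the static features reaches
≈ 0.75 at 60 patients).

### Patient descriptors and outcomes

Statics are truncated normals whose *truncated* means are solved
numerically to hit the cohort targets (age 14.6 ± 2.7 in [10, 18], BMI
17.29 ± 1.23, Risser 1.52 ± 1.21 in [0, 5]); 46% female, 64.7% left
curves.  The thoracic convexity follows the curve direction with a
compensatory lumbar curve on the opposite side.

Baseline Cobb angles are truncated normals (thoracic 19.12 ± 5.95 on
[10, 40]; lumbar 15.28 ± 6.71 on [5, 40]).  Week-24 values are
`Cobb_24 = ρ · Cobb_0` with an independent improvement ratio whose mean
and sd are solved so the week-24 lumbar moments land on 9.53 ± 4.21; the
thoracic post-treatment cell is unpublished, so its mean reduction
defaults to the lumbar relative reduction (37.6%), exposed as
`cobbT_reduction_frac`.  Trajectories are linear in week (no intermediate
radiographs exist to constrain anything richer).

Secondary outcomes interpolate the published baseline/week-24 anchors
linearly and add a linear coupling to the concurrent regional Cobb
deviation plus Gaussian noise sized to the anchor sds: ART-T couples at
0.30 °/° (moderately predictable), BST at −2.5 s/° (larger curves, lower
endurance), while ART-L (0.05 °/°) and SRS-22 (no coupling) are
noise-dominated *by design*, so the benchmark reproduces the finding that
quality-of-life and lumbar rotation are poorly predictable from EMG.

Everything is reproducible from `(SimParams, seed)`: per-patient and
per-recording RNG streams derive from `numpy.random.SeedSequence` keyed
by the seed and stable patient identifiers, so any recording can be
regenerated in isolation.

## Signal conditioning and features

A 4th-order Butterworth band-pass, 20–400 Hz, applied zero-phase
(forward–backward) by default: this doubles the effective attenuation
order and removes phase distortion; a causal single-pass mode is kept for
ablation.  The zero-phase magnitude response is the squared single-pass
response — the test suite checks the measured sinusoid gains against the
exact frequency response of the designed digital system to 1e-3.

RMS is computed over the whole recording (one value per channel per
hold; no sliding window), and PMSI per pair as filtered-RMS convex over
concave, with the convex side read from the patient's regional
convexity map.

Network inputs: the filtered 8-channel series is polyphase-resampled to
100 Hz (anti-aliased), centre-cropped/zero-padded to 2,000 samples and
per-channel z-scored — at 1,000 Hz raw length the recurrent stack would
be needlessly heavy, and the asymmetry information the cohort carries is
delivered through the feature vector.  The static vector is
`[sex one-hot, BMI/20, measurement-week one-hot, (PMSI − 1) for 4 pairs ×
4 weeks]`, where PMSI slots for weeks after the sample's week stay zero
(no future leakage) and the −1 origin maps symmetric activation to 0.
All features are O(1) by construction; the scaling constants are fixed,
not fitted, so no statistics leak across splits.

## Models

All four models share the prediction contract (time-series tensor +
static vector → outcome), and the three neural models are implemented in
NumPy with hand-written backpropagation (the engine is gradient-checked
against finite differences in the test suite):

* **TCN-LSTM hybrid** — one dilated causal convolution block per
  dilation rate (2, 4, 8, 16, 32; kernel 3): conv → batch norm → ReLU →
  dropout.  Blocks are plain (non-residual) by default, matching the
  architecture description; canonical residual blocks are a config flag.
  The stack's receptive field is 1 + (k−1)·Σd = 125 input steps.  Its
  output is average-pooled along time (default factor 20) and fed to two
  LSTM layers whose final hidden state is concatenated with a dense
  embedding of the static vector; fully connected layers (128/64/32
  default) produce the linear output.  Sequential composition (TCN feeds
  LSTM) is the default; a parallel-branch variant is a config option.
* **TCN** — the LSTM module replaced by global average pooling over time.
* **LSTM** — the input series, strided to at most 500 steps, feeds the
  LSTM stack directly (full-length 2,000-step recurrence is numerically
  and computationally pathological on CPU).
* **SVR** — RBF-kernel support vector regression (scikit-learn) on the
  flat vector [8 per-channel RMS values + static vector], standardised
  in-pipeline; the strongest fair shallow baseline, one regressor per
  output.

Loss is mean squared error (matching the RMSE evaluation); optimiser
Adam at the configured learning rate, batch size 16.  Weight
initialisation is fan-in-scaled and fully seeded.  Each target is
predicted by its own model with a scalar output per sample (the sample's
week is part of the input, so one model covers all strata of a target).

## Protocol

Splits are at **patient** granularity: ⌊0.7·n⌋ patients to training, the
rest to test, with 10% of the training patients carved out as a
validation set that drives early stopping (patience 10 within at most
100 epochs, best-validation weights restored).  Sample-level splitting
(which leaks a patient's other exercises into test) is available behind
`group_by_patient=False` for comparison.  Three-fold cross-validation
partitions patients into three mutually exclusive subsets, each serving
once as the test fold; reported metrics are fold means ± sd per week
stratum and overall, the machine twin of the published comparison
tables.  Hyperparameter search runs a seeded random phase over the
published grids (dropout 0.1–0.5, LSTM units {128, 256, 512}, learning
rate 0.0001–0.01 in 0.0005 steps) followed by a local grid around the
incumbent; selection is by validation loss.  An exhaustive sweep of the
full grid is deliberately not attempted — the random + local-grid
budget (default 20 draws) finds the same neighbourhood at a small
fraction of the cost.

### Controls and stratified scoring

Two details of the shipped verification design matter for interpreting
its numbers.  First, the no-signal control cohort switches the asymmetry
coupling off *and* removes the treatment trend (week-24 Cobb drawn with
the baseline moments): with the trend left in, the measurement-week
indicator alone recovers the week-conditional mean and yields a pooled
R² near 0.3 that reflects a calendar effect, not EMG information.
Second, model-ordering comparisons use the mean of *within-week* test
R² rather than the pooled value: every secondary outcome shares a
strong week trend (e.g. SRS-22 rises from 3.25 to 4.54 over the
programme) that any model reproduces from the week indicator, so pooled
R² overstates predictability; within-week strata isolate patient-level
skill.

## Problem sizes used in the shipped checks

The package's own verification runs use scaled-down cohorts chosen to
keep the full suite practical on a single CPU while leaving the
protocol untouched: design-count checks at the full n = 143; moment
calibration at n = 5,000 patients (statics/outcomes) with the recording
realisation verified against latent targets on a subsample; the
learnability benchmark at n = 60 patients with 100 Hz × 2,000-sample
tensors and a reduced hybrid (16 filters, 32–64 LSTM units) trained for
at most ~80 epochs; the model-comparison ordering at n = 36 patients
over three seeds.  These sizes are package defaults for the smoke
profile, not protocol changes.

## Numerical choices and edge cases

* Filter design via second-order sections (numerically stable at order
  4 × 2 passes); band edges validated against Nyquist before use.
* PMSI with a zero concave RMS raises (undefined ratio) rather than
  returning infinity; RMS of an empty sequence raises.
* Truncated-normal draws use the solved parent location so means match
  after truncation; parent sds are kept at the printed values (the
  truncated sd is slightly smaller — means, not sds, are the calibration
  anchors).
* Ratio and level clips (r ∈ [0.2, 3.5], level ∈ [3, 100] µV) bound
  amplitude tails at physiological values; their mean distortion is
  < 0.4 µV (verified by the Monte-Carlo calibration sample).
* Batch norm uses running statistics at evaluation time, making
  prediction batch-size invariant; training-mode statistics are per
  batch over batch × time.
* Early stopping compares against the running best with a 1e-12 margin,
  so a perfectly flat validation curve halts at epoch patience + 1.
* Cross-validation re-seeds each fold's model (config seed + fold) and
  validation carve-out deterministically.

## Known limitations

* The signal model carries no waveform-level physiology; spectral or
  temporal-pattern claims cannot be evaluated on it.
* The printed convex-side RMS sd (7.43 µV) is not reproduced — it is
  incompatible with the mean structure (see above); the realised convex
  sd is larger (~15–25 µV) because matching all three means forces a
  strong level–ratio correlation.
* PMSI measured during exercise holds is calibrated to values the study
  reports for natural standing posture; the generator treats them as
  exchangeable.
* Per-exercise RMS differences are not modelled (one amplitude target
  per patient–week–channel, plus per-recording jitter): no published
  per-exercise statistics exist to calibrate them.
* Cobb trajectories are linear in week by assumption; only endpoints are
  ever observed.
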