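# Methods

## Scope and model

`vo2arm` regresses second-by-second oxygen uptake (VO2, mL·kg⁻¹·min⁻¹)
on per-second statistical features of a single forearm armband's 8-channel
surface EMG (200 Hz, signed 8-bit) and 3-axis accelerometer/gyroscope
(50 Hz).  The regressor is a stack of two recurrent layers (LSTM, BiLSTM or
GRU), dropout 0.3, a ReLU dense layer, dropout 0.3, and a linear scalar
head, trained with Adam (learning rate 0.001) on MSE with early stopping.
Generalisation to unseen people is estimated by leave-one-subject-out (LOSO)
cross-validation; task-level oxygen cost is the mean of the per-second
predictions over a task, converted to L·min⁻¹ by `mean × mass / 1000`.

## Synthetic-data generator

Real armband + metabolic-analyzer cohorts are not redistributable, so the
package ships a generator whose outputs exercise every pipeline stage with a
known answer.

* **VO2 kinetics.** Oxygen uptake follows first-order on/off kinetics toward
  an intensity-dependent steady state `vo2_rest + I·(vo2_peak − vo2_rest)`.
  Discretisation per 1 s step is exact:
  `v[t+1] = v[t] + (target − v[t])·(1 − e^(−1/τ))`, stable for any τ.
  Defaults: vo2_rest 5, vo2_peak 38 mL·kg⁻¹·min⁻¹, τ_on 30 s, τ_off 35 s —
  a fit, active young adult.  Observed VO2 adds Gaussian measurement noise
  (default SD 1.0 mL·kg⁻¹·min⁻¹, typical of a 1 Hz portable analyzer);
  the noiseless trace is kept alongside as ground truth.
* **IMU.** One accelerometer axis carries the 1 g gravity baseline; the
  primary motion axis carries a sinusoid of amplitude `0.4 g × intensity` at
  the bout's motion rate (error above the 25 Hz Nyquist limit), secondary
  axes scaled copies with independent phases; gyro channels are zero-mean
  sinusoids of amplitude `60 deg/s × intensity`.  Noise: 0.02 g / 1 deg/s.
* **EMG.** Zero-mean Gaussian noise whose envelope
  `gain·(0.2 + 0.8·intensity)·(1 + load/20 kg)·channel_gain` is separable in
  work intensity and carried load (so a loaded hold and an unloaded swing
  are distinguishable), zero when a bout has neither intensity nor load,
  plus a resting noise floor (2 quantisation units); per-channel gains
  spread over [0.7, 1.3]; samples quantised and clipped to [−128, 127].
* **Activity scripts.** The default template cycles through a 14-task
  manual-scaffolding taxonomy (walking, carrying 17 kg frames, hammering,
  ladder climbing, ...) as (intensity, load, motion-rate) triples.  Inter-
  bout rest is a free parameter (default 30 s) because field protocols rest
  subjects to a heart-rate criterion, not a fixed time.
* **Cohorts.** Subject profiles are jittered around mass 76.7 ± 8.25 kg and
  the kinetic defaults above; all randomness is spawned from one master seed
  per subject and stream, so cohorts are bit-reproducible.

What the generator does **not** emulate: physiological EMG spectra (only
amplitude structure), sensor drift and motion artefacts, breath-by-breath
noise autocorrelation, orientation/magnetometer channels, and between-task
posture effects.  Passing the parameter-recovery tests therefore shows the
pipeline is correct and that the model class can learn kinetics-lagged
mappings — not that field accuracy on humans would match.

## Feature engineering

Per non-overlapping 1 s window, 17 statistics × 17 channels = 289 columns,
plus derived history columns.  Conventions (chosen once; the test oracles
assert exactly these): population (ddof = 0) variance/SD; cv = stdev/avg
with 0 when the mean is 0; percentiles by linear interpolation between order
statistics; population Fisher skew and excess kurtosis with the
zero-variance convention skew = kurtosis = 0.  The 17th statistic is the
50th percentile — numerically the median, kept as its own column so the
channel × statistic grid is square and the published `*_per50` feature names
exist.  EMGsum is the per-sample sum of absolute channel values: a raw sum
of signed 8-bit noise would cancel to ≈ 0.

Two derived-column modes are first-class because the available description
of the lag/rolling step is ambiguous: `basic_290` (default) appends only
`EMGsum_lag1` (the previous second's EMGsum mean), matching the stated
289 + 1 total; `extended_295` appends shift-1 and rolling-mean (window 3,
min_periods 1) columns for each of the res_acc, res_gyro and EMGsum
second-level means, matching the fuller derived-feature table.  The first
row of every recording is dropped (lag undefined), so an S-second recording
yields S − 1 rows.

Selection keeps a feature iff |Pearson r| > 0.1 **and** mutual information
> 0.1 (nats).  MI uses the KSG k-nearest-neighbour estimator (k = 3) with
seeded tie-breaking jitter, so selection is deterministic given the seed.
Zero-variance features get r = 0 and are never kept.  By default selection
runs once on the pooled training corpus before cross-validation (the
replicated order of operations); a leakage-safe `per_fold` mode exists and
reports label which was used.  Min-max scaling to [0, 1] is always fit on
training rows only; constant columns map to 0 and test-fold values are not
clipped.

## Recurrent networks

Implemented directly in NumPy with analytically derived backpropagation
(validated against central-difference numeric gradients in the test suite).
Conventions: LSTM gates ordered i, f, g, o with a single combined bias and
forget bias 1 — 4(dh + h² + h) parameters per direction; GRU gates z, r, n
with the reset gate applied before the candidate's recurrent matmul and a
single combined bias — 3(dh + h² + h); bidirectional layers run a forward
and a time-reversed pass and concatenate, doubling the count.  Glorot
uniform initialisation throughout; inverted dropout; dropout disabled at
inference, so prediction is deterministic.

Training details: Adam (β₁ 0.9, β₂ 0.999); MSE loss on an internally
standardised target (z-scored on the training split) so the linear head
starts on scale — losses are recorded and predictions returned on the raw
mL·kg⁻¹·min⁻¹ scale; validation split is the chronologically last 10 % of
rows per subject (chronological, to avoid leaking the lag feature across
the split); early stopping with patience 10 and best-weight restoration;
NaN loss aborts with a diagnostic.  All randomness (init, shuffling,
dropout) derives from one seed: identical seeds give identical weights on a
fixed platform.

Two width profiles exist: the desk-scale default (32 recurrent / 32 dense
units) used by the tests and experiments, and a 1024/1024 profile
(`ModelConfig.full_profile()`) matching the deployed architecture.  The
contracts being validated — gradient correctness, early stopping,
reproducibility, LOSO generalisation — do not depend on width.

### Sequence length

`seq_len` controls how many consecutive per-second rows form one input
sequence (`[samples, timestamps, features]`, non-overlapping, never spanning
subjects; the target is the last row's VO2).  The default is 1 — with the
lag feature, a memoryless model — but VO2 kinetics with τ ≈ 30 s make the
instantaneous mapping information-limited: on the synthetic cohort the
correlation between true VO2 and instantaneous intensity is only ≈ 0.66, and
a seq_len 1 model plateaus near r ≈ 0.75.  The parameter-recovery experiment
therefore uses seq_len 60 (one minute of context, comfortably above 2τ),
where the same 32-unit BiLSTM reaches held-out r ≈ 0.97.  Bidirectionality
is only meaningful for seq_len > 1; with sequences ending at the prediction
time it uses no future information.

## Evaluation

Metrics: MAE, MSE, RMSE = √MSE, MAPE (zero-target samples excluded and
counted — physiological VO2 is strictly positive, so exclusion is explicit
bookkeeping, not data loss), Pearson r, and R² = 1 − SS_res/SS_tot.  The raw
SS_res/SS_tot ratio is also emitted as `eq5_literal` because one published
formulation prints that ratio in place of a correlation; the standard
definitions are what the package computes and reports (their internal
consistency, r² ≈ R² on near-linear fits, is asserted in tests).
Fold-averaged metrics are unweighted means over folds, except RMSE, which is
recomputed as √(mean MSE) so every emitted metric set satisfies rmse² = mse.

The comparison harness runs the 3 architectures × 3 sensor-combination grid
(imu+emg / imu / emg), restricting candidate columns to each family before
selection.

## Task-level reporting

Per-subject task cost: mean VO2 over the task and its L·min⁻¹ conversion.
Measured-vs-estimated agreement across subjects uses a two-group one-way
ANOVA (F with df 1, 2n−2) on the per-subject means — on the embedded
10-participant reference table this reproduces the published p ≈ 0.964,
whereas a paired formulation gives ≈ 0.88, which identifies the two-group
form as the published computation; the paired t-test is emitted alongside.
Work-severity bands are pure configuration (an example table ships with the
package); no thresholds are asserted as claims.

## Numerical and degenerate-input choices

* Sigmoid inputs clipped to ±60 before exponentiation (exactness unaffected
  in float64).
* `compute_metrics` requires length ≥ 2 and a non-constant reference;
  constant *predictions* get r = 0 rather than NaN.
* Recordings shorter than 3 s are rejected by the feature builder (rolling
  window unsatisfiable); span trimming floors to whole seconds and errors on
  empty intersections.
* Stream loading enforces strictly increasing timestamps with ≤ 1 % jitter
  of the nominal period, 8-bit integer EMG range (errors name the first
  offending sample), and exact channel widths.

## Known limitations

* The synthetic EMG/IMU signals are amplitude-realistic but spectrally
  simplistic; frequency-domain features would not be exercised meaningfully.
* LOSO at desk scale uses 6 subjects; between-subject variance of the fold
  metrics is correspondingly wide.
* The NumPy trainer is single-threaded and CPU-bound; the 1024-unit profile
  trains slowly and is provided for architectural fidelity, not routine use.
* `selection_mode="global"` leaks target information from test folds into
  feature *screening* (not into scaling or weights); it exists because it
  replicates the original order of operations, and reports always record
  which mode produced them.
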