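# Methods

`adrisk` implements a cross-subject screening pipeline for genetic
Alzheimer's-disease risk from task-state EEG: multitaper time–frequency
estimation, band/region/time feature reduction, mass-univariate
screening with false-discovery-rate control, and leave-subjects-out
classification with class-weighted metrics.  This note documents the
model, the parameters that matter, the synthetic-data generator used to
exercise the pipeline, and the numerical and design choices that were
genuinely open.

## Data model

The exchange container is an epoch set: a `trials × channels × samples`
microvolt array at sampling rate `fs` (default 250 Hz), epoched on the
half-open interval [−80, 1200) ms around stimulus onset — exactly 320
samples — with per-trial metadata (subject, binary genetic-risk group
`neutral`/`risky`, task condition, response time, correctness).  Sixty
10-10 channels are partitioned into six scalp regions (prefrontal,
frontal, temporal, central, parietal, occipital); the partition is the
basis of the spatial averaging step.  Task conditions are an
interference task and a working-memory (retrieval-phase) task, each at
low/high demand (ML, MH, SL, SH), their unions (MSIT, STMT), and
resting-state segments (Rest) cut into 1.2-s pseudo-epochs.

## Preprocessing

* Re-reference: subtract the average of the two mastoid channels
  (TP9/TP10) from every channel; reference channels are retained.
* Bandpass 1–30 Hz, stated as half-amplitude (−6 dB) cut-offs with a
  12 dB/octave roll-off.  Realised as one second-order Butterworth
  section per edge applied forward–backward (`sosfiltfilt`).  A
  second-order Butterworth is −3 dB at its natural frequency, so the
  two-pass magnitude is exactly −6 dB there: designing each edge at the
  nominal cut-off puts the half-amplitude point on it with no warping.
* Trial gates (all inclusive): correct response required; response time
  in [200 ms, 1500 ms] for the interference task or [200 ms, 2000 ms]
  for the memory task; any channel whose peak-to-peak amplitude exceeds
  150 μV over the epoch rejects the trial.  The filter is idempotent.
* A decimation helper (anti-aliased, zero-phase) is provided for
  1000→250 Hz plumbing; synthetic data is generated at 250 Hz directly.

ICA-based artifact suppression and bad-channel handling are out of
scope; the synthetic data is artifact-controlled by construction.

## Multitaper time–frequency estimation

Windows of `nperseg = 64` samples slide with `noverlap = 32` (step 32);
a 320-sample epoch yields `⌊(320−64)/32⌋+1 = 9` windows, with centres
from 48 ms to 1072 ms (the fifth window is centred at 560 ms).  Each
window is tapered with `K = 7` Slepian sequences at time–bandwidth
`NW = 4` (the eigenfunctions of the spectral-concentration operator;
the leading eigenvalue exceeds 0.999, and `K ≤ 2NW−1` is enforced),
transformed with an `nfft = 512`-point DFT, and the `K` per-taper power
densities are averaged with equal weight.  Eigenvalue-weighted
(adaptive) combination is deliberately not used.

Numerical notes:

* Spectra are one-sided (257 bins at spacing `fs/nfft ≈ 0.488` Hz) with
  power doubled at non-DC/non-Nyquist bins; band averages are identical
  to the two-sided convention.  Units are power per Hz; all downstream
  statistics (two-sample tests, classifiers after z-scoring) are
  invariant to the normalisation constant.
* The production path evaluates each taper's zero-padded DFT as a real
  matrix product (the 64×257 complex exponential matrix folded with the
  taper), which is algebraically identical to the FFT path; tests pin
  both against a literal summation oracle at 1e-8 relative error.
* Tapers are unit-energy and pairwise orthogonal to 1e-10, ordered by
  descending eigenvalue, with each taper's first non-zero element
  positive (a sign convention only; power is sign-invariant).
* No detrending or per-window demeaning is applied beyond the 1 Hz
  high-pass.

## Feature spaces

Band scheme: Delta 1–4, Theta 4–8, Alpha 8–13, Beta 13–30 Hz, half-open
`[low, high)`; a bin belongs to the band containing its centre.

* **F216** — mean PSD over band bins, then over the channels of each
  region, per window: 6 regions × 4 bands × 9 windows.  Names are
  region-major, band-middle, window-minor (`Pre_δ_1 … O_β_9`), fixed so
  serialized matrices are reproducible.
* **F24** — F216 averaged over the 9 windows (unweighted).
* **PBTST subset** — the fixed nine prefrontal-beta features
  `Pre_β_1 … Pre_β_9`, used without screening.

## Screening

Per feature, a two-sample t-test between neutral and risky trials
pooled across subjects, Welch variant (group sizes and variances
differ).  P-values are corrected per feature space and condition with
Benjamini–Hochberg; a feature is selected when `q < α` with `α = 1e-3`.
Constant features get `p = 1`.  The region-concentration ratio is
`PreF/Total × 100` (two decimals) where `PreF` counts selected features
in prefrontal or frontal cortex.

Pooling trials across subjects pseudo-replicates: trials of one subject
are not independent, so the nominal error rates of both the screening
t-tests and the downstream significance stars are anticonservative with
respect to subject-level variability.  The pipeline reproduces this
design faithfully rather than correcting it (a per-subject-mean switch
is deliberately not offered; see Limitations for the measured
consequence).

## Cross-subject validation

Leave-p%-subjects-out: each of 100 iterations (one seed per iteration,
42–141) draws 5 neutral + 4 risky test subjects (≈23% of the default
21 + 18 cohort) without replacement within the iteration; iterations
redraw independently, so test sets overlap across iterations.  Train
and test subject sets are disjoint by construction and asserted on
every run.

Four classifiers with library-default hyperparameters: logistic
regression, random forest, RBF-kernel SVM and gradient boosting; the
per-iteration seed sets each model's random state.  Features are
z-scored inside each fold with train-fold statistics (the linear and
kernel models are scale-sensitive, and cross-subject pooling would
otherwise leak scale).  Scores for ROC analysis are predicted
positive-class probabilities, or decision-function values for models
without probabilities (SVM).

Metrics per iteration: accuracy; precision, recall and F1 computed with
each class treated as positive in turn and combined with weights
proportional to the true class sizes of the *test* fold (the scored
set); ROC AUC by the trapezoidal rule on the score-sorted ROC curve —
exactly the Mann–Whitney pair-counting estimator with ties counted
half — weighted the same way (for complementary binary scores the
weighted AUC equals the positive-class AUC).  The positive class is
`risky` throughout.  Per-iteration confusion matrices (rows = true
class) are row-normalised to percentages and averaged.  Each metric
series is tested against chance with a one-sample one-tailed t-test of
mean > 0.5, starred at 5e-2 / 1e-2 / 1e-3; a zero-variance series gets
the conservative `p = 1`.

### Experiments

* **TFAAT** (time–frequency area average test): per condition, classify
  on the F24 features that survive screening.  By default screening runs
  on the full condition dataset before the validation loop — the
  screened feature table is a result in its own right and this mirrors
  a common reporting order — but it leaks selection information across
  folds.  `screen_within_fold=True` instead refits the selector inside
  every training fold (with a keep-best-1 fallback so folds where
  nothing passes can still be scored).  A condition whose full-data
  screening selects nothing is skipped and logged.
* **PBTST** (prefrontal beta time-series test): classify on the fixed
  nine-window prefrontal-beta vector for every condition; no screening.
  (One prefrontal-beta window feature may sit slightly above the
  screening threshold in some conditions; the set is fixed by design.)

The prefrontal-beta group-mean PSD curves per window (neutral vs risky,
working-memory conditions) are emitted as a data table; plots are not
contractual.

## Synthetic-data generator

The generator emulates the study conditions so every stage is testable
without the source database.  Defaults: 21 neutral + 18 risky subjects;
per-condition trial counts drawn from truncated (≥10) normals at the
published scale (means ≈77/73 for interference low/high, ≈64/53 for
memory low/high, 100 for rest); 60 channels; 250 Hz; [−80, 1200) ms.

Signal model per trial: (i) per-channel AR(1)-filtered Gaussian noise
(coefficient 0.95, ~1/f-like decay, scale `noise_sd = 5` μV); (ii) per
region and canonical band, a band-passed Gaussian source shared by the
region's channels (amplitude 3 μV) — this is what gives the features
their band × region structure; (iii) in prefrontal channels only, a
beta-band source (amplitude 4 μV) whose envelope follows a nine-window
temporal profile — full gain in windows 1–2, minimum 0.35 in window 5
(centred at 560 ms), partial rebound to 0.75 — and whose amplitude is
multiplied by `1 − beta_effect` for risky subjects.  Between-subject
variability is a log-normal gain on the prefrontal beta source with
log-power standard deviation `subject_sd = 0.2`.  Everything derives
from one seed via spawned substreams, so datasets are bit-reproducible.

The effect-size and variability defaults are the package's calibration
choices: the source study plots group PSD curves without printing their
gap, and factor-level between-subject band-power variability of
e^0.2 ≈ 1.2 is at the conservative end of what task-EEG studies report.
`beta_effect = 0` makes the groups exchangeable by construction.

What the generator does *not* emulate: volume-conduction mixing and
channel covariance beyond region-shared sources, artifacts
(blinks/muscle), non-stationarity across a session, response-time/
difficulty coupling, and any genetics beyond the binary label.  Passing
tests therefore demonstrate the pipeline's statistical behaviour under
a controlled spectral model, not classification performance on real
EEG.

## Problem sizes used in tests and the acceptance script

Monte-Carlo suites run at reduced scale, chosen as the smallest sizes
at which the checked properties are stable: null-calibration and
planted-effect pipeline runs use the full 39-subject cohort at ~30
trials per subject on a single working-memory condition (the
prefrontal-beta experiment with the linear and kernel models); the
screening-recovery suite uses 15 subjects per group at ~10 trials;
FDR calibration uses 1000 Gaussian null features at 200 trials per
group.  The acceptance script repeats the same computations at
slightly smaller replicate counts and prints the measured quantities.

## Known limitations

* **Single-cohort significance stars are anticonservative.**  Because
  every validation iteration re-samples test subjects from the same
  finite cohort, the 100 per-iteration metric values share a
  dataset-conditional offset: with between-subject variability the mean
  AUC of a *null* cohort is not 0.5 but 0.5 plus a cohort-level random
  term (measured standard deviation ≈ 0.02–0.03 at the default
  cohort size), while the across-iteration standard error is ≈ 0.005.
  The one-tailed t-test therefore stars a substantial fraction of null
  cohorts.  This is a property of the replicated design itself (the
  pseudo-replication noted above), reproduced faithfully; the package's
  null-calibration test measures it rather than hiding it.  Conclusions
  from starred metrics on a single cohort should be read accordingly.
* Full-dataset screening in the default TFAAT mode leaks selection
  information into validation; the within-fold switch is the clean
  variant.
* Library-default classifier hyperparameters are a reconstruction
  convention, not a tuned choice.
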