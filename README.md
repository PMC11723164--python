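# adrisk — cross-subject Alzheimer's-risk screening from task-state EEG

`adrisk` is a Python package for asking whether task-state EEG carries a
cross-subject signature of genetic Alzheimer's-disease risk in healthy
middle-aged adults.  It implements the full analysis chain for epoched
multichannel EEG recorded during cognitive tasks (an interference task
and a working-memory task, each at two demand levels, plus resting
state), where each subject carries a binary genetic-risk label
(`neutral` = no risk allele, `risky` = single risk allele):

1. **Preprocessing** — averaged-mastoid re-referencing, zero-phase
   1–30 Hz bandpass (half-amplitude cut-offs, 12 dB/octave),
   response-time / correctness / 150 μV peak-to-peak trial gates,
   resting-state segmentation into 1.2-s pseudo-epochs.
2. **Multitaper time–frequency estimation** — for each trial, sliding
   64-sample windows (step 32; nine windows over the [−80, 1200) ms
   epoch at 250 Hz) are tapered with K = 7 Slepian sequences (NW = 4)
   and the per-taper power densities S_k(f) = |Σ_t x(t) ψ_k(t)
   e^{−2πift}|² are averaged: Ŝ(f) = (1/K) Σ_k S_k(f), on a 512-point
   frequency grid.
3. **Feature reduction** — mean band power (δ 1–4, θ 4–8, α 8–13,
   β 13–30 Hz) per scalp region (prefrontal, frontal, temporal,
   central, parietal, occipital) per window: the 6×4×9 **F216** space;
   averaged over windows, the 6×4 **F24** space; and the fixed
   prefrontal-beta nine-window vector `Pre_β_1..9`.
4. **Screening** — per-feature Welch t-tests (neutral vs risky trials)
   with Benjamini–Hochberg FDR correction at q < 10⁻³, and the
   region-concentration ratio PreF/Total × 100.
5. **Cross-subject validation** — Leave-p%-Subjects-Out: 100
   iterations (seeds 42–141), each holding out 5 neutral + 4 risky
   whole subjects; logistic regression, random forest, SVM and
   gradient boosting scored with class-weighted precision/recall/F1,
   trapezoidal ROC AUC and percentage confusion matrices, plus
   one-tailed t-tests of each metric against chance.

Two experiment designs are packaged: **TFAAT** (classify on the
screened F24 features per condition) and **PBTST** (classify on the
fixed prefrontal-beta time series).  A synthetic two-group EEG
generator with a planted prefrontal-beta power reduction in the risky
group makes the whole chain testable end to end without any private
dataset.

Key pieces follow scikit-learn conventions and compose with sklearn
tooling: `MultitaperSpectrogram` (transformer), `TTestFDRScreen`
(feature selector usable inside a `Pipeline`), `LeavePSubjectsOut`
(cross-validator).

## Worked example

```python
from adrisk import (SyntheticConfig, generate_dataset,
                    ExperimentConfig, run_experiment)

epochs = generate_dataset(SyntheticConfig(
    trials_per_subject_mean=30, trials_per_subject_sd=5,
    conditions=("SH",), beta_effect=0.3, seed=1))
report = run_experiment(epochs, ExperimentConfig(
    experiment="PBTST", conditions=("SH",), classifiers=("logreg",)))
r = report.conditions["SH"].report
print(r.mean_metrics.round(3))
print("AUC star:", r.stars.loc["logreg", "roc_auc"])
print(r.confusion_pct["logreg"].round(1))
```

prints (seed 1):

```
            accuracy  precision  recall     f1  roc_auc
classifier
logreg         0.614      0.616   0.614  0.613    0.646
AUC star: ***
[[57.4 42.6]
 [35.1 64.9]]
```

A 30% planted reduction of prefrontal beta-band source amplitude in
the risky group is recovered across subjects: the logistic model
separates held-out subjects' trials at mean ROC AUC ≈ 0.65 over the
100 leave-subjects-out iterations (significantly above chance, `***`),
and the averaged confusion matrix shows ~57% of risky trials (top row,
positive class) and ~65% of neutral trials correctly classified.
With `beta_effect=0` the same pipeline sits at chance (mean AUC ≈ 0.5).

The same workflow is available from the shell:

```bash
adrisk synth --config synth.yaml --out data/cohort
adrisk run --config experiment.yaml --out results/
```

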