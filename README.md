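# perfml

Quantifying myocardial blood flow (MBF) from first-pass contrast-enhanced
cardiac MRI, and detecting dark-rim-artefacted signals, with machine
learning benchmarked against the classical deconvolution baseline.

`perfml` is built for perfusion-imaging researchers who want a tested,
fully synthetic testbed for the *modified dual-bolus* analysis chain:

1. **Synthetic cohort** — per subject and physiological state (rest /
   adenosine stress), 24 myocardial ROI signal–intensity curves sampled
   once per heartbeat over 60 frames, plus left-ventricular blood-pool
   curves for a 1/21-diluted pre-bolus and a full-dose bolus. Roughly half
   of the tissue curves carry a dark-rim artefact: a transient dip below
   the pre-contrast baseline at contrast arrival. Every record carries its
   ground-truth MBF.
2. **Dual-bolus AIF correction** — the full-dose arterial input function
   (AIF) is saturation-blunted; the diluted pre-bolus stays in the linear
   signal regime, so its concentration curve, scaled by the dilution
   factor (21) and aligned to the full-dose arrival, replaces it.
3. **Model-independent deconvolution** — the tissue curve obeys
   C_t(t) = C_b(t) ⊗ h(t); the tissue impulse response h(t) is recovered
   by Tikhonov-regularized least squares (second-difference penalty,
   nonnegativity), and h(0) gives the flow estimate, since for a
   single-compartment residue function h(t) = F·e^(−F t/λ) the initial
   value *is* the flow F.
4. **ML benchmarking** — subject-held-out evaluation (calibrate on 4
   subjects, test on the 5th) of SVM and random-forest regressors trained
   on the whole h(t), against ordinary least squares on the single h(0)
   estimate; plus SVM/RF classifiers that detect artefacted impulse
   responses. Hyperparameters come from an exhaustive grid search with
   5-fold internal cross-validation on the calibration subjects only.

The central mechanism the package reproduces: dark-rim dips corrupt the
deconvolved h(0), so the linear baseline degrades badly on artefacted
data, while learners that see the whole h(t) remain accurate and can
flag the artefacted curves.

## Worked example

The numbered scripts under `analysis/` run the study end to end:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_correct_and_deconvolve.py
python analysis/03_train_and_evaluate.py --seed 7
python analysis/04_mechanism_experiment.py
```

Output of the first two steps (seed 1):

```
cohort written to results/cohort
  records: 216 (120 rest, 96 stress)
  excluded sessions: ((3, 'stress'),)
  artefacted: 103/216 (48%)
impulse responses written to results/impulse_responses.csv
  artefact-free records: h(0) vs truth slope=1.014, R^2=0.997
  median |h0 - truth|: clean 0.039, artefacted 0.489 mL/g/min
  rule label vs injection flag agreement: 0.981
```

216 signals is the full design (5 × 24 × 2 − 24 for the one excluded
stress session). On artefact-free curves the deconvolution pipeline
recovers the true flow nearly unbiasedly (slope 1.01, R² 0.997); a
dark-rim dip inflates the median h(0) error more than tenfold — the
failure mode the ML models are meant to absorb. Step 03 then prints the
held-out benchmark (seed 7, test subject 5):

```
held-out test metrics:
  svm     rho=0.987 R^2=0.995 RMSE=0.08 MAE=0.05 mL/g/min
  rf      rho=0.998 R^2=0.996 RMSE=0.07 MAE=0.05 mL/g/min
  linear  rho=0.786 R^2=0.611 RMSE=0.70 MAE=0.53 mL/g/min
  svm classifier: accuracy=0.94 sensitivity=0.90 specificity=1.00
  rf classifier: accuracy=0.90 sensitivity=0.84 specificity=1.00
```

SVM and RF regressions beat the h(0) linear baseline by a wide margin on
both correlation and error, and the SVM classifier detects artefacted
impulse responses with ~94% accuracy. Step 04 repeats the comparison
over 10 independently seeded cohorts (SVM wins on R² and RMSE in 10/10;
mean classifier accuracy ≈ 0.96).

The same pipeline is available as a CLI (`perfml simulate | deconvolve |
label | run-all | render`) and as a library:

```python
from perfml import RunConfig, run_all
report = run_all(RunConfig(seed=7), out_dir="results/run")
```

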