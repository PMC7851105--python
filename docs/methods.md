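# Methods

## The forward model the generator emulates

One synthetic "study" mimics a dual-bolus first-pass perfusion protocol
on 5 subjects. Per subject and state (rest, stress) the generator draws:

- **Arterial input function.** A gamma-variate bolus
  C_b(t) = A·(t−t0)^α·exp(−(t−t0)/β) for t > t0 (zero before), with an
  optional recirculation tail (a delayed, dispersed copy at 10% of the
  first-pass amplitude). Defaults A ≈ 0.28 mmol/L-scale, α = 3, β = 2 s
  give a first-pass peak near 3 mmol/L at t0 + αβ ≈ t0 + 6 s — typical
  for a compact intravenous bolus. Onset t0 is drawn uniformly in
  8–12 s per session; amplitude and shape get ±10% per-subject jitter.
- **Tissue kinetics.** Each of 24 ROIs (8 apical + 16 mid-ventricular)
  has a true flow F (MBF, mL/g/min): rest ~ U(0.4, 1.5), stress
  ~ U(1.5, 4.0); a configurable 25% of segments per subject are
  "ischemic" and draw from reduced ranges (rest U(0.25, 0.8), stress
  U(0.5, 1.2)), emulating a stented territory without a response to
  stress. The residue function is the Kety single-compartment form
  h(t) = F·exp(−F·t/λ) with partition coefficient λ = 1 mL/g, chosen
  because its initial value *is* the flow — the property the h(0)
  readout depends on. Tissue concentration is the discrete causal
  convolution C_t = (C_b ⊛ h)·Δt on the frame grid, i.e. exactly the
  linear system the deconvolution stage inverts; there is no separate
  continuous-time discretization error by construction.
- **Signal model.** Saturation-recovery conversion
  SI(C) = S0·(1 − exp(−TS·(R10 + r1·C))) with S0 = 1000 a.u.,
  TS = 150 ms, R10 = 1 s⁻¹, r1 = 4 L·mmol⁻¹·s⁻¹. The map is strictly
  increasing and concave: approximately linear for the 1/21-diluted
  pre-bolus (peak ≈ 0.14 mmol/L) and visibly compressive for the
  full-dose AIF peak (≈ 3 mmol/L, >50% blunting under a naive linear
  read-out). Additive Gaussian noise: 2 a.u. on tissue-segment curves,
  0.5 a.u. on blood-pool curves — the LV blood-pool ROI averages over
  roughly 16× more pixels than one segment. Rician noise is not
  modeled; at these SNRs (baseline signal ≈ 139 a.u.) the Gaussian
  approximation is exact for practical purposes.
- **Sampling.** 60 frames at 1.0 s (a steady 60 bpm heart rate). The
  inter-bolus arrival offset is drawn in whole frames (−2…+2): both
  acquisitions are cardiac-gated at one sample per heartbeat, and whole-
  frame offsets are the regime in which the correction's integer-frame
  alignment is identifiable; sub-frame jitter between boluses is not
  emulated (see Limitations).
- **Dark-rim artefact.** An additive raised-cosine dip (default depth
  60 a.u., 4 frames) at contrast arrival, injected into an exact-count
  random subset of records so the cohort prevalence equals 103/216
  (≈ 48%). The injection verifies its own contract: the curve must
  actually cross below the pre-contrast baseline and rebound afterwards.
- **Bookkeeping.** Subject 3's stress session is excluded (a technical
  failure in the emulated protocol), leaving 216 records: 120 rest, 96
  stress; holding out a subject with both sessions gives the 168/48
  calibration/test split.

Everything is reproducible byte-for-byte from (design, seed).

### What the generator does *not* emulate

No image domain (k-space, motion, partial volume), no heart-rate
variability within a scan, no T2* signal loss, no sub-frame bolus
timing, no PET reference noise (the truth MBF is exact). Passing tests
therefore demonstrate the analysis chain's correctness and its behavior
under the modeled noise and artefact mechanisms — not robustness to
every failure mode of real scanner data.

## Dual-bolus AIF correction

The pre-bolus is converted to concentration with the *linear* small-
concentration gain dSI/dC|₀ (valid in its regime), multiplied by the
dilution factor 21, and time-shifted by an integer number of frames onto
the full-dose arrival. Two implementation details matter:

- **Alignment** maximizes the integer-lag cross-correlation between the
  scaled pre-bolus and the exact-inverse full-dose concentration, rather
  than subtracting two threshold-crossing frames. Both define "matching
  detected arrivals", but threshold crossings tie-break unstably when a
  sample sits within noise of the threshold, and a one-frame alignment
  error changes h(0) by a factor ~2–3. A fractional-peak arrival
  detector (`bolus_arrival`, threshold at 10% of each curve's own peak
  enhancement) is still used to locate the arrival frame itself; its
  amplitude-relative threshold avoids the systematic ~1-frame lag a
  noise-referenced threshold shows on a 21×-smaller bolus.
- **Pre-arrival zeroing.** Frames earlier than two frames before the
  detected full-dose arrival are set to zero. Blood concentration is
  physically zero there; without this, the clipped (nonnegative) noise
  floor of the 21×-amplified pre-bolus acts as a spurious early input
  and biases h(0) downward by ~10%.

A per-bolus scalar gain hook (default 1) exists for protocols that
rescale between boluses (e.g. heart-rate or baseline-signal ratios).

## Deconvolution

With A the lower-triangular Toeplitz matrix A[i,j] = C_b[i−j]·Δt,

  h = argmin ‖A·h − C_t‖² + λ‖D₂·h‖²,  h ≥ 0,

solved by NNLS on the stacked system after normalizing A by its spectral
norm (so λ is dimensionless). D₂ is the second-difference operator;
order 0/1 penalties and unconstrained solves are configurable.

- **λ selection.** The default is a *fixed* λ = 10⁻² applied uniformly
  to every record. Per-record L-curve maximum-curvature selection is
  implemented (`reg_selection="l_curve"`) but not the default: on
  near-noise-free synthetic curves the L-curve corner is ill-defined and
  the selected λ varies erratically between records, which leaves h(0)
  recovery intact but makes the h(t) *feature vectors* incomparable
  across records — held-out artefact-classification accuracy dropped
  from ~0.95 to ~0.82 under per-record selection. Uniform smoothing is
  the deliberate design choice for a pipeline whose downstream consumers
  compare h across records.
- **Degenerate inputs.** An identically-zero AIF raises a singularity
  error; mismatched grids raise grid errors; a zero tissue curve yields
  exactly zero h. With λ → 0 and no constraint the solution matches
  triangular back-substitution on well-conditioned systems (tested).
- **Identifiability.** When the AIF has k leading zero frames, the last
  k taps of h never influence the observed window; accuracy statements
  about noise-free inversion are made on the identifiable support.
- **Units.** h is computed in s⁻¹; MBF = 60·h(0) in mL/g/min. Feature
  vectors exported for ML are the full h(t) in mL/g/min units.

## Artefact rule

A curve is labeled artefacted iff some frame within 10 frames of the
(LV-detected) arrival falls below baseline_mean − 2·baseline_sd and a
later frame exceeds the baseline mean. The 2-sd margin and finite search
window make the qualitative rule ("dropped below the baseline at
arrival, then rose") noise-robust; the margin is monotone (raising it
can only remove labels). The baseline window defaults to frames 0–6 —
always pre-contrast under the default designs, and seven samples
estimate the baseline sd far more stably than a minimal window, keeping
false-positive labels on clean noisy curves below 5%. Classifiers are
trained on these *labels*, not the hidden injection flags, mirroring an
observational labeling process; label/flag agreement is 100% noise-free
and ≥ 95% at default noise.

## ML benchmarking

- **Split.** All records of one subject held out; the variance criterion
  (test MBF variance ≤ calibration variance) is checked and logged, with
  a warning (not an error) on violation so the caller can reselect.
- **Features.** The whole h(t) (60 values), standardized with
  calibration-set statistics inside a scikit-learn Pipeline, so no
  test-subject information leaks into scaling, fold assignment, tuning
  or fitting. The linear baseline uses only the scalar h(0) estimate
  (OLS of reference MBF on it); a full-vector linear variant is
  deliberately not the default.
- **Grids.** The full protocol grids register exactly 500 SVM
  combinations (4 kernels × 5 C × 5 gamma × 5 degree → 2500 fits at 5
  folds) and 2160 RF combinations (12 tree counts × 2 criteria × 9
  depths × 10 max-features → 10800 fits), and contain the winning
  settings (rbf, gamma = 100, C = 10 regression / C = 1 classification).
  The end-to-end drivers default to *reduced* grids (SVM: rbf+linear,
  4 C × 5 gamma bracketing 1/n_features; RF: 8 combinations) sized for
  single-workstation runs; the full grids remain selectable
  (`grid_preset="full"`).
- **Scoring.** R² for regression, accuracy for classification; ties in
  grid search break to the first combination in deterministic grid
  order. Fold assignment is seeded (stratified for classification);
  single-class calibration labels raise a fold error, which the
  orchestrator records per-classifier while still reporting regression.

## Numerical and design notes

- Negative concentrations after inversion (noise below baseline) are
  clipped to zero with a logged warning, never silently.
- The exact signal inversion re-references each curve so its measured
  baseline maps to C = 0, removing additive offsets before inverting.
- The tissue arrival used by the artefact rule is the LV arrival, not
  the tissue's own onset (the two coincide in the generator; a tissue
  delay field exists but defaults to 0, since no delay term is fitted
  downstream).
- Metrics: R² = 1 − SS_res/SS_tot, Spearman rho with average ranks,
  RMSE/MAE in mL/g/min; confusion counts with "artefacted" positive,
  sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
- Problem sizes used by the shipped experiments: 216-record cohorts,
  60-frame curves, 10-seed repetitions for the mechanism comparison and
  10 seeded sessions for the peak-recovery summary — large enough for
  stable medians on a single workstation.

## Known limitations

- The artefact model is an additive dip with one shape family; real
  dark-rim artefacts vary with readout, field strength and motion.
- Flow truth ranges are plausible physiology, not measured values.
- Integer-frame alignment cannot represent sub-heartbeat bolus timing
  differences; with fractional inter-bolus offsets the h(0) estimate
  degrades (by design, this regime is excluded from the generator).
- The h(0) baseline's failure on artefacted curves is partly an effect
  of nonnegativity-constrained deconvolution of a clipped dip; other
  regularizers would fail differently.
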