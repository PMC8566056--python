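# mselat — multiscale-entropy lateralization of the epileptogenic hemisphere

`mselat` implements an analysis pipeline for lateralizing the
epileptogenic hemisphere in mesial temporal lobe epilepsy (mTLE) from
resting-state fMRI: region-wise BOLD complexity is quantified with
multiscale sample entropy (MSE), the entropy parameters are optimized
on the cohort by intergroup statistics and ROC/AUC sensitivity
analysis, biomarker regions are selected at the optimum, and the
hemisphere (left- vs right-positive hippocampal indicator) is
classified with an RBF-kernel SVM under leave-one-out
cross-validation.  It is written for methods researchers who want a
tested, reproducible implementation of this workflow, exercised
end-to-end on a synthetic cohort generator because clinical cohorts of
this kind are not publicly distributable.

## The statistic

For a region's time series x₁..x_N (N = 246 time points at TR = 2 s in
the reference design), the series is coarse-grained at scale τ,

    y_j = (1/τ) Σ_{i=(j−1)τ+1}^{jτ} x_i ,   j = 1..⌊N/τ⌋,

and sample entropy is computed on y:

    SampEn(m, r) = −ln(A/B),

with B the count of ordered template pairs of length m (Chebyshev
distance ≤ r·sd(x), self-matches excluded, positions 1..L−m) and A the
corresponding count at length m+1.  MSE(τ, m, r) = SampEn of the
τ-coarse-grained series; larger values mean more irregular dynamics.
The parameters are selected on the data: m ∈ {1, 2} by intergroup
significance counts over the (τ, r) grid, then r ∈ 0.30..0.60 (step
0.02) and τ ∈ 1..5 by per-region AUC.  Biomarkers are regions with
intergroup p < .01 at the optimum; their entropy values feed the SVM
((C, g) = (2^a, 2^b), exponents searched on [−10, 10]).

See `docs/methods.md` for conventions, design choices and limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on a
synthetic cohort (20 subjects, 90 regions, 246 time points, 9 planted
biomarker regions):

```sh
python analysis/01_simulate.py
python analysis/02_optimize_parameters.py
python analysis/03_select_biomarkers.py
python analysis/04_classify.py
python analysis/05_null_calibration.py
```

A run with the default seed prints (abridged):

```
stage m: grand-mean significant-region counts {1: 12.025, 2: 11.662} -> m=1
stage m: mean counts by tau {1: 4.625, 2: 18.562, ...} -> candidate scales (2, 5)
selected parameters: m=1, r=0.3, tau=2
13 biomarker regions at (m=1, r=0.3, tau=2), p < .01:
  ROI005: p=1.78e-07, AUC=1.00
  ROI021: p=3.99e-04, AUC=0.12
  ...
against planted truth: 9/9 recovered, 4 false positives
LOOCV over 20 subjects: 20 correct -> mean accuracy 100.00%
balanced 8-train / 12-test holdout: accuracy 100.00%
null t-test rejection rate at alpha=.05: 0.053 (nominal 0.05, 100 replicates)
null LOOCV accuracy, nested selection: 0.42 (chance = 0.5, 20 replicates)
```

Reading the output: significance counts collapse at scale 1 (4.6
regions, pure false positives) and peak at τ ≥ 2 — the planted group
difference lives in the slow dynamics and is invisible before
coarse-graining, so the optimization correctly picks τ > 1.  All nine
planted regions are recovered at p < .01 (AUC 1.00 means planted-region
entropy is consistently higher in the left-positive group; the ROC
orientation is never flipped, so a sub-0.5 AUC like ROI021's 0.12 marks
a region separating in the opposite direction).  This seed also drags
in four false positives — testing at data-selected parameters runs
slightly above the nominal 1% rate, a property of the procedure that
`analysis/05_null_calibration.py` quantifies.  On this synthetic effect
size the SVM separates the groups perfectly; on real 20-subject cohorts
accuracies in the 90% range are the realistic ceiling.

The same pipeline is available as a CLI (`mselat simulate|entropy|
optimize|biomarkers|classify|run-all`) and as a library
(`mselat.generate_dataset`, `mselat.optimize_all`,
`mselat.select_biomarkers`, `mselat.loocv`, ...).  Real data enter
either as per-subject TSV matrices (regions × timepoints, with a
manifest listing subject ids and labels) or as a preprocessed 4D NIfTI
volume plus an integer-labelled atlas via
`mselat.io.extract_roi_timeseries_nifti`.

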