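# Methods

`mselat` implements a lateralization pipeline for mesial temporal lobe
epilepsy (mTLE): given resting-state BOLD time series averaged over the
90 cortical regions of the AAL parcellation, it computes multiscale
sample entropy (MSE) per region, selects the entropy parameters
(m, r, τ) on the cohort itself, identifies biomarker regions whose
entropy separates the left- and right-positive groups, and classifies
the epileptogenic hemisphere with an RBF-kernel SVM.  Because no
clinical cohort of this kind is publicly distributable, the package
ships a synthetic-cohort generator that reproduces the statistical
structure the analysis assumes, and every stage is validated against
it.

## The entropy statistic

For a series x₁..x_N, coarse-graining at scale τ averages
non-overlapping windows:

    y_j = (1/τ) Σ_{i=(j−1)τ+1}^{jτ} x_i ,   j = 1..⌊N/τ⌋,

discarding the trailing N mod τ samples.  Sample entropy of the coarse
series y (length L) with embedding dimension m and tolerance r_abs is

    SampEn = −ln(A/B),

where B is the number of ordered pairs (i ≠ j) of length-m templates
with Chebyshev distance ≤ r_abs, A the same count for length-(m+1)
templates, and both template sets run over positions 1..L−m so that
every (m+1)-match is an m-match and A/B ≤ 1 (the Richman–Moorman
estimator with self-matches excluded; normalization constants cancel in
the ratio).  MSE(τ, m, r) is SampEn applied to the coarse-grained
series.

Numerical conventions, stated because the literature is not uniform:

- **r is a fraction of the standard deviation of the original series**
  (population sd, ddof = 0), computed *before* coarse-graining.  This
  is the convention of the classic multiscale-entropy literature; it
  makes a grid such as r = 0.3–0.6 meaningful across regions, and it
  means entropy at τ > 1 reflects both the regularity and the
  variance-retention of the coarse series.
- **Matches use d ≤ r_abs** (closed inequality).  For continuous data
  ties have probability zero; for quantized data the closed form is the
  one the brute-force oracle in the test suite also uses.
- **Zero counts yield an undefined (NaN, masked) value**, not an
  exception: small tolerances on short series legitimately produce no
  matches.  Downstream group statistics drop masked subjects per region
  and log the drop.
- The optimized implementation counts pairs via windowed distance
  matrices (memory-bounded chunking above 2048 templates) and, on
  parameter grids, thresholds each distance matrix at every r at once;
  it is exactly count-equivalent to the naive enumerator — the test
  suite asserts bit-identical (A, B) over random series, and grid
  evaluation is asserted identical to per-parameter evaluation.

## Parameter optimization

The three parameters interact, so they are selected in stages, each
formalizing an informal "pick the setting that looks best" rule into a
reproducible statistic:

1. **m ∈ {1, 2}** — for every grid point (m, τ, r), τ = 1..5,
   r = 0.30..0.60 step 0.02, count the regions whose entropy differs
   between groups (two-sample pooled-variance t-test, p < .05,
   uncorrected); select the m with the larger grand-mean count.  m ≤ 2
   is dictated by series length: with 246 time points, reliable SampEn
   estimation needs roughly 10^m–20^m samples.
2. **r** — at the selected m and the two scales with the highest mean
   counts (the "candidate scales"), compute each region's ROC/AUC for
   group separation and select the r maximizing the mean over candidate
   scales of the mean of the top-2 *folded* AUCs.
3. **τ** — with (m, r) fixed, the same top-2 folded AUC score over
   τ = 1..5.

Folding (AUC ↦ max(AUC, 1−AUC)) is used for ranking only: a region
whose entropy runs consistently *lower* in the positive group is just
as informative a separator.  Reported tables keep the raw orientation
(positive class = left group, rule "entropy ≥ threshold ⇒ positive"),
so AUC < 0.5 values are visible.  The top-k rule (k = 2, configurable)
formalizes judging a setting by its best exemplar regions; k, the
screening α = .05, and the number of candidate scales (2) are
configurable in `ParamGrid`.  All argmax ties break toward the smaller
parameter value, deterministically.  AUC is computed as the exact
Mann–Whitney pair probability (ties count ½), which equals the
trapezoidal area under the threshold-sweep ROC curve; the test suite
holds both routes to each other and to an exhaustive pair enumerator.

Because every stage conditions on the same cohort, the procedure is a
*data-dependent* selection; the biomarker test that follows does not
correct for it.  This mirrors the conventional workflow the package
reproduces, and its cost is measurable: on planted synthetic data the
false-positive count at the selected parameters runs slightly above
the nominal binomial expectation (see "What the synthetic validation
shows" below).

## Biomarker selection and classification

At the optimized (m, r, τ), biomarker regions are those with intergroup
p < .01 (uncorrected t-test; a Benjamini–Hochberg option exists but is
off by default so that the default pipeline is the conventional
single-threshold procedure).  The biomarker entropy values form the
feature vectors of an RBF SVM.  (C, g) = (2^a, 2^b) are searched
exhaustively with exponents on [−10, 10] (default step 0.2, the
standard libsvm-style grid; the kernel width is parameterized as
g = 1/2σ²), scored by stratified k-fold cross-validation accuracy
(default 5 folds) on the training subjects, with features standardized
inside each fold using training-fold statistics.  Ties prefer the
smallest C, then the smallest g.  Evaluation is leave-one-out
cross-validation over the N = 20 subjects — (C, g) are re-tuned on
every training set of N−1 — plus an optional single class-balanced
8-train / 12-test split.

Biomarker selection is by default performed once on the full cohort and
held fixed across LOOCV folds.  That is the conventional procedure for
cohorts of this size, and it leaks selection information into the
evaluation: on null data it inflates apparent accuracy above chance.
The `selection_scope="nested"` mode re-selects biomarkers inside every
training fold (falling back to the single smallest-p region when
nothing passes α, so every fold stays classifiable) and is calibrated
at chance on null data.  The test suite demonstrates the gap rather
than hiding it; the default replicates the conventional analysis, the
nested flag is the methodologically correct alternative.

## The synthetic cohort generator

Each region series is `slow + fast`: a stationary AR(1) component
(`lfilter` with a stationary initial draw and 100-sample burn-in) plus
independent white noise with sd = `fast_noise_sd_ratio` × sd(slow),
standardized to mean 0, sd 1.  Group labels are 1 = left-positive
(first 10 subjects), 0 = right-positive.  In nine *planted* regions the
AR(1) coefficient of group-1 subjects is `ar_slow_group1`; everywhere
else both groups use `ar_slow_group0`.  Everything is deterministic
given the config seed.

The defaults are `ar_slow_group0 = −0.7`, `ar_slow_group1 = +0.7`,
`fast_noise_sd_ratio = 1.0`.  The opposite-sign, equal-magnitude design
is deliberate: the two structured components are equally predictable at
the native sampling rate, so scale-1 sample entropy barely separates
the groups, but window-averaging cancels the anti-persistent group-0
component while the persistent group-1 component survives it — the
group difference is expressed in the slow dynamics and emerges only at
coarse-graining scales τ > 1, which is precisely the structure the
τ-selection stage is designed to detect.  Exploratory scans during
design showed that a *one-sided* difference in positive AR coefficients
cannot deliver this: the regularity effect (more persistent ⇒ more
template matches at scale 1) and the amplitude effect (persistent
variance survives averaging ⇒ relatively larger coarse series against a
fixed tolerance) partially cancel, leaving both a residual scale-1
signature and a weak coarse-scale one.  Effect magnitude was chosen so
that planted regions separate decisively (per-region |t| ≈ 10 at τ ≥ 2
with n = 10+10) while non-planted regions stay exactly exchangeable;
`fast_noise_sd_ratio` scales the overall effect down if a weaker regime
is wanted.

What the generator does *not* emulate: hemodynamic response, spatial
correlation between regions, motion or physiological artifacts,
scanner drift, preprocessing residue, or any realistic BOLD spectrum —
regions are independent by construction, and the "fast" noise is white.
Passing tests therefore show that the pipeline's statistics behave as
designed under the assumed two-group complexity structure; they say
nothing about effect sizes, confound structure, or region identities in
real mTLE cohorts.

## What the synthetic validation shows

- **Null calibration.**  On null cohorts (no planted regions) the
  per-region t-test rejects at its nominal rate (≈5% at α = .05;
  ≈0.9 of 90 regions at α = .01), and nested-selection LOOCV accuracy
  is centered at chance.
- **Scale structure.**  On planted cohorts the planted-region entropy
  difference at τ = 3 exceeds that at τ = 1 in the large majority of
  seeds, and the optimization selects τ > 1 essentially always.  The
  selected scale is usually τ = 2 (the anti-persistent component is
  already cancelled at pair-averaging, and ties break toward smaller
  τ); the selected r tends to the lower grid edge for the same
  saturation reason.
- **Recovery.**  Biomarker selection at the recovered parameters
  recovers ≥ 8 of the 9 planted regions with few false positives in the
  large majority of seeds.  The false-positive count runs somewhat
  above the binomial expectation for a fixed test — the price of
  testing at data-selected parameters, reported here as a property of
  the procedure.
- **Classification.**  LOOCV accuracy on planted cohorts is ≥ 0.9 in
  the large majority of seeds; on null cohorts, fixed (leaky) selection
  is optimistic while nested selection is at chance.

Monte-Carlo problem sizes used by the test suite and the acceptance
script (number of replicates, SVM exponent-grid resolution for repeated
runs) are chosen to keep a full run on one CPU in minutes; the
properties above are insensitive to these resolutions, and the
per-analysis scripts use the full default grids.

## Known limitations

- The region-count tables and AUC tables are descriptive; no
  multiple-testing correction is applied anywhere in the default path,
  by design.
- The NIfTI front-end only averages voxels over integer atlas labels on
  a shared grid; it performs no registration, resampling, filtering or
  motion correction — those are upstream of this package.
- Sample entropy is the only complexity statistic implemented; no
  composite/refined MSE or fuzzy entropy variants.
- With 10 subjects per group, the t-test operates at the edge of its
  comfort zone; Welch's correction is available (`welch=True`) but the
  pooled test is the default to match standard practice for balanced
  designs.
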