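# Methods

## Edge time series and sampled FC

A run is a time × parcel matrix of parcellated BOLD signal. Each parcel is
z-scored over the full run using the **population** standard deviation
(ddof = 0); the edge time series of pair (i, j) is the element-wise product
of the two z-scores. This convention makes the time-mean of the ETS equal
the full-run Pearson correlation exactly, an identity the test suite asserts
to 1e-12 and that the package relies on conceptually: FC is the average of
per-frame co-fluctuations, so selecting frames re-weights FC.

RSS(t) is the root sum of squares over all edges at frame t. Frames are
ranked by descending RSS with ties broken by ascending frame index (a stable
sort, so the ranking is deterministic). Three samplers turn a ranking into a
frame set: sequential (top or bottom ⌊pct/100·T⌋ frames), individual bins
(T must divide evenly into n_bins; bin 1 is the highest-RSS bin), and
combined bins (the disjoint union of two bins). FC on a frame subset is
plain Pearson correlation on the extracted rows — means and standard
deviations are recomputed on the subset. A `reuse_global_zscores` variant
(keeping full-run means/sds) was considered and not implemented as the
default because subset-Pearson is the plain reading of "correlation on the
selected time points"; a parcel constant on a subset gets zero correlations
with a warning rather than an error, keeping batch processing total.

FC matrices are averaged element-wise on raw correlations (no Fisher z):
first across phase-encoding directions (two matrices per subject, the
fingerprinting input), then across days (one matrix per subject, the
prediction input).

## Preprocessing

The nuisance design holds, for each of WM/CSF/GS: the series, its square,
its backward-difference derivative (leading 0, length-preserving), and the
squared derivative — 12 columns; binary spike regressors for frames with
FD > 0.25 mm are appended after the 12 and are not part of that count.
Cleaning detrends linearly, bandpasses (zero-phase Butterworth, order 5 per
side via `sosfiltfilt`, default 0.008–0.08 Hz), and then regresses the
design out — with the design itself detrended and filtered through the same
operators, and an intercept added to the regression. Filtering both sides
before projecting is what makes the cleaned signal exactly orthogonal
(|r| < 1e-8) to every retained design column; projecting first and filtering
afterwards would re-introduce correlation with the confounds. Collinear
design columns are dropped greedily with a warning. Cleaning is off by
default for synthetic cohorts, which are generated clean.

Run trimming takes head/tail frame counts explicitly (e.g. 20/18 turning a
478-frame run into 440) rather than assuming a source run length.

## Fingerprinting

The similarity matrix holds Pearson correlations between day-1 and day-2
upper-triangle FC vectors for all subject pairs. Identification accuracy
averages the day1→day2 (row argmax) and day2→day1 (column argmax) rates; a
**tied** maximum counts as a failed identification — conservative and
deterministic. I_self is the mean diagonal, I_other the mean of all
off-diagonal entries of the single cross-day matrix, and
I_diff = (I_self − I_other) × 100; a `both_directions`-style averaging of
the transposed matrix changes nothing for I_diff because transposition
preserves the diagonal and the off-diagonal set, so only I_acc uses both
directions explicitly. The bootstrap resamples n subjects with replacement,
keeps the unique set (resamples with < 2 unique subjects are redrawn, a
vanishing-probability event at realistic n), and recomputes both metrics;
conditions are compared by two-tailed Wilcoxon signed-rank tests with
Bonferroni correction, with an explicit degenerate path (p = 1, flagged)
when all paired differences are zero.

## Prediction

Kernel ridge with a Pearson kernel is the main model: the Gram matrix is
the subject × subject correlation of FC edge vectors, and the dual system
(K + αI)c = y − ȳ is solved directly; α = 0 from the printed grid is
handled by a fixed 1e-10 jitter rather than exclusion. The α grid is the
39-value list {0, 1e-5, 1e-4, 1e-3, 0.004, 0.007, 0.01, 0.04, 0.07, 0.1,
0.4, 0.7, 1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 10, 15, 20, 30, 40, 50, 60, 70,
80, 100, 150, 200, 300, 500, 700, 1000, 1e4, 1e5, 1e6}; a 50-value
log-spaced C grid (0.01–100) is exported for SVC-style classifiers for
completeness. Outer folds are grouped k-fold (families never split; 10
folds by default) or repeated k-fold (5 × 5 for unrelated cohorts); the
inner 5-fold CV selects the grid value maximising mean inner-validation
Pearson r (accuracy for classification), first-in-grid on ties. Gram
matrices are computed once per inner split, not per grid value.

Confound handling is CV-consistent everywhere, including inside the inner
loop: an OLS model of target on confounds (with intercept, collinear
columns dropped) is fitted on the training partition only and applied to
both partitions. For classification, binary labels cannot be meaningfully
residualised, so confounds are regressed from the **features** instead,
again train-fitted only; this is a documented design choice, not a
symmetric operation to the regression recipe. The leakage audit makes the
guarantee testable: `fit_fold` touches only training rows, so permuting
test-fold targets leaves every fitted coefficient bit-identical.

CBPM screens edges by train-set correlation with the target at an
uncorrected two-tailed p < 0.01 (exposed), sums positive- and negative-set
edge values per subject, and fits a two-regressor linear model; if no edge
survives it falls back to an intercept-only model with a warning. The ridge
classifier is primal ridge on ±1-coded labels with sign decisions.

Scores implement the textbook formulas directly: Pearson's r in its
sums-of-products form, R² = 1 − SSE/SST, MAE, accuracy, and balanced
accuracy as the mean of sensitivity and specificity (requires two classes).

## ROPE comparison

The posterior of the mean difference of paired fold scores is Student-t
with dof k − 1, location mean(d), and scale
sqrt((1/k + n_test/n_train)·var(d, ddof=1)) — the correlated Bayesian
t-test for cross-validated results, whose variance correction accounts for
the overlap of training sets across folds. The plain paired posterior
(factor 1/k) is available via `correlated=False` and is the exact limit as
n_test/n_train → 0. The ROPE half-width defaults to 0.05 in the score's own
units (five accuracy points, or 0.05 in r). Zero-variance differences give
a point mass at mean(d), so the probabilities remain defined; the decision
symbol is the region with the highest posterior mass, ties resolved toward
"=".

## Structure–function coupling

SC matrices are consumed as symmetric nonnegative streamline counts with
zero diagonal; raw counts are used by default with an optional log1p
transform (common practice; either choice only monotonically rescales the
edge weights). Coupling is the Pearson correlation of FC and SC
upper-triangle vectors. Residualisation regresses each subject's FC vector
on [1, SC vector] across edges — per subject, not per edge — and returns
the residuals as that subject's feature row; the operation is idempotent to
1e-10.

## Synthetic cohorts

The generator draws each run as x(t) = L_s·u(t)·g(t) + ε(t): L_s is the
Cholesky factor of the subject's correlation matrix Σ_s, u(t) are iid
standard-normal latents, g(t) is an event-gain trace (1 outside
Poisson-placed bursts of duration `event_duration` frames and gain
1 + `event_amplitude` inside), and ε is white noise with sd `noise_sd`.
Σ_s is a hierarchical blend: population correlation + family perturbation
(weight `family_mix · subject_snr`) + subject perturbation (weight
`subject_snr`), renormalised to a correlation matrix. Scaling the family
weight by `subject_snr` makes the zero-SNR cohort fully exchangeable, so
identification falls to 1/n exactly rather than to 1/family-size. The
multiplicative gain raises co-fluctuation amplitude brain-wide, which is
the structure the RSS ranking detects; additive spikes would not reproduce
that HACF/LACF behaviour.

Phenotypes are effect_size · z(signal) + confound_weight · z(confound
component) + N(0, target_noise_sd²), where the signal is a random linear
combination of a chosen number of **true** FC edges (standardised across
subjects) and the confound component is a random direction in
(age, sex, mean-FD) space. FD is positive AR(1) noise
(fd_base · exp(0.4·AR1), AR coefficient 0.4, base 0.12 mm — a realistic
resting-state level), independent of the event gain unless
`fd_event_coupling` > 0, so the RSS–FD diagnostic can be validated in both
the null and the coupled regime. SC counts are Poisson with rate
sc_scale · (Σ_pop + 1)/2 per edge, making SC–FC coupling positive by
construction.

Defaults (4 runs = 2 days × 2 encodings, TR 0.72 s, event rate 4/run,
amplitude 1.5, duration 5 frames, noise sd 0.5) emulate the regime of a
two-day, four-run resting-state cohort. What the generator does **not**
emulate: haemodynamic autocorrelation and nuisance spectra (latents are
white), voxel-level structure, scanner drift, or realistic phenotype
distributions. Passing recovery tests therefore demonstrates the
correctness and leakage-safety of the estimators under the stated
covariance model, not performance on real fMRI.

## Problem sizes and numerical choices

Recovery checks run at sizes chosen to put each estimand in its
identifiable regime while staying desk-sized: fingerprint recovery uses 60
subjects × 100 parcels × 1200 frames (high SNR → I_acc = 1; zero SNR →
binomial chance band around 1/60); prediction recovery uses 200 subjects ×
15 parcels, so the 105 edges are fewer than the ~180 training subjects per
fold and a noise-free linear target is recoverable (r ≥ 0.9) — with many
more edges than subjects no linear method could recover it and the check
would measure sample size, not correctness; the null-phenotype check
averages 20 seeds at 60 subjects. The RSS–FD null uses a 1000-run cohort.

Ties and degenerate inputs are handled deterministically throughout
(stable sorts, first-in-grid hyperparameter ties, tie-as-failure
identification, flagged undefined scores as NaN). All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; the
pipeline writes results as sorted-key JSON and fixed-format TSV, so reruns
with the same config are byte-identical.

## Limitations

- The generator's covariance-blend SNR knob is not calibrated to any
  empirical test-retest reliability; `subject_snr` is in arbitrary blend
  units.
- Sequential thresholds, bins, and bin pairs must divide the run length
  evenly for bin strategies; no interpolation is attempted.
- The correlated t-test treats fold scores as exchangeable given the
  overlap correction; with grouped folds of very unequal sizes the
  n_test/n_train factor is an approximation using the average fold size.
- SVC classifiers are not implemented (the ridge classifier covers the
  classification path); the C grid is exported for users who wire up their
  own.
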