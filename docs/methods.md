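# Methods

This note documents the models, conventions and numerical choices behind
`edaffect`, in the order the pipeline applies them, followed by what the
synthetic generator does and does not emulate.

## Signal model and preprocessing

A recording is a skin-conductance trace `x[i]` (µS) at sampling rate `fs`
(nominally 4 Hz), with event markers in epoch seconds. Sample `i` is taken
to occur at `start_time + i/fs` (sample-start convention). Markers must
form consecutive begin/end pairs, one pair per exercise in protocol order;
segment windows are half-open `[begin, end)`. A lone trailing marker is an
error rather than an implicit "until end of recording".

**Wavelet denoising.** Each segment is denoised with a Symlet wavelet
(default `sym4`; the Symlet order is configurable since nothing in the
analysis pins it down). The decomposition depth is capped at
`level(n) = min(⌊log₂ n⌋, 10)`; the floor is needed because a wavelet level
must be an integer, and the implementation additionally respects
PyWavelets' filter-length cap. Each detail band is soft-thresholded at its
own universal threshold `σ_j √(2 ln n_j)` with `σ_j` the band's
MAD/0.6745 noise estimate. Soft universal thresholding is a standard
default; the shrinkage rule is deliberately kept local to one function so
alternatives can be swapped in.

**Tonic/phasic split.** The tonic component is either the per-segment OLS
trend (`linear`, the default — consistent with the regression-line features
the battery computes) or a centred moving median (`moving_median`, default
window 4 s). The phasic component is the residual, so
`tonic + phasic == samples` holds exactly (asserted to 1e-9 in tests). This
is a trend-removal model, not a deconvolution model: no sudomotor-driver
estimation is attempted.

## GSR event detection

An event trigger is a strict interior local maximum of the first-difference
sequence of the phasic component with positive value; a plateau counts
once, at its first sample. The event peak is the first subsequent local
maximum of the phasic trace itself, or the final sample when the trace ends
rising. Amplitude is the phasic value at the peak; event energy is the
squared peak amplitude (summed per segment for `gsr_energy`), which matches
the µS² scale of segment-level energies; an integral definition was
considered and rejected as the default because scalar peak energy is what
the count/energy features need. Events with amplitude above 1.5 µS are
*significant*.

Two practical conventions matter:

- **Minimum amplitude.** Deflections below 0.05 µS (configurable,
  `min_amplitude`) are discarded as noise. Without a floor, the literal
  definition counts machine-precision ripples of a detrended straight line
  as "events", which makes the count features meaningless on clean data.
  0.05 µS is the conventional SCR scoring floor in psychophysiology;
  passing `min_amplitude=0` restores the raw definition (the test suite's
  brute-force equivalence check runs in that mode).
- **Derivative = first difference**, with no smoothing; smoothing belongs
  to the denoising stage.

## Feature battery

26 features per segment: `mean, standard_deviation, median, variance, p25,
p75, quartile_deviation, minimum, maximum, moment4, moment5, skewness,
kurtosis, rms, total_sum, entropy, reg_slope, reg_intercept,
reg_mean_abs_residual, reg_rmse, n_crossings, n_gsr, rpm, gsr_energy,
n_sig_gsr, sig_gsr_energy`.

Conventions: sample (n−1) variance and SD; percentiles by linear
interpolation; 4th/5th central moments are population moments; skewness
`m₃/m₂^1.5` and non-excess kurtosis `m₄/m₂²` (a Gaussian scores 3); both
defined as 0 for a constant segment. RMS is the root mean square of the
signal itself, while `reg_rmse` is the RMS of the residuals about the OLS
line — the literature is ambiguous between the two readings ("root mean
square error" vs "root mean square"), so both are computed as separate
features, which is also why the battery has 26 names where a 25-count is
sometimes quoted. Entropy is Shannon entropy (base 2) of a 16-bin histogram
over `[min, max]` with `0·log 0 = 0`; bin count is configurable in spirit
but fixed at 16 here since nothing downstream is sensitive to it.
`n_crossings` counts sign changes of the OLS residuals, ignoring exact
zeros. Statistics are computed on the raw segment; GSR detection runs on
the phasic component of the denoised segment — both feature passes exist
because the processing order of the source analysis places the statistics
list before the denoising step.

## Feature selection

- **CV filter**: reject features with `|s/x̄| < 0.5` across participants
  (ties kept; zero-mean features are undefined and rejected). The absolute
  value matters because features such as `moment5` can have negative means.
- **WCSS filter**: for each feature, the minimal two-cluster within-cluster
  sum of squares of its values (optimal 1-D two-means, computed by dynamic
  programming over contiguous splits of the sorted values — optimal
  clusters are contiguous in 1-D). Keep features with WCSS ≤ threshold, or
  the `top_k` smallest (default mode, k = 13, reproducing the published
  selection cardinality without the histogram-eyeball threshold step).
  Features are *not* standardised before WCSS by default: the published
  WCSS spread (0.02–300) implies raw scales; a `standardize` flag exists.
- **Named sets**: contextual subsets (`statistical`, `signal`, `error`) and
  fixed per-exercise presets (`paper_ex1/2/3`) are shipped for users who
  want the published subsets instead of data-driven selection. In the
  Exercise-3 preset, "root of the mean square error" is mapped to
  `reg_rmse` and "energy of signal" to `rms` (the published mean values for
  that row sit on the signal's µS scale, not the residuals').
- **PCA**: covariance eigendecomposition of the (z-scored by default)
  matrix, keeping *all* components, ordered by decreasing eigenvalue with a
  deterministic sign convention (largest-|loading| entry positive).
  Implemented directly on `numpy.linalg.eigh` so the component count always
  equals the feature count, even with fewer participants than features.
  Constant columns are dropped with a warning before z-scoring.

## Clustering and evaluation

Hierarchical clustering builds an agglomerative tree (scipy linkage;
`single`/`average`/`complete`, default `average` — a robust middle ground,
since the linkage is not otherwise determined) on one of three distances:
Euclidean, Spearman (1 − rank correlation of the two feature rows) and
correlation (1 − Pearson r; the "difference from maximal correlation"
phrasing in the source is read as the standard correlation distance). The
two-cluster cut undoes the final merge (`cut_tree` by merge order), which
still yields exactly two clusters when merge heights tie. k-means uses
k-means++ starts, 10 restarts, tolerance 1e-6, fixed seed.

Cluster indices are arbitrary, so a polarity rule orients them against the
reference: `fixed` keeps labels as produced (cluster 0 = the first
participant's cluster), `best_match` applies the agreement-maximising flip.
Recovery experiments use `best_match`; `fixed` exists because agreement
below 50% is meaningful when no relabelling is applied.

Confusion counts treat label 1 (the high-score side of the reference
scale) as positive; for the JAWS_neg scale, label 1 therefore means
negative-dominant, and reports carry the reference provenance so this stays
explicit. Undefined rates (empty margins) are reported as missing, never
coerced to 0.

## JAWS scoring

Twelve Likert items (1..5), six positively and six negatively keyed (the
item→polarity map is user configuration; the generator's convention is
items 1–6 positive). The total reverse-codes negative items
(`6 − raw`) before summing, giving `total = pos + 36 − neg` with ranges
12–60 and 6–30 — the reading that reproduces the published mean identity
`18.29 + 36 − 9.90 = 44.39`. Reference labels come from optimal 1-D
two-means on the chosen scale; the induced threshold is the midpoint of the
inter-cluster gap; fixed-threshold dichotomisation uses strict `>` (one
rule had to be fixed for integer thresholds; half-integer thresholds make
it moot).

## Synthetic generator

Defaults are the study conditions the pipeline targets: 41 participants,
4 Hz, exercises of 60/10/10 s with 5 s rests and 10 s padding, a balanced
21/20 latent class split. Per class: Poisson SCR trains at 8/min vs 1/min
with lognormal peak amplitudes (median 2.0 vs 0.5 µS, σ = 0.4), on a
uniform 2–6 µS baseline with a small linear drift, plus 0.02 µS Gaussian
sensor noise; SCR shape is the Bateman biexponential
`e^(−t/4) − e^(−t/0.75)` normalised to unit peak. Questionnaire items load
on a single latent trait per participant (class means ±1, trait SD 0.5,
item-trait correlation 0.8, equal-width cuts at ±0.5, ±1.5). A
`separation` dial linearly interpolates every class-dependent parameter
toward the pooled mean: 1 = default contrast, 0 = indistinguishable
classes.

What the generator does *not* emulate: overlapping/superposed SCR dynamics
at high rates, motion artefacts, electrode drift or detachment, temperature
coupling, habituation across exercises, item-specific questionnaire factor
structure, or missing data. Passing recovery tests therefore show the
pipeline recovers a clean latent two-class structure at realistic rates and
amplitudes — not that it is robust to real-world artefacts.

## Canonical experiments

`label_recovery_accuracy(seed, separation)` is the package's reference
experiment: simulate a default cohort, featurise the 60 s first exercise
(the segment that carries most event-rate information), apply the default
CV → WCSS(top-13) cascade, PCA, k-means, `best_match` orientation against
the latent truth. At separation 1 the mean accuracy over 20 seeds is ≈ 0.94;
at separation 0 it sits near chance (≈ 0.54; slightly above 0.5 because
`best_match` takes the better of the two orientations). Problem sizes in the
acceptance script (20 seeds, 200 oracle trials, n ≤ 12 exhaustive WCSS
enumeration, n ≤ 10 k-means enumeration) were chosen to keep the full
recomputation under a minute while leaving Monte-Carlo error well inside
the asserted margins.

## Known limitations

- The feature battery is time-domain only; no frequency-domain or
  deconvolution-based SCR descriptors.
- `wcss_1d` is exact but O(k·n²); fine for cohort-sized inputs, not for
  thousands of points.
- The correlation/Spearman distances are undefined for constant feature
  rows and raise rather than imputing.
- Two-cluster support only (k = 2 is baked into the selection statistic,
  the clustering cut and the evaluation); this is by design.
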