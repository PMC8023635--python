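# Methods

`comanet` re-implements, as a tested pipeline, a resting-state EEG analysis
for acute post-traumatic unresponsive states: spectral band power and
phase-lag connectivity features from low-density clinical EEG, graph-theoretic
network summaries, cross-montage reliability screening, canonical-correlation
inference against the clinical picture, and stepwise prognostic regression on
transformed GOSE outcomes. Because the underlying clinical recordings are not
shipped with the package, every stage is exercised end-to-end on synthetic
EEG and synthetic cohorts whose generative structure is under test control.

## Preprocessing

Pipeline order is fixed: band-pass filter → 10-s epoching → artifact
rejection → average reference.

* **Filter.** Zero-phase Chebyshev type-II band-pass specified by its band
  edges (default 0.5–45 Hz): maximally flat passband (≤ 0.8 dB two-pass
  deviation), ≥ 28 dB two-pass attenuation from half an octave outside each
  edge. Chebyshev-II was chosen over a low-order Butterworth because the
  narrow 45→50 Hz transition (mains rejection at 256/512 Hz clinical rates)
  demands a sharp upper edge that a 4th-order Butterworth cannot provide;
  the inverse-Chebyshev form keeps the passband ripple-free, which matters
  for relative band-power ratios. Signals are demeaned and zero-padded by
  6/lo seconds before `sosfiltfilt` — the impulse response at a 0.5 Hz edge
  rings for seconds, far beyond the default reflection padding, and the
  residual edge transient otherwise dominates stopband measurements.
* **Epoching.** Consecutive non-overlapping 10-s epochs; the trailing
  remainder is discarded. Usable data length is epochs × 10 s.
* **Artifact rejection.** Interactive ICA-based review is not reproducible
  programmatically, so rejection is a deterministic two-stage screen:
  channels whose per-epoch variance z-score (across channels) exceeds
  `z_var` (default 3) in more than half the epochs are dropped; then epochs
  in which any remaining channel's peak-to-peak amplitude exceeds `ptp_uV`
  (default 200 µV) are dropped. Both thresholds are exposed in config and
  CLI. No channel interpolation afterwards: interpolated channels would
  inject synthetic signal into connectivity estimates.
* **Reference.** Instantaneous mean of all channels subtracted per sample.

## Spectral features

Welch PSD per channel (2-s Hamming segments, 50 % overlap, 0.5 Hz
resolution), averaged within and across epochs, clipped to the analysed
range 0.5–45 Hz. Relative band power = trapezoidal band integral divided by
the 0.5–45 Hz integral. Bands are delta [0.5, 4), theta [4, 8), alpha
[8, 13]; delta is integrated from the 0.5 Hz high-pass edge because bins
below the cutoff hold filter roll-off, not signal; half-open edges prevent
the shared 4 and 8 Hz bins from being counted twice. The two power features
are the channel means of relative alpha and relative delta power.

## Connectivity

Debiased weighted phase lag index (dwPLI), the debiased squared-WPLI
estimator. Per 10-s epoch, Hanning-tapered FFT per channel; one
cross-spectral observation per epoch per in-band frequency bin. With
`I_k = Im(Z_k)` over the K epochs of a pair at one bin,

    dwPLI = ((Σ I_k)² − Σ I_k²) / ((Σ |I_k|)² − Σ I_k²)

with 0/0 defined as 0, then averaged over in-band bins. The estimator uses
only the imaginary cross-spectrum, so instantaneous (zero-lag,
volume-conducted) coupling does not register; debiasing removes the positive
small-sample bias of WPLI², at the cost of slightly negative values under
independence. Median over the strict upper triangle gives the two
connectivity features (alpha, delta).

## Graph metrics

Connectivity matrices are thresholded proportionally: negatives clipped to
0, the `round(density · n(n−1)/2)` strongest pairs keep their weights
(ties broken by lexicographic pair order, for determinism). Metrics are
computed on the weighted thresholded graph at densities 90 %…10 % in 10 %
steps (the grid granularity is our choice; only the 90-10 % range is part of
the analysis design) and averaged arithmetically:

* **Modularity Q** (Newman weighted form) of the best partition found by
  Louvain with 100 restarts from seeded shuffled node orders (node order is
  canonicalized to sorted labels first, making features invariant to input
  channel order). Candidate partitions are re-scored by our own modularity
  implementation; the highest-Q partition wins. igraph's C implementation
  performs the Louvain sweeps.
* **Participation coefficient** P_i = 1 − Σ_m (κ_im/κ_i)², isolated nodes
  0; the feature is the population SD over nodes.
* **Clustering coefficient** (Onnela weighted form, weights normalized by
  the maximum); degree-<2 nodes get 0; feature = mean.
* **Modular span**: for each module with at least one internal edge, the
  weight-weighted mean Euclidean distance between its electrode positions
  (unit-head-radius coordinates, so spans are in head-radius units);
  feature = mean over such modules. The prose definition ("average
  topographical distance spanned by a module") admits several formalizations;
  this weight-weighted form is isolated in one function so it can be swapped.

The eight features of a recording are: `alpha_rel_power`,
`alpha_median_dwpli`, `alpha_modular_span`, `alpha_participation_sd`,
`delta_rel_power`, `delta_median_dwpli`, `delta_clustering_mean`,
`delta_modularity`.

## Montages

`ld1020` is the 19-electrode clinical 10/20 montage. The high-density
healthy-control layout is not part of the published analysis
description, so `hd91` is a fixed
91-site superset: the 86 scalp sites of the extended 10-10 table (synonym
and ear/mastoid labels excluded) plus five 10-5 sites; any fixed superset of
the 10/20 set preserves the validation design. Coordinates come from the
standard montage tables shipped with mne and are radially projected to unit
head radius. Old-nomenclature labels (T3/T4/T5/T6) are mapped to
T7/T8/P7/P8 on EDF read; mastoid channels are read but excluded from
analysis montages.

## Synthetic EEG generator

One source per electrode. Per band, narrowband Gaussian sources are made by
band-pass filtering white noise; a 1/f broadband background (white noise
shaped to amplitude slope −1, flattened below 0.5 Hz) takes the band-profile
remainder; components are variance-normalized so band-profile weights are
variance fractions. Within a coupled band, each channel's source is
√c·(module driver, phase-rotated) + √(1−c)·independent noise. The driver
copy for the k-th member of a module is rotated by k·lag_deg via
analytic-signal multiplication by e^{−iθ}: a uniform rotation of all members
would leave pairwise lags at zero and dwPLI blind to the coupling, so the
rotation is staggered; pairwise lags are then multiples of lag_deg. Zero-lag
volume conduction is emulated last: x ← (1−m)x + m·(Gaussian-smoothed
neighbour average) with spatial width 0.5 head radii. All draws come from
one seeded generator; outputs are bit-identical given the seed.

Defaults emulate a healthy eyes-closed recording: 5 min (matching the mean
usable length of the acute clinical recordings) at 256 Hz, alpha-dominant
band profile (delta 0.15, theta 0.10, alpha 0.35, background 0.40), a
two-module anterior/posterior alpha coupling at c = 0.5, 45° lag, mixing
m = 0.2. What the generator does **not** emulate: volume conduction through
a realistic head model, non-stationarity, muscle/ocular artifact morphology
(only amplitude spikes, via a helper used to test rejection), and 1/f knee
behaviour. Passing tests therefore demonstrate correctness of the
estimators and the stated robustness properties (e.g. insensitivity of
dwPLI to zero-lag mixing), not performance on real clinical EEG.

## Synthetic cohorts

Clinical covariates are drawn independently (age uniform 18–90, sex male
with probability 15/18 as in the published cohort table, CT grade uniform 1–6, days
since injury uniform 3–24, GCS uniform 3–11). Each patient has a latent
alpha level α ~ N(0,1) and an independent slow-wave level δ ~ N(0,1); the
latent outcome is

    h = β_gcs·z(GCS) + β_alpha·z(α) + ε,  ε ~ N(0, 0.6²)

mapped onto GOSE 1–8 through seven cutpoints (default: octiles of h's
marginal distribution, i.e. a uniform GOSE margin); the 6-month GOSE adds
N(0, 0.3²) drift to h before cutting. The patient's EEG gets alpha band
weight logistic(α); the remaining spectral mass is split between delta and
the rest with delta's logit-share perturbed by 0.8·δ — without the
independent slow-wave factor, relative delta power would be a deterministic
mirror of alpha (band fractions are compositional), which is both
unrealistic and makes predictor identity ill-posed.

Default effect sizes β_gcs = 0.7, β_alpha = 0.4 are the recovery-experiment
conditions. Note that even with independent delta variation the *extracted*
relative delta power remains strongly negatively correlated with relative
alpha power (compositionality plus the 1/f background concentrating ~88 % of
its power below 4 Hz); the predictor-recovery experiment therefore offers
the five clinical candidates plus extracted relative alpha power, and not
the delta mirror, as regression candidates — with both, "which proxy
enters" is an arbitrary tie-break rather than a recovery question.

## Reliability screening

Cross-montage validation runs the full pipeline per healthy subject twice:
on all high-density channels, and on the 19 10/20 channels selected
*before* preprocessing (so the low-density path mirrors clinical data
exactly, including its average reference). Features are correlated across
paths over subjects; Shapiro–Wilk on each marginal gates Pearson vs
Spearman (Spearman if either p < 0.05 — the exact bivariate normality
test of the original analysis is unnamed, so the conservative OR-gate on marginals is
used); selection at raw p < 0.05 with no multiplicity correction (a
deliberate reproduction of the original selection rule). The same machinery
correlates features computed from the first 10 vs the first 5 minutes.

Experiment populations: montage-validation subjects carry a single
whole-head alpha network with per-subject synchrony c ~ U(0.2, 0.9) (keeps
median dwPLI continuous and unimodal across subjects, which a gated
correlation measure needs); segment-reliability subjects instead vary their
alpha and delta module count (1–3) as well as c, giving the structural
individual differences that the graph features index. Validation recordings
are sampled at 128 Hz (ample for a 45 Hz analysis edge).

## Inference

* **CCA** on z-scored variable sets via QR + SVD (singular values of
  Q_x'Q_y are the canonical correlations). Rank deficiency raises an error
  naming the collinear columns.
* **Permutation test**: rows of one set shuffled, CCA refit, the *largest*
  canonical correlation recorded per shuffle (2000 by default); every
  observed pair is compared against this max-statistic null, which accounts
  for selecting the best pair. p = plain proportion of null maxima strictly
  greater than the observed correlation — the plain-proportion convention
  (not (b+1)/(P+1)) is used deliberately, so p = 0 is attainable.
  Implementation note: the QR factor of a row-permuted matrix is the
  row-permuted Q, so each shuffle costs one small matmul + SVD.
* **Loadings**: Pearson correlation (two-tailed) of each original variable
  with the opposite set's first canonical variate.
* **Rank-based inverse normal transform** with the Blom offset 3/8
  (z_i = Φ⁻¹((r_i − 3/8)/(n + 1/4)), tied ranks averaged); the offset is
  configurable since the literature varies in the constant.
* **Stepwise regression** (forward entry p ≤ 0.05 on the partial-F test,
  backward removal p ≥ 0.10, fixed point termination) after listwise
  deletion (dropped ids logged). Constant candidates are excluded up front;
  forward entry stops when another predictor would exhaust the residual
  degrees of freedom. Standardized betas come from refitting on z-scored
  outcome and predictors; raw coefficients, adjusted R², the model F with
  (k, n−k−1) df and the per-step log are reported. R²-change compares
  nested models on the identical case set.

## Problem sizes and numerical conventions

Experiments are sized to finish in minutes on one CPU: estimator-vs-oracle
checks use 50 random instances of ≤ 8 nodes/≤ 5 epochs at tolerance 1e-12;
permutation calibration uses 500 null cohorts (n = 40, 3+3 variables, 200
permutations); predictor recovery uses 20 cohorts of 100 patients with 30-s
recordings (band power stabilizes well within 30 s); reliability
experiments use 20 subjects of 5 or 10 minutes at 128 Hz. Community
detection in the reliability experiments keeps the default 100 restarts.
Degenerate inputs have fixed conventions: dwPLI 0/0 → 0, isolated node
participation → 0, degree-<2 clustering → 0, modules without internal edges
are skipped by modular span (0 if none remain), thresholding that would
retain zero edges raises.

## Known limitations

* The generator's electrode-level sources cannot probe source-space or
  head-model effects; cross-montage agreement on synthetic data is easier
  than in real hdEEG.
* Louvain restarts make partitions deterministic given the seed but not
  canonical; modularity-degenerate graphs can flip partitions between
  adjacent densities (the density average damps this).
* The stepwise procedure inherits the known instability of stepwise
  selection at small n; it is reproduced here because it is part of the
  analysis design under study, not because it is recommended.
* Applied to the clinical recordings this analysis design was developed
  on (deposited externally, not distributed here), the pipeline can
  recompute the corresponding cross-montage correlations and regression
  models, but exact agreement is not asserted: several internals of the
  reference MATLAB implementation (modular-span formula, density step,
  rank-INT constant) are unstated, and this package fixes each by a
  documented choice of its own.
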