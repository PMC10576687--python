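# Methods

## Overview

`microdyn` analyses resting-state, high-density EEG along two axes and
validates every stage end to end on synthetic cohorts with planted,
recoverable structure:

1. **Temporal dynamics** — segmentation of the scalp field into four
   quasi-stable microstates (canonically labelled A–D) and per-subject
   dynamics features: mean duration, occurrence rate, time coverage and
   the matrix of transition probabilities (24 features at K = 4).
2. **Spectral structure** — absolute band power per channel (delta,
   theta, low/high alpha, beta, gamma, plus the theta/beta ratio),
   organised into subject × channel matrices and decomposed by group ICA
   into spatial components whose per-subject loadings are compared
   between groups.

A linear SVM with recursive feature elimination, inside stratified
five-fold cross-validation, quantifies how well the combined features
discriminate patients from controls and one patient subtype from the
other.

## Synthetic cohort model

Real pediatric recordings for this design are not publicly deposited, so
the package ships a generator that emulates the study conditions: 91
average-referenced channels at 250 Hz, 120 s per subject, 54 controls and
107 patients (53 combined-subtype, 53 + 1 inattentive) by default.

The signal model per subject is

```
V(t) = s_seg · A · c(t) · T_L(t)  +  regional band oscillations  +  white noise
```

* `L(t)` — a four-state first-order Markov chain: geometric dwell times
  (mean 80 ms by default, inside the 60–120 ms range typical of resting
  microstates) and a row-stochastic, zero-diagonal transition matrix over
  segment successions.
* `T_k` — four fixed unit-norm, average-referenced topographies on a
  synthetic disc montage: two saturated diagonal gradients (A, B), an
  anterior–posterior gradient (C) and a fronto-central focus (D).  The raw
  gradients are symmetrically (Löwdin) orthogonalized — the orthonormal
  set closest to the raw geometry — so that each planted state carries
  spatial information the others do not.  Real microstate maps are
  mutually correlated; we deliberately trade that realism for exact
  ground-truth identifiability, which is what the validation needs.
* `c(t)` — a unit-RMS oscillatory carrier: a 10.3 Hz alpha tone plus a
  0.6-weighted 6.7 Hz theta tone with random phases.  The carrier choice
  is load-bearing.  A slow or rectified envelope parks most of the
  topography's power near DC; with ~80 ms dwells the switching process has
  a Lorentzian spectrum with a corner near 2 Hz, and the mandatory 1 Hz
  high-pass then removes a large slow component of the signal, leaving
  interference that corrupts per-sample labelling beyond repair.  An
  oscillatory carrier places the topography's power at the carrier
  frequencies ± the switching bandwidth — safely inside the 1–45 Hz
  pass-band — which is also how real microstate topographies survive
  band-pass filtering.
* `s_seg` — an independent random ±1 per microstate segment, so all
  analysis must be polarity invariant (the resting-EEG convention).
* Segment switches are cross-faded over 20 ms (raised cosine) in cohort
  data; instantaneous topography steps are non-physical and ring under a
  zero-phase band-pass.  The raw primitive keeps hard switches by default
  so that noiseless identifiability (every GFP-peak map equals ±T exactly)
  holds for it.
* Regional oscillations plant the group spectral effects: a 2.5 Hz tone
  on fronto-central channels (delta), 6 Hz on fronto-temporal channels
  (theta, which drives the theta/beta ratio) and 40 Hz on
  posterior-occipital channels (gamma), each with per-channel random
  phase and a per-subject amplitude (SD 0.3 µV between subjects).
* White sensor noise, 1 µV per channel by default.

Planted group effects mirror the reported directions for this design:
patients get weaker A↔C switching, a 20 % reduction of →C inflow,
stronger B↔D switching, a longer state-D dwell (95 vs 80 ms), and +1.5 µV
fronto-central delta and +1.2 µV fronto-temporal theta amplitude; the
combined subtype additionally gets a shorter state-A dwell (70 ms),
further A↔C/B↔D shifts, more →B inflow and +1.2 µV posterior-occipital
gamma.  Demographics (sex, age, handedness, rating-scale scores) are
sampled from the reference cohort's margins.

What the generator does **not** emulate: volume conduction from real
sources (no leadfield), correlated physiological background (the
non-microstate residual is white), artifacts (blinks, EMG, electrode
drift), and mutually correlated microstate maps.  Passing tests therefore
demonstrate that the algorithms recover known structure under realistic
band-limited, polarity-ambiguous conditions — not that real recordings
would yield the same parameter values.

## Preprocessing

Channel exclusion (a configurable name list; the classic 129→91 lateral
exclusion is the worked example) → zero-phase band-pass (1–45 Hz,
linear-phase FIR, Hamming design, transition width ≈ the low edge, exact
group-delay compensation) → anti-aliased polyphase resampling to 250 Hz →
average reference → rejection of contiguous 2-s windows containing any
|V| > 100 µV sample → concatenation and truncation to the first 120 s.
Filtering happens at the native rate, before resampling, so the 45 Hz
edge cannot alias.  Microstate timing must not be phase-distorted, hence
the zero-phase constraint.  Shorter-than-requested survivors produce a
warning, not an error, and the retained duration is logged in the
recording's history.

## Microstate analysis

* **GFP** is the per-sample spatial standard deviation of the
  average-referenced field.  Peaks (strict rise, non-strict fall; plateau
  start) mark high-SNR topographies; only those enter clustering.
* **Modified k-means**: assignment by maximal squared spatial correlation
  (polarity-invariant); centroid update as the dominant eigenvector of
  the assigned maps' channel covariance; iterate to an assignment
  fix-point (max 100 iterations); best of `n_restarts` restarts by GEV.
  A plain-k-means switch (signed correlation, mean centroids) exists for
  comparison.  The default restart count is 100 for production use;
  scaled-down analyses in this repository use 5–30 restarts, which the
  noiseless identifiability test shows is already far past saturation for
  data of this SNR.
* **Two-level design**: subjects are clustered individually (on their own
  GFP peaks); each group's individual maps are pooled and re-clustered
  into the group model.
* **Canonical labels**: the cross-group mean model is matched to four
  reference gradients by the exhaustive best permutation (24 candidates)
  over summed |spatial correlation|; each group model is then matched to
  the labelled mean the same way.  The built-in references are the
  generator's own canonical gradients; users may supply their own
  reference maps.
* **Back-fitting** labels every sample with the map of maximal |spatial
  correlation|.  By default no temporal regularization is applied (ties
  keep the previous label; zero-variance samples inherit it).  The
  pipeline enables a ±1-sample triangular evidence window (GFP²·corr²
  pooled with neighbour weight 0.5): an oscillatory field passes through
  zero many times per second, those samples carry no evidence of their
  own, and their labels are otherwise decided by noise — which chops the
  dwell statistics (recovered mean durations fall to roughly half the
  planted value without the window, and are within a few percent with
  it).  This is the package's analogue of the temporal smoothing that
  microstate toolboxes conventionally apply, kept minimal (one sample of
  context) so genuinely short segments survive.
* **Features**: run-length statistics of the label sequence.  Boundary
  (truncated) segments are included.  Transition probabilities are
  per-source-state over consecutive distinct segments — the only
  normalisation that makes the 12 off-diagonal entries independent of
  recording length.  Absent states get zeros rather than errors.
* **GEV** = Σ GFP²·corr² / Σ GFP², with polarity-invariant correlation,
  over all samples.

## Spectral analysis and group ICA

Welch PSD per channel (2-s Hamming windows, 50 % overlap — mirroring the
preprocessing segmentation), integrated over each band with the trapezoid
rule on the FFT grid, gives absolute power in µV².  Band edges are
treated as closed intervals; the shared edge between adjacent bands
contributes to both, which matters only at the resolution bandwidth.
The theta/beta ratio is computed channel-wise, so it forms a subject ×
channel matrix like the power bands.

Each of the seven matrices is column-centred, reduced by PCA to M
components over subjects, and the component "time courses" over channels
are unmixed by extended Infomax (mne's implementation, fixed seed).
Spatial maps are the independent rows over channels; loadings are the
least-squares per-subject coefficients, so `loadings @ maps` equals the
rank-M approximation of the centred matrix.  Components are
sign-oriented so the reference group (controls, or the combined subtype)
has the higher mean loading; maps are z-scored across channels and
channels with |Z| > 2 are reported for components that pass a two-sample
t-test at the Bonferroni level 0.05/M.  The sweep helper decomposes at
M ∈ {5, …, 10}; analyses in this repository report M = 5 (the smallest
order in the sweep) unless noted.

## Group statistics

* Two-way fixed-effects ANOVA (group × state) in long format per feature
  family, reporting the interaction F.  States are technically
  within-subject; the fixed-effects form is used deliberately and noted
  here because the original design's ANOVA variant is not further
  specified anywhere.  Constant input raises rather than returning a
  meaningless F.
* Post-hoc pooled-variance two-sample t-tests per feature with Bonferroni
  correction at 0.05/24.
* Pearson χ² on 2×2 demographic tables **without** continuity correction
  — the convention validated by reproducing the printed 0.73 / 0.34 /
  4.17 from the reference cohort's count tables (with Yates' correction
  they do not reproduce).
* Pooled-variance (Student) t from raw data or summary statistics;
  Welch's variant is available via `scipy` directly but the pooled form
  is the package default for the same reproduction reason.
* Kruskal–Wallis (tie-corrected) compares topography similarity between
  groups; the ranked scalar is each subject's best |spatial correlation|
  between their individual maps and the grand-mean map of each state —
  one defensible operationalization of "comparing topographies", made
  explicit here because the quantity being ranked is otherwise
  under-determined.

## Classification

Within each training fold of a stratified (class-ratio-preserving)
five-fold split: features are z-scored with training statistics only, a
linear SVM (C = 1) is fitted, and the feature with the smallest squared
weight is eliminated, one per step, down to a single feature — yielding a
full ranking and a nested family of subsets.  Each nested subset's fitted
model is evaluated on the held-out fold; the fold's "best" subset
maximizes test accuracy (ties go to the smaller subset).  Reported
accuracy/sensitivity/specificity are means over fold bests; sensitivity
is recall of the patient class.  Selection counts (0–5 per feature) tally
appearances in fold-best subsets.  Because the best subset is chosen on
the held-out fold, the reported "best accuracy" is optimistically biased;
the permutation-null check in the test suite quantifies that bias
(chance-level inputs score above 0.5 but within the documented band).

## Numerical choices and degenerate inputs

* Clustering restarts draw initial maps without replacement from the peak
  maps; empty clusters are re-seeded from the worst-fitted map.
* The eigenvector centroid update sign-aligns with the previous centroid,
  making restarts deterministic given the seed.
* Back-fit ties (exact correlation equality) keep the previous label;
  leading degenerate samples get state 0.
* Transition rows with no outgoing segment are all-zero and flagged by
  the conservation tests rather than renormalised.
* All randomness flows through `numpy` Generators; cohort subjects use
  independent `SeedSequence` children, so cohorts are bit-reproducible
  and subjects independent of cohort ordering.
* The pipeline writes a manifest with SHA-256 hashes of every artifact;
  the reproducibility test asserts byte-identical re-runs.

## Problem sizes used in this repository

The validation suite uses scaled cohorts chosen to exercise every code
path at comfortable statistical power: 20-subject cohorts (120 s each)
across 20 seeds for Markov parameter recovery; 32-subject cohorts (40 s)
across 10 seeds for the planted delta-effect ICA recovery; 200 synthetic
null matrices for family-wise-error calibration; 500 replicates for
type-I-error calibration of the ANOVA, t and Kruskal–Wallis paths; and a
12-subject pipeline for bit-reproducibility.  The analysis drivers use a
36-subject, 60-s cohort.  Defaults in `CohortSpec` remain the full-scale
study conditions (161 subjects, 120 s).

## Known limitations

* The generator's residual is white noise; real EEG residuals are
  spatially and temporally correlated, so real-data GEV (~80 %) is lower
  than the synthetic cohorts' (~92 %).
* Orthogonalized templates overstate the separability of real microstate
  classes; recovery tolerances reported here do not transfer to real maps.
* The fixed-effects ANOVA ignores the within-subject correlation across
  states; its interaction test is calibrated under the generator's
  exchangeable null (verified empirically) but is not a mixed model.
* Manual artifact-removal steps (ocular ICA, bad-channel interpolation)
  are intentionally absent; `apply_external_cleaning` is a recorded no-op
  hook in the preprocessing chain where users can plug an external
  cleaner.
* EDF files can be read (via mne) but not written in this environment;
  the plain-text matrix format is the canonical interchange.
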