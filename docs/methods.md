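# Methods

## Paradigm model

Stimulus sequences consist of 38 isochronous syllables (250 ms
inter-onset interval, 4 Hz) grouped into 19 disyllabic units (2 Hz).
Target trials replace one unit with a same-syllable repetition; sessions
allocate `round(target_fraction * n_trials)` targets exactly (default
29% of 210 trials, split equally across conditions, remainder assigned
to conditions in sorted order), deterministically rather than by
Bernoulli draws so counts are testable.  Conditions are interleaved
within blocks (default 15).  Syllables beginning with a plosive hold
230 ms of content preceded by 20 ms of silence, modeling oral occlusion;
all tokens occupy the full 250 ms slot.

Syllable repetitions are reserved for targets: generated sequences avoid
both immediate unit repeats and repeated syllables across unit
boundaries (a cross-boundary repetition would sound like a target).  The
constraint is dropped for degenerate lexicons (for example a single
word) that cannot satisfy it.

## Lexicon profiles and transitional probabilities

Syllables are CV(C) combinations with explicit (onset, nucleus, coda)
annotation and a manner-of-articulation class per onset consonant.
Three profiles control the statistical structure of the syllable stream:

* `native_like` / `foreign_like` — each first syllable maps to a unique
  second syllable through phoneme-level bijections (consonants mapped
  between manner classes of equal size, vowels and codas permuted).
  Because the mapping is bijective at every projection level, all six
  phonological measurements (identity, CV pattern, onset, onset manner,
  rime, cross-boundary phoneme pair) inherit predictable within-word
  transitions.  Wordform frequencies follow a Zipf-like profile
  (frequency proportional to rank^-0.8, minimum 10).
* `random` — pseudo-word templates are position-balanced draws from a
  shared inventory, and sequence generation re-draws each pseudo-word
  freshly, so the stream is a (repetition-free) uniform syllable stream
  with no grouping cue.

TP(e2 | e1) = freq(e1,e2) / freq(e1).  Transitions of generated
sequences are scored against a reference bigram table.  For synthetic
lexicons the reference is the *analytic expected* bigram table of the
generative stream model: within-word bigrams occur with the word
probability, between-word bigrams with the product of word-final and
word-initial marginals (each class carrying half the stream's
transitions); for the random profile both classes are uniform over
non-identical pairs.  This plays the role that a language corpus plays
for real stimuli; a brute-force stream-counting oracle verifies it in
the tests.  Laplace smoothing (default pseudo-count alpha = 1,
configurable — no canonical value exists) covers unseen pairs; the
within/between contrast uses a two-sided Mann-Whitney test with an exact
(exhaustive-permutation) null when both samples have at most 8 values
and a tie-corrected normal approximation otherwise, Bonferroni-corrected
by the declared family size.  An optional flag drops TP values more than
2.5 SD above the sample mean before testing.  Word selection retains
entries with wordform frequency >= 10 and within-word syllable
transition probability (wordform frequency over the summed frequencies
of wordforms sharing the first syllable) >= 0.003.

## Audio and envelope model

Each syllable renders as a band-limited noise burst (second-order
Butterworth band around a label-specific log-uniform centroid,
400–3600 Hz) under a Hann window of the token's content duration,
peak-normalized per token.  Because the amplitude window is identical
across odd and even positions, the envelope modulation spectrum peaks at
4 Hz with no systematic 2 Hz component (verified to within 2 SD of the
neighbor bins across sequences).

The speech envelope is the across-band mean Hilbert magnitude of 8
zero-phase third-order Butterworth bands spaced equidistantly on the
ERB-rate scale (21.4 log10(1 + 0.00437 f)) between 100 and 8000 Hz — the
cochlear-map interpretation adopted here; a log-spaced variant is
available.  Envelopes are anti-aliased and resampled to the neural rate
(default 500 Hz).  Modulation spectra are periodograms of the
mean-removed envelope over a 9 s window (resolution 1/9 Hz, placing
2 Hz and 4 Hz exactly on bins).

## Trial simulator

Trials are simulated at 1200 Hz over the epoch (−2.1, 9.6) s by default
(tests and examples use 300–600 Hz to keep runtimes in seconds; results
do not depend on the rate as long as the analysis bands fit).  Each
trial mixes, through a quasi-dipolar toy leadfield:

1. a 4 Hz auditory response in both auditory ROIs — the 3–5 Hz band of
   the trial's syllable envelope (phase-locked to the acoustics, with no
   spectral spill into the 2 Hz band), multiplied by (1 + 0.9 m(t)) where
   m(t) is a standardized low-pass (0.3 Hz) random fluctuation;
2. a 2 Hz sinusoid in the ROIs named by `effect_2hz[condition]`, gated
   to the stimulation period, with instantaneous amplitude
   1 + cfc_strength · 0.9 m(t).  With cfc_strength > 0 the 2 Hz power
   envelope therefore follows the 4 Hz amplitude fluctuation — the
   planted cross-frequency dependence; with 0 they are independent;
3. spatially correlated 1/f^a noise (independent spectrally shaped
   channels mixed by a fixed random matrix), scaled so that the ratio of
   projected-signal RMS to noise RMS equals `snr`.

Two realism choices matter for beamforming.  Dipole orientations default
to each source's dominant (most magnetically visible) leadfield
direction; a `random` mode exists but makes reconstruction quality
depend on an arbitrary orientation draw.  Both tagged responses receive
fixed per-source phase offsets drawn uniformly within a third of a cycle
(tens of milliseconds of timing jitter): perfectly coherent extended
patches are partially cancelled by adaptive beamformers, which no real
cortical patch is.  A constant phase offset leaves coherence magnitudes
with the envelope unchanged.

`simulate_source_trials` returns the same generative model sampled
directly in source space (per-source independent 1/f noise, no sensor
projection), for testing source-level estimators against ground truth.

The forward model is parametric: sensors on a spherical cap (radius
7 cm) with slightly tilted pickup directions (so no orientation is
silent), sources on a regular 0.8 cm grid, field of orientation e at
sensor i proportional to (e x d)/|d|^3 projected on the pickup.  ROIs
(`auditory_left`, `auditory_right`, `frontal`, `posterior`) are disjoint
nearest-neighbor sets around lateral/anterior/posterior seed points.
It stands in for anatomy-based head models, which are out of scope; its
purpose is to make localization claims testable, not to be realistic.

## Sensor pipeline

Band-pass 1–160 Hz and line band-stops (49.5–50.5, 99.5–100.5,
149.5–150.5 Hz), all fourth-order zero-phase (forward-reverse)
Butterworth.  Artifact screening z-scores the 110–140 Hz amplitude
envelope (muscular, threshold z = 15) or the absolute first difference
of a 9-sample running-median-filtered signal (jumps, z = 30), averaging
z over sensors so that evidence accumulates across sensors; z statistics
are pooled over the trial set per sensor, because per-trial
normalization lets an artifact inflate its own denominator and caps the
attainable z below any useful threshold.  Range rejection discards
trials whose per-channel min-max range exceeds a threshold (default
0.75e−5, in recorded units; simulated data use a data-scaled value).
Epoching crops to (−2.1, 9.6) s and resamples (polyphase, anti-aliased)
to 500 Hz, giving 5850 samples.  Trial matching keeps correct-response
trials and subsamples every condition to the smallest count (seeded).
M100 sensors are the k sensors with the largest RMS evoked amplitude
80–120 ms after tone onset, ties broken toward lower indices.

## Tagging spectra and trends

Evoked power is the single-taper (Hann by default) periodogram of the
time-domain trial average over (0.5, 9.5) s — the first 500 ms is
excluded as onset response — restricted to 1–7 Hz at 1/9 Hz resolution.
The tagging statistic is the neighbor-bin contrast: power at the target
bin minus the mean of bins at offsets {−3, −2, +2, +3}; offsets ±1 are
excluded to avoid leakage from the target bin, and a relative
(ratio-based) variant is available since the choice between subtraction
and relative change is not canonical.

Trial-wise power uses leave-one-out jackknifing.  Raw leave-one-out
values are anti-correlated with the left-out trial's own contribution;
jackknife pseudo-values (n·full − (n−1)·loo) restore the sign and are
used when fitting trends.  Block trends are OLS fits on orthonormal
polynomial bases of block order (signs fixed so a negative quadratic
coefficient means inverted-U), compared by BIC between first- and
second-order models.  This is a fixed-effects simplification; random-
slope mixed models are out of scope.

## Beamforming

DICS: sensor CSD averaged over trials and band bins (common-filter band
1.333–4.666 Hz), regularized as C + λ·mean(diag)·I with λ = 10% of the
mean sensor power; per source the orientation maximizing output power
(eigenvector of the smallest eigenvalue of Re(LᴴC⁻¹L)) reduces the
three-orientation leadfield to a scalar column l, and w = lᴴC⁻¹/(lᴴC⁻¹l)
(unit gain).  The filter is computed once across conditions and applied
to each condition, so condition contrasts are not biased by filter
estimation.  LCMV is the time-domain analog on the band-limited
(1.5–4.5 Hz) covariance, yielding virtual-channel time series.  No depth
normalization is applied because all statistics are condition contrasts
through a common filter.

Cerebro-acoustic coherence: per-trial tapered Fourier coefficients at
4 Hz for all sensors and the paired envelope; sensor coefficients are
projected through the common DICS filter (equivalently, the filter is
applied to both auto- and cross-spectral terms — "project first, then
cohere" is available behind the same computation), magnitude-squared
coherence is formed across trials per source, Fisher z = arctanh(|coh|)
applied, and ROI means reported.  For independent signals the estimator
has the known small-sample bias E[coh²] ≈ 1/n_trials, which the tests
verify.

## Cross-frequency coupling

Source trials are downsampled to 100 Hz, band-passed (fourth-order
zero-phase Butterworth) at 1.5–2.5 and 3.5–4.5 Hz, and Hilbert power
envelopes are concatenated across trials per condition.  Envelopes are
copula-normalized (average ranks mapped through r/(n+1) and the inverse
normal CDF) and MI in bits is −½ log₂(1 − r²) on the normalized pair,
with the analytic Gaussian entropy bias (digamma expansion) subtracted
by default — small negative values are then possible and reported
as-is.  The map computes MI per seed voxel against every source and
averages over the seed-ROI voxels ("per-voxel then average"; the
ROI-mean-envelope alternative is a flag).  Perfect dependence is capped
with a warning.  A surrogate null permutes the seed's trial blocks
before concatenation (copula normalization commutes with a block
permutation, so normalized envelopes are permuted directly) and records
the map maximum per surrogate.

Envelopes of band-limited responses share the trial-locked evoked time
course (onset/offset transients at stimulus edges), so even with no
planted coupling the raw MI between two stimulus-driven sources is not
exactly zero; the surrogate null retains that shared structure and is
the appropriate reference, which is how the no-coupling tests are
framed.

## Cluster statistics

Node-wise t (paired or pooled-variance independent), thresholded
two-sided at cluster alpha = 0.05; suprathreshold nodes are kept only if
at least `min_neighbors` (default 2) of their graph neighbors are also
suprathreshold, then clustered by connectivity per sign; the cluster
statistic is the summed t.  The Monte-Carlo reference distribution
records, per permutation (within-subject label exchange for paired,
group-label permutation for unpaired), the most extreme summed cluster
t; each observed cluster's two-sided p is (b+1)/(n_perm+1) against the
absolute permutation maxima, so p can never be zero.  Adjacency comes
from a distance threshold over node positions (face connectivity at one
grid step for volumetric grids).  No correction is applied across
separate cluster tests, matching the design each contrast is run under.

ROI tests are Wilcoxon signed-rank (exact null for small untied samples)
or Mann-Whitney, with corrected alpha = alpha / n_tests (for example
0.05/12 ≈ 0.0042 for six ROIs by two hemispheres).

The mixed ANOVA implements the balanced split-plot decomposition for one
between-subject factor and two within-subject factors: each within
effect and its interactions with the between factor are tested against
the corresponding factor-by-subject error stratum, the between effect
against subjects-within-groups; partial eta squared is
SS_effect/(SS_effect+SS_error).  Unequal group sizes are handled by
group-weighted sums; incomplete within-subject cells raise.  The
implementation is validated against a frozen R `aov` (Error-strata)
decomposition of a seeded dataset.

## Problem sizes and what the tests show

Tests and the acceptance checks run on scaled-down problems chosen as
the package's own desk-scale defaults: 32 sensors, a 5x5x4 grid of 100
sources at 0.8 cm spacing, 10–24 trials per condition, 300–600 Hz
simulation rates, and 19 simulated participants for the end-to-end run.
Multi-seed guarantees (localization within one grid step at SNR 10 in
>= 19/20 seeds, auditory-ROI coherence dominance in >= 18/20, CFC
top-decile recovery in >= 18/20 on ground-truth source trials,
family-wise error of the cluster test within [0.01, 0.10] over 200 null
runs) are statements about this synthetic model, not about real MEG:
the simulator has no eye/heart artifacts, no head movement, no
anatomical variability, stationary noise, and effects planted in known
ROIs.  Passing therefore shows the estimators and statistics are
implemented correctly and recover known truth at realistic SNR — it
does not certify effect sizes or power for recorded data.  Through an
LCMV projection on the toy geometry the CFC map is blurred by the
beamformer's one-grid-step point spread, so voxel-precise top-decile
recovery is demonstrated on ground-truth source trials, with the
projected map tested for elevated MI in and around the planted region.

## Known limitations

* The toy forward model is not anatomical; absolute localization
  geometry is meaningful only relative to its own grid.
* Coherence and MI maps inherit beamformer leakage; interpretations are
  contrast- and ROI-based, as in the analysis design.
* The mixed ANOVA assumes complete within-subject cells and does not
  implement sphericity corrections (2-level factors need none).
* The statistical-learning trend analysis is fixed-effects only.
* Audio synthesis targets envelope structure, not speech realism (no
  formants, no pitch contour).
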