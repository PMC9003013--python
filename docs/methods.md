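# Methods

This note documents the models, estimators, conventions and design choices
behind `eegdynet`, in the spirit of a statistical-software methods appendix.
It states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model of the synthetic cohort

Clinical EEG of the kind this framework targets is rarely shareable, so the
package ships a generative stand-in. Each channel of a record is

    s_i(t) = κ(t) · c_i(t) + (1 − κ(t)) · o_i(t) + σ η_i(t)

where

* `c(t)` is a shared narrow-band source: Gaussian noise band-passed to
  `band_center ± band_halfwidth` (default 10 ± 2 Hz), unit variance. Filtered
  noise rather than a sinusoid, so spectral estimators see realistic,
  finite-bandwidth spectra with naturally drifting phase.
* `c_i(t)` is the shared source rotated by a fixed per-channel phase offset
  drawn uniformly in (0, π/4]. Without lags, the mixing would be purely
  instantaneous and the two volume-conduction-robust estimators (iCOH, PLI)
  would be identically zero on coupled channels — the offsets are what makes
  those pipelines testable. A `max_phase_offset=0` switch restores pure
  zero-lag mixing for identity tests.
* `o_i(t)` are independent narrow-band oscillations in the same band.
* `η_i(t)` is white (optionally 1/f) noise, `σ = 1` by default.

The coupling strength κ carries the group structure on three scales:

| level | default | rationale |
|---|---|---|
| group mean κ | PC 0.3, PE 0.6 | the primary group contrast in coupling |
| per-record jitter (SD) | 0.08 | subjects differ; keeps groups from being trivially separable |
| temporal modulation (SD) | PC 0.05, PE 0.20 | an Ornstein–Uhlenbeck drift of κ with ~10 s timescale |

The asymmetric temporal modulation is deliberate and is the scientific crux
of the emulation: the patient-group recordings this framework is aimed at
are *seizure* EEG, whose defining property is strong nonstationarity of
coupling, while control recordings during sleep are comparatively
stationary. A cohort whose groups differ only in mean coupling cannot, even
in principle, reward sliding-window analysis over whole-record analysis —
the window summaries then add only estimator noise (we measured exactly
that: with equal modulation the dynamic iCOH condition scored ~0.76 vs
~0.96 for static). With the modulation contrast, window-to-window
variability of connectivity carries genuine group information that only the
dynamic features can see. The modulation depths were set from the measured
estimator noise floor (window-mean MSC fluctuates with SD ≈ 0.004 from
estimation alone; 0.05 and 0.20 modulation produce SD ≈ 0.005 and ≈ 0.013),
so the contrast is resolvable across ~98 windows without saturating either
group.

What the generator does **not** emulate: seizure waveform morphology,
artifacts (blinks, EMG), 1/f background structure by default, volume-
conduction geometry, or any spatial organisation of the montage. Passing
tests therefore demonstrate correct and internally consistent *methodology*
(estimators, thresholding, features, validation hygiene) and the *ordinal*
behaviour of the pipeline under controlled coupling contrasts — not
clinical performance on real EEG.

## Preprocessing

Downsampling uses polyphase anti-aliased resampling. Band-pass filtering is
a Hamming-windowed linear-phase FIR applied forward–backward (zero phase,
FFT convolution, reflection padding), with transition bandwidth 25% of the
lower band edge and the tap count capped at a third of the record. Zero
phase matters: any inter-channel group delay introduced by filtering would
be read as spurious phase coupling by PLI/iCOH. The filter family and order
are implementation choices — common EEG practice — not prescribed by the
framework itself.

Segmentation produces `floor(duration / min_len)` consecutive segments; a
trailing remainder shorter than `min_len` is appended to the last segment
rather than discarded, and records shorter than `min_len` pass through
whole with a warning.

## Connectivity estimators

Coherence-family estimators use Welch averaged periodograms with 1 s Hann
segments at 50% overlap, constant detrending, and an unweighted mean over
in-band frequency bins. One-second segments are the only well-conditioned
choice inside 3 s sliding windows; the same parameters are used for
whole-record (static) estimation for comparability. Two estimator
properties worth knowing:

* **Delay bias.** For a pure d-sample delay the Welch coherence estimate
  converges to the squared taper autocorrelation at lag d, not to 1
  (≈ 0.988 for 3 samples at 1 s / 100 Hz segments). Longer segments shrink
  the bias; a test pins the effect to its closed form.
* **Noise bias of |Im K|.** With ~5 segments per 3 s window, the absolute
  imaginary coherency of uncoupled channels has a substantial positive
  bias, which compresses mean-level group differences in windowed iCOH.

PLI is computed from Hilbert instantaneous phases with the signed phase
difference wrapped to (−π, π]; the first and last 10% of each analytic
signal are trimmed before averaging (Hilbert boundary distortion is severe
in short windows). The classical formulation this follows defines PLI on
the *signed* difference; a formulation that first takes the absolute phase
difference and then the sign would be identically nonnegative and
degenerate, so the signed convention is used. iCOH and Pearson weights take
absolute values because network edge weights must be nonnegative.

## Threshold selection

Group-averaged networks (over participants for static; over participants
and windows for dynamic) are thresholded on a 1% grid: at proportion p the
`floor(p·E)` lowest-weight edges are removed (stable tie-break by weight,
then lexicographic node pair) and connectivity is tested. The selected
proportion is one grid step below the smallest disconnection point across
groups, and is then applied *proportionally* to every individual network
(per-network edge count, floor rounding). Individual thresholded graphs may
be disconnected; only the averages are guaranteed connected.

## Topological features and their conventions

The five features deliberately mix weight conventions — the historical
defaults of classical graph libraries, and the only combination under which
a weighted diameter of ~0.2 can coexist with an average path length of ~1.6
on the same 19-node graph:

* average vertex strength: weighted;
* average path length: unweighted hop count over connected pairs;
* diameter: weighted shortest paths with edge weight as length;
* transitivity: binary skeleton, 3·triangles / connected triples;
* small-world index `S = (C/C_rand)/(L/L_rand)` with C = transitivity,
  L = hop path length, and the baseline the mean over `n_random = 20`
  seeded Erdős–Rényi G(n, m) graphs matched in node and edge count.

Disconnected graphs are handled by computing path-based metrics on the
largest connected component (with a warning and a component count carried
in outputs). Per-window small-world baselines derive their seeds
deterministically from the base seed and window index.

## Dynamic features

Windows of 3 s stepped by 1 s (2/3 overlap) give `floor((T−3)/1)+1`
snapshots (98 for a 100 s record); a trailing partial window is dropped.
Summaries are the sample SD (n−1) and linear-interpolation quantiles
(median, IQR), yielding 20 features named `{mean,sd,median,iqr}-{feature}`.
The threshold proportion is selected once at cohort level and reused for
every window.

## Selection, PCA and cross-validation

Univariate screening tests each feature with a two-sample t-test when both
groups pass Shapiro–Wilk at 0.05, otherwise the Wilcoxon rank-sum
(Mann–Whitney) test; features with p > α (default 0.05) are dropped, with
no multiplicity correction by default (a Benjamini–Hochberg flag exists).
Constant features get p = 1 with a warning. Note the small-sample
behaviour: at n = 3 per group the exact rank-sum test cannot reach
p ≤ 0.05, and tiny evenly spaced samples pass the normality gate, so the
t branch applies to them.

PCA standardises features and keeps the leading components whose cumulative
explained variance first reaches 85% (the scree criterion made
reproducible). By default selection, scaling and PCA are all re-fit inside
each training fold of LOOCV, so the held-out unit never influences its own
preprocessing; a "global" mode fits them once on the full table for
comparability with workflows that order the steps that way (it leaks, and
is off by default). If a training fold retains no feature, that fold
predicts the training majority class with a chance-level score — the honest
baseline when nothing informative survives.

The six classifiers run with their scikit-learn defaults (seeds pinned;
convergence warnings of the default iteration budgets suppressed rather
than silenced by parameter changes). AUC is computed from pooled held-out
scores (decision function where available, positive-class probability
otherwise); per-model results retain the better accuracy and the better AUC
of the with-/without-PCA variants, each flagged. `cv_unit="subject"` groups
fragments of one recording into a single fold, since fragment-level LOOCV
on split records leaks subject identity; fragment-level mode exists for
comparability and its leakage caveat applies.

## Acceptance experiment design and problem sizes

The end-to-end discrimination experiment uses the full default cohort
(20 + 16 records, 19 channels, 100 s at 100 Hz) and analyses connectivity
in the band the synthetic source occupies (8–12 Hz). The in-band choice is
an experiment-design decision: the stand-in cohort couples only in a 4 Hz
band by construction, and averaging estimators over a 44.5 Hz full band
dilutes that coupling with noise-only bins — a property of the synthetic
cohort's narrowbandness, not of the estimators (broadband seizure EEG has
no such mismatch). The null-cohort check re-runs the identical pipeline
with both groups at the midpoint coupling and modulation; its accuracies
are compared against the 95% normal-approximation binomial band around
chance, 0.5 ± 1.96·√(0.25/36). The selection-calibration check pools
univariate screening over 12 smaller null cohorts (10 + 8 records, 60 s)
to keep its runtime modest; topological features within a cohort are
correlated, so the retained fraction is compared loosely (< 0.18) against
its nominal 5% level rather than at binomial tightness.

## Known limitations

* Estimator bias in 3 s windows is substantial for iCOH and coherence; the
  dynamic pipeline's value rests on summaries across ~100 windows, not on
  per-window precision.
* The small-world index is undefined (NaN, with a warning) on graphs with
  no edges or a degenerate random baseline.
* EDF export writes plain 16-bit EDF (1 s records, truncating a trailing
  part-second); EDF+ annotations are not supported.
* LOOCV with 36 samples has high variance; reported accuracies are
  means across classifier families, and single-model numbers should not be
  over-read.
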