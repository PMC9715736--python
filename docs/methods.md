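# Methods

## The microstate model

Resting EEG topographies do not vary continuously: the scalp potential
field stays in one quasi-stable configuration for tens of milliseconds and
then switches abruptly to another. The analysis models the recording as a
sequence of discrete states drawn from a small set of prototype
topographies (conventionally four, labeled A–D), each state polarity-free:
a map and its negation express the same underlying generator, because
spontaneous oscillatory activity reverses sign within a state.

The pipeline estimates the prototypes from the data, assigns every sample
to one of them, and summarizes the resulting label sequence per subject.
All spatial similarity computations use the spatial correlation of
average-referenced maps (equivalently, cosine similarity of zero-mean
maps), squared or taken in absolute value wherever polarity must not
matter.

## Stages and their parameters

**Preprocessing.** Common-average reference (mandatory: GFP and spatial
correlation assume zero-mean topographies), then optional decimation with
a zero-phase FIR anti-alias filter, then global normalization. The
normalization dialect divides the *whole record* by its mean GFP rather
than normalizing each sample, so the within-record GFP profile — and hence
the per-class mean-GFP feature — survives; it makes amplitudes comparable
across subjects and is idempotent. An optional 1–45 Hz zero-phase FIR
band-pass is provided for real recordings; artifact correction (ICA,
bad-channel repair) is considered an upstream concern of acquisition
tooling and is out of scope.

**Segmentation.** GFP is the spatial standard deviation with divisor `N`
(population form). Peaks are strict interior local maxima; a plateau
bounded by strictly smaller neighbors counts once, at its first sample
(deterministic and order-independent). When two peaks fall within
`min_separation` (default 10 ms, configurable — the field has no single
convention) the larger survives. All peak maps are clustered; a cap is
available for very long recordings.

**Clustering.** Modified k-means with: assignment by maximal squared
spatial correlation; centroid update as the dominant eigenvector of the
member maps (the polarity-free analogue of the mean — it maximizes the
summed squared projection, which for peak maps is exactly the GEV
numerator, so the iteration is coordinate ascent on GEV); `n_restarts`
(default 20) independent initializations seeded from randomly chosen peak
maps, best by GEV; convergence when GEV improves by less than `tol = 1e-6`
or after 100 sweeps. An emptied cluster is re-seeded from the currently
worst-explained map and logged. Prototypes are returned zero-mean,
unit-norm, ranked by per-class explained variance.

GEV weights each peak's squared correlation by its squared GFP:

    GEV = Σᵢ GFPᵢ² · corr²(xᵢ, p_{aᵢ}) / Σᵢ GFPᵢ²

Model-order diagnostics, reported but never applied automatically (k = 4
is the fixed convention for cross-study comparability):

* CV — residual noise variance `σ̂² = Σᵢ(‖xᵢ‖² − (pᵀxᵢ)²) / (n(C−1))`
  penalized by `((C−1)/(C−1−k))²`, `C` the channel count;
* W — within-cluster dispersion with the polarity-free dissimilarity
  `d²(x, y) = 1 − corr²(x, y)`;
* KL — Krzanowski–Lai index `|DIFF(k)| / |DIFF(k+1)|` with
  `DIFF(k) = (k−1)^{2/m} W_{k−1} − k^{2/m} W_k` and `m = C − 1` effective
  dimensions (one dimension is lost to average-referencing); the scan fits
  one extra k on each side of the requested range to make KL computable.

**Canonical labeling.** Prototypes are matched one-to-one to built-in
idealized templates defined on a deterministic sunflower sensor layout:
two diagonal gradients (A: left-posterior/right-anterior, B:
right-posterior/left-anterior), an anterior–posterior gradient (C), and a
frontocentral radial maximum (D). The A/B orientations follow the standard
diagonal convention. Matching maximizes total |spatial correlation| and is
solved exactly (Hungarian algorithm). The templates are stylized — with
real data the labeling should be reviewed, which is why the matched
correlations are stored in the diagnostics.

**Back-fitting.** Every sample gets the label of the prototype with the
highest |spatial correlation| (ties to the lowest class index,
deterministic); flat samples get an unassigned sentinel and are excluded
from all feature denominators. Temporal smoothing then absorbs segments
shorter than 30 ms (not genuine microstates): repeatedly the shortest
offending segment (ties: earliest) is dissolved, each of its samples
relabeled to whichever *flanking* class has the higher stored
|correlation| at that sample — the segment's own class is excluded, which
guarantees progress and termination. Segments truncated by the record edge
are exempt by default. The procedure is idempotent, conserves labeled
duration, and never introduces a class absent from its input. The
window-free rejection-by-duration rule is deliberate; the
smoothness-penalty segmentation variant is a non-goal.

**Features.** Per class: mean segment duration (ms), occurrence (segment
onsets per second of labeled time), coverage (fraction of labeled
samples), and mean GFP during dominance. Counting onsets rather than
samples makes `Cov = Occ × Dur / 1000` an exact identity — the bundled
single-subject reference table satisfies it to four decimal places, which
pins down this occurrence dialect. Transitions are counted only between
temporally adjacent segments of the smoothed sequence, so the TP matrix
has an exactly zero diagonal; rows over classes that never transition are
all-zero and flagged. Mean GFP is reported in whatever units the record is
in — normalized units when `normalize_global` ran, µV otherwise.

**Statistics.** Welch's t (unequal variances, Welch–Satterthwaite df) per
feature, patient minus healthy; no multiplicity correction by default
across the 28 tests (each is reported as-is, mirroring standard practice
in small clinical cohorts), Benjamini–Hochberg behind a flag. Pearson r
with the t-transform p and Fisher-z CI; first-order partial correlation
`r_xy·z = (r_xy − r_xz r_yz) / √((1−r_xz²)(1−r_yz²))` with df = n − 3,
controlling for age; a constant control degenerates to the simple
correlation. Correlations are computed within the patient group (healthy
subjects carry no scale scores). The "group effect adjusted for age"
question is answered twice, because the design is genuinely ambiguous:
a two-factor ANOVA (type-II SS) with age binned at the cohort median, and
an ANCOVA with continuous age; when age is fully confounded with group —
which age-mismatched cohorts can produce under a median split — the
two-factor variant is skipped with a logged warning and the ANCOVA is
still reported.

## The synthetic generator

The generator emulates the target data class — 64-channel, 250 Hz,
≥ 60 s eyes-open resting recordings — at the level that matters for the
pipeline: a semi-Markov sequence of prototype topographies with dwell
times of tens of ms, random per-segment polarity, a smoothly varying
amplitude envelope, and Gaussian sensor noise.

* **Prototypes** are random combinations of low-order polynomial patterns
  over the sensor layout plus light unstructured texture, rejected until
  all pairs satisfy |corr| ≤ 0.5 — separated enough to be identifiable,
  close enough that clustering is not trivial.
* **Dwell law**: `dwell = floor + Geometric(p)`, mean matched to the
  configured per-class mean (defaults 79.1 / 85.1 / 92.7 / 67.9 ms, the
  values of the bundled reference table). The floor (default 32 ms)
  ensures the generated ground truth itself satisfies the quasi-stability
  that the 30 ms smoothing stage enforces; a plain memoryless geometric
  would put ~30% of segments under the threshold, so the pipeline's
  mandatory smoothing would systematically rewrite the generator's own
  truth and no round-trip comparison would be meaningful. Setting
  `min_dwell_ms = 0` restores the plain law.
* **Transition matrix** default: off-diagonal entries proportional to
  stationary class frequencies matching the reference table's occurrence
  row, `tp[i, j] = π_j / (1 − π_i)`.
* **Amplitude envelope**: rectified Gaussian-smoothed noise (≈ 20 ms
  correlation length) with a positive floor, scaled so the clean signal's
  mean GFP equals `gfp_level`; it gives the GFP genuine local maxima
  within segments, which the peak-extraction step requires.
* **Sensor noise**: i.i.d. Gaussian per channel, sd expressed relative to
  the mean signal RMS (`noise_sigma`, default 0.3).
* **Cohort effects** (all configurable): the patient group's class-C mean
  duration is reduced by 25 ms against a 15 ms between-subject sd; the
  C→D transition probability is an affine function of an FMA-like score
  plus noise, scaled so the planted population correlation is ≈ +0.74; the
  class-A duration couples negatively to a lower-limb score with planted
  r ≈ −0.64. Ages are drawn per group (patients 59.8 ± 12.8 y, healthy
  29.0 ± 7.1 y — note this makes age and group deliberately confounded,
  as in realistic stroke cohorts). Per-subject transition rows are
  clipped and renormalized if a planted probability leaves (0.02, 0.9),
  with a logged warning.

All randomness flows from explicit integer seeds; one master seed is split
per subject with numpy's `SeedSequence`.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: volume-conducted forward-model
geometry, 1/f spectral structure, artifacts (blinks, EMG, electrode
drift), non-geometric dwell distributions, within-subject nonstationarity,
and topographies that only approximately repeat across subjects. Results
on synthetic cohorts certify the estimators and the statistics, not the
neurophysiology.

## Numerical choices and degenerate inputs

* Spatial correlation of a zero-variance map is defined as 0; such samples
  are sentinel-labeled and excluded from features.
* Matrix text I/O uses `%.17g`, so float64 round-trips bitwise. The EDF
  writer quantizes to 16 bits over each channel's range (the format stores
  integers); the physical min/max written to the 8-character header fields
  are the exact values used for scaling, so decoding inverts encoding up
  to quantization.
* The smoothing threshold in samples is `ceil(min_ms · fs / 1000)`; at
  250 Hz, 30 ms means segments of ≤ 7 samples (28 ms) are rejected and 8
  samples (32 ms) are kept.
* `welch_ttest` on two zero-variance groups returns a flagged result
  (t = 0, p = 1 when the means agree) instead of raising, so a degenerate
  feature cannot abort a 28-feature sweep.
* The k-scan seeds each k's fit from an independent child of the scan
  seed; fits across k are therefore independent, and the per-run
  monotonicity of W is an empirical property of good fits, not a
  guarantee of the optimizer.

## Problem sizes used in the test suite

Tests run the estimators at reduced but statistically adequate sizes
chosen as a deliberate design point: recovery tests use 2000 peak maps and
15 000–50 000-sample sequences; transition-probability convergence is
checked at 250 000 samples, where the ±0.03 tolerance corresponds to
≈ 3.5 standard errors; statistics calibration uses 1000 simulated cohorts
of 12 + 12 at the parameter level (no EEG rendering); the end-to-end
qualitative check runs ten full 24-subject, 60 s cohorts. All seeds are
fixed in the test sources.

## Known limitations

* Group-level prototypes use two-stage clustering (per-subject fits, then
  clustering of the pooled prototypes); with very heterogeneous subjects
  a single-stage pooled fit (available via `two_stage: false`) can behave
  differently, and neither is canonical in the field.
* Template labeling is only as good as the idealized templates; on real
  64-channel montages the sunflower layout is a geometric stand-in, and
  the matched-correlation diagnostics should be inspected.
* The statistics layer implements the uncorrected-by-default testing
  scheme typical of small clinical studies; with 28 features, ~1.4 false
  positives per cohort are expected at α = 0.05, and the report should be
  read accordingly (or the FDR flag enabled).
* Healthy subjects carry no scale scores, so correlation analyses are
  patient-only by construction; n is correspondingly small and sample
  correlations scatter widely around their population values.
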