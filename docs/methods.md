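# Methods

## Problem and data model

Parkinson's disease dysgraphia (PDYS) — slow, shaky, shrinking
handwriting — is measurable with a digitizing tablet that records the
pen at some ~130–180 Hz: position x[n], y[n] (device counts), timestamp
t[n], the binary pen state b[n] (1 on-surface, 0 hovering in air up to
~1.5 cm), axial pressure p[n], and the pen orientation angles tilt and
azimuth.  `graphomotor` turns such recordings into per-subject feature
vectors and evaluates PD-vs-control classifiers under three
multilingual scenarios.  Two tasks are supported: the Archimedean
spiral drawing (language-independent) and sentence writing
(language-dependent).

## Preprocessing

Positions are converted to millimetres and time to seconds via a
per-device profile (counts/mm, ticks/s).  All recordings are resampled
onto a uniform 133 Hz grid: continuous channels are antialias-filtered
with a zero-phase windowed-sinc FIR low-pass (cutoff 0.45 × target
rate, 101 taps, shrunk for short records; records shorter than the
filter warm-up fall back to linear interpolation with a warning) and
linearly interpolated; the pen state is resampled by zero-order hold so
it stays binary.  Zero-phase application was chosen over causal
filtering to avoid group delay between the kinematic channels; this is
a design choice of this package, not a claim about how any particular
study filtered.  Non-uniform raw timestamps are first gridded linearly
at the source nominal rate because FIR filtering assumes uniform
sampling.  The output grid spans [t0, t_end] with
floor((t_end − t0)·fs) + 1 samples.

Strokes are maximal runs of constant pen state.  Runs shorter than 2
samples are treated as digitizer glitches (pen bounces) and merged into
the preceding stroke.  Strokes tile the record exactly and alternate
on-surface / in-air.  A stroke's duration is n_samples/fs — each sample
owns one sampling interval — so stroke durations add up to the
recording's total length exactly.

## Handcrafted features

Named `INF:DIR-FN(HL)` (information source : direction - feature
(aggregation)).  Time-series features are reduced by median, iqr
(P75 − P25, linear-interpolation percentiles), ncv = iqr/median, and
the Theil–Sen slope against time; kinematic series additionally by the
95th percentile.  The Theil–Sen estimator is the median of all pairwise
slopes; above 2000 samples it switches to a fixed-seed random subsample
of 10^6 pairs (the seed is a module constant, independent of any cohort
seed, so the estimate is reproducible).

Families:

* temporal — DUR per surface class, DURR = on/air duration ratio, SDUR
  per-stroke durations, SDURR aggregated over adjacent (on-stroke,
  following air-stroke) duration ratios.  The pairwise definition keeps
  a distribution that can be aggregated; a single global ratio would
  not.
* spatial — WIDTH/HEIGHT (coordinate ranges), LEN (path length summed
  within strokes; differences never span a pen lift), and per-stroke
  SWIDTH/SHEIGHT/SLEN.
* kinematic — VEL = |(ẋ, ẏ)| (or |ẋ|, |ẏ| for the H/V projections),
  ACC = d(VEL)/dt, AVEL = dφ/dt with φ the unwrapped direction-of-motion
  angle atan2(ẏ, ẋ).  Defining AVEL from the motion direction (rather
  than a polar angle about a spiral centre) gives one definition valid
  for both tasks.  Derivatives are first differences × fs, computed
  strictly within strokes and concatenated: differencing across a pen
  lift would fabricate enormous velocities.  Strokes with fewer than 3
  samples contribute nothing to ACC/AVEL.
* dynamic — PRESS over on-surface samples only (an all-zero pressure
  channel means the sensor was absent and the features are missing);
  TILT and AZIM over all samples, since the pen is tracked in air too.
* other — NINT (in-air strokes flanked by on-surface strokes), RNINT
  per second of total duration; crossing counts NIEI (between
  on-stroke pairs), NIAI (median per-stroke self-crossings), TNIAI
  (total self-crossings), each also relative to on-surface LEN in mm;
  RNCV/RNCP/RNCT/RNCA count local extrema (sign changes of the first
  difference, zero-plateaus ignored) of the velocity/pressure/tilt/
  azimuth profiles per second of on-surface time.  Temporal events are
  normalised by time, geometric events by path length.

Crossing counts use an exact orientation predicate on segment pairs
(bounding-box prefilter, block-wise to bound memory): a crossing is a
strict transversal intersection; endpoint touching does not count;
collinear overlap counts once per pair; in self mode adjacent segments
are excluded.  The implementation is verified against an
exact-arithmetic brute-force oracle in the tests.

### Spiral-specific metrics

Computed only for the spiral task and only when the on-surface trace
spans at least one full revolution of unwrapped angle (otherwise all
spiral features are missing, with a QC warning).  The centre is the
centroid of on-surface points refined by regressing r on
{1, θ, cos θ, sin θ} and shifting the centre by the harmonic
coefficients (a small centre offset (dx, dy) appears in the radius as
dx·cos θ + dy·sin θ); a few passes reduce the residual of an ideal
spiral to numerical zero.  The innermost trace (r < 5 % of max) is
skipped before unwrapping because the polar angle is ill-conditioned
through the centre.  The radius is resampled on a uniform 1° angle
grid, an ideal spiral r̂ = c0 + c1·θ is fitted by least squares, and the
residual e = r − r̂ yields: TGHTNS = c1 (mm/rad), 1stSm/2ndSm = std of
Δe / Δ²e, 1stZC/2ndZC = zero-crossings of Δe / Δ²e per radian,
DoS = RMS(e)/range(r̂), SWVI = iqr of the loop gap r(θ+2π) − r(θ),
SPI = 1 − RMS(e)/mean(r̂) clipped to [0, 1], and MDS = on-surface
length / on-surface duration.  On an ideally drawn spiral these give
TGHTNS = c1, DoS = 0, SPI = 1, SWVI = 0 to numerical precision, and
DoS/SPI respond monotonically to radial tremor amplitude (both are
asserted in the tests).

Missing values anywhere in the battery are carried as NaN and imputed
with training-fold medians inside the evaluation pipeline — never
earlier, to avoid leakage.

## Offline images and deep features

The offline path renders only the on-surface trajectory — the visible
product of writing: 1-px connected polylines, dark on white, bounding
box padded 5 %, letterboxed square, drawn on a 448-px working canvas
and resized to 224×224 by nearest-neighbour interpolation.  Pressure
and speed are deliberately not encoded.  A "backbone" is any frozen
deterministic image→vector map.  The default is a seeded Gaussian
random projection of the 32×32 block-averaged grayscale (512-d): a
dependency-free linear embedding whose projection matrix is part of the
frozen model (its seed is a model constant, never a cohort seed).  An
ImageNet-pretrained VGG16 wrapper (global-average-pooled last
convolutional block, 512-d) is provided for environments with torch and
downloadable weights.  Deep features enter the same table/evaluation
path as the handcrafted battery under the names `CNN:0000…`, and are
classified with the linear model below — pooling the last conv block to
a vector keeps both feature kinds on one evaluation path instead of a
separate dense head.

## Classifiers and evaluation protocol

Handcrafted features → gradient-boosted trees (XGBoost, 100 rounds,
single-thread `hist`); deep features → L2-regularised logistic
regression on standardised features.  Hyperparameters are tuned by
uniform randomized search over fixed grids — learning rate {0.001,
0.01, 0.1, 0.2, 0.3}, γ {0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.5}, max
depth {6, 8, 10, 12, 15}, subsample {0.5…1.0 by 0.1}, column subsample
per level and per tree {0.4…1.0 by 0.1}, min child weight {0.5, 1, 3,
5, 7, 10}, positive-class weight {1, 2, 3, 4}; for the linear model
C ∈ {0.001, 0.01, 0.1, 1, 10, 100, 1000} — scored by mean balanced
accuracy (BACC) over stratified inner folds, 500 draws by default, ties
to the earlier draw.  Class imbalance is handled only through the
positive-class-weight grid; no resampling.

Scenarios: single language (SL) and all languages combined (ALC) use
stratified 5-fold cross-validation with 5 repetitions on the outside
and a fresh randomized search inside each outer training fold (nested
tuning: the search never sees its test fold, which costs computation
but removes optimistic bias); leave one language out (LOLO) tunes on
the pooled training languages, fits once, and reports a single
confusion table for the held-out language (hence no variance
estimate).  Reported metrics are BACC, F1, sensitivity and specificity;
a ratio whose class is absent from a test fold is NaN, not zero.
SL/ALC summaries are mean ± sd across the 25 outer splits (the sd is
labelled as across-splits).  All decisions are per subject.  Every run
is bit-reproducible given its seed: outer splits, per-split search
seeds, and estimator seeds all derive from one `SeedSequence`.

Feature importance is reported as the top ten features by total gain
(tree models) or absolute standardised coefficients (linear proxy),
normalised to sum to one.

## Synthetic cohorts

The generator emulates the motor signature of PDYS with independent
deficit knobs: `velocity_scale` (bradykinesia; PD < 1), `tremor_amp` /
`tremor_freq` (default band centre 5 Hz — the classic 4–7 Hz
parkinsonian band), `amplitude_decay` (micrographia: radius shrinks per
revolution, stroke height per stroke), `pressure_scale` (reduced axial
pressure), `extra_lift_rate` (dysfluency: Poisson pen lifts of
0.1–0.3 s), and `jitter_sd` (0.05 mm positional noise).  Per subject,
spiral tightness c1 ~ N(2, 0.2²) mm/rad over 3–5 revolutions and base
speed v0 ~ N(30, 5²) mm/s; pressure sits near 512 device units; tilt
and azimuth are slow AR(1) processes.  Sentences are left-to-right
sequences of loopy oscillatory strokes with in-air transitions;
language style (stroke-count range, letter height, slant) is a nuisance
applied to both groups, so the class signal is injected only through
the deficit profile — mirroring the fact that spiral drawing is
language-independent.  `null_mode` forces every deficit to its neutral
value so PD and HC are draws from one distribution.  All randomness
derives from a single root seed via per-subject `SeedSequence`
spawning.

What the generator does *not* model: legible letterforms or real
orthography, correlation between deficits (they are independent knobs),
device quantisation, or hesitation/planning pauses.  A passing suite
therefore shows the pipeline detects the modelled kinematic deficits
and stays at chance under the null — not that any particular clinical
accuracy is reproducible.

One emergent property worth knowing: 1 mm of 5 Hz tremor adds a
~30 mm/s oscillatory component to instantaneous pen speed, so median
velocity alone does not separate the groups under combined deficits —
tremor-sensitive residual metrics and angular velocity do.  This is
physically sensible and left as-is.

## Problem sizes used by tests and the acceptance script

The published study's clinical recordings are not public, so scenario
checks run on synthetic cohorts at these scales, chosen as this
package's own study conditions: strong-effect cohorts (velocity_scale
0.6, tremor_amp 1 mm) with 30 subjects per group per language over two
languages for SL/ALC; four languages at 15 per group for the LOLO
transfer checks; a 50-draw randomized search with nested 5×5 outer /
5-fold inner stratified CV.  Chance-band assertions use the interval
[0.35, 0.65] for a ~60-subject cohort (binomial spread of BACC around
0.5 at that n).  Arithmetic on the published summary tables (cohort
sizes, cross-language LOLO means, the BACC ≡ (SEN+SPE)/2 identity) is
recomputed exactly from transcribed rows; the identity is asserted on
the LOLO rows (single confusion tables, holds within 2-decimal
rounding ≤ 0.005) and only reported for the SL rows, where per-metric
NaN-dropping on small test folds lets the published means deviate by up
to ~0.045.

## Known limitations

* The default deep-feature backbone is a random projection: it proves
  the plumbing (determinism, fixed length, linear separability of
  strongly separated cohorts) but carries no visual semantics; swap in
  the VGG16 wrapper for semantic features.
* Spiral centre refinement assumes a roughly centred drawing; a spiral
  drawn as a small arc far from its centroid can fail the
  one-revolution gate.
* Theil–Sen on very long series is a seeded approximation (10^6 pairs).
* LOLO reports a single split by design; it has no variance estimate.
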