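# Methods

This note records the models, conventions, and numerical choices behind
`gazebench`, and what its synthetic benchmark does and does not show.

## Data model and units

A `GazeRecording` is a uniformly sampled monocular gaze time series:
timestamps in milliseconds (strictly increasing; spacing may deviate from
uniform by at most 1% of the nominal period before a warning is raised and
the timestamps are trusted over any declared rate), and x/y position in
**degrees of visual angle** — the canonical internal unit, because every
detection threshold is angular.  Pixel data must be converted first via
`pixels_to_degrees`, which applies `atan(offset_px · pitch / distance)`
per axis relative to an origin at the screen point nearest the eye.
Missing samples (blinks, track loss) are NaN coordinates; they are
pre-labeled BLINK by every detector and velocities touching them are
undefined.

Velocity conventions:

- `sample_diff`: the speed of the step (i−1 → i) is stored at index i;
  index 0 is undefined.  Storing the step at the later sample preserves
  causality (a sample's velocity never depends on the future), which
  matters for boundary placement.  Used by I-VT, I-VVT, I-DVT and for
  event features.
- `moving_window`: the 5-sample centred difference
  `v[i] = (x[i+1]+x[i+2]−x[i−1]−x[i−2])·rate/6` used by Engbert's
  detector; the outermost two samples are undefined.

Samples whose velocity is undefined but whose coordinates are valid
default to FIXATION — the oculomotor resting state.

Dispersion of a window is `(max x − min x) + (max y − min y)` over its
non-missing points.

## Detectors

All detectors end with `enforce_durations`: every maximal non-BLINK run
shorter than its minimum — 2 samples for every type, and additionally
10 ms for saccades — is dissolved into the longer non-BLINK flanking run
(ties to the preceding run; runs walled in by blinks are left alone).
Millisecond minima convert to samples by ceiling so a minimum is never
undershot by rounding.  The operation is idempotent.  Blink runs are never
dissolved.  Note the 55 ms "minimum fixation duration" is *not* an
enforcement rule: it is the I-DT protocol's initial window span.

- **I-VT**: saccade where speed > `v_sac` (45 °/s), else fixation.
- **I-VVT**: adds a pursuit band: speed in (`v_sp` = 26, `v_sac` = 45] °/s
  is smooth pursuit.
- **I-DT**: sliding-window dispersion protocol.  A window of the minimum
  fixation duration is grown one sample at a time while its dispersion
  stays ≤ `disp_max` (2.7°; the comparison is inclusive, so a single
  point — dispersion 0 — is trivially fixational).  When extension would
  exceed the bound, the grown window is a fixation, the offending sample
  is not, and a new window starts after it.  If the *initial* window
  already exceeds the bound, its first sample is non-fixational and the
  window slides by one (the protocol sentence only covers the
  extend-then-exceed path; this is the original sliding rule).  A
  terminal window still under threshold, or shorter than the minimum
  span, is wholly fixational.
- **I-DVT**: fixations from the I-DT protocol; remaining samples are
  saccades above `v_sac`, otherwise smooth pursuit.  Note that at 500 Hz
  with the default 55 ms window, a constant drift slower than 45 °/s can
  never exceed 2.7° of dispersion within one initial window, so I-DVT
  needs a longer window to produce pursuit from slow drift.
- **Engbert**: per-axis threshold η = λ·σ with λ = 6 and the median-based
  SD σ = sqrt(median(v²) − median(v)²) of the moving-window velocities,
  computed once per recording; a sample is saccadic outside the ellipse
  (vx/ηx)² + (vy/ηy)² > 1.  A zero-variance axis is degenerate: its
  threshold falls to a tiny epsilon so any strictly nonzero velocity
  counts as saccadic (with a warning).  A perfectly constant trace
  therefore comes out all-FIXATION, while noise-free traces with real
  saccades are still segmented.  Labels are invariant under rigid
  translation and uniform scaling of the positions.
- **NH**: positions are Savitzky–Golay smoothed (order 2, window
  ≈ 2 × the minimum saccade duration, forced odd) and the velocity taken
  from the filter's derivative.  The peak threshold iterates
  PT ← mean + 6·SD over the samples below PT, from PT₀ = 100 °/s, until
  the change is < 1 °/s (bounded at 100 iterations; failure raises a
  convergence error reporting the last PT).  The onset threshold is
  mean + 3·SD of the final sub-threshold set.  Each supra-PT peak run is
  walked backward to the first local velocity minimum below the onset
  threshold (the saccade onset) and forward analogously (the offset).  A
  PSO is labeled after the offset where velocity re-exceeds the onset
  threshold within a 40 ms window while staying below PT; this
  single-excursion rule is a simplification of the original's
  direction-reversal criteria.  A spread (SD or MAD) below 10⁻⁶ °/s is
  treated as degenerate — numerically still data has no detectable peaks.
- **REMoDNaV**: a global NH-style threshold finds major saccades; the
  recording is chunked at major-saccade onsets, and each chunk of at
  least 100 ms recomputes local thresholds with robust statistics
  (median + 6·1.4826·MAD, onset at 3·1.4826·MAD), then labels saccades
  and PSOs as in NH.  Shorter chunks inherit the global thresholds.
  Remaining spans are scanned for smooth pursuit: within each span the
  drift velocity is the Savitzky–Golay slope over a 100 ms window
  (computed from the span's own positions, so saccade displacement cannot
  leak in; a quadratic local fit passes a constant-velocity drift
  unchanged while suppressing fixational jitter by over an order of
  magnitude), and samples whose drift exceeds 2 °/s become pursuit.

## Evaluation

**Sample level.**  κ and MCC are computed from the confusion matrix over
the labels present in either sequence; 1−NLD uses the unit-cost edit
distance (via `edlib`) normalized by the longer length (1 for two empty
sequences).  Ground-truth UNDEFINED samples carry no truth value and are
excluded pairwise from κ/MCC/d′ (switchable); they are kept for 1−NLD,
which is a whole-string measure.  Degenerate cases: expected agreement of
1 makes κ undefined (NaN with a warning); a zero-variance MCC denominator
returns 0 with a warning.  Per-class d′ counts a predicted-positive sample
as a hit if the ground truth agrees, else a false alarm; misses are
ground-truth positives the detector missed; all ground-truth negatives
form the negative total.

**Boundary level.**  Onsets (offsets) of the events of one label are the
run start (end) indices.  Matching pairs each detected boundary with the
nearest ground-truth boundary within |Δ| ≤ Δt.  The default mode is
one-to-one: candidate pairs are consumed greedily in order of increasing
|Δ| (ties to the earlier ground-truth boundary, then the earlier
detection), so one ground-truth boundary cannot absorb several detections
and inflate hit counts; a many-to-one mode is provided for comparison and
reports name the mode.  Because enlarging Δt only appends candidates to
the end of the greedy order, the matched count is provably non-decreasing
in Δt.  The sign convention is Δ = detected − ground truth (positive =
detector late), stated in all outputs.  RTO/RTD are the mean and sample
SD (ddof = 1; 0 for a single pair) of the matched Δ.  All boundary
arithmetic is in sample indices; millisecond conversion belongs to
reporting.

**Negative windows and d′.**  The recording is tiled from sample 0 with
consecutive non-overlapping windows of 2Δt+1 samples; a final partial
window is discarded (windows of size 2Δt+1, read literally).  Windows
containing no ground-truth boundary are the negatives — the denominator
of the boundary false-alarm rate.  d′ = z(TPr) − z(FAr), with the
log-linear correction (0.5 to hit and false-alarm counts, 1 to both
totals) applied exactly when a rate is extreme: no hits, no false alarms,
or the complementary extremes.  The correction keeps d′ finite whenever
there is at least one ground-truth boundary and one negative window;
zero negatives leave FAr (and d′) undefined and flagged.

## Synthetic generator

The generator emulates a fixation-dominated, high-speed (default 500 Hz)
screen-based recording of free viewing: alternating fixations and
saccades, with optional PSO ringing and blink gaps.  Defaults: fixation
durations normal(250, 100) ms truncated at 60 ms; saccade amplitudes
uniform(2.5°, 8°); main sequence duration = 2.2·A + 21 ms; fixational
jitter SD 0.02° (typical of a good video eye tracker); PSO probability
0.25 with a 0.4°, 50 Hz, 8 ms-decay ringing lasting 20 ms; blink
probability 0.05 per fixation (150 ms of missing signal); gaze confined
to ±12° by reflecting the saccade direction at the field edge.

The saccade waveform is a logistic position profile truncated to its
central 15–85% span and renormalized, sampled so the first saccade-labeled
sample sits exactly at the launch position and the last exactly at the
landing position.  Consequences, both deliberate: the peak velocity has a
closed form (`saccade_peak_velocity`), and on noise-free traces the
sample-to-sample velocity crosses the 45 °/s threshold within ±1 sample
of the scheduled boundaries, so threshold detectors can be tested for
*exact* boundary recovery.  The 2.5° amplitude floor keeps the mean
saccade speed of the smallest saccades comfortably above that threshold;
amplitudes below ~2° have mean speeds near or under 45 °/s and are not
recoverable by a 45 °/s global threshold even in principle.

All randomness flows from the single config seed; there is no global
generator state, and equal seeds give bit-identical output.

Two harnesses validate the evaluation metrics themselves:
`jitter_boundaries` displaces every run boundary by a discretized
normal(μ, σ) draw (clamped to preserve run order and ≥ 1-sample runs), so
RTO/RTD estimation can be checked against known (μ, σ) — note rounding
adds 1/12 to the variance; `degrade` flips sample labels independently,
so agreement metrics can be shown to decay toward chance.

**What passing these tests does not show.**  The generator's fixations
are stationary with white Gaussian jitter: no drift or tremor spectra, no
pink noise, no tracker-specific artifacts (sample dropout bursts,
interpolation smoothing), no binocular disparity, and its pursuit input
is a bare constant-velocity ramp rather than target tracking.  Human
annotators — the usual ground truth for real recordings — disagree with
each other systematically, while the simulator's schedule is exact.
Detector rankings on the synthetic benchmark therefore demonstrate
correctness of the implementations and the metric pipeline, not expected
performance on any particular real dataset.

## Problem sizes

The test suite and the acceptance script use simulation sizes chosen to
exercise every code path at desk scale: benchmark batches of 12
recordings × 15 saccades (~2,400 samples each), oracle-equivalence sweeps
of 100 × 10,000-sample random walks, 500-boundary jitter-recovery runs,
and 10–20-seed Monte-Carlo checks.  Sample-level metrics are reported
against the pooled sample count and boundary metrics against the pooled
ground-truth boundary count.

## Known limitations

- NH's PSO stage uses the simplified single-excursion rule above; it
  finds ringing reliably but does not reproduce the original's
  direction-reversal subtleties, and PSO boundary placement is coarser
  than for saccades.
- REMoDNaV's chunk boundaries are major-saccade onsets; very long
  saccade-free stretches form one chunk and adapt no further.
- The I-DT family inherits the protocol's blindness to events whose
  spatial extent stays under the dispersion bound, and its window
  arithmetic makes sub-threshold-velocity pursuit undetectable at the
  default 55 ms window (see above).
- `enforce_durations` resolves conflicts deterministically (longer flank,
  ties to the preceding run); other merge policies would shift boundaries
  by a sample or two in dense alternations.
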