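# Methods

This note records the models, conventions and numerical choices behind
`eeglike`, and what the synthetic studies do and do not demonstrate.

## Synthetic study model

The generator emulates a gallery-walk EEG design: per subject, a blank
baseline segment followed by one observation segment per painting, recorded
at 512 Hz from a dry-electrode montage, each (subject, painting) trial
labelled with an integer liking score in [0, 50].

**Scores.** A two-component truncated-normal mixture: components centred at
15 and 35 VAS units, common sd 6, equal weights, truncated to [0, 50] and
rounded to integers.  This yields a clearly non-normal distribution
(a Kolmogorov–Smirnov test rejects normality at n = 2000) that is symmetric
about the scale midpoint 25 by construction.  The mixture is a modelling
choice — it reproduces the qualitative facts (bimodal tendency, symmetry,
integer support) without claiming to estimate any real score histogram.

**Signal.** Background activity is white noise (sd `noise_sd`, default 1)
low-pass filtered to the analysis range (0, 52] Hz with a 6th-order
Butterworth filter, so that every 4 Hz analysis band is populated.  Trials
whose score was drawn from the high mixture component ("like") additionally
carry a burst: unit-variance noise band-passed to 36–44 Hz (inside γ),
scaled by `like_amplitude` (default 2), added to the target channels
(default: the first two) during a contiguous window covering
`burst_fraction` (default 0.3) of the trial with a uniformly random onset.
"Dislike" trials carry amplitude 0 by default.  The uniform onset is
deliberate: the interval-temporal learner must find the burst wherever it
sits, not at a fixed latency.

What this generator does *not* model: volume conduction and montage
geometry, 1/f spectral slope, eye-blink/muscle artifacts, non-stationary
baselines, inter-subject variability.  Passing tests therefore demonstrate
that the pipeline recovers a planted band-limited, interval-localized
class difference at realistic SNR — not that it would reach any particular
accuracy on real recordings.

## Preprocessing conventions

* Resampling 512 → 104 Hz uses polyphase filtering (ratio 13/64) with
  linear-edge padding; 30720-sample (60 s) slices become 6240 samples.
* STFT framing is non-centred: frame *f* covers samples
  [*f*·step, *f*·step + window); trailing partial frames are dropped.  At
  104 Hz the 50 ms window and 20 ms step are 5 and 2 samples; frames are
  zero-padded to a 64-point transform (bin spacing 1.625 Hz) so the 4 Hz
  bands are resolvable.  A 60 s trial yields 3118 frames under this
  convention; the frame count is recorded in each spectrogram rather than
  assumed.
* Band power is the plain sum of |FFT|² over the bins in (4(i−1), 4i] Hz;
  DC is excluded everywhere.  The 13 bands tile (0, 52] exactly, so the
  per-frame band sum equals the total non-DC spectral power (a tested
  invariant).  log₁₀ is applied after flooring power at 1e−12, since
  synthetic inputs can produce exact zeros.

## Measure catalog

The 22 non-elementary measures follow the canonical catch22 feature
definitions, implemented here in numpy and documented per measure in
`eeglike.measures`; MIN/MAX/AVG complete the catalog of 25.  Conventions
worth stating:

* All 22 operate on the z-scored series (sample sd, n−1); a constant
  series z-scores to all zeros rather than dividing by zero.
* Undefined cases (series shorter than the measure's minimum length,
  degenerate inputs such as too few usable fluctuation scales) return NaN —
  an explicit sentinel that screening averages and split search skip.
* The fluctuation-analysis statistics (FDFA, FLF) fit two straight lines to
  (log τ, log F) over ~50 log-spaced scales in [5, n/2] and report the
  fraction of scales in the first regime; each regime keeps at least three
  scales and the split minimizes total squared error.
* The periodicity measure detrends with a least-squares cubic spline (one
  interior knot at the series midpoint) and returns the lag of the first
  ACF peak that follows a trough, exceeds it by ≥ 0.01, and is positive.

The test suite carries independent, loop-based reference implementations of
all 22 and requires agreement to 1e−6 relative tolerance on 100 random
series; agreement with any particular compiled library is not claimed.

## Screening

Feature variance is the sample variance (n−1), min-max normalized *jointly*
across all electrode × band × measure features; e-scores and m-scores are
plain averages of normalized variances, ranked descending (highest variance
= most informative) with lexicographic tie-breaks.  Two consequences are
worth knowing.  First, screening is label-blind by construction.  Second,
because the min-max rescale is global, measures whose outputs live on large
numeric scales (lag-valued measures such as FM or C) tend to dominate the
m-ranking on synthetic data; the greedy information-gain split search, not
the screen, is what ultimately decides which features classify.  On planted
data the burst channels reliably top the e-ranking.

## Interval temporal trees

* **Timeline.** Native frame series are coarsened into W = 10 equal spans;
  an interval [x, y] (1 ≤ x < y ≤ W) covers coarse frames x…y, and measures
  are evaluated on the full-resolution frames inside that span, so [1, W]
  reproduces the whole-series measure exactly.  W = 10 keeps the interval
  count at 45 (a ~3000-frame native timeline would have ~4.5M intervals,
  which is not searchable).
* **Semantics.** A split ⟨R⟩(p) sends an instance left iff some interval
  reachable through Allen relation R from the instance's current reference
  interval satisfies p; the witness (the lexicographically smallest such
  interval) becomes the new reference on the left branch, while the right
  branch keeps the old reference — it is the universal dual [R](¬p).  The
  initial reference interval is [1, 2], from which ⟨L⟩/⟨A⟩ reach essentially
  the whole timeline.  Undefined (NaN) measure values never satisfy a
  proposition.
* **Search.** Candidate thresholds are the nine deciles of the feature's
  interval values pooled across the node's instances and accessible
  intervals (the union of the 13 relations' accessible sets is all
  intervals, so the pool is per-feature).  Both comparators (≥, <) are
  searched over all 13 relations.  The existence test reduces to a
  per-instance maximum (or minimum) over accessible intervals, which keeps
  the search O(instances) per threshold.  Max-gain wins; ties go to the
  first candidate in the deterministic (feature, relation, comparator,
  threshold) order.
* **Stopping.** Leaf when node size < 2, purity ≥ 0.95, depth = 6, or no
  candidate has positive gain.  No pruning.
* **Forests.** 100 trees, bootstrap resamples of size n, ⌈√F⌉ features per
  node, majority vote with ties to "dislike" (the safer class for a model
  meant to be specific).  All randomness descends from one master seed;
  identical seeds give identical forests.

## Evaluation

Leave-p-out is Monte-Carlo: each repetition draws p = 10 instances without
replacement (independent draws, not exhaustive enumeration over all
subsets).  Metrics are percentages; when a held-out set lacks a class the
affected metric is undefined for that repetition and excluded from the
mean with a logged warning rather than imputed.  The shuffle control
permutes the label vector (class counts preserved) and reruns the whole
protocol per shuffle seed.

## Rules

Left edges render as existential atoms ⟨R⟩(p), right edges as universal
atoms [R](¬p) with the negation folded into the comparator (¬(f ≥ θ) is
f < θ), matching interval-temporal-logic notation.  Per-class merging joins
leaf paths with ∨; merged rules from one tree partition the instance space,
and `rule_predict` is tested to coincide with tree prediction.  Atoms in a
conjunction are evaluated left to right with the same reference-interval
updates as tree routing; rendering uses either unicode (⟨L⟩, ∧, ≥, ⇒) or an
ASCII fallback (<L>, &, >=, =>), and thresholds print with full `repr`
precision so parsing round-trips exactly.

## Problem sizes in the shipped studies

The acceptance script and heavy tests simulate 20 subjects × 18 paintings
(360 trials) on 6 channels with 15 s trials — the full design's structure
(rates, bands, score mixture, burst parameters, ⟨<17, ≥34⟩ binning leaving
~100 instances per class) at problem sizes a single CPU handles comfortably.
Screening in the test suite uses a label-blind subsample of 120 trials; the
acceptance script screens all trials.  The forest protocol is leave-10-out
with 10 repetitions and 100 trees; the shuffle control uses 3 shuffle seeds.

## Known limitations

* The coarse-timeline granularity (W = 10) bounds how sharply rules can
  localize events in time: ~1.5 s per coarse frame on a 15 s trial.
* Variance screening inherits the global min-max scale sensitivity noted
  above; rescaling measures per-family before the screen would change the
  m-ranking and is deliberately not done, to keep the published procedure.
* The EDF writer quantizes to 16 bits over each channel's observed range;
  round-trips are exact only to that quantization step.
* Forest training cost grows linearly in instances × features × intervals;
  W much above ~20 or feature sets beyond a few hundred become slow.
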