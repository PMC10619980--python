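# Methods

## Scope and shape

`dualsleep` implements the analysis chain used to contrast drug-induced
("quiet") and optogenetically induced ("active") sleep in *Drosophila*:
imaging preprocessing → per-neuron activity statistic → correlation
connectivity, per-minute sleep-bout architecture, air-puff responsiveness,
and post-fit differential-expression filtering. It is organised as one
module per stage with a thin `click` CLI, because the stages are
deterministic transformations with thresholds rather than a fitted
statistical model; there are no estimated parameters or uncertainties that
would warrant a model/results object design.

## The activity statistic

Each neuron's raw trace is z-scored against its own whole-experiment mean
and SD (baseline and treatment pooled; `zscore` is configurable to a
baseline-only window if desired). Binarization assigns 1 strictly above
`threshold_sd` = 3; a value exactly at 3 maps to 0 (the underlying rule
specifies ">3" and "<3" and leaves equality open, so the strict reading is
adopted and unit-tested). A neuron is *active* iff any run of `window` =
10 consecutive frames contains at least `min_count` = 7 ones; the window
slides by one frame. Event counting finds strict local maxima above
`min_peak_height` = 3 and suppresses any peak strictly closer than
`min_peak_distance` = 30 frames to a taller kept peak (ties broken toward
the earlier peak for determinism) — the semantics of MATLAB `findpeaks`
with `minpeakheight`/`minpeakdistance`. The separation is expressed in
frames, not seconds, because the statistic is defined on the per-slice
frame grid; convert via the slice rate if needed.

Plateaus (equal neighbouring samples) are not peaks under the strict
local-maximum rule; with continuous-valued z-traces ties occur with
probability zero.

Epoching around sleep onset: onset is the start of the first run of
behavioral inactivity lasting ≥ 30 s; the 5 min following that initial
30 s form the "early" sleep epoch and the next 5 min "mid" sleep; a
pre-treatment window can be emitted as the "wake" baseline. Epoch overlap
is 100·|A ∩ B| / |denominator|, with the denominator defaulting to the
first (sleep-epoch) set; `union` gives a symmetric variant. An empty
denominator yields NaN rather than an error.

## Imaging preprocessing

*Registration* uses single-step DFT upsampled phase cross-correlation
(scikit-image) with the first frame as reference (configurable to the
temporal mean), reporting each frame's displacement to 1/`upsample` px
(default 10). Frames with zero variance get zero shift and a warning.
Shifts are applied and undone by Fourier translation, so integer-shift
round trips are exact to numerical precision.

*Slice-timing correction*: slices are assumed acquired sequentially in z
(slice 0 first) with the flyback frames at the end of each volume, so
slice *j* lags the reference slice (default index 8, the ninth slice) by
(j − 8)/(n_slices + n_flyback) volume periods. Every voxel series is
resampled onto the reference grid by truncated-sinc interpolation of the
mean-subtracted series on a reflection-padded copy (pad 64 samples):
subtracting the temporal mean makes the DC component pass through exactly
despite kernel truncation, reflection padding suppresses edge ringing, and
the reference slice is returned bit-identical. Interior accuracy on
band-limited signals is ~1e-4 (verified against an analytic sinusoid);
fewer than 8 time points are refused as too little sinc support.

*Segmentation* runs marker-based watershed on the Gaussian-smoothed
(`smoothing_sigma` = 1 px) temporal-SD projection: markers are local
maxima (minimum separation 3 px) above an Otsu threshold, the watershed
floods the inverted intensity within the Otsu mask, and regions outside
[`min_area`, `max_area`] px are discarded with consecutive relabeling. The
original analysis delegated to an ImageJ plugin with unstated parameters;
Otsu is the neutral automatic choice and every knob is surfaced in the
config. A blank image yields zero ROIs, not an error.

Whether the original recordings were registered per slice or per volume is
not recoverable; the default here registers each slice's time series
independently.

## Connectivity

Pairwise Pearson correlation of epoch-restricted traces of active neurons;
zero-variance traces are flagged and their rows/columns set to missing.
The graph has an undirected, unweighted edge where r > `r_threshold`
(default 0.5); the exact edge rule behind the original mean-degree figure
is not reproducible from the source, so the threshold is deliberately a
prominent free parameter. Mean degree averages edge counts over valid
nodes only, excluding flagged neurons from numerator and denominator.

## Sleep architecture

Inactivity bouts are maximal runs of zero-activity minutes, split at light
transitions of the 12:12 schedule (lights on 08:00, minute 0 of each
simulated day), which caps any bout at 720 min. A bout of exactly 5 min
is sleep (the "5 min or more" criterion is taken as authoritative over a
">5 min" shorthand elsewhere; the boundary is configurable and
unit-tested); bouts of 1 up to but not including 5 min are short sleep.
The short-sleep percentage divides cumulative short-sleep minutes by all
inactivity minutes (short + sleep). Waking activity per minute divides
total counts by the number of minutes with nonzero activity. Multi-day
totals and bout counts are averaged per day (ratios and means are not).
Phases with no waking minutes report waking activity as missing.

Response rates average each fly's per-window response first, then report
the across-fly mean (×100) and SEM, with the first 10 stimuli per fly
labelled "pre" by default.

## Gene filtering and qPCR

The CPM filter removes a gene only when its mean CPM is strictly below 5
in *both* groups; genes with missing CPM are retained with a warning. The
significance filter requires FDR < 0.05 and |log2FC| > 0.58, both strict,
split by sign. The filters are idempotent and commute on the retained
universe. Whether the CPM values are pre- or post-normalization is the
caller's concern; the filter operates on the columns supplied. qPCR
relative expression follows 2^−ΔΔCq with the reference Cq per sample taken
as the arithmetic mean of the housekeeping genes' Cq values (the geometric
mean on the linear scale; no combination rule was stated for the three
housekeeping genes) and PCR efficiency assumed exactly 2.

## The synthetic-data generators

The generators provide every input with planted ground truth.

*Traces*: active neurons carry a Poisson number of transients (default
0.5 events/min) at uniform frames, convolved with an instantaneous-rise
exponential-decay kernel (default τ = 2.5 s) scaled to peak `amplitude` =
8, plus i.i.d. Gaussian noise (SD 1); silent neurons are noise only.
Defaults describe ~11.6 min (3000 frames) at 4.3 volumes/s with a *slow
nuclear-localized* calcium indicator: nuclear GCaMP variants decay over
seconds, so a real transient spans several volumes — which is also the
only regime in which the ≥7-of-10-frame activity call can respond at all.
A fast cytosolic τ of ~0.5 s would leave a transient supra-threshold for
roughly one frame at any realistic volume rate and make the published
classifier blind by construction. Sparse firing keeps the whole-trace SD
near the noise floor, so the z > 3 threshold sits below the transient
peaks. One `SeedSequence` child stream per neuron makes simulations
reproducible and extensible without perturbing existing draws.

*Movies*: Gaussian-blob ROIs (σ = 2.5 px) on a jittered grid with ≥ 4σ
spacing, brightness following the simulated traces over a constant
baseline, rigidly translated per frame in the Fourier domain so sub-pixel
shift truths are exact. Shifts beyond a quarter frame are refused.

*Behavior*: alternating wake/sleep bouts with integer geometric durations
whose means are phase-specific (day sleep/wake 12/24 min; night 25/10 min
— night-time spontaneous bouts average ~25 min in this system). Wake
minutes draw activity 1 + Poisson(1.69), mean 2.69 counts/min, matching
the reported waking-activity scale; sleep minutes are 0. Truth bouts are
maximal same-state runs split at light transitions, so they tile the log.

*Responses*: Bernoulli per stimulus with state-dependent probability.

*DE tables*: true positives get |log2FC| = 1.0 + |N(0, 0.5)| with random
sign and FDR ~ U(0, 0.01), well expressed in both groups; nulls get
log2FC ~ N(0, 0.1) and FDR ~ U(0, 1), with a lognormal CPM spread that
leaves some lowly expressed. Under these defaults the planted set is
exactly recoverable by the two filters, which the tests assert.

What the generators do **not** emulate: photobleaching, slow drift,
non-rigid motion, neuropil contamination, correlated noise across neurons,
arousal-threshold dose dependence, circadian modulation beyond the 12:12
square schedule, and realistic DE effect-size/abundance joint structure.
Passing tests therefore demonstrate algorithmic correctness against
planted truth, not robustness to every artifact of real recordings.

## Problem sizes

The verification suite runs at desk scale: parameter-recovery checks use
200 active + 200 silent traces of 3000 frames (fixed seed), a 96 × 96 px,
60–120-frame movie with 8 ROIs, oracle-equivalence sweeps of 1,000 random
10⁴-frame binary rows / 1,000 random logs / 500 random traces, and the
boundary sweeps are exhaustive over their grids. The boundary values
reported by `scripts/acceptance.py` (7 frames, 5 min, 720 min, 0.58, 5)
are exact properties of the classifiers and independent of the seed; the
seed still drives all synthetic backgrounds used to compute them.

## Known limitations

- Per-slice independent registration may disagree with volume-wise
  registration on real data with z-coupled motion.
- The watershed parameterization (Otsu + local maxima) is a stand-in for
  an interactively tuned plugin; on dim or crowded fields it will need
  per-dataset tuning of `smoothing_sigma`, marker separation and area
  bounds.
- The connectivity edge rule (positive r > 0.5) is a declared convention,
  not a reproduction of the original graph construction.
- Behavioral scoring assumes activity counts are already computed per
  minute; no video/beam preprocessing is provided.
- Descriptive summaries only; hypothesis testing is out of scope.
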