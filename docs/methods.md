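# Methods

`cardiomap` quantifies the functional phenotype of cardiomyocyte-like cell
cultures from three kinds of raw data: calcium-sensitive fluorescence movies
(optical mapping), single-frame images of labelled cells, and patch-clamp
sweep tables.  Every estimator in the package is exercised end-to-end
against a synthetic-data generator with analytic ground truth; this note
describes the models, the conventions, the tunable parameters, and what the
synthetic tests do and do not demonstrate about real recordings.

## Calcium transients

A region-of-interest trace is the mean intensity over the ROI per frame.
Transients are detected on ΔF/F computed against a rolling 10th-percentile
baseline (window 5 s by default), which tolerates slow drift over a 30 s
recording; peaks are local maxima whose prominence exceeds a configurable
fraction (default 0.2) of the trace's maximal ΔF/F.  The spontaneous
excitation interval T is the difference of successive peak times, and a
cell is classed by its **median** interval — robust to a single missed
beat — as *regular* (750 ms < T < 1250 ms), *irregular* (T > 5000 ms), or
*intermediate*.

**CaT50** is the transient duration at 50 % decay: the time from the peak
sample to the first crossing below baseline + ½·(peak − baseline), with
linear interpolation between samples for sub-frame precision at 110 ms
sampling.  "Duration at 50 % decay" admits two readings; the default is
peak-to-half-decay (the decay-kinetics reading), with full-width at half
maximum available via `convention="fwhm"`.

The amplitude reference matters more than it may appear.  At ~1 s firing
with a decay constant τ ≈ 400 ms the fluorescence never fully returns to
the diastolic level between beats, so a percentile baseline sits roughly
0.09 amplitudes high and biases CaT50 low by ~30 ms.  The default
per-transient baseline is therefore estimated by **exponential-tail
regression**: for a mono-exponential decay sampled at interval Δ,
F[k+1] = ρ·F[k] + b(1 − ρ) with ρ = e^(−Δ/τ), so an ordinary
least-squares line through successive decay samples yields the asymptote
b = intercept/(1 − slope).  This is unbiased under overlapping tails and
degrades gracefully: if the fitted slope is not in (0, 1) or the asymptote
is implausible, the estimator falls back to the rolling-percentile
baseline.  On a noiseless mono-exponential the measured CaT50 equals
τ·ln 2 up to the convexity error of linear interpolation on a 110 ms grid
(≲ 4 ms for τ in 200–500 ms).

Population summaries are Gaussian (mean ± SD) over **per-cell median**
CaT50 values, so heavily firing cells do not dominate.

## Activation maps and conduction velocity

The activation map is adaptive per pixel: a pixel activates at the first
frame within the beat window whose intensity exceeds (1 + θ) times that
pixel's own temporal mean brightness.  Because the threshold is relative,
the map is invariant to global intensity scaling and tolerant of uneven
staining, unlike a fixed global threshold.  θ has no canonical value and
is a mandatory, logged parameter (default 0.10); the pixel mean is taken
over the full recording (stable across beats), and an optional 3×3 median
prefilter (off by default) suppresses salt noise.  Never-activated pixels
carry a sentinel distinct from "activated at t = 0"; multi-beat movies are
split into beat windows at the global-mean-trace peaks.  The threshold is
applied to raw intensity by default, with a ΔF/F-normalized mode available.

When a wave visibly spans ≥ 3 frames, conduction velocity is estimated
directly from the map by least-squares fitting a plane t(x, y) to the
activated pixels; CV = 1/|∇t| (µm/ms ≡ mm/s).  Frame quantization averages
out over the fit; synthetic planar waves are recovered within a few
percent.

### The frame-censored CV lower bound

Cultured clusters conduct so fast that a crossing often completes between
two frames.  With the wave-start phase uniform in [0, Δt), the probability
that a crossing of duration T is captured within a single frame is
p = max(0, 1 − T/Δt).  Observing k consecutive single-frame events has
probability p^k; requiring p^k ≥ α gives p ≥ α^(1/k) and hence

    T ≤ Δt·(1 − α^(1/k)),    CV = L/T ≥ L / T_upper ,

where L is the cluster length (maximal caliper of the mask).  At
Δt = 110 ms and α = 0.05 the bound is 16.05 ms for k = 19 and 14.62 ms for
k = 21; both evaluations are computed and reported by the acceptance
script, since they bracket the values quoted in the optical-mapping
literature this model addresses.  An alternative form replacing α^(1/k)
with (1 − α)^(1/k) circulates in print but does not follow from the
inequality above and collapses to near-zero bounds at conventional α; it
is available behind `variant="alt"` strictly for comparison.  A
Monte-Carlo oracle (`mc_validate`) confirms both the capture probability
and the nominal miss rate α at the bound, and a coverage simulation
verifies P(T_true ≤ T_upper | k captures) ≥ 1 − α.

Pooling choices: events from one recording and from separate recordings
are treated identically as independent phase draws; the pooled L is the
**minimum** cluster length across events, the conservative choice.  Any
multi-frame event means the traversal is resolved by the frame clock, so
the censored bound is refused and gradient estimation recommended instead.

Synchronization of named ROI groups (e.g. labelled cells embedded in a
monolayer) is judged by the absolute offset of each group's median
activation time from a reference group, with a default tolerance of one
frame interval.

## Morphometry and striation

Segmentation is Otsu's threshold plus connected components with a minimum
area (masks are also accepted directly).  The five descriptors are: area
(pixel count × pixel size²); elongation as the major/minor axis ratio of
the moments-fitted ellipse (a bounding-box fallback, flagged, covers
1-pixel-wide degenerates); circularity 4πA/P² with the perimeter measured
on a lightly smoothed sub-pixel marching-squares contour (the smoothing
undoes the stair-step overshoot of rasterized smooth shapes; a rasterized
disk scores ≈ 0.98, a square ≈ 0.79); the box-counting fractal dimension
of the one-pixel outline (boxes in powers of two from 2 px to a quarter of
the bounding box, least-squares slope of log N vs log 1/s — a disk gives
≈ 1.0, a level-5 Koch snowflake ≈ 1.25 against the analytic
log 4/log 3 ≈ 1.262); and the Feret diameter as the maximal caliper
distance over the convex hull.

Striation detection samples the intensity profile along the region's major
axis (interior pixels only — the rotated mask edge carries interpolation
ripple whose period can fall in the sarcomere band), detrends it, and
estimates its power spectral density by Welch's method (Hann window,
64-sample segments, 50 % overlap).  The dominant period is the highest
in-band peak (band 1.0–3.0 µm, the sarcomere scale); the decision
statistic is that peak's power over the median power of the positive
spectrum, striated iff ≥ 5.  Heavy segment averaging keeps the
peak-to-median ratio of a featureless profile near 2–3, well below the
threshold, while a genuine 2 µm modulation scores in the thousands — the
synthetic fixture suite separates perfectly with a wide margin.  Welch
segmentation trades frequency resolution for variance: the reported period
is accurate to about one frequency bin (~0.2 µm near 2 µm).

Group comparisons report per-descriptor means ± SD and a two-sided
Mann–Whitney p-value; the significance threshold is always supplied by the
caller.

## Patch-clamp metrics

Sweep tables carry one command/current trace per step; the test step is
located from the command waveform itself.  The fast and slow inward
components recorded in one prestep/step protocol (−30 mV prestep, 0 mV
step) are separated by a configurable time split after step onset (default
10 ms).  Currents are baseline-subtracted against the pre-step holding
current (no P/4-style leak protocol is modelled) and lightly smoothed with
a Savitzky–Golay filter, which suppresses noise without flattening the
ms-scale fast peak; the slow component uses a wider window (20 ms) because
searching a long interval for a minimum otherwise picks up noise extremes.
Densities are peak current over membrane capacitance (pA/pF).  I–V curves
use the mean current over the terminal window of each step (steady-state
mode, default 100 ms) or the in-step extreme (peak mode).  APD80 runs from
the point of maximal upstroke velocity (the standard convention) to the
linearly interpolated crossing of peak − 0.8 × amplitude, and is invariant
to voltage offset and amplitude scaling.

## The synthetic-data generator

The generator encodes the study conditions the package targets and gives
every artifact an analytic truth record:

- **Wave movies**: an elliptical cluster (default length 300 µm) crossed
  by a planar wavefront (target waves optional) at a set CV, sampled at
  Δt = 110 ms; each beat's start phase is uniform in [0, Δt) — exactly the
  assumption behind the censored-bound model.  Transients rise
  instantaneously and decay mono-exponentially (τ = 408 ms by default, so
  the analytic CaT50 is τ·ln 2 ≈ 283 ms); noise is additive Gaussian.
- **Spontaneous traces**: regular cells fire with Gaussian-jittered
  ~1000 ± 80 ms periods; irregular cells draw intervals uniformly in
  5.5–9 s.  Per-cell decay constants are drawn N(408, 43) ms, i.e. a
  CaT50 spread of ~30 ms — a population with zero spread would be an
  unrealistically easy recovery target.
- **Cell images**: rotated stadium shapes (length/width/orientation free),
  optionally modulated sinusoidally along the major axis at a sarcomere
  period in [1, 3] µm; rendering rejects periods under 4 pixels
  (aliasing).  The analytic area, perimeter, circularity, aspect ratio and
  Feret of a stadium serve as descriptor truth.
- **Ephys sweeps**: three phenomenological components — a fast inward
  α-function (τ = 1.2 ms, fully inactivated before the 10 ms split), a
  delayed slow inward α-function (peak ~30 ms), and an outward current
  rising to a plateau with delayed-rectifier-like activation (closed at
  ≤ 0 mV, so it does not contaminate the inward protocol).  All amplitudes
  scale linearly with capacitance (drawn from 12–30 pF), making densities
  capacitance-invariant by construction; default density scales are
  7.66 / 4.35 / 15.07 pA/pF.  An ideal ohmic mode provides closed-form
  I–V truth.  AP traces use a half-cosine upstroke (maximal dV/dt exactly
  at its midpoint) and linear repolarization with slope chosen so APD80 is
  exact by construction.

What the synthetic tests show — and what they do not: they verify the
estimators against known truth under the stated noise model (additive
Gaussian; an optional shot-noise mode exists for movies).  Real recordings
add motion, photobleaching, heterogeneous dye loading, cell-to-cell
waveform variation and optical blur, none of which are emulated; passing
tests therefore certify the algorithms, not the biology.  Camera bit
depth, magnification and field size are free parameters with documented
defaults, not inferences.

## Problem sizes and numerical choices

The validation suite uses sizes chosen to make Monte-Carlo statements
sharp while staying cheap: 50 000 phase draws for the capture-probability
check (3 binomial SE), 10 000–20 000 replicates for the miss-rate and
coverage checks, 1000 simulated movies for event-outcome frequencies,
20–50 seed batches for CV and CaT50 recovery, and a 20 + 20 cell fixture
suite for striation.  Threshold crossings are linearly interpolated
everywhere; ties in Mann–Whitney use midranks, with full enumeration exact
up to group size 8 (configurable) and a tie- and continuity-corrected
normal approximation beyond.  Degenerate inputs (empty ROIs, flat traces,
sub-threshold movies, silent groups, too-short regions) are flagged or
rejected with named errors rather than guessed at; readers refuse stacks
whose frame interval is unknown.

## Known limitations

The censored CV bound assumes a single coherent wavefront per beat and
independence of beat phases; re-entrant activity or phase-locked sampling
would violate it.  Gradient CV assumes locally planar propagation.  The
box-counting dimension of a rasterized outline is resolution-dependent
below ~2 px features.  Striation detection reports a single dominant
period; it does not separate multiple spatial frequencies.  The ephys
templates are phenomenological: they reproduce amplitudes, time scales and
capacitance scaling, not gating kinetics, so activation/inactivation
curves are out of scope.
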