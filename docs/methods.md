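# Methods

This note documents the models and procedures implemented in `caltrack`,
the parameters that matter, the design choices made where the procedure
was genuinely open, and what the synthetic-data validation does and does
not establish about real recordings.

## Acquisition model

The pipeline targets 1 Hz time-lapse stacks of 512×512 px covering
300×300 µm (0.586 µm/px), 600–900 frames per recording — microglia in
cortical layer I expressing a calcium indicator (cytosolic GCaMP6s-like,
or membrane-tethered Lck-GCaMP6f-like) over a dim constitutive label
(eYFP-like). All µm quantities derive from px × pixel size; coordinates
are 0-based (row, col) with pixel centres at integer coordinates, and
polygon ROI vertices live on pixel corners (a 10×10 axis-aligned
rectangle rasterizes to exactly 100 px).

## Motion correction

Each frame is aligned to a template — the mean of the first
`template_frames` frames (default 30) — by cross-correlation with
upsampled sub-pixel peak localisation (default 1/50 px). Plain
cross-correlation is used rather than spectrally whitened "phase"
correlation, which we found mis-estimates shifts on smooth, low-texture
fluorescence frames by ~0.2 px even without noise. Out-of-frame pixels
after resampling are filled with the frame's median so projections stay
NaN-free. Recovery on simulated jitter: programmed integer shifts are
recovered exactly (to the upsampling quantum), and 0.5 px sub-pixel
shifts at 2 % Gaussian noise with ≤ 0.05 px RMSE.

## ΔF/F baseline and events

F₀ is the linear-interpolation 25th percentile, across all frames, of a
centred 100 s moving average of the raw trace, with *shrinking* windows
at the edges (no padding — no fabricated data at boundaries). "Lower
25th quartile" is read as the 25th percentile. For recordings with
global contamination (seizures, spreading waves), a manual variant takes
the 25th percentile of a user-selected 200-frame quiet period, unsmoothed.

The event threshold is 3 × σ_baseline in ΔF/F units. The baseline frame
set over which σ is computed is not uniquely determined by the
procedure's verbal definition; we define it as the frames whose moving
average lies at or below the 25th percentile — the same frames that
determine F₀ — which keeps σ uncontaminated by transients. An
alternative ("all frames below the median") is available via
`baseline_mode`. σ uses the population SD (ddof = 0).

Events are maximal runs of contiguous frames with ΔF/F strictly above
threshold, with one robustness addition: a run must last at least
`min_duration_frames = 2` frames. At a 3σ threshold, Gaussian noise alone
produces ~0.8 single-frame crossings per 600-frame trace
(P(z > 3) ≈ 0.13 %), which would contaminate event counts at the sparse
rates typical of microglia; a two-frame minimum at 1 Hz removes
essentially all of them while leaving multi-second transients untouched
(sensitivity ≥ 0.99 for ≥ 5σ peaks on the validation traces). Setting
`min_duration_frames = 1` restores the literal maximal-runs definition.
Runs separated by a single subthreshold frame are *not* merged
(`merge_gap_frames = 0`); merging is available but off by default.

Signal area sums every suprathreshold ΔF/F sample (the values
themselves, not the excess over threshold) times the frame interval; at
1 Hz it equals the per-frame sum. The activity criterion is inclusive:
signal area ≥ 5 ΔF/F·s. With the default minimum event duration,
per-event areas partition the whole-recording signal area exactly
whenever every suprathreshold run lasts ≥ 2 frames; single-frame
crossings contribute to the signal area but not to any event. The
constitutive label's contribution to F is deliberately not subtracted —
it inflates F₀ and correspondingly compresses ΔF/F, which is part of the
measurement model.

Baseline accuracy condition: the moving-percentile F₀ is accurate to
< 2 % when at least a quarter of the smoothed trace is transient-free;
with a 100 s window this means sparsity at the smoothing scale, not just
raw occupancy. The validation traces use ≤ 3 transients of 30–40 frames
per 600 frames (15–20 % occupancy, ≥ 150-frame gaps); recordings in a
near-continuous high-activity state should use the manual baseline.

## Segmentation

Somata are assumed manually segmented (they are unambiguous by size and
brightness); the package validates rather than detects them. Process
territories are found on the whole-series average projection: somata
dilated by 2 px (halo suppression) are masked out, the remainder is
binarized — Otsu by default, since the original threshold was chosen
interactively; a fixed threshold is available for strict
reproducibility — and 8-connected components (ImageJ-wand-like) with
area strictly greater than 50 px become territories. Manual-segmentation
rules are checked advisorily: every process must have an associated soma
in the field, and secondary branches must exceed 15 px skeleton length
(~10 µm); violations are flagged, never silently dropped. Grid
parcellation (default 32 px tiles, a free choice) supports field-wide
low-level activity analysis.

## Motility

The two-projection protocol: average the first and last 100 frames,
threshold both at one uniform value (the recording's process threshold),
measure each ROI's suprathreshold area in both. Inclusion requires a
first area strictly greater than 9 µm²; a fractional change ≥ +50 %
classifies extension, ≤ −50 % retraction, otherwise stable (the exact
±50 % boundary counts as motile). The original workflow's visual
confirmation step is replaced by this quantitative rule alone, with the
red/green (first/last) overlay image emitted for optional human review.

The dynamic phase is bounded on a windowed area series (15 s sub-stack
projections): the start is the first window of a run of ≥ 3 successive
same-sign area changes each exceeding a noise tolerance; the end is the
first window at which the incoming change and the next one are both
within tolerance (the plateau), or the final window if no plateau
occurs. The tolerance defaults to max(SD of the first five window areas,
5 % of their mean): on clean projections the SD is exactly zero, so a
purely SD-based tolerance would flag rounding noise — the relative floor
makes the detector well-defined there. On a programmed +60 % ramp over
60 s, start and end are recovered within one 15 s window.

## Sholl profiles

Intersections are counted as contiguous foreground runs along a
1-px-wide circle walked in angular order (equivalent to the
circle-perimeter variant of the classical analysis), at radii step, 2
step, … r_max with step defaulting to 2 µm — the radius schedule is a
free parameter. A 4-ray analytic star yields exactly 4 at every radius
between soma edge and ray tip.

## Latency association

Qualifying calcium events have peak ΔF/F ≥ 0.5. For each
extending/retracting process the nearest qualifying peak before and
after the motility start are retained (ties go to the preceding event);
the smaller latency is binned into nested < 30 / < 60 / < 120 s windows.
Processes with no qualifying event remain in bin denominators —
fractions read "of all processes of that class" — configurable, and both
latencies stay in the record so the alternative convention can be
recomputed. SEM columns state their aggregation unit (microdomains) in
the report manifest, since mixing units across tables is a classic
source of irreproducibility.

## Synthetic data generator

The generator is the package's oracle, not a biophysical model. It
emulates: disk somata (radius 4 µm) with 4 random-walk processes each
(~3 px wide, optional one-level 1-px branches), soma ≫ process ≫
background intensities (1000 / 350 / 100 a.u.); sparse Poisson event
trains per microdomain (defaults 0.002 Hz soma, 0.004 Hz process —
roughly one to a few events per 10 min recording, matching the sparse
activity regime); a ΔF/F kernel with a 2-frame linear rise and
single-exponential decay (τ = 8 s cytosolic-slow, τ = 1.5 s
membrane-fast with half the amplitude scale — free parameters chosen for
qualitative sensor contrast, with the guaranteed property that the slow
preset integrates more area per event); lognormal peak amplitudes
(median 1.0, log-σ 0.4); programmed extension/retraction ramps rendered
by signed-distance-ordered pixel addition/removal (uniform
dilation/erosion, exact in pixel count, linear in time); rigid per-frame
jitter (integer by default, sub-pixel optional); additive Gaussian noise
(σ = 2 % of soma intensity) and optional Poisson scaling. Rendering is
linear — frame = static × (1 + ΔF/F) per compartment — so integrating
(frame − static)/static over a mask reproduces the injected kernel
exactly at zero noise. Identical config and seed give bit-identical
stacks and sidecars.

Not emulated: optics (PSF, depth attenuation), two true spectral
channels, bleaching, non-rigid motion, and any quantitative claim about
real amplitude/duration distributions (none are established for this
preparation). Passing the validation battery therefore demonstrates
algorithmic correctness — recovery of known signals under the stated
noise model — not robustness to every property of real tissue.

## Condition-shift experiment design

The end-to-end recovery experiment multiplies the process event rate by
k ∈ {2, 3} between a baseline and a treatment epoch at constant soma
rate, sharing each seed's morphology between epochs (one field imaged
twice, independent event draws). Field and cohort sizes were set by a
power calculation on the null (soma) ratio: with signal areas pooled
across 10 seeds of 10-cell 320×320 px fields at a 0.004 Hz soma rate,
each arm accrues ≈ 240 soma events, putting the soma ratio's standard
error near 10 % so that its expected range is well inside [0.8, 1.2].
The process ratio modestly underestimates k at k = 3 (≈ 2.3 recovered):
higher event occupancy inflates the moving-percentile F₀ and compresses
ΔF/F — the known bias of percentile baselines under dense activity,
shared with the original procedure.

## Problem sizes

Validation runs use reduced geometry so the whole battery completes in
minutes on one CPU: 128×128 px stacks for registration, 256×256 px for
segmentation, 160×160 px for motility, 1-D traces (600 frames) for
baseline/event statistics, and 320×320 px × 600 frames × 30 recordings
for the condition-shift experiment. All are package choices; the
algorithms are resolution-independent and run unchanged on full 512×512
× 900-frame recordings.
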