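# Methods

This note documents the models, conventions and parameter choices behind
`vasculomap`, in the spirit of a methods appendix: what each stage
computes, which decisions were genuinely open, and what the synthetic
validation does and does not establish.

## Coordinate and calibration conventions

All rasters are row-major with the row index increasing downward, the
standard image convention; for a coronal slice with the cortical surface
at the top, "descending" axial flow (toward larger rows) corresponds to
penetrating arterioles. Physical calibration (µm per pixel, default 2) is
always supplied by the caller and never inferred from file metadata,
because the scanner's export format does not specify it. Pixel `(r, c)`
has its center at `((r+0.5)·px, (c+0.5)·px)` µm.

## Vascular coverage

The density export carries nonzero intensity wherever at least one
microbubble track crossed a pixel, so binarization uses threshold 1 (any
nonzero pixel is vessel) by default; the threshold is exposed for
sensitivity analyses. No morphological cleanup is applied. Coverage of a
region is `100 · (foreground ∩ region) / |region|`; `whole_brain` is
defined as the union of all labeled pixels, so its coverage is the
pixel-weighted average of the per-region values.

## Local thickness

The diameter estimator is the model-independent *local thickness*: each
foreground pixel's value is the diameter of the largest circle fully
inscribed in the mask that contains the pixel. Digital circles need an
explicit rule for "contains" and "fits", and reference implementations
differ at boundaries, so the package fixes one rule and verifies it
exhaustively:

- circle centers lie on pixel centers; radii on the half-pixel lattice;
- a circle of radius ρ contains pixel p iff the center-to-center distance
  is ≤ ρ; it fits iff every contained pixel is foreground, with pixels
  beyond the image border counting as background.

Under this rule the largest circle centered at c has integer pixel
diameter `k(c) = max{k : (k/2)² < d²(c)}`, with `d²(c)` the exact squared
Euclidean distance to the nearest background pixel. The fast path obtains
`d²` exactly from the Euclidean distance transform's nearest-background
indices (integer arithmetic throughout, so no floating-point boundary
drift), then propagates each circle's diameter over the pixels it
contains, one radius class at a time via binary dilation, keeping the
per-pixel maximum. A brute-force oracle (`thickness_oracle`, guarded to
≤ 64×64 masks) re-derives the same quantity by explicit pairwise integer
distance comparisons and agrees with the fast path pixel-for-pixel on
hundreds of random masks. The reference FIJI plugin's sub-pixel
interpolation is *not* reproduced; absolute agreement with it is not
claimed.

Consequences of the digitization rule worth knowing:

- an isolated pixel has thickness 1 px; an n-pixel-wide straight band has
  thickness n px along its whole width (away from its ends);
- values taper near structure ends and the image border, where large
  circles no longer fit;
- a capsule whose centerline lies on a pixel *boundary* rasterizes one
  pixel wider than nominal (the footprint rule `dist ≤ w/2` is
  inclusive), so width recovery is exact for odd pixel widths on
  pixel-center rows and accurate to ±1 px (±2 µm) in general.

**Reliability floor.** Transcranial ULM's effective resolution limits
trustworthy radii to ≳5 µm, so pixels with diameter < 10 µm are flagged.
Flagged values remain in the map (they are reported) but are excluded
from diameter distributions, regional summaries and flow maps by default.

## Speed and Poiseuille flow

The 8-bit speed export maps 0–100 mm/s linearly to 0–255; decoding
divides by 2.55 and clips defensively to [0, 100]. Per-pixel volumetric
flow uses the velocity-area form of Poiseuille flow,

    Q = v · A = v · π r² · K ,

with `v` in mm/s, `r = thickness/2` in µm, and `K = 6×10⁻⁸` the exact
unit conversion to mL/min (`1 mm/s · 1 µm² = 10⁻¹⁵ m³/s = 6×10⁻⁸
mL/min`). The exported speed is treated as a scalar per-pixel speed; no
vessel-axis projection is attempted. Pixels flagged by the reliability
floor contribute Q = 0.

**Averaging domain.** Regional CBF is the mean Q over vessel-positive,
unflagged pixels (Q is undefined off-vessel). An all-pixel average —
which weights the summary by vascular density — is available via
`domain="all"`; the choice is ambiguous in principle and both readings
are supported. Speed histograms use 2 mm/s bins; flow histograms use
logarithmic bins because Q spans orders of magnitude across calibers.

## Arteriole-to-venule ratio

The RGB direction export is split by channel: red-dominant pixels are
arteriolar (descending), blue-dominant venular, and exact ties or black
pixels are unclassified — a deterministic, conservative rule. AVR is the
arteriole:venule pixel-count ratio restricted to the cortex, where the
single-axis direction sensitivity aligns with penetrating vessel
orientation; the result also reports each class as % of total vascular
pixels so either reading of the biomarker can be reproduced. The
red=arteriole convention is configurable (`red_is_arteriole=False`) for
acquisitions with the opposite axis sign; swapping channels maps
AVR → 1/AVR exactly.

## Neurovascular coupling

A session is 7 cycles of 30 s baseline / 30 s stimulation / 30 s post,
sampled at dt = 0.2 s (the scanner's minimal inter-scan pause). Each
cycle is normalized to its own baseline mean
(`ΔCBV% = 100·(s − b̄)/b̄`, scale-invariant), then summarized by the
average ΔCBV% over the stimulation window, the peak, and the time to
peak. The peak search is restricted to the stimulation window (the
measured quantity is stimulation-evoked hyperemia); the first stimulated
sample carries time dt after onset, and a trial that never rises above
baseline reports peak 0 with a missing time-to-peak, excluded pairwise
from that metric's statistics. The statistical unit is the individual
response (trial), pooled across animals within a group. No detrending or
filtering is applied by default.

## Group statistics

Animal-level metrics (coverage, regional CBF, AVR) and per-response NVC
metrics are compared with the unpaired pooled-variance Student t-test;
pixel-level speed and thickness distributions with Welch's t-test
(unequal variances, Welch–Satterthwaite df). Treating pixels as
observations is a faithful reproduction of the upstream analysis
convention, not a statistical endorsement — it massively inflates
effective n, and the per-animal unit is available by passing animal-level
summaries to the same tests. Two-sided p-values throughout; no
multiple-testing correction; stars at 0.05/0.005/0.001/0.0001. The t
machinery is scipy's, verified in the test suite against independent
closed-form implementations to 1e-10 and Monte-Carlo calibrated (type-I
error at α = 0.05 within the binomial 95% CI over 1000 null replicates).

## Synthetic phantom: the stated world

The generator emulates the scanner's exports from explicit ground truth.
Vessels are straight constant-width capsules — the simplest geometry with
an analytic area (`L·w + π(w/2)²`) — rendered at 2 µm/pixel: density 255
on the footprint union, speed `round(v·2.55)`, direction pure red/blue.
Overlaps in the speed and direction rasters resolve in favor of the
later-listed vessel (deterministic and documented). NVC traces sit at a
fixed baseline of 100 arbitrary units (so percent-change math is
transparent) plus, per trial, a unit-peak gamma-variate kernel
`(t/tp)^α · e^{α(1−t/tp)}` scaled to the response amplitude, plus white
noise.

Default cohort parameters (chosen once as physiologically plausible for
mouse cortical/deep microvasculature, not tuned to any outcome): 6 young
and 7 aged animals; 330×330 px (660×660 µm) slices with three horizontal
bands (cortex, hippocampus, white matter); young target coverage
fractions 0.20/0.16/0.12; log-normal widths (median 14 µm, σ = 0.35,
clipped to 3–50 µm); region mean speeds 10/8/6 mm/s with 15% per-vessel
CV; cortical vessels near-vertical, arteriole area fraction 0.6 met by
quota; HRF amplitude 20%, latency 5 s, shape 3, noise SD 2%;
between-animal variability as mean-1 log-normal jitter with 5% CV. Aged
effects are multiplicative on the truth: coverage ×0.8 (applied to the
target area fraction, so the aged/young true-coverage ratio is 0.8 by
construction), widths ×0.8, hippocampal velocity ×0.7, cortical velocity
×1.15, HRF amplitude ×0.6, latency ×1.5, arteriole fraction ×0.8. All
randomness flows from a single integer seed through one
`numpy.random.SeedSequence`, spawned once per animal, so runs are
bit-reproducible and adding animals never perturbs earlier ones.

**What a green phantom test establishes — and what it does not.** The
phantom validates the *quantification*: that each stage recovers known
geometry, speeds, flows, direction ratios and response parameters, and
that imposed group contrasts propagate through the full pipeline to
correctly-signed, significant comparisons. It does not model microbubble
localization statistics, point-spread blur, tortuosity, branching,
out-of-plane flow, or the noise texture of real exports (which is
unpublished); agreement with phantom truth therefore says nothing about
upstream reconstruction quality on real data.

## Numerical choices and degenerate inputs

- Thickness: exact integer arithmetic end to end; ties in the histogram
  mode or direction classification break deterministically (direction
  ties → unclassified).
- Empty masks yield all-zero thickness maps; empty regions, zero-venule
  AVR, non-positive NVC baselines, and zero-variance t-tests raise
  errors rather than returning NaN.
- Speed decoding round-trip error is bounded by half a grey level,
  100/255 ≈ 0.39 mm/s.
- The acceptance check of K uses rel = 1e-14 because the literal product
  `1e-3·1e-12·1e6·60` differs from `6e-8` by one ulp in IEEE-754.

## Known limitations

- 2-D only; no 3-D local thickness or volumetric flow integration.
- One thresholded mask serves both coverage and thickness (the upstream
  workflow used a trainable segmenter for the diameter masks; that step
  is deliberately out of scope).
- Straight-segment phantoms cannot probe curvature-dependent biases of
  the thickness estimator.
- Pressure-gradient/viscosity terms of the full Poiseuille law are
  context only; the operational formula is the velocity-area form.
- Absolute perfusion in mL/100 g/min is not computed.
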