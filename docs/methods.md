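# Methods

This note documents the models implemented in `mobivls`, the parameters
that matter, the numerical choices made where the design was open, and
what the synthetic experiments do and do not show about real imagery.

## 1. The line-scan detector

MOBIVLS processes each image row left-to-right and each column
top-to-bottom as independent scan lines through four stages.

**Photoreceptor adaptation (PRC).** Divisive (Naka–Rushton-form)
normalisation `y = v / (v + v̄)` against a causal exponential moving
average `v̄` of the line with smoothing factor `1/prc_adapt_length`
(default 25 px), initialised at the first sample. This compresses the
raw 14-bit counts into [0, 1) without a global transfer curve: a
constant line maps to 0.5 regardless of its level, and responses become
contrast-like quantities that are comparable across frames. The
adaptation state trails the signal, so a step is followed by a genuine
recovery transient (see section 1.1 below).

**Lamina filtering (LMC).** An antisymmetric difference-of-boxes along
the scan direction: `z_i = mean(y_{i+1..i+h}) − mean(y_{i−h..i−1})`,
half-width `h = lmc_halfwidth` (default 3 px). The coefficients sum to
zero at every position, so constant input yields exactly zero, and the
output is a *signed edge code*: positive at intensity rises, negative at
falls. Windows are cropped at the line ends and the mean taken over
available samples (an empty side falls back to the centre sample).
Cropping matters: padding with zeros instead fabricates edge lobes at
the frame border that pair with the leading edge of any target within
about one scale of the border and produce a bright false blob several
pixels off-target.

The signed edge code is what gives the detector its polarity
selectivity. A bright target emits ON (rise) at its leading edge and
OFF (fall) at its trailing edge; a dark target emits the opposite
ordering. The bright correlator below only responds to ON-before-OFF.

**Rectification (RTC).** Half-wave rectification into non-negative ON
and OFF channels, `ON − OFF` reconstructing the input exactly. An
optional asymmetric smoother (fast attack, slow decay per channel) is
available but off by default: the detector operates on single images,
so per-line channel adaptation is a refinement, not a requirement.

**Delay-and-multiply correlation (ESTMD).** For bright targets,
`r_i = Σ_{s∈scales} ON_{i−s}·OFF_i` with out-of-range reads zero; for
dark targets the channel roles swap; `both` sums the two. The scale
bank (default 3–11 px, matching the expected animal sizes) makes the
stage size-selective: the leading-ON/trailing-OFF separation of a
width-*w* target matches a delay *s ≈ w*, so targets inside the band
respond much more strongly than 1-px noise or ≥ 25-px structures
(measured ratio ≈ 8× and ≈ 7× respectively on clean pulses). Because
the ordering is multiplicative, the correlator is *exactly* blind to
the OFF-before-ON signature of the opposite polarity; end-to-end a
small residue remains at opposite-polarity targets because the PRC
recovery transient after the trailing edge is itself a genuine
intensity event (dominance of the correct channel is better than 10×
in the shipped tests).

**Cross-directional combination.** The row grid H and column grid V
are each pooled with a uniform window equal to the median scale
(7 px for the default bank) and shifted back by half that window along
their own scan axis. The raw correlation response concentrates at a
target's trailing edge — at its right edge for the row scan and its
bottom edge for the column scan — so without re-centring the two grids
peak at *different pixels* and their product carries no signal. After
re-centring, the map is `H∘V + H + V` (the product rewards targets
compact along both axes; the sum retains single-axis evidence).

**Normalisation.** The combined response is divided by a fixed
`response_scale` (default 1.0, roughly the pooled response of an ideal
full-contrast compact target) and clipped to [0, 1]. The scale is
*absolute*, not per-frame: PRC already makes responses comparable
across frames, and stretching each frame's map to [0, 1] independently
would assign saliency 1.0 to the brightest clutter of every frame that
happens to contain no visible animal — which destroys the low-FPR
operating region of a pooled threshold sweep for any detector. A
constant frame maps to an all-zero map.

**Detection.** Threshold at `mean + threshold_k·std` of the map
(k = 5 by default), 8-connected components, components smaller than
`min_blob_area` (default 2 px) discarded, one record per component at
its response-weighted centroid with confidence equal to the component's
peak value.

### 1.1 Known behaviours

- The PRC recovery transient after a strong target adds a weak trailing
  response; it is genuine adaptation dynamics, not an artifact of the
  discretisation.
- Confidences are absolute response levels; dim-but-real targets
  legitimately have small confidences (~10⁻³). Threshold sweeps sample
  every component-appearance event, so this costs nothing.

## 2. Baseline detectors

The seven comparison detectors are windowed-contrast methods; where
their literature offers variants, the simplest published formulation is
used, with shared settings: inner scales {3, 5, 7, 9, 11} px, outer
window 21 px (a single outer size for all inner scales), ILCM window
10 px at 1 px step, TMBM constants C = 0.2, T = 0.6, scoring threshold
0.8, intensity floor 0.1.

- **AAGD** — max over inner scales of mean(inner) − mean(outer ring),
  bright responses only.
- **IAAGD** — min over the 8 surrounding same-size cells of
  mean(inner) − mean(cell); a straight edge always has at least one
  equally bright neighbour cell, so edges are suppressed.
- **MLCM** — max over scales of min over the 8 neighbour cells of
  `L²/m_i`, `L` the centre-cell maximum. Note the max statistic gives
  dark targets no excess over background: MLCM is bright-only.
- **ILCM** — the mean-based single-coarse-window variant.
- **HB-MLCM** — high-boost sharpening (`x + (x − boxmean₅(x))`) before
  MLCM.
- **MPCM** — min over the four opposing-direction products
  `(m₀−m_i)(m₀−m_{i+4})`; positive for bright *and* dark targets.
- **TMBM** — counts scaled by the 16-bit container full scale (so the
  absolute intensity floor is meaningful), floored, constant-subtracted
  and hard-thresholded into a binary mask; normalised cross-correlation
  against flat-disc templates at the inner scales; scores below 0.8
  zeroed. The diameter-3 "disc" fills its bounding box (zero variance)
  and is skipped; TMBM cannot score targets that small.

All windows are cropped at frame borders with means over available
pixels, so every centre response is reproducible by a brute-force
windowed-statistics oracle (asserted to 10⁻¹⁰ in the tests). All maps
are min-max normalised per frame except TMBM, whose correlation score
is already in [0, 1].

## 3. Evaluation protocol

A detection matches a ground-truth instance when their centroids are
within 6 px (Euclidean). Matching is greedy nearest-first, each record
used at most once, with ties broken by detection confidence; on small
instances this equals the optimal assignment (asserted by exhaustive
permutation in the tests). Fully occluded instances carry no thermal
signature: they are excluded from the positive set and a detection at
such a location is a false positive.

True negatives are non-overlapping 12×12-px patches anchored at (0,0):
a W×H frame contributes ⌊W/12⌋·⌊H/12⌋ patches and
`tn = patches − tp − fp` (640×512 → 2226 patches). This makes FPR
denominators proportional to frame count, putting survey-scale FPRs in
the 10⁻⁶–10⁻⁴ regime.

Curves sweep one global threshold from 1 to 0 over per-frame maps:
`n_steps` uniform values (default 2000) plus every distinct local-peak
value of the maps, quantised to 10⁻⁴ of the largest peak (the sweep's
threshold resolution), so each component-appearance event is sampled.
Points carry raw counts; with component detections the raw TPR/FPR are
not forced monotone, because blobs merge as the threshold falls and a
false positive can become part of a matched component. AUROC integrates
the monotone upper envelope of TPR over FPR ∈ [0, 10⁻⁴] (trapezoid,
divided by the range, in percent), extending the last TPR if the curve
never reaches the range end. EER interpolates the crossing of recall
and precision along the sweep. The operating point for summary metrics
is the threshold with the largest raw FPR not exceeding the requested
operating FPR, recall breaking ties; precision at `tp+fp = 0` is
defined as 0.

Per-animal detectability (`avg_kdet`) averages, over unique animals,
the fraction of frames in which the animal is present *and not fully
occluded* where it was detected. Excluding fully occluded frames from
the denominator mirrors the matching rule.

## 4. Synthetic scenes

Backgrounds are white Gaussian noise smoothed with a Gaussian of sigma
`clutter_correlation_px` (default 8 px) and standardised, so the sample
temperature mean and SD equal the configured values exactly (defaults
14.2 °C and 1.35 °C, the cooler of the two survey sites). Only the
marginal temperature distribution of real canopy is characterised, so
the spatial correlation length is a free knob. Temperatures convert to
counts through a linear map (100 counts/°C, 8000-count offset),
validated to stay inside the 14-bit range.

Targets are discs with a flat core and Gaussian-tapered rim, diameter
3–11 px, amplitude rescaled so the *mean* excess over the disc
footprint equals the drawn contrast exactly. Placement is uniform with
a 12 px border margin and 24 px minimum separation. Each target is,
independently per frame, fully occluded with probability 0.40 (recorded
in ground truth, not rendered), optionally partially occluded (half
contrast, random half-disc masked), else rendered and flagged visible.
A pool of unique animals with fixed base positions is re-placed each
frame with ±2 px jitter to emulate revisits across overlapping survey
frames.

All randomness flows from integer seed sequences
(`[seed, frame_index, stream]`) through numpy's default bit generator,
so datasets are bit-reproducible across runs and platforms.

**What passing these tests shows — and does not.** The synthetic scenes
have smooth, stationary, Gaussian clutter and isolated axis-independent
targets. Real survey frames contain structured clutter (sun-heated
ground seen through gaps, trunks, specular reflections), non-stationary
statistics along the flight, partial occlusion shapes more complex than
half-discs, and animals at lower contrast. Perfect scores on the
high-contrast synthetic condition demonstrate that the pipeline's
mechanics (scale selectivity, polarity handling, absolute response
scale, matching and bookkeeping) are correct; they are not a forecast
of field performance.

## 5. Occlusion simulator

Trees are a 9×9 lattice (spacings 1/3/5 m): stems are 30 m vertical
capped cylinders of 0.30 m diameter; branches four 1 m cylinders of
0.15 m diameter at 45° elevation, laid out as a cross at the stem top;
foliage a sphere at the stem top, 1 m diameter (light) or 2 m (heavy).
The four structure levels are nested, so with the same ray set the
blocked set can only grow and detection probability is cellwise
monotone non-increasing across levels — asserted exactly. The animal is
a 0.25 m-radius sphere tangent to the central stem on one of eight
compass sides, at altitude 25/15/0 m.

Occlusion is binary: a ray from the camera centre to the animal that
intersects (or grazes, within 10⁻⁶ m) any primitive is fully blocked;
no intensity attenuation. Visibility samples 64 deterministic Fibonacci
lattice points on the camera-facing hemisphere. The on-image size uses
the slant-range/pin-hole relations (`dca = (fh−ka)/cos(90−da+θ)`,
`size = ImageDim·0.5 / (2·dca·tan(FOV/2))`, the printed form of the
slant-range equation read with the numerator parenthesised — the only
reading consistent with the sub-8 px and sub-5 px size bounds);
"detected" means at least one estimated visible pixel, which is what a
simple threshold filter reduces to on a binary-occlusion render.

Flights are serpentine, 2 m transect spacing and 2 m along-track step
(≈ 2.9° angular discrimination between transects at 40 m), bounded by
the lattice footprint plus a flight-height margin; poses where the
animal leaves the 50°×50° FOV are excluded from the probability
denominator. Detection probability pools the eight compass orientations
per configuration cell.

Ray–primitive intersections are analytic (quadratic for sphere and
cylinder side, plane tests for the caps, grazing inclusive); the test
suite checks them against a dense ray-marching point-membership oracle
with a ±1 mm radius bracket. A cheap 2-D ground-track cull discards
primitives that cannot touch a pose's ray bundle before the exact
tests; culling is conservative (primitive footprint plus animal radius
plus 5 cm slack), verified by identical sweep outputs with and without
it during development.

The Beer–Lambert surrogate reports the integrated chord length of the
camera→animal segment through foliage spheres, as a percentage of the
foliage radius; multiplying by an attenuation coefficient α gives
relative attenuation. No exponential imaging model is applied.

## 6. Problem sizes in the shipped tests

The default test run uses 256×256-px synthetic frames (8 per dataset),
sweeps of a few hundred thresholds, and occlusion sweeps restricted to
representative cells (nadir and 60°, 25 m altitude, one flight height);
these sizes keep the whole suite around half a minute while exercising
every code path at full parameter defaults. The generators and sweeps
scale to survey-sized inputs (640×512 frames, 0–90° depression in 10°
steps, 40–100 m flight heights) through the same interfaces.

## 7. Known limitations

- The synthetic clutter is an isotropic Gaussian surrogate; no attempt
  is made to reproduce the empirical size–contrast joint histogram of
  real detections.
- TMBM's flat-disc template bank is a reconstruction; the original
  template is not described in the sources available here.
- The evaluation's TN patch tiling is anchored at (0,0) and not
  overlap-aware; it is bookkeeping for FPR denominators, not a spatial
  model of negatives.
- The occlusion simulator has no terrain, no tree-height variability,
  and binary occlusion only; its absolute probabilities are indicative,
  and known artefacts of such simple geometry (e.g. dips at mid
  depression angles) should not be over-interpreted.
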