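# Methods

`hvipipe` implements the measurement and analysis chain used to quantify
aqueous humor outflow in episcleral veins from hemoglobin video imaging
(HVI): slit-lamp video under a green filter (505–575 nm), in which
hemoglobin absorbs strongly, so the flanking blood lanes of a vein appear
dark and the clear central aqueous column appears bright. The pipeline has
five stages — synthetic scene generation, video I/O, preprocessing, width
and flow measurement, and crossover statistics — each usable on its own.

## The measurement model

### Aqueous-column width

A cross-sectional intensity profile of an episcleral vein carrying an
aqueous column has a bright central maximum (the column) flanked by two
local minima (the blood lanes). The column width is defined as the distance
between those two minima. `width.measure_width` implements this as:

1. Gaussian-smooth the profile (`smooth_sigma_px`, default 2 px). The
   default suits sensor noise around SD 0.05 on a unit intensity scale;
   noiseless or lightly noisy profiles can use less.
2. Take the most prominent interior local maximum as the aqueous core.
   Prominence rather than the raw global maximum is used deliberately: on a
   noisy profile the single brightest sample can sit on the background
   (scleral) plateau, while the core peak — walled in by two dark lanes —
   always dominates in prominence.
3. On each side of the core, take the deepest local minimum; ties between
   equally deep minima break toward the minimum nearer the core.
4. Refine each minimum to subpixel precision with a parabola through its
   3-point neighbourhood; the width is the distance between the two refined
   minima, in pixels (no physical calibration is attempted).

Profiles whose maximum falls on an edge, or that lack a minimum on either
side, raise an "unmeasurable profile" error; `measure_width_clip` excludes
and counts such frames, failing only when they exceed half of the 30-frame
slice. Per-clip widths are the mean over frames; two observers' means are
averaged arithmetically. Percent change from baseline is computed per
subject *before* averaging — the mean of per-subject percent changes is not
the percent change of group means, and the reporting follows the former.

### Frame handling and preprocessing

Footage is nominally 4K at 60 fps, converted to AVI, and analysed at 30 fps
by keeping alternate frames. Which of the two interleaved frame sets is
kept is a pure convention: `subsample_alternate_frames` keeps even 0-based
indices and halves the fps. RGB clips are reduced to the green plane, the
channel carrying the hemoglobin contrast.

Blinks are detected as global-intensity dips: a frame is a blink frame when
its mean intensity falls below `dim_factor` (default 0.6) times the rolling
median (window 31) of the mean-intensity trace. The detector is
self-normalizing, so uniformly dark footage produces no events. Measurement
segments are anchored *immediately after* a blink (offset 0 frames — the
protocol states no offset, so none is added), because aqueous flow slows
between blinks.

Camera shake is removed by translation-only registration against the first
frame of the selected segment: rotation in slit-lamp footage is negligible
at this magnification, and the width itself is translation-invariant (a
documented limitation rather than a lack — no affine correction is
attempted). Shifts are estimated by partially whitened phase correlation:
both frames are low-pass filtered (sigma 1 px), edge-tapered with a Tukey
window (full Hann tapering would down-weight the static scleral texture
near the borders, which is precisely what anchors the estimate against the
moving blood speckle), and the cross-power spectrum is normalized with its
magnitude floored at 5% of the mean magnitude — full phase normalization
would let spectral bands without scene energy contribute pure noise. The
correlation peak is refined to subpixel by a one-axis-at-a-time quadratic
fit. Corrected frames are resampled with linear interpolation and edge
replication. On synthetic clips the estimator recovers injected jitter of
SD up to 5 px with RMS error below 0.5 px; residual error is dominated by
the along-vessel component, where the advecting speckle is indistinguishable
from camera motion for any translation registrar.

### Flow metric

A pixel inside a blood lane sees moving speckle, so its temporal
autocorrelation

    R(n) = E[(p(t) − μ)(p(t + n) − μ)] / σ²

decays with lag n at a rate set by the flow speed. The expectation is
estimated as the mean over the T − n valid frame pairs. Two normalization
conventions are implemented and tagged in every result: *per-pixel-temporal*
(μ, σ from the pixel's own series; R(0) = 1 exactly, the default) and
*segment-spatial* (μ, σ from the segmented region as a whole, matching a
segment-level reading of the normalization). The per-pixel variance is
computed as the mean centred square — the same expression as the lag-0
numerator — so R(0) is exactly 1 in floating point, not merely close.

The scalar reduction is deliberately simple and robust, since the exact
reduction used historically with this formula is not public: per ROI pixel,
n\* is the smallest lag with R(n) < 0.5; the flow proxy is the median of
1/n\* (frames⁻¹). Pixels that never decorrelate within `max_lag` (including
constant pixels) are excluded and counted; an ROI in which every pixel is
excluded yields a "no decorrelation detected" result rather than an
exception. The proxy is monotone in the true advection speed on synthetic
scenes (median lags 6, 3, 2, 1 at 0.5, 1, 2, 4 px/frame with the default
2 px speckle grain) but is not calibrated to physical velocity.

## The crossover statistics

The trial design is a two-sequence, two-period crossover: 16 subjects
randomized 1:1 to ripasudil-then-latanoprost or latanoprost-then-ripasudil,
with washout between periods. The primary analysis models the per-subject
percent change in column width from the same-drug baseline (raw width is
available behind a flag):

    y = β₀ + β_seq + β_drug + β_period + u_subject + ε,
    u ~ N(0, σ_u²), ε ~ N(0, σ²)

fitted by REML. Because the model has a single variance ratio
λ = σ_u²/σ², the fit profiles the REML criterion over log λ with a bounded
1-D optimizer; for each λ the GLS estimate and profiled residual variance
are closed-form (block-diagonal V with V_i = I + λJ). The λ → 0 boundary is
checked explicitly, where the fit reduces to OLS. The implementation agrees
with `statsmodels` `MixedLM` to 4+ decimals on fixed datasets.

The drug-effect p-value defaults to the between-within (containment)
method: a t reference with within-subject degrees of freedom
(n_obs − rank(X) − (n_subjects − between-rank); 14 here) and the SE
estimated from the within-subject stratum. For a balanced 2×2 crossover
the drug contrast is orthogonal to the subject space, making this statistic
exactly t-distributed under normality; simulation confirms a 5.0% type-I
rate and a uniform null p-value distribution at n = 16. A REML-Wald normal
reference is selectable (`df_method="normal"`) but is anticonservative at
this sample size (≈8% empirical type-I): the normal tail is too light for
14 df, and the pooled REML σ̂² shrinks when the variance ratio is
overestimated by chance. Satterthwaite and Kenward–Roger corrections are
out of scope. α = 0.05 two-sided throughout; no multiplicity adjustment.

Supporting tests: Pearson χ² on 2×2 tables without continuity correction
(required to reproduce the reference baseline-characteristics p-values,
verified analytically); pooled-variance unpaired t from summary statistics;
Wilcoxon signed-rank (zeros dropped — the classic convention) and rank-sum.
Exact two-sided Wilcoxon p-values (n ≤ 25 signed-rank, ≤ 10 per group
rank-sum) are computed by dynamic programming over doubled midranks, which
reproduces full enumeration over sign patterns / group assignments, ties
included; larger samples use the normal approximation with tie correction.
Two-sided p is twice the smaller tail, capped at 1.

## The synthetic scene generator

No raw HVI footage is publicly available, so every stage is validated on
rendered scenes with exact ground truth.

**Geometry.** A straight vessel (default width 120 px, column 64 px — the
scale of reported baseline widths at 45× magnification in 4K) crosses a
192×256 frame at 20° . The noiseless cross-section is built piecewise so
that its two minima sit *exactly* `column_width_px` apart: each blood-lane
well is an even function of the distance from its centre within a matching
half-width (a parabola continued by a mirrored cubic Hermite shoulder),
blended into the aqueous plateau (intensity 0.88) and scleral background
(0.62) by monotone Hermite segments. Evenness around the minima makes their
positions invariant under the Gaussian smoothing used by the measurement;
segment lengths are capped so no piece overshoots (no spurious extrema).
The default angle is non-zero and the background carries static band-limited
texture (contrast 0.08, grain 3 px, outside the vessel only) because a
perfectly axis-aligned vessel over a featureless sclera makes the
along-vessel translation component unobservable — a degenerate scene no
real footage resembles.

**Dynamics.** Blood speckle is band-limited unit-variance noise (Gaussian
filtered, grain 2 px) advected rigidly along the axis by
`flow_speed_px_per_frame` (whole-pixel plus linear interpolation),
amplitude-windowed onto the lane centres (contrast 0.05). Blinks multiply
whole frames by 0.3 — the pipeline only uses blinks as segment markers, so
eyelid geometry is not modelled. Camera jitter is a per-frame global
translation drawn from N(0, jitter_sd²), applied exactly in scene
coordinates (no resampling loss). Sensor noise is additive white Gaussian,
clipped to [0, 1]. All randomness flows from one seed; rendering is a pure
function of the scene parameters.

**Study generator.** `render_crossover_study` draws, per subject and drug,
a baseline width from the per-drug baseline model (ripasudil 63.7 ± 19.6 px,
latanoprost 66 ± 18.9 px) and percent changes per timepoint from the
reported distributions (ripasudil 2 h: 28.8 ± 16.3%, 8 h: 7.6 ± 12.6%;
latanoprost 2 h: −2.5 ± 5.7%, 8 h: −4.3 ± 8.1%), with IOPs from the
corresponding mmHg models. SD = 0 degenerates to a point mass. Optionally
one vein video per observation is rendered with the observed width as its
true column width.

**What the generator does not emulate** — and hence what passing tests do
not establish about real footage: curved or branching vessels, pulsatile or
non-rigid speckle motion, illumination drift and specular reflections,
eyelash shadows, rotation or scale changes of the camera, RGB Bayer
demosaicing, and compression artifacts (the AVI layer is uncompressed).
Observer line placement is simulated only as a lateral offset.

## Numerical and design choices

- Intensities live in [0, 1] as float64 from read time; AVI I/O quantizes
  to 8 bits (values on the 1/255 grid round-trip bit-exactly).
- Profile sampling uses bilinear interpolation at uniform spacing
  `length/ceil(length)` ≤ 1 px, endpoints inclusive; an axis-aligned line
  on integer coordinates reproduces raw pixel values exactly.
- Subpixel refinements (correlation peak, profile minima) are 3-point
  parabolic fits, clipped to ±0.5 sample.
- The number of clips recorded per eye in the source protocol is ambiguous,
  so the simulator exposes `n_clips` as a free parameter rather than fixing
  a count.
- Degenerate inputs fail loudly and specifically: constant signals
  (autocorrelation), all-zero differences (Wilcoxon), zero margins (χ²),
  single-sequence designs (LMM), monotone profiles (width) each have a
  dedicated exception; batch commands flag per-clip failures without
  aborting the batch.
- Default problem sizes used by the test-suite simulations: 30-frame width
  slices, 40-frame registration clips, 120-frame flow clips, 500-replicate
  power checks and 2,000-replicate type-I calibration — sizes at which the
  Monte-Carlo error is comfortably inside the asserted tolerances.

## Known limitations

- Translation-only registration; rotation/affine drift is not corrected.
- The flow proxy is ordinal, not a calibrated velocity; between-condition
  comparisons should treat it as a rank-scale quantity.
- The LMM handles a single random intercept; carryover beyond the sequence
  fixed effect is not modelled (matching the trial's analysis).
- Widths are reported in pixels; no micron calibration exists for the
  optical chain.
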