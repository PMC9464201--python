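# hvipipe

Analysis pipeline for **hemoglobin video imaging (HVI)** of aqueous humor
outflow. Under a green filter (505–575 nm) on a slit-lamp microscope,
hemoglobin absorbs strongly: blood in an episcleral vein appears dark,
while the clear central stream of aqueous humor — the *aqueous column* —
appears bright between the two blood lanes. The width of that column is a
direct, non-invasive readout of conventional-pathway aqueous outflow, and
is the primary endpoint when comparing IOP-lowering drugs (e.g. the ROCK
inhibitor ripasudil versus the prostaglandin analog latanoprost) in a 2×2
crossover design.

The package is for researchers who have vein video clips (or want fully
synthetic ones with known ground truth) and need the complete chain:

- **`synthetic`** — render episcleral-vein videos (bright column, dark
  advecting blood lanes, blinks, camera jitter, sensor noise) and whole
  simulated crossover studies, with exact ground truth.
- **`video_io`** — uncompressed AVI read/write, green-channel extraction,
  60→30 fps alternate-frame subsampling.
- **`preprocess`** — blink detection, post-blink segment selection, and
  translation stabilization by subpixel phase correlation.
- **`width`** — aqueous-column width as the distance between the two
  blood-lane intensity minima of a cross-sectional profile:
  `w = |x₋ − x₊|`, minima refined to subpixel, averaged over a 30-frame
  slice and over two observers.
- **`flow`** — per-pixel temporal autocorrelation
  `R(n) = E[(p(t) − μ)(p(t+n) − μ)]/σ²` and its reduction to a
  decorrelation-lag flow proxy (median over an ROI of 1/n\*, with n\* the
  smallest lag where R < 0.5).
- **`stats`** — the crossover analysis: linear mixed model
  `y = β₀ + β_seq + β_drug + β_period + u_subject + ε` fitted by REML
  (1-D profile over σ_u²/σ²), exact Wilcoxon signed-rank / rank-sum tests,
  Pearson χ² without continuity correction, pooled t from summaries.
- **`pipeline` / `hvipipe` CLI** — `simulate`, `measure`, `flow`,
  `analyze` subcommands over TOML configs with full seed control.

## Worked example

```python
import numpy as np
from hvipipe import (SceneParams, render_video, detect_blinks,
                     select_post_blink_segment, stabilize, SamplingLine,
                     measure_width_clip, StudyDesignParams,
                     render_crossover_study, fit_crossover_lmm)

# a synthetic vein: 64 px column, a blink at frames 40-44, camera jitter
params = SceneParams(column_width_px=64.0, blink_frames=((40, 5),),
                     n_frames=120, seed=7)
clip, truth = render_video(params)

blinks = detect_blinks(clip)
segment = select_post_blink_segment(clip, blinks, segment_len=30)
stabilized, trace = stabilize(segment)

# measurement line perpendicular to the vessel axis, through its centre
th = np.deg2rad(params.axis_angle_deg)
cx, cy = params.axis_point
line = SamplingLine(cx + 40*np.sin(th), cy - 40*np.cos(th),
                    cx - 40*np.sin(th), cy + 40*np.cos(th))
m = measure_width_clip(stabilized, line)
print(f"blinks: {[(b.start_frame, b.end_frame) for b in blinks]}")
print(f"width: {m.mean_width_px:.2f} +/- {m.sd_width_px:.2f} px "
      f"(true {truth.column_width_px} px)")

# a simulated 16-subject crossover study and its primary analysis
table, _ = render_crossover_study(StudyDesignParams(), seed=1)
fit = fit_crossover_lmm(table, timepoint="2h")
print(f"drug effect: {fit.drug_effect:+.1f} percentage points "
      f"(SE {fit.drug_se:.1f}), p = {fit.drug_p:.2e} (t, df={fit.df:.0f})")
```

prints

```
blinks: [(40, 45)]
width: 63.80 +/- 0.45 px (true 64.0 px)
drug effect: +36.6 percentage points (SE 4.9), p = 2.93e-06 (t, df=14)
```

The blink detector finds the injected blink; the width measurement recovers
the true 64 px column to 0.2 px from 30 noisy, stabilized frames; and in a
study simulated with a ripasudil-like dilation (+28.8 ± 16.3% at 2 h)
against a latanoprost-like null (−2.5 ± 5.7%), the mixed model attributes a
strongly significant width increase to the drug — the drug effect is the
ripasudil-minus-latanoprost difference in mean percent change, in
percentage points.

The same flow end-to-end from a shell:

```sh
hvipipe simulate --seed 5 --out-dir run --n-clips 4
hvipipe measure  --seed 5 --out-dir run
hvipipe flow     --seed 5 --out-dir run
hvipipe analyze  --seed 5 --out-dir run
```

which writes per-clip width CSVs, per-pixel decorrelation-lag maps, and the
crossover report tables (width, IOP, mixed-model fits).

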