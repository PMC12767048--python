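# vasculomap

Quantification of cerebrovascular structure and function from
super-resolution ultrasound image exports.

Ultrasound localization microscopy (ULM) and functional ultrasound (fUS)
can map the living mouse brain's microvasculature at ~2 µm/pixel and track
its hemodynamics at 5 Hz. The scanner-side software exports each coronal
slice as plain 8-bit rasters — a vascular density map, a microbubble speed
map (0–255 encoding 0–100 mm/s), and an RGB axial-direction map — plus
region-averaged relative cerebral blood volume (rCBV) time series during
stimulation. `vasculomap` turns those exports into the biomarkers used to
characterize cerebrovascular aging:

- **Vascular coverage** — percentage of vessel-positive pixels per
  anatomical ROI (whole brain, cortex, hippocampus, subcortical white
  matter), after binarizing the density map at intensity ≥ 1.
- **Vessel diameter** — per-pixel *local thickness*: the diameter of the
  largest circle that fits inside the segmented vasculature and contains
  the pixel. Values below a 5 µm-radius reliability floor (the effective
  ULM resolution limit) are flagged and excluded from statistics.
- **Resting cerebral blood flow** — per-pixel volumetric flow from the
  simplified Poiseuille relation `Q = v · π r² · K` with `v` the decoded
  speed (grey/2.55, mm/s), `r` the local radius (µm) and `K = 6×10⁻⁸`
  converting to mL/min; regional CBF is the mean Q over reliable vessel
  pixels.
- **Arteriole-to-venule ratio (AVR)** — cortical pixels with descending
  axial flow (red) are penetrating arterioles, ascending (blue) are
  venules; AVR is their pixel-count ratio, a structural biomarker of
  cerebrovascular remodeling.
- **Neurovascular coupling (NVC)** — 30 s baseline / 30 s whisker
  stimulation / 30 s recovery, repeated 7 times; per response the package
  reports average ΔrCBV%, peak ΔrCBV% and time-to-peak within the
  stimulation window.
- **Group statistics** — unpaired Student's t for animal-level metrics,
  Welch's t for pixel-level speed and thickness distributions, with
  `*/**/***/****` stars at p < 0.05/0.005/0.001/0.0001.

Because no acquisition data are released with such studies, the package
includes a **synthetic phantom generator** that replaces the scanner:
straight capsule-footprint vessels with known width, speed and flow
direction are rendered into exactly the export formats above (plus NVC
traces from a gamma-variate response model), so every stage is validated
by ground-truth recovery — including a full 6-young vs 7-aged cohort with
imposed aging effects.

## Worked example

```python
import numpy as np
from vasculomap import *

# one 30 µm vessel carrying 20 mm/s on a 512x512 µm slice
vessel = VesselSpec(endpoints=((101.0, 40.0), (101.0, 460.0)),
                    width_um=30.0, velocity_mm_s=20.0,
                    axial_direction="descending")
scene = make_scene([vessel], grid_shape=(256, 256), pixel_size_um=2.0)
regions = make_region_set((256, 256), {"cortex": (0, 256, 0, 256)})

mask = binarize(render_density_map(scene))
print(f"coverage: {coverage(mask, regions, 'cortex'):.2f} %")

tmap = apply_reliability_floor(local_thickness(mask))
vals = tmap.values[tmap.values > 0]
print(f"median diameter: {np.median(vals):.1f} um")

speed = decode_speed(render_speed_map(scene))
fmap = flow_rate_map(speed, tmap)
q = regional_cbf(fmap, mask, regions, "cortex")
print(f"regional CBF: {q:.3e} mL/min")
```

prints

```
coverage: 5.08 %
median diameter: 30.0 um
regional CBF: 8.473e-04 mL/min
```

The 30 µm width is recovered exactly; the regional mean Q is within 0.2%
of the analytic `20 · π · 15² · 6×10⁻⁸ = 8.482×10⁻⁴` mL/min (the small
deficit comes from tapered thickness at the vessel's end caps). Coverage
matches the capsule's analytic area fraction.

## Command line

```sh
vasculomap run --seed 11 --out report/        # full phantom-mode study
vasculomap phantom --seed 4 --out exports/    # scanner-style exports only
vasculomap coverage --density d.tif --regions roi.tif --out cov.csv
vasculomap thickness --mask m.tif --regions roi.tif --floor-um 5 --out t.csv
vasculomap cbf --speed s.tif --thickness t.tif --mask m.tif --regions roi.tif --out q.csv
vasculomap avr --directional dir.tif --regions roi.tif --out avr.csv
vasculomap nvc --trace trace.csv --out nvc.csv
vasculomap compare --table tidy.csv --out stats.csv
```

`run` writes per-animal metrics, young-vs-aged comparison tables (with
test method, t, df, p and stars), per-response NVC metrics, group mean
response curves, and a manifest capturing config and seed; identical
config + seed reproduces every CSV byte-for-byte.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the complete phantom-cohort pipeline end to end at the given seed
(the study's own numbers derive from unreleased animal imaging, so there
are no published values to recompute) and leaves the full CSV report
bundle beside the output file.

See `docs/methods.md` for the models, parameter choices, numerical
conventions and known limitations.
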