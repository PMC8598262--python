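# microquant

Image quantification and statistics for **collagen microtissue fibrosis
assays** — and a synthetic-scene generator that makes every stage of the
pipeline verifiable against known ground truth.

Cell-laden collagen microspheres (~300 μm) are a miniaturized,
high-content alternative to classic hydrogel contraction assays for
studying fibrotic fibroblast function (e.g. in idiopathic pulmonary
fibrosis) and screening anti-fibrotic compounds. Each droplet is imaged as
a 2D multi-channel fluorescence projection (nuclei / marker / live
stains). `microquant` turns those images into per-droplet readouts and
screen-ready statistics:

* **Compaction** — droplet masks by texture-suppressed isodata
  thresholding; projected area, equivalent diameter
  `d = 2·√(A/π)`, and spherical volume fold-change `(d₀/d)³`.
* **Marker expression per cell** — `(mean − p₁₀)/N`: mean in-mask
  intensity minus the construct's own 10th-percentile background, divided
  by the nuclear count from blob detection.
* **Viability** — per-cell live-stain classification; live fraction per
  droplet.
* **Statistics** — 3-SD outlier filter, carrier-control (DMSO)
  normalization, paired t (replicate experiments), nested t (patients as
  the experimental unit), one-way ANOVA with Tukey HSD, 95% CIs and star
  codes.

The generator (`microquant.synthgen`) renders droplets with exponential
compaction kinetics, condition-dependent marker fold-changes, Hill
dose-response attenuation, per-patient random effects and
Poisson–Gaussian sensor noise — with a ground-truth table for recovery
testing. See `docs/methods.md` for the models and defaults.

## Worked example

The `demo` subcommand chains simulate → quantify → stats → recovery on a
small built-in two-arm design (control vs TGF-β1-activated, day 7):

```bash
microquant demo --out demo_out --seed 1 --n-droplets 8
```

```
demo complete: outputs in demo_out
  normalized_intensity_per_cell: student_t control vs activated p=4.64e-22 [****]
  area_um2: student_t control vs activated p=1.54e-19 [****]
  live_fraction: student_t control vs activated p=0.651 [ns]
```

The activated arm shows strongly elevated per-cell marker intensity and
reduced projected area (both ****), while viability does not differ (ns)
— the expected phenotype. `demo_out/recovery.json` compares measurements
with the generator's ground truth; with this seed the measured
activated/control intensity fold is 3.293 against a true fold of 3.269,
cell counts are recovered exactly, and mean projected areas sit within
~1% of truth. (The intensity fold exceeds the programmed 2.2× expression
effect because activated droplets have also compacted — per-cell signal
concentrates as area shrinks; matched-diameter designs isolate expression
alone.)

Individual stages are plain functions:

```python
from microquant import synthgen, pipeline, quantify

cfg = synthgen.GeneratorConfig(seed=1)
img, truth = synthgen.render_microtissue(
    cfg, synthgen.DropletSpec("d1", diameter_um=150, n_cells=25), seed=1
)
(m,) = pipeline.quantify_image(img)
print(m.equiv_diameter_um, m.cell_count, m.normalized_intensity_per_cell)
print(quantify.volume_fold_change(300.0, m.equiv_diameter_um))
```

For real data, `microquant quantify --manifest manifest.csv --out out/`
walks a manifest CSV (`image_path, droplet_id, condition, dose_uM,
timepoint_days, patient_id, replicate, channel_map`) of multi-page TIFFs,
and `microquant stats` runs the test battery from a YAML design spec.

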