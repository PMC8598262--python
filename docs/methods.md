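# Methods

`microquant` quantifies fibrotic function in cell-laden collagen
microtissues from multi-channel 2D fluorescence images, and ships a
synthetic-scene generator so every stage of the pipeline can be validated
against known ground truth. This note records the models, the defaults and
the reasoning behind the open design choices.

## The assay being modeled

A microtissue is a collagen microsphere (~300 μm at fabrication) carrying
encapsulated fibroblasts, imaged as a 2D projection. Fibrotic activation
(e.g. TGF-β1) is read out three ways:

* **Compaction** — cells contract the gel; the projected area shrinks.
  Summarized as the spherical volume fold-change `(d0/d)^3`, where `d` is
  the projected-area equivalent diameter and `d0 = 300 μm` the starting
  construct.
* **Marker expression per cell** — mean in-mask fluorescence minus the
  construct's own 10th-percentile intensity, divided by the nuclear count:
  `(mean − p10) / N`. The p10 term makes the readout exactly invariant to
  any global additive offset; the division by `N` removes cellularity
  differences.
* **Viability** — calcein-positive cells over all cells per droplet.

Hypothesis tests follow high-content screening practice: droplets are
technical replicates; the experiment (paired t) or the patient (nested t)
is the unit of analysis.

## Synthetic-scene generator (`synthgen`)

The generator is first-class, tested code: its defaults define the
conditions under which the pipeline's recovery claims are made.

**Geometry.** One centered disk per 384×384 px field at 1 μm/px, 16-bit.
Compaction follows exponential decay to a plateau,
`d(t) = d_inf + (d0 − d_inf)·exp(−t/τ)` — the simplest profile with the
sharp early contraction and later plateau characteristic of collagen-gel
contraction assays. Plateau diameters default to the values implied by
inverting the 37-fold (activated) and 18-fold (control) spherical volume
reductions from 300 μm: `d_inf = 300/37^(1/3) ≈ 90.0 μm` and
`300/18^(1/3) ≈ 114.5 μm`. The time constant is not published; τ = 1.5
days is chosen once so that arms separate within 48 h and reach ~99% of
plateau by one week, matching the described kinetics. Fabrication size
dispersion (`d0_cv`) defaults to 0 (monodisperse emulsion) but is exposed
as a parameter.

**Cells.** Counts are Poisson with mean 25 per droplet (negative binomial
when over-dispersion is requested), spanning the realistic 10–40 range.
Nuclei are placed by rejection sampling at integer pixels with pairwise
separation ≥ 4 nucleus sigmas (σ = 2 px) and ≥ 3σ from the rim, so that
counting ground truth is unambiguous and punctum mass stays inside the
tissue. Because nuclei in a 2D projection must remain resolvable, the
drawn count is truncated at ~70% of the disk's hexagonal packing capacity
(logged when applied), and plateau diameters are floored at 80 μm —
physically, compaction saturating at a threshold tissue stiffness.

**Intensity model.** Marker channel = diffuse tissue signal (300 counts/px)
plus one Gaussian punctum per cell (integrated mass 5×10⁵ counts), both
multiplied by the condition's effect scale; nuclei and live channels carry
puncta only. Activation multiplies the marker scale by `activated_fold`
(default 2.2, the hallmark cross-linking-enzyme effect size; 1.7 models
the weaker enzyme). Drug dose z attenuates activation by a Hill factor
`1 − e_max·z^h/(z^h + ic50^h)`, applied to both the marker fold and the
compaction depth beyond the control plateau. Patient heterogeneity is a
log-normal multiplicative random effect (σ = 0.15) on marker amplitude and
compaction depth, drawn once per patient from a substream keyed on the
patient label.

**Noise.** Background = constant offset (100) + linear column gradient
(0.05 counts/px), then Gaussian noise with variance
`shot_scale·signal + read_sigma²` (0.3, 20) — the standard Poisson–Gaussian
sensor approximation. Pixels are clipped to the bit depth with a warning.
Per-droplet render streams derive from `SeedSequence([seed, 0, index])`,
so any droplet is reproducible in isolation and whole cohorts are pure
functions of (config, design, seed).

**Ground truth** records, per droplet, the true diameter/area, cell count,
realized live count, and the idealized per-cell intensity
`scale·per_cell_amp / area_px` (the blob-tail contribution to the p10
baseline is neglected, which the recovery tolerances absorb).

## Image analysis (`imaging`)

**Preprocessing.** Large-scale background (Gaussian at half the image
size — far wider than any droplet) is subtracted, negatives are clamped,
and contrast is stretched between the 1st and 99.5th percentiles. The
correction is exactly invariant to global additive offsets; a constant
image is returned unchanged with a warning. The corrected image is used
*only* to find masks — intensity readouts always come from the raw
channel, so no display-oriented rescaling can leak into quantification.

**Segmentation.** The default segmentation channel is the maximum
projection over non-nuclear channels, where the droplet outline is
visible. Bright per-cell puncta are 50-fold brighter than the diffuse
tissue signal and would capture any histogram threshold, so the global
threshold is *estimated* on a grey-opened copy of the channel (disk
footprint of radius 7 px — larger than a punctum, much smaller than a
droplet), where the histogram is cleanly background-vs-tissue. The
threshold itself is the isodata (Ridler–Calvard) value — the fixed point
at the midpoint of the two class means, which tracks the tissue edge's
half-height crossing and, unlike the between-class-variance criterion,
stays stable when zero-background pixels dominate the histogram. The
threshold is then *applied* to the unopened, Gaussian-smoothed (σ = 2 px)
channel, so the opening's min-filter erosion bite cannot pull the mask
boundary inward. A fixed threshold can be supplied instead. Binary
closing (edge-padded so borders are not eroded), hole filling and
connected-component labeling follow. Components under 1000 px² (debris)
or touching the border (censored projected area) are dropped by default;
border exclusion is configurable and flagged.

Measured accuracy under the generator's defaults: area within 2% of truth
on noiseless disks (radius ≥ 20 px) and within ~1% on average at default
noise across the 90–300 μm diameter range.

**Nuclear counting.** Smoothing (σ = 1 px — the channel already carries
the 2 px nucleus PSF) followed by local maxima inside the mask, with a
prominence threshold at 25% of the in-mask dynamic range above the 10th
percentile. The minimum peak separation defaults to 2 nucleus sigmas:
half the generator's packing distance, so two genuine nuclei at the
minimum packing separation always resolve, while anything closer merges
into one detection by design. Counting is exact on noiseless scenes and
within 10% on average at default noise.

**Viability.** Each detected cell's mean live-stain intensity over a
3 px-radius disk is classified by an automatic bimodal (Otsu) split of the
per-cell means. Otsu misbehaves when a droplet is all-live or all-dead
(it happily splits a unimodal cluster), so the split is accepted only when
the class separation exceeds twice the within-class spread *and* 5% of the
intensity scale; otherwise the classifier falls back to a fixed absolute
threshold (5% of the dtype range by default) with a warning. Live + dead
always equals the detected total.

## Quantification conventions (`quantify`)

* Percentiles use the linear-interpolation convention.
* `(mean − p10)` is floored at zero (signal is physically non-negative);
  the droplet is flagged.
* Zero-cell droplets keep their area but are excluded from per-cell
  intensity statistics (flagged, value NaN).
* The in-mask p10 is computed over construct pixels only, not the whole
  field — the construct serves as its own background reference.
* Volume folds treat the droplet as a sphere whose diameter is the
  projected-area equivalent diameter.
* Secreted-protein normalization (`concentration × volume / cells`) and
  batch seeding arithmetic (`μL/1000 × cells/mL`) are plain unit
  conversions kept in the package so the whole analysis is reproducible
  from one API.

## Statistics (`stats`)

* **Outliers**: one pass per (metric, group) — points beyond 3 sample SDs
  (n−1 denominator) of the full group are dropped, before any
  normalization or testing; no re-iteration. Below n = 3 or at zero SD
  nothing is removed.
* **Carrier-control normalization**: each droplet's metric is divided by
  the mean of the designated control group within the same replicate
  experiment, so the control's normalized mean is exactly 1.
* **Paired t**: on per-replicate condition means (the replicate experiment
  is the pairing unit); two-sided, with a 95% CI of the mean difference.
* **Nested t**: droplets collapse to unweighted per-patient means, then an
  equal-variance two-sample t on patient means — the exact equivalent of
  the nested mixed model for balanced designs; unbalanced designs are
  handled by the unweighted means. Degrees of freedom count patients, so
  the test is immune to droplet-level pseudo-replication by construction.
* **ANOVA + Tukey HSD**: one-way fixed effects with studentized-range
  adjusted pairwise p-values (scipy); the Tukey family is per metric per
  screen, with no cross-metric adjustment. With two groups the procedure
  degrades to an unpaired Student t with a warning.
* Equal-variance (Student) forms throughout, matching the named classical
  tests. Star codes use strict inequalities: * < 0.05, ** < 0.01,
  *** < 0.001, **** < 0.0001, else ns.
* Whether outliers were removed before or after carrier normalization is
  not specified by the protocol; "before" is implemented. Tests run on
  droplet-level values by default (the screen's data points are droplets);
  replicate- or patient-level designs opt in via the design spec.

## What the simulations do and do not show

Recovery experiments use the sample sizes of the assay's own claims: 30
droplets/arm for compaction and marker folds, ≥ 500 cells for viability,
1000 replicates for type-I calibration. Marker-fold cohorts are rendered
at matched droplet diameters across arms: in `(mean − p10)/N` the per-cell
signal scales inversely with projected area, so matched geometry isolates
the expression effect from the compaction confound — exactly the
comparison the per-cell normalization is designed to make. Compaction
cohorts emulating the single-donor (NHLF) experiment disable the patient
random effect.

The generator emulates the assay's statistical structure, not its optics:
no out-of-focus light, no overlapping or non-circular droplets, no
spatially varying PSF, no debris, and nuclei never overlap in projection.
Passing recovery tests therefore demonstrates that the measurement and
statistics chain is unbiased and calibrated under the stated image model;
it does not certify segmentation performance on real micrographs with
focus drift or irregular morphology. On real data the area and border
filters are the only droplet-exclusion mechanisms; any manual curation of
dim or out-of-focus droplets is outside the pipeline.

## Numerical details

* Thresholding, peak detection and label bookkeeping are deterministic;
  peak ordering follows scikit-image's deterministic intensity ordering.
* All intensity parameters are in camera counts (no fluorophore
  calibration, as in the assay itself).
* Degenerate inputs are contracts, not crashes: constant images warn and
  pass through; empty masks, zero cells, mismatched pairs, and patients in
  both arms raise with explicit messages; unknown config keys are rejected
  recursively.
* The measurements CSV is written with a stable column order; reruns with
  the same config and seed are byte-identical.
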