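"""Synthetic microtissue image generator with known ground truth.

Emulates the collagen-droplet contraction assay: disk-shaped microtissues
(~90-300 μm equivalent diameter) carrying 10-40 nuclei, a marker stain with
a diffuse tissue component plus per-cell puncta, a live stain, additive
background (offset + linear gradient) and Poisson-Gaussian sensor noise.
Every rendered droplet is paired with a :class:`GroundTruth` record so the
downstream segmentation/quantification/statistics stages can be validated
by recovery tests.

Compaction follows exponential decay to a plateau,
``d(t) = d_inf + (d0 - d_inf) * exp(-t/tau)``, the simplest profile matching
the sharp early contraction that levels off seen in classic collagen-gel
contraction assays.  Default plateau diameters are derived by inverting the
spherical volume folds (d0/d)^3 = 37 (activated) and 18 (control) from a
300 μm starting construct.

Drug action is a Hill attenuation of the activated phenotype: at dose z the
activation effect (marker fold and compaction depth beyond control) is
multiplied by ``1 - e_max * z^h / (z^h + ic50^h)``.
"""
from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging import MicrotissueImage

logger = logging.getLogger(__name__)

__all__ = [
    "CompactionParams",
    "MarkerParams",
    "BackgroundParams",
    "NoiseParams",
    "DoseResponseParams",
    "CellCountParams",
    "GeneratorConfig",
    "DropletSpec",
    "GroundTruth",
    "Cohort",
    "simulate_compaction",
    "simulate_dose_effect",
    "render_microtissue",
    "generate_cohort",
    "CHANNEL_ORDER",
]

#: starting construct diameter, μm
DEFAULT_D0_UM = 300.0
#: plateau diameters implied by the 37-fold (activated) and 18-fold
#: (control) spherical volume reductions from a 300 μm construct
DEFAULT_D_INF_ACTIVATED_UM = DEFAULT_D0_UM / 37.0 ** (1.0 / 3.0)   # ≈ 90.0 μm
DEFAULT_D_INF_CONTROL_UM = DEFAULT_D0_UM / 18.0 ** (1.0 / 3.0)     # ≈ 114.5 μm

CHANNEL_ORDER = ("nuclei", "marker", "live")


@dataclass
class CompactionParams:
    """Plateau diameters (μm) and time constant (days) of the decay model."""

    d_inf_control_um: float = DEFAULT_D_INF_CONTROL_UM
    d_inf_activated_um: float = DEFAULT_D_INF_ACTIVATED_UM
    tau_days: float = 1.5


@dataclass
class MarkerParams:
    """Marker-channel intensity model.

    ``diffuse_base`` is the per-pixel tissue-level signal; ``per_cell_amp``
    is the integrated intensity of one cell's punctum; ``activated_fold`` is
    the multiplicative up-regulation of both under activation (>= 1).
    """

    diffuse_base: float = 300.0
    per_cell_amp: float = 5.0e5
    activated_fold: float = 2.2


@dataclass
class BackgroundParams:
    """Additive camera background: constant offset + linear column gradient."""

    offset: float = 100.0
    gradient_slope: float = 0.05


@dataclass
class NoiseParams:
    """Sensor noise with variance ``shot_scale*signal + read_sigma**2``."""

    shot_scale: float = 0.3
    read_sigma: float = 20.0


@dataclass
class DoseResponseParams:
    """Hill model for drug attenuation of the activated phenotype."""

    e_max: float = 1.0
    ic50_um: float = 10.0
    hill: float = 1.0


@dataclass
class CellCountParams:
    """Count distribution per droplet: Poisson(mean), over-dispersed to a
    negative binomial with variance ``mean*(1+dispersion)`` when
    ``dispersion > 0``."""

    mean: float = 25.0
    dispersion: float = 0.0


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic scene.

    Defaults emulate the assay's stated conditions: a 300 μm starting
    construct compacting to plateaus implied by the 37-/18-fold volume
    reductions, ~25 cells per droplet, a 2.2-fold activated marker
    up-regulation, 95% viability, and modest Poisson-Gaussian camera noise.
    """

    image_size: int = 384
    pixel_size_um: float = 1.0
    bit_depth: int = 16
    droplet_d0_um: float = DEFAULT_D0_UM
    compaction: CompactionParams = field(default_factory=CompactionParams)
    cells_per_droplet: CellCountParams = field(default_factory=CellCountParams)
    nucleus_sigma_px: float = 2.0
    nucleus_amp: float = 5.0e4
    live_amp: float = 3.0e5
    marker: MarkerParams = field(default_factory=MarkerParams)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    dose_response: DoseResponseParams = field(default_factory=DoseResponseParams)
    live_fraction: float = 0.95
    #: droplet-to-droplet fabrication size dispersion (lognormal sigma);
    #: 0 models a monodisperse emulsion
    d0_cv: float = 0.0
    #: lognormal sigma of the per-patient multiplicative random effect on
    #: marker amplitude and compaction depth
    patient_sd: float = 0.15
    #: compaction saturates once the tissue reaches a threshold stiffness;
    #: plateau diameters are floored here (μm) after patient effects
    d_inf_floor_um: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        c = self.compaction
        if not (0 < c.d_inf_activated_um < self.droplet_d0_um):
            raise ValueError("d_inf_activated_um must lie in (0, d0)")
        if not (0 < c.d_inf_control_um < self.droplet_d0_um):
            raise ValueError("d_inf_control_um must lie in (0, d0)")
        if c.tau_days <= 0:
            raise ValueError("tau_days must be > 0")
        if not 0.0 <= self.live_fraction <= 1.0:
            raise ValueError("live_fraction must be in [0, 1]")
        dr = self.dose_response
        if dr.hill <= 0 or dr.ic50_um <= 0:
            raise ValueError("hill and ic50_um must be > 0")
        if not 0.0 <= dr.e_max <= 1.0:
            raise ValueError("e_max must be in [0, 1]")
        m = self.marker
        for name, v in (
            ("diffuse_base", m.diffuse_base),
            ("per_cell_amp", m.per_cell_amp),
            ("nucleus_amp", self.nucleus_amp),
            ("live_amp", self.live_amp),
            ("background.offset", self.background.offset),
            ("noise.shot_scale", self.noise.shot_scale),
            ("noise.read_sigma", self.noise.read_sigma),
        ):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if m.activated_fold < 1.0:
            raise ValueError("activated_fold must be >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class DropletSpec:
    """Fully resolved per-droplet rendering parameters."""

    droplet_id: str
    diameter_um: float
    n_cells: int
    marker_scale: float = 1.0
    live_fraction: float = 0.95
    condition: str = ""
    dose_uM: float = 0.0
    timepoint_days: float = 0.0
    patient_id: str = ""
    replicate: int = 1


@dataclass
class GroundTruth:
    """True per-droplet values encoded by the generator."""

    droplet_id: str
    true_equiv_diameter_um: float
    true_area_um2: float
    true_cell_count: int
    true_live_count: int
    true_live_fraction: float
    true_normalized_intensity: float
    true_marker_scale: float
    condition: str = ""
    dose_uM: float = 0.0
    timepoint_days: float = 0.0
    patient_id: str = ""
    replicate: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# closed-form models
# ---------------------------------------------------------------------------

def simulate_compaction(config: GeneratorConfig, t, activated: bool = False):
    """Equivalent diameter d(t) = d_inf + (d0 - d_inf)·exp(-t/tau), in μm.

    ``d_inf`` is the activated or control plateau per the flag; d(0) = d0
    and d(t) is strictly decreasing toward the plateau.  Scalar or array
    ``t`` (days); negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be >= 0 days")
    c = config.compaction
    d_inf = c.d_inf_activated_um if activated else c.d_inf_control_um
    d0 = config.droplet_d0_um
    out = d_inf + (d0 - d_inf) * np.exp(-t / c.tau_days)
    return float(out) if out.ndim == 0 else out


def simulate_dose_effect(config: GeneratorConfig, dose):
    """Remaining activation effect at a drug dose (μM): Hill attenuation
    ``1 - e_max * z^h / (z^h + ic50^h)``, in [1 - e_max, 1].

    Equals 1 at dose 0 and is monotone non-increasing in dose.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    dr = config.dose_response
    zh = dose**dr.hill
    with np.errstate(invalid="ignore"):
        frac = np.where(dose > 0, zh / (zh + dr.ic50_um**dr.hill), 0.0)
    out = 1.0 - dr.e_max * frac
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _place_nuclei(
    rng: np.random.Generator,
    n: int,
    r_place: float,
    min_sep: float,
    max_attempts_per_cell: int = 500,
) -> np.ndarray:
    """Rejection-sample ``n`` integer pixel centers inside a disk of radius
    ``r_place`` (centered at origin) with pairwise distance >= ``min_sep``."""
    placed: list[tuple[int, int]] = []
    attempts = 0
    budget = max_attempts_per_cell * max(n, 1) * 4
    while len(placed) < n:
        if attempts >= budget:
            raise ValueError(
                f"could only place {len(placed)} of {n} nuclei at minimum "
                f"separation {min_sep:.1f} px inside radius {r_place:.1f} px; "
                f"request fewer cells (achievable maximum here ~{len(placed)})"
            )
        attempts += 1
        y = rng.uniform(-r_place, r_place)
        x = rng.uniform(-r_place, r_place)
        if y * y + x * x > r_place * r_place:
            continue
        yi, xi = int(round(y)), int(round(x))
        ok = all(
            (yi - py) ** 2 + (xi - px) ** 2 >= min_sep**2 for py, px in placed
        )
        if ok:
            placed.append((yi, xi))
    return np.asarray(placed, dtype=int).reshape(n, 2)


def render_microtissue(
    config: GeneratorConfig,
    spec: DropletSpec,
    seed,
) -> tuple[MicrotissueImage, GroundTruth]:
    """Render one microtissue field of view and its ground truth.

    The scene is a disk-shaped collagen region; nuclei are Gaussian blobs at
    rejection-sampled centers (pairwise separation >= 4 nucleus sigmas, and
    >= 3 sigmas from the rim so punctum mass stays inside the tissue).  The
    marker channel is the diffuse tissue signal plus per-cell puncta, both
    scaled by ``spec.marker_scale``; the live channel holds puncta at nuclei
    sampled live with probability ``spec.live_fraction``.  Background offset
    + gradient and variance-matched shot + read noise are then applied and
    the result is clipped to the bit depth (clipping logged as a warning).

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`; an identical seed reproduces the image
    bit for bit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size = config.image_size
    px = config.pixel_size_um
    sigma = config.nucleus_sigma_px
    r_px = spec.diameter_um / (2.0 * px)
    if r_px + 3.0 * sigma >= size / 2.0:
        raise ValueError(
            f"droplet diameter {spec.diameter_um:.0f} μm does not fit the "
            f"{size}x{size} px field with margin at {px} μm/px"
        )
    center = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    disk = (yy - center) ** 2 + (xx - center) ** 2 <= r_px**2

    n = int(spec.n_cells)
    if n < 0:
        raise ValueError("n_cells must be >= 0")
    r_place = r_px - 3.0 * sigma
    if n > 0 and r_place < 1.0:
        raise ValueError("droplet too small to hold any nucleus")
    offsets = (
        _place_nuclei(rng, n, r_place, min_sep=4.0 * sigma)
        if n > 0
        else np.empty((0, 2), dtype=int)
    )
    rows = np.round(offsets[:, 0] + center).astype(int)
    cols = np.round(offsets[:, 1] + center).astype(int)

    def _blobs(amp_per_cell: float, which: np.ndarray) -> np.ndarray:
        imp = np.zeros((size, size))
        np.add.at(imp, (rows[which], cols[which]), amp_per_cell)
        return ndi.gaussian_filter(imp, sigma=sigma)

    all_cells = np.ones(n, dtype=bool)
    live_flags = rng.random(n) < spec.live_fraction
    n_live = int(live_flags.sum())

    nuclei_clean = _blobs(config.nucleus_amp, all_cells) * disk
    m = config.marker
    marker_clean = (
        m.diffuse_base * spec.marker_scale * disk
        + _blobs(m.per_cell_amp * spec.marker_scale, all_cells) * disk
    )
    live_clean = _blobs(config.live_amp, live_flags) * disk

    bg = config.background.offset + config.background.gradient_slope * xx
    top = float(2**config.bit_depth - 1)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    noise = config.noise

    channels: dict[str, np.ndarray] = {}
    n_clipped = 0
    for name, clean in (
        ("nuclei", nuclei_clean),
        ("marker", marker_clean),
        ("live", live_clean),
    ):
        total = clean + bg
        if noise.shot_scale > 0 or noise.read_sigma > 0:
            std = np.sqrt(noise.shot_scale * total + noise.read_sigma**2)
            total = total + rng.standard_normal(total.shape) * std
        n_clipped += int(np.count_nonzero((total < 0) | (total > top)))
        channels[name] = np.rint(np.clip(total, 0.0, top)).astype(dtype)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} pixels clipped to the {config.bit_depth}-bit range "
            f"in droplet {spec.droplet_id}",
            stacklevel=2,
        )

    true_area_um2 = np.pi * (spec.diameter_um / 2.0) ** 2
    area_px_true = true_area_um2 / px**2
    truth = GroundTruth(
        droplet_id=spec.droplet_id,
        true_equiv_diameter_um=spec.diameter_um,
        true_area_um2=true_area_um2,
        true_cell_count=n,
        true_live_count=n_live,
        true_live_fraction=(n_live / n) if n else float("nan"),
        true_normalized_intensity=m.per_cell_amp * spec.marker_scale / area_px_true,
        true_marker_scale=spec.marker_scale,
        condition=spec.condition,
        dose_uM=spec.dose_uM,
        timepoint_days=spec.timepoint_days,
        patient_id=spec.patient_id,
        replicate=spec.replicate,
    )
    image = MicrotissueImage(
        channels=channels,
        pixel_size_um=px,
        bit_depth=config.bit_depth,
        metadata={
            "droplet_id": spec.droplet_id,
            "condition": spec.condition,
            "dose_uM": spec.dose_uM,
            "timepoint_days": spec.timepoint_days,
            "patient_id": spec.patient_id,
            "replicate": spec.replicate,
        },
    )
    return image, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated image set with its ground truth and manifest tables."""

    images: list
    ground_truth: pd.DataFrame
    manifest: pd.DataFrame


_DESIGN_DEFAULTS = {
    "activated": False,
    "dose_uM": 0.0,
    "timepoint_days": 7.0,
    "patient_id": "P1",
    "replicate": 1,
    "diameter_um": np.nan,
    "live_fraction": np.nan,
}


def _patient_effects(config: GeneratorConfig, patient_ids) -> dict:
    """One (marker, depth) lognormal multiplicative effect per patient,
    drawn from a substream keyed on the patient label so the draw is
    independent of design row order."""
    effects = {}
    for pid in patient_ids:
        key = zlib.crc32(str(pid).encode("utf8"))
        prng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, key]))
        effects[pid] = (
            float(np.exp(prng.normal(0.0, config.patient_sd))),
            float(np.exp(prng.normal(0.0, config.patient_sd))),
        )
    return effects


def generate_cohort(
    config: GeneratorConfig,
    design,
    out_dir=None,
) -> Cohort:
    """Generate one image per requested droplet across a factor design.

    ``design`` is a table (DataFrame or list of dicts) with one row per
    condition cell; required columns ``condition`` and ``n_droplets``,
    optional ``activated``, ``dose_uM``, ``timepoint_days``, ``patient_id``,
    ``replicate``, ``diameter_um`` (overrides the compaction model) and
    ``live_fraction`` (overrides the config).

    Per-patient random effects are drawn once per patient; droplet i is
    rendered from substream ``SeedSequence([config.seed, 0, i])`` so any
    single droplet is reproducible independently.  When ``out_dir`` is
    given, one multi-page TIFF per field of view plus ``manifest.csv`` and
    ``ground_truth.csv`` are written there.
    """
    df = pd.DataFrame(design)
    if df.empty:
        raise ValueError("design must be non-empty")
    for col in ("condition", "n_droplets"):
        if col not in df.columns:
            raise ValueError(f"design is missing required column {col!r}")
    for col, default in _DESIGN_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default

    effects = _patient_effects(config, df["patient_id"].unique())
    d0_global = config.droplet_d0_um
    c = config.compaction

    images: list[MicrotissueImage] = []
    truths: list[dict] = []
    manifest_rows: list[dict] = []
    idx = 0
    for row in df.itertuples(index=False):
        marker_re, depth_re = effects[row.patient_id]
        eff = simulate_dose_effect(config, float(row.dose_uM))
        activated = bool(row.activated)
        if activated:
            fold = 1.0 + (config.marker.activated_fold - 1.0) * eff
            d_inf_base = c.d_inf_control_um + (c.d_inf_activated_um - c.d_inf_control_um) * eff
        else:
            fold = 1.0
            d_inf_base = c.d_inf_control_um
        live_frac = (
            config.live_fraction
            if pd.isna(row.live_fraction)
            else float(row.live_fraction)
        )
        for _ in range(int(row.n_droplets)):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0, idx]))
            d0 = d0_global
            if config.d0_cv > 0:
                d0 = d0_global * float(np.exp(rng.normal(0.0, config.d0_cv)))
            if not pd.isna(row.diameter_um):
                diameter = float(row.diameter_um)
            else:
                depth = (d0 - d_inf_base) * depth_re
                d_inf = float(np.clip(d0 - depth, config.d_inf_floor_um, d0))
                t = float(row.timepoint_days)
                diameter = d_inf + (d0 - d_inf) * np.exp(-t / c.tau_days)
            cc = config.cells_per_droplet
            if cc.dispersion > 0:
                r_nb = cc.mean / cc.dispersion
                p_nb = 1.0 / (1.0 + cc.dispersion)
                n_cells = int(rng.negative_binomial(r_nb, p_nb))
            else:
                n_cells = int(rng.poisson(cc.mean))
            # in a 2D projection nuclei must stay resolvable: truncate the
            # count at ~70% of the hexagonal packing capacity of the disk
            sig = config.nucleus_sigma_px
            r_place = diameter / (2.0 * config.pixel_size_um) - 3.0 * sig
            capacity = int(0.7 * np.pi * r_place**2 / ((4.0 * sig) ** 2 * np.sqrt(3) / 2))
            if n_cells > capacity:
                logger.warning(
                    "droplet %d: truncating cell count %d to packing capacity %d",
                    idx, n_cells, capacity,
                )
                n_cells = capacity
            n_cells = max(1, n_cells)

            droplet_id = f"{row.condition}_{row.patient_id}_r{row.replicate}_{idx:04d}"
            spec = DropletSpec(
                droplet_id=droplet_id,
                diameter_um=diameter,
                n_cells=n_cells,
                marker_scale=fold * marker_re,
                live_fraction=live_frac,
                condition=str(row.condition),
                dose_uM=float(row.dose_uM),
                timepoint_days=float(row.timepoint_days),
                patient_id=str(row.patient_id),
                replicate=int(row.replicate),
            )
            image, truth = render_microtissue(config, spec, rng)
            images.append(image)
            truths.append(truth.to_dict())
            manifest_rows.append(
                {
                    "image_path": f"{droplet_id}.tif",
                    "droplet_id": droplet_id,
                    "condition": str(row.condition),
                    "dose_uM": float(row.dose_uM),
                    "timepoint_days": float(row.timepoint_days),
                    "patient_id": str(row.patient_id),
                    "replicate": int(row.replicate),
                    "channel_map": ";".join(
                        f"{name}:{i}" for i, name in enumerate(CHANNEL_ORDER)
                    ),
                }
            )
            idx += 1

    manifest = pd.DataFrame(manifest_rows)
    if manifest["droplet_id"].duplicated().any():
        dupes = manifest.loc[manifest["droplet_id"].duplicated(), "droplet_id"]
        raise ValueError(f"duplicate droplet identifiers: {sorted(set(dupes))}")
    ground_truth = pd.DataFrame(truths)

    if out_dir is not None:
        import tifffile
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for image, mrow in zip(images, manifest_rows):
            stack = np.stack([image.channels[c] for c in CHANNEL_ORDER])
            tifffile.imwrite(out / mrow["image_path"], stack, photometric="minisblack")
        manifest.to_csv(out / "manifest.csv", index=False)
        ground_truth.to_csv(out / "ground_truth.csv", index=False)
        logger.info("wrote %d images to %s", len(images), out)

    return Cohort(images=images, ground_truth=ground_truth, manifest=manifest)
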