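"""Per-droplet readouts: normalized mean fluorescence per cell, compaction
metrics, secreted-protein normalization, and cohort-table assembly.

The central quantity is the normalized intensity per cell,

    (mean in-mask intensity - 10th-percentile in-mask intensity) / cell count,

computed on the *raw* marker channel: the 10th percentile of each construct
serves as its own background estimate, so the readout is invariant to a
global additive offset, and dividing by the nuclear count puts conditions
with different cellularity on a common per-cell scale.

Compaction is summarized as the spherical volume fold-change ``(d0/d)**3``
where ``d`` is the projected-area equivalent diameter.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .imaging import DropletMask

__all__ = [
    "DropletMeasurement",
    "mean_intensity",
    "background_p10",
    "normalized_intensity_per_cell",
    "volume_fold_change",
    "normalize_secreted_protein",
    "batch_cell_requirement",
    "build_cohort_table",
    "MEASUREMENT_COLUMNS",
]


@dataclass
class DropletMeasurement:
    """One row of the analysis: per-droplet morphology, intensity and
    viability joined to experimental metadata.

    ``normalized_intensity_per_cell`` is NaN when ``cell_count`` is zero
    (flagged ``zero_cells``; the droplet still contributes its area).
    """

    droplet_id: str
    condition: str = ""
    dose_uM: float = 0.0
    timepoint_days: float = 0.0
    patient_id: str = ""
    replicate: int = 1
    area_um2: float = float("nan")
    equiv_diameter_um: float = float("nan")
    circularity: float = float("nan")
    cell_count: int = 0
    mean_intensity: float = float("nan")
    background_p10: float = float("nan")
    normalized_intensity_per_cell: float = float("nan")
    live_fraction: float = float("nan")
    qc_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc_flags"] = ";".join(self.qc_flags)
        return d


MEASUREMENT_COLUMNS = [f.name for f in DropletMeasurement.__dataclass_fields__.values()]  # type: ignore[attr-defined]


def _mask_pixels(image: np.ndarray, mask) -> np.ndarray:
    binary = mask.mask if isinstance(mask, DropletMask) else np.asarray(mask, bool)
    image = np.asarray(image)
    if image.shape != binary.shape:
        raise ValueError("image and mask shapes differ")
    vals = image[binary]
    if vals.size == 0:
        raise ValueError("mask is empty")
    return vals


def mean_intensity(marker: np.ndarray, mask) -> float:
    """Arithmetic mean of the raw marker pixels inside the droplet mask."""
    return float(_mask_pixels(marker, mask).mean())


def background_p10(marker: np.ndarray, mask) -> float:
    """10th percentile of in-mask pixel values — the construct's own
    background estimate (linear-interpolation percentile convention).

    Masks below 10 pixels are flagged with a warning but still evaluated.
    """
    vals = _mask_pixels(marker, mask)
    if vals.size < 10:
        warnings.warn(
            f"background percentile over only {vals.size} pixels", stacklevel=2
        )
    return float(np.percentile(vals, 10))


def normalized_intensity_per_cell(mean: float, p10: float, cell_count: int) -> float:
    """(mean - p10) / cell_count, floored at 0.

    A negative net signal (mean below its own 10th percentile cannot occur
    for a genuine in-mask distribution, only under pathological inputs) is
    floored to 0; callers should flag the droplet.  Zero cells is an error:
    the per-cell value is undefined.
    """
    if cell_count < 1:
        raise ValueError("normalized intensity is undefined for cell_count < 1")
    net = mean - p10
    if net < 0:
        warnings.warn("mean below background percentile; flooring at 0", stacklevel=2)
        net = 0.0
    return net / cell_count


def volume_fold_change(d0_um: float, d_um: float) -> float:
    """(d0/d)**3 — spherical volume fold-change between two equivalent
    diameters (e.g. a 300 μm starting construct vs the compacted droplet)."""
    if d0_um <= 0 or d_um <= 0:
        raise ValueError("diameters must be > 0")
    return (d0_um / d_um) ** 3


def normalize_secreted_protein(
    concentration: float, media_volume: float, cell_count: int
) -> float:
    """Secreted protein per cell: concentration * media_volume / cell_count.

    Units follow the inputs (e.g. ng/mL * mL / cells = ng/cell).
    """
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    if concentration < 0 or media_volume < 0:
        raise ValueError("concentration and media_volume must be non-negative")
    return concentration * media_volume / cell_count


def batch_cell_requirement(collagen_volume_ul: float, seeding_density_per_ml: float) -> float:
    """Cells needed for a collagen batch: volume (μL → mL) × seeding density
    (cells/mL)."""
    if collagen_volume_ul <= 0 or seeding_density_per_ml <= 0:
        raise ValueError("volume and density must be > 0")
    return collagen_volume_ul / 1000.0 * seeding_density_per_ml


def build_cohort_table(
    measurements,
    ground_truth: pd.DataFrame | None = None,
    conditions=None,
) -> pd.DataFrame:
    """Assemble per-droplet measurements into one long-format table.

    One row per droplet; droplet ids must be unique.  When ``ground_truth``
    is provided it is joined on ``droplet_id`` (every measured droplet must
    be present, for recovery tests).  When ``conditions`` declares the
    factor levels, rows with unknown conditions are rejected with their row
    numbers.
    """
    rows = [
        m.to_dict() if isinstance(m, DropletMeasurement) else dict(m)
        for m in measurements
    ]
    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    if table["droplet_id"].duplicated().any():
        dupes = table.loc[table["droplet_id"].duplicated(), "droplet_id"]
        raise ValueError(f"duplicate droplet ids: {sorted(set(dupes))}")
    if conditions is not None and len(table):
        known = set(conditions)
        bad = ~table["condition"].isin(known)
        if bad.any():
            raise ValueError(
                f"unknown condition levels at rows {list(table.index[bad])}: "
                f"{sorted(set(table.loc[bad, 'condition']))}"
            )
    if ground_truth is not None:
        missing = set(table["droplet_id"]) - set(ground_truth["droplet_id"])
        if missing:
            raise ValueError(
                f"droplet ids missing from ground truth: {sorted(missing)}"
            )
        gt = ground_truth.drop(
            columns=[
                c
                for c in ("condition", "dose_uM", "timepoint_days", "patient_id", "replicate")
                if c in ground_truth.columns
            ]
        )
        table = table.merge(gt, on="droplet_id", how="left", validate="1:1")
    return table
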