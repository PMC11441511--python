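"""Scalar phenotype quantification: spreading area, YAP nuclear/cytoplasmic
ratio, RhoA activation normalization and group comparisons.

The mechanosensing readouts are simple per-cell scalars: cell spreading
area from a traced outline polygon, the background-subtracted nuclear over
cytoplasmic mean intensity of YAP (> 1 means nuclear, mechanoactive
localization), and G-LISA RhoA signal normalized by a positive-control
protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

__all__ = [
    "CellOutline",
    "CellIntensityMeasure",
    "RhoAssay",
    "spreading_area",
    "nc_ratio",
    "measure_image",
    "normalize_rho",
    "compare_groups",
    "read_outlines",
]


@dataclass(frozen=True)
class CellOutline:
    """Traced cell boundary: ordered planar vertices in pixels."""

    vertices: tuple
    pixel_size: float = 1.0  # micrometres per pixel

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValueError("an outline needs at least 3 vertices")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class CellIntensityMeasure:
    """Mean intensities (arbitrary units) for one cell."""

    nuclear_mean: float
    cytoplasmic_mean: float
    background_mean: float

    def __post_init__(self):
        for name in ("nuclear_mean", "cytoplasmic_mean", "background_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RhoAssay:
    """G-LISA luminescence readings for one lysate."""

    lysate_signal: float
    positive_control_signal: float


def spreading_area(outline: CellOutline) -> float:
    """Cell spreading area in square micrometres (shoelace on the outline).

    Orientation-independent; vertices are taken in pixel units and scaled
    by ``pixel_size**2``.
    """
    poly = Polygon(outline.vertices)
    return poly.area * outline.pixel_size**2


def nc_ratio(measure: CellIntensityMeasure) -> float:
    """Nuclear-to-cytoplasmic ratio:
    (nuclear - background) / (cytoplasmic - background).

    Undefined (NaN) when the background-subtracted cytoplasmic signal is
    not positive.
    """
    denom = measure.cytoplasmic_mean - measure.background_mean
    if denom <= 0:
        return math.nan
    return (measure.nuclear_mean - measure.background_mean) / denom


def measure_image(image: np.ndarray, nuclear_mask: np.ndarray,
                  cell_mask: np.ndarray,
                  background_mask: Optional[np.ndarray] = None
                  ) -> CellIntensityMeasure:
    """Mean nuclear/cytoplasmic/background intensities from masks.

    The cytoplasm is the cell mask minus the nuclear mask; background
    defaults to everything outside the cell mask.
    """
    nuclear_mask = nuclear_mask.astype(bool)
    cell_mask = cell_mask.astype(bool)
    cyto = cell_mask & ~nuclear_mask
    bg = ~cell_mask if background_mask is None else background_mask.astype(bool)
    for name, mask in (("nuclear", nuclear_mask), ("cytoplasmic", cyto),
                       ("background", bg)):
        if not mask.any():
            raise ValueError(f"{name} mask is empty")
    return CellIntensityMeasure(float(image[nuclear_mask].mean()),
                                float(image[cyto].mean()),
                                float(image[bg].mean()))


def normalize_rho(assay: RhoAssay) -> float:
    """RhoA activation: lysate signal divided by the positive control."""
    if assay.positive_control_signal <= 0:
        raise ValueError("positive control signal must be positive")
    return assay.lysate_signal / assay.positive_control_signal


def compare_groups(a: Sequence[float], b: Sequence[float],
                   test: str = "mann_whitney") -> float:
    """Two-sided p-value comparing two replicate groups.

    ``mann_whitney`` uses the exact null distribution when min(n) <= 8 and
    there are no ties, otherwise the tie-corrected normal approximation;
    ``welch`` is the unequal-variance t-test (Welch ANOVA with two groups).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if test == "mann_whitney":
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) \
            else "asymptotic"
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method=method).pvalue)
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown test {test!r}")


def read_outlines(path, pixel_size: float = 1.0) -> dict:
    """Read outlines from a TSV with columns cell_id, vertex_index, x_px, y_px."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "vertex_index", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    outlines = {}
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("vertex_index")
        outlines[cid] = CellOutline(tuple(zip(grp["x_px"], grp["y_px"])), pixel_size)
    return outlines
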