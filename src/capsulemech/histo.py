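"""Histology quantification: IHC positive-area fractions inside an ROI.

Binarized immunostain masks (positive signal = 255) are quantified as the
fraction of pixel centers inside a polygonal tissue ROI that are positive —
the "analyze particles area sum over a polygon selection" readout.  The same
slide's negative-control fraction is subtracted, and section values can be
normalized to a dermis control to express elastin as a percentage of dermal
levels.  Sections come in four types: one cross section through the capsule
thickness and three tangential cuts (inner, middle, outer surface).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .config import SECTION_TYPES, SampleMeta

__all__ = [
    "HistoSection",
    "roi_mask",
    "area_ratio",
    "corrected_ratio",
    "relative_to_dermis",
    "section_profile",
]


@dataclass(frozen=True)
class HistoSection:
    """One slide: positive mask, negative-control mask, ROI, section type."""

    meta: SampleMeta
    section: str  # cross | in | mid | out
    mask: np.ndarray      # uint8, positive = 255
    neg_mask: np.ndarray  # same shape
    roi: np.ndarray       # (V, 2) vertex list, (x_px, y_px)

    def __post_init__(self):
        if self.section not in SECTION_TYPES:
            raise ValueError(f"section must be one of {SECTION_TYPES}")
        if self.mask.shape != self.neg_mask.shape:
            raise ValueError("mask and neg_mask must have identical dimensions")
        roi = np.asarray(self.roi, dtype=float)
        object.__setattr__(self, "roi", roi)
        if roi.ndim != 2 or roi.shape[1] != 2 or len(roi) < 3:
            raise ValueError("roi must be a (V>=3, 2) vertex list")
        if not shapely.Polygon(roi).is_valid:
            raise ValueError("roi polygon must be simple (non-self-intersecting)")


def roi_mask(roi: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of pixel centers inside (or on the edge of) the ROI.

    Pixel (row r, col c) has center (x=c, y=r).  Containment uses the
    polygon's closed region (boundary points count as inside); for the simple
    polygons required here this coincides with the even-odd rule.
    """
    poly = shapely.Polygon(np.asarray(roi, dtype=float))
    if not poly.is_valid:
        raise ValueError("roi polygon must be simple")
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    shapely.prepare(poly)
    inside = shapely.intersects_xy(poly, cols.ravel(), rows.ravel())
    return inside.reshape(shape)


def area_ratio(mask: np.ndarray, roi: np.ndarray) -> float:
    """Positive-pixel fraction inside the ROI polygon.

    fraction = (# positive pixel centers inside roi) / (# centers inside roi).
    """
    inside = roi_mask(roi, mask.shape)
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("ROI contains no pixel centers (outside the image?)")
    pos = np.asarray(mask) > 0
    return float(np.count_nonzero(pos & inside) / n_inside)


def corrected_ratio(section: HistoSection) -> float:
    """Background-corrected positive fraction: raw minus negative control.

    Clamped at zero (with a warning) when the negative control exceeds the
    raw signal.
    """
    raw = area_ratio(section.mask, section.roi)
    neg = area_ratio(section.neg_mask, section.roi)
    if neg > raw:
        warnings.warn(
            f"negative-control fraction {neg:.4f} exceeds raw {raw:.4f}; "
            "clamping corrected ratio to 0",
            stacklevel=2,
        )
        return 0.0
    return raw - neg


def relative_to_dermis(fraction: float, dermis_fraction: float) -> float:
    """Express a section fraction as a percentage of the dermis control."""
    if dermis_fraction <= 0:
        raise ValueError("dermis reference fraction must be positive")
    return 100.0 * fraction / dermis_fraction


def section_profile(
    sections: list[HistoSection],
    dermis_reference: dict | None = None,
) -> pd.DataFrame:
    """Per-section-type profile for one sample.

    Averages technical replicates within each section type and emits one row
    per type (cross, in, mid, out) with the corrected fraction and, when a
    dermis reference (type -> fraction) is supplied, the dermis-relative
    percentage.
    """
    if not sections:
        raise ValueError("no sections supplied")
    by_type: dict[str, list[float]] = {}
    for sec in sections:
        by_type.setdefault(sec.section, []).append(corrected_ratio(sec))
    rows = []
    for sec_type in SECTION_TYPES:
        if sec_type not in by_type:
            continue
        frac = float(np.mean(by_type[sec_type]))
        row = {"section": sec_type, "corrected_fraction": frac,
               "n_replicates": len(by_type[sec_type])}
        if dermis_reference is not None:
            if sec_type not in dermis_reference:
                raise ValueError(f"missing dermis reference for section {sec_type!r}")
            row["relative_to_dermis_pct"] = relative_to_dermis(
                frac, dermis_reference[sec_type])
        rows.append(row)
    return pd.DataFrame(rows)
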