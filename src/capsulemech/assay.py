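"""Dye-binding elastin assay: calibration, quantification and skin-control QC.

Soluble alpha-elastin released from tissue is complexed with a porphyrin dye
and read as absorbance at 513 nm.  A standards ladder calibrates a linear
absorbance-vs-mass curve (with an intercept absorbing the reagent blank);
sample absorbances are converted to elastin mass and normalized to tissue wet
mass, giving ug elastin per mg tissue.  A pig-skin positive control is
expected near 3.5 ug/mg; the run is accepted only if that control lands
within a relative tolerance of the expected value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import SampleMeta

__all__ = [
    "AssayPlate",
    "Calibration",
    "fit_standards",
    "quantify",
    "qc_skin",
    "SKIN_EXPECTED_RATIO",
]

SKIN_EXPECTED_RATIO = 3.5  # ug elastin / mg tissue


@dataclass(frozen=True)
class AssayPlate:
    """One plate: standards ladder plus normalized-tissue samples.

    standards: list of {"mass_ug": float, "A513": float}
    samples:   list of {"meta": SampleMeta, "A513": float, "tissue_mass_mg": float}
    """

    standards: list = field(default_factory=list)
    samples: list = field(default_factory=list)

    def __post_init__(self):
        masses = [s["mass_ug"] for s in self.standards]
        if len(set(np.round(masses, 9))) < 3:
            raise ValueError("need >= 3 distinct standard mass levels")
        if max(masses) - min(masses) <= 0:
            raise ValueError("standards must span a nonzero mass range")
        for s in self.samples:
            if s["tissue_mass_mg"] <= 0:
                raise ValueError("tissue_mass_mg must be positive")


@dataclass(frozen=True)
class Calibration:
    slope: float      # absorbance per ug
    intercept: float  # absorbance (reagent blank)
    r2: float


def fit_standards(standards: list) -> Calibration:
    """Ordinary least squares A513 = slope * mass_ug + intercept.

    Fails if fewer than 3 distinct mass levels are present or if the fitted
    slope is non-positive (a dead or inverted calibration).
    """
    mass = np.array([s["mass_ug"] for s in standards], dtype=float)
    A = np.array([s["A513"] for s in standards], dtype=float)
    if len(np.unique(np.round(mass, 9))) < 3:
        raise ValueError("need >= 3 distinct standard mass levels")
    res = stats.linregress(mass, A)
    if res.slope <= 0:
        raise ValueError(f"calibration failure: non-positive slope {res.slope:g}")
    return Calibration(slope=float(res.slope), intercept=float(res.intercept),
                       r2=float(res.rvalue**2))


def quantify(sample: dict, calibration: Calibration) -> float:
    """Normalized elastin ratio for one sample, ug elastin / mg tissue.

    mass_ug = (A513 - intercept) / slope, clamped at 0 (with a warning) if
    the absorbance falls below the blank.
    """
    mass_ug = (sample["A513"] - calibration.intercept) / calibration.slope
    if mass_ug < 0:
        warnings.warn(
            f"absorbance {sample['A513']:.4f} below blank; clamping mass to 0",
            stacklevel=2,
        )
        mass_ug = 0.0
    return float(mass_ug / sample["tissue_mass_mg"])


def qc_skin(ratio: float, expected: float = SKIN_EXPECTED_RATIO,
            tol: float = 0.20) -> bool:
    """Skin positive-control check: |ratio - expected| <= tol * expected.

    The acceptance band "around the expected 3.5 ug/mg" is quantified as a
    +/-20% relative tolerance by default (configurable).
    """
    return abs(ratio - expected) <= tol * expected
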