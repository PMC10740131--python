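"""Colorimetric assay calculators and the urea/thiourea force partition.

Covers the bench assays that accompany a binding study:

* bromophenol-blue (BPB) surface hydrophobicity — bound dye mass from the
  depletion of a 200 ug dye aliquot;
* Ellman's sulfhydryl assay — free/total SH content from the 412 nm
  absorbance of the TNB anion via Beer-Lambert;
* linear standard curves with inverse prediction for free-ligand
  quantification;
* the urea/thiourea bond-blocking partition: urea preferentially disrupts
  hydrogen bonds, thiourea hydrophobic contacts, so the free ligand
  released by each agent apportions the noncovalent binding force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._linfit import ols_line
from .exceptions import InvalidInputError, QuenchBindWarning

__all__ = [
    "CalibrationFit",
    "ForcePartition",
    "bpb_bound",
    "sulfhydryl_content",
    "fit_linear_calibration",
    "invert_calibration",
    "partition_forces",
    "TNB_EXTINCTION",
    "DEFAULT_DILUTION_FACTOR",
]

#: Molar extinction coefficient of the TNB anion at 412 nm, M^-1 cm^-1.
TNB_EXTINCTION = 13600.0

#: Default assay dilution: 0.5 mL sample + 4.5 mL buffer + 0.5 mL reagent
#: -> 5.5 mL total / 0.5 mL sample = 11.
DEFAULT_DILUTION_FACTOR = 11.0


@dataclass(frozen=True)
class CalibrationFit:
    """Linear standard curve A = slope * c + intercept."""

    slope: float  # absorbance per (ug/mL)
    intercept: float  # absorbance
    r_squared: float
    conc_range: tuple[float, float]  # (min, max) standard concentration

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class ForcePartition:
    """Free ligand released by each bond-blocking agent, with the call."""

    hydrogen_bond_release: float  # ug free ligand after urea
    hydrophobic_release: float  # ug free ligand after thiourea
    dominant: str  # hydrogen_bond | hydrophobic | comparable


def bpb_bound(a_blank: float, a_sample: float) -> float:
    """Bound bromophenol blue, ug: 200 * (A_blank - A_sample) / A_blank.

    A sample more absorbing than the blank yields a negative value, which
    is returned with a warning rather than clamped.
    """
    if not a_blank > 0:
        raise InvalidInputError("blank absorbance must be positive")
    value = 200.0 * (a_blank - a_sample) / a_blank
    if value < 0:
        warnings.warn(
            f"negative BPB bound ({value:.3g} ug): sample absorbs more than blank",
            QuenchBindWarning,
            stacklevel=2,
        )
    return value


def sulfhydryl_content(
    a412: float,
    extinction: float = TNB_EXTINCTION,
    path_cm: float = 1.0,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    protein_mg_per_ml: float = 5.0,
) -> float:
    """Sulfhydryl content, umol SH per g protein (Ellman's assay).

    Beer-Lambert gives the TNB concentration in the cuvette,
    ``a412 / (extinction * path_cm)`` (M); multiplying by the dilution
    factor refers it back to the undiluted sample, and dividing by the
    protein concentration converts to a specific content:

        umol/g = A412 / (eps * l) * dilution * 1e6 / (mg/mL)

    (1 M = 1e6 umol/L and 1 mg/mL = 1 g/L cancel to the 1e6 factor).
    """
    if a412 < 0:
        raise InvalidInputError("absorbance must be >= 0")
    for name, v in (
        ("extinction", extinction),
        ("path_cm", path_cm),
        ("dilution_factor", dilution_factor),
        ("protein_mg_per_ml", protein_mg_per_ml),
    ):
        if not v > 0:
            raise InvalidInputError(f"{name} must be positive")
    molar = a412 / (extinction * path_cm)
    return molar * dilution_factor * 1e6 / protein_mg_per_ml


def fit_linear_calibration(points) -> CalibrationFit:
    """OLS standard curve from (concentration ug/mL, absorbance) pairs."""
    pts = [(float(c), float(a)) for c, a in points]
    if len(pts) < 3:
        raise InvalidInputError("calibration needs >= 3 standards")
    conc = np.array([c for c, _ in pts])
    absb = np.array([a for _, a in pts])
    if len(np.unique(conc)) < 2:
        raise InvalidInputError("standards need >= 2 distinct concentrations")
    slope, intercept, r2 = ols_line(conc, absb)
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        conc_range=(float(conc.min()), float(conc.max())),
    )


def invert_calibration(fit: CalibrationFit, absorbance: float) -> float:
    """Concentration (ug/mL) from absorbance: (A - intercept) / slope.

    Predictions outside the standards' concentration range are returned
    with an extrapolation warning.
    """
    if abs(fit.slope) < 1e-12:  # numerically flat curve
        raise InvalidInputError("calibration slope is zero: curve not invertible")
    conc = (absorbance - fit.intercept) / fit.slope
    lo, hi = fit.conc_range
    if not (lo <= conc <= hi):
        warnings.warn(
            f"inverse prediction {conc:.4g} ug/mL outside standards range "
            f"[{lo:g}, {hi:g}]",
            QuenchBindWarning,
            stacklevel=2,
        )
    return conc


def partition_forces(
    free_after_urea: float,
    free_after_thiourea: float,
    rel_tol: float = 0.1,
) -> ForcePartition:
    """Apportion the noncovalent binding force from bond-blocking releases.

    ``dominant`` is hydrogen_bond when the urea release exceeds the
    thiourea release by more than ``rel_tol`` relative margin (and vice
    versa); releases within the margin are ``comparable``.
    """
    if free_after_urea < 0 or free_after_thiourea < 0:
        raise InvalidInputError("releases must be >= 0")
    larger = max(free_after_urea, free_after_thiourea)
    if larger == 0:
        dominant = "comparable"
    else:
        margin = abs(free_after_urea - free_after_thiourea) / larger
        if margin <= rel_tol:
            dominant = "comparable"
        elif free_after_urea > free_after_thiourea:
            dominant = "hydrogen_bond"
        else:
            dominant = "hydrophobic"
    return ForcePartition(
        hydrogen_bond_release=float(free_after_urea),
        hydrophobic_release=float(free_after_thiourea),
        dominant=dominant,
    )
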