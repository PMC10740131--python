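"""Far-UV CD secondary-structure deconvolution.

A measured far-UV circular-dichroism spectrum is modelled as a convex
combination of reference basis spectra for four secondary-structure
classes (alpha-helix, beta-sheet, beta-turn, random coil).  Fractions are
estimated by non-negative least squares followed by renormalisation to
the unit simplex, which makes the estimate invariant to the overall scale
of the measured spectrum (so the unknown path-length / concentration
normalisation to mean-residue ellipticity drops out).

The packaged basis is synthetic: each class curve is parameterised as a
sum of Gaussian bands placed at the canonical band positions (helix:
positive ~193 nm, double negative minima at 208 and 222 nm; sheet:
positive ~195 nm, single negative ~218 nm; turn: weak positive ~205 nm;
coil: strong negative ~198 nm).  It reproduces the qualitative shapes,
not any proprietary reference set, so absolute fractions from real
spectra are indicative only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .exceptions import InvalidInputError
from .spectra import Spectrum

__all__ = [
    "STRUCTURE_CLASSES",
    "CdBasis",
    "SecondaryStructure",
    "synthetic_basis",
    "deconvolve",
]

STRUCTURE_CLASSES = ("alpha_helix", "beta_sheet", "beta_turn", "random_coil")

# (amplitude, center nm, width nm) Gaussian bands per class; amplitudes in
# arbitrary mean-residue-ellipticity-like units
_BAND_PARAMS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "alpha_helix": ((65.0, 193.0, 6.0), (-38.0, 208.0, 5.0), (-37.0, 222.0, 5.5)),
    "beta_sheet": ((40.0, 195.0, 9.0), (-22.0, 218.0, 12.0)),
    "beta_turn": ((12.0, 205.0, 12.0), (-6.0, 225.0, 14.0)),
    "random_coil": ((-45.0, 198.0, 10.0), (4.0, 220.0, 16.0)),
}


@dataclass(frozen=True)
class CdBasis:
    """Reference spectra for the four structure classes on a common grid."""

    wavelengths: np.ndarray
    basis_spectra: dict[str, np.ndarray]

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise InvalidInputError("basis grid must be strictly increasing")
        if wl.min() > 190.0 or wl.max() < 240.0:
            raise InvalidInputError("basis grid must cover at least 190-240 nm")
        spectra = {}
        for name in STRUCTURE_CLASSES:
            if name not in self.basis_spectra:
                raise InvalidInputError(f"basis missing class {name!r}")
            vec = np.asarray(self.basis_spectra[name], dtype=float)
            if vec.shape != wl.shape:
                raise InvalidInputError(f"basis vector {name!r} not on the common grid")
            spectra[name] = vec
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "basis_spectra", spectra)

    def matrix(self) -> np.ndarray:
        """Column-stacked basis, shape (n_wavelengths, 4), class order
        :data:`STRUCTURE_CLASSES`."""
        return np.column_stack([self.basis_spectra[c] for c in STRUCTURE_CLASSES])


@dataclass(frozen=True)
class SecondaryStructure:
    """Estimated structure fractions (sum to 1) and the relative residual."""

    fractions: dict[str, float]
    residual_norm: float

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise InvalidInputError("fractions must sum to 1")
        if any(not (0.0 <= v <= 1.0) for v in self.fractions.values()):
            raise InvalidInputError("fractions must lie in [0, 1]")


def synthetic_basis(
    lo: float = 185.0, hi: float = 250.0, step: float = 0.5
) -> CdBasis:
    """Synthetic 4-class CD basis from Gaussian band parameterisations."""
    wl = np.arange(lo, hi + step / 2, step)
    spectra = {
        name: sum(
            amp * np.exp(-0.5 * ((wl - ctr) / wid) ** 2) for amp, ctr, wid in bands
        )
        for name, bands in _BAND_PARAMS.items()
    }
    return CdBasis(wavelengths=wl, basis_spectra=spectra)


def deconvolve(spectrum: Spectrum, basis: CdBasis) -> SecondaryStructure:
    """Estimate secondary-structure fractions from a far-UV CD spectrum.

    The spectrum is linearly interpolated onto the basis grid over the
    overlapping wavelength range (>= 30 nm required); non-negative least
    squares yields class weights which are renormalised to sum to one.
    ``residual_norm`` is ||A w - y|| / ||y|| with the *unnormalised* NNLS
    weights, i.e. the fraction of the signal the basis cannot explain.
    """
    if spectrum.kind != "cd":
        raise InvalidInputError("deconvolve expects a spectrum of kind 'cd'")
    lo = max(spectrum.wavelengths.min(), basis.wavelengths.min())
    hi = min(spectrum.wavelengths.max(), basis.wavelengths.max())
    if hi - lo < 30.0:
        raise InvalidInputError(
            f"spectrum/basis overlap {hi - lo:.1f} nm < 30 nm required"
        )
    mask = (basis.wavelengths >= lo) & (basis.wavelengths <= hi)
    grid = basis.wavelengths[mask]
    y = np.interp(grid, spectrum.wavelengths, spectrum.intensities)
    a = basis.matrix()[mask]
    w, _ = nnls(a, y)
    total = w.sum()
    if total <= 0:
        raise InvalidInputError(
            "NNLS assigned zero weight to every class; spectrum is not "
            "representable by the basis (wrong sign convention?)"
        )
    y_norm = float(np.linalg.norm(y))
    resid = float(np.linalg.norm(a @ w - y)) / y_norm if y_norm > 0 else 0.0
    fractions = {c: float(wi / total) for c, wi in zip(STRUCTURE_CLASSES, w)}
    return SecondaryStructure(fractions=fractions, residual_norm=resid)
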