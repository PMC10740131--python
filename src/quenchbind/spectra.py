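"""Peak location and red/blue shift calls for fluorescence and CD spectra.

Intrinsic emission spectra (excitation ~280 nm) and synchronous scans at
a fixed wavelength offset (delta-lambda = 15 nm isolates tyrosine, 60 nm
tryptophan) report on the polarity of the fluorophore microenvironment:
a move of the emission maximum to longer wavelength (red shift) indicates
increased polarity/solvent exposure, a move to shorter wavelength (blue
shift) increased hydrophobicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, QuenchBindWarning

__all__ = ["Spectrum", "SPECTRUM_KINDS", "find_lambda_max", "classify_shift"]

SPECTRUM_KINDS = ("emission", "synchronous_15", "synchronous_60", "cd")


@dataclass(frozen=True)
class Spectrum:
    """Wavelength grid (nm, strictly increasing) with paired intensities."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    kind: str = "emission"
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or wl.shape != it.shape:
            raise InvalidInputError("wavelengths and intensities must be equal-length 1-D")
        if len(wl) and np.any(np.diff(wl) <= 0):
            raise InvalidInputError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(it)):
            raise InvalidInputError("spectrum values must be finite")
        if self.kind not in SPECTRUM_KINDS:
            raise InvalidInputError(f"kind must be one of {SPECTRUM_KINDS}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return len(self.wavelengths)

    def smoothed(self, window: int) -> "Spectrum":
        """Centred moving-average smoothing (odd window, edges shrink)."""
        if window < 1 or window % 2 == 0:
            raise InvalidInputError("window must be a positive odd integer")
        if window == 1:
            return self
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(self.intensities, pad, mode="edge")
        sm = np.convolve(padded, kernel, mode="valid")
        return Spectrum(self.wavelengths, sm, self.kind, self.label)


def find_lambda_max(
    s: Spectrum,
    window: tuple[float, float] | None = None,
    *,
    refine: bool = True,
) -> float:
    """Wavelength (nm) of the intensity maximum.

    The discrete argmax (ties broken toward shorter wavelength) is refined
    by fitting a parabola through the peak point and its two neighbours,
    which recovers sub-grid peak positions on smooth bands.  A maximum on
    the window boundary is returned unrefined with a warning.  Set
    ``refine=False`` for the raw grid argmax.
    """
    wl, it = s.wavelengths, s.intensities
    if window is not None:
        lo, hi = window
        mask = (wl >= lo) & (wl <= hi)
        wl, it = wl[mask], it[mask]
    if len(wl) < 3:
        raise InvalidInputError("need >= 3 points in the search window")
    i = int(np.argmax(it))  # first occurrence -> shorter wavelength on ties
    if i == 0 or i == len(wl) - 1:
        warnings.warn(
            f"intensity maximum at window boundary ({wl[i]:g} nm); "
            "peak may lie outside the window",
            QuenchBindWarning,
            stacklevel=2,
        )
        return float(wl[i])
    if not refine:
        return float(wl[i])
    # parabola through (x_{i-1},y_{i-1}), (x_i,y_i), (x_{i+1},y_{i+1});
    # vertex formula for a possibly non-uniform grid
    x0, x1, x2 = wl[i - 1 : i + 2]
    y0, y1, y2 = it[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # flat or degenerate: keep raw argmax
        return float(wl[i])
    vertex = -b / (2 * a)
    if not (x0 <= vertex <= x2):
        return float(wl[i])
    return float(vertex)


def classify_shift(lambda_ref: float, lambda_sample: float, tol: float = 0.5) -> str:
    """Call a spectral shift: ``red`` (sample at longer wavelength than the
    reference by more than ``tol`` nm), ``blue`` (shorter), else ``none``."""
    delta = lambda_sample - lambda_ref
    if delta > tol:
        return "red"
    if delta < -tol:
        return "blue"
    return "none"
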