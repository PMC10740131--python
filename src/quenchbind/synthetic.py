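"""Synthetic inputs with known ground truth for every analysis stage.

Each generator inverts the corresponding analysis: quenching titrations
from a chosen Stern-Volmer constant, Ka(T) sets from chosen Van't Hoff
enthalpy/entropy, Gaussian emission bands with controllable peak
positions, CD spectra as basis mixtures, linear calibration standards,
and rigid-body-plus-jitter toy trajectories.  At zero noise every
generator/analysis pair is an exact round trip, which is the backbone of
the test suite.

Noise models: fluorescence intensities get multiplicative lognormal noise
(detector noise scales with signal); CD ellipticities and absorbances get
additive Gaussian noise.  A single integer seed drives an independent
named substream per generator so modules stay decoupled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .cd import CdBasis, STRUCTURE_CLASSES, synthetic_basis
from .exceptions import InvalidInputError
from .quenching import R_GAS, QuenchingSeries
from .spectra import Spectrum
from .trajectory import Frame, Trajectory

__all__ = [
    "PAPER_CONCENTRATIONS_M",
    "GeneratorConfig",
    "gen_quenching_series",
    "gen_vant_hoff_dataset",
    "gen_spectrum",
    "gen_cd_spectrum",
    "gen_calibration_standards",
    "gen_toy_trajectory",
]

#: Default quencher concentration ladder (M): 0 plus five equally-spaced
#: working concentrations up to 3.802e-4 M.
PAPER_CONCENTRATIONS_M = (0.0, 0.760e-4, 1.520e-4, 2.282e-4, 3.041e-4, 3.802e-4)

#: Default incubation temperatures (K).
DEFAULT_TEMPERATURES_K = (293.0, 303.0, 310.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings.

    ``noise_sigma`` is the relative intensity noise (lognormal sigma for
    fluorescence, relative additive sigma for spectra).  The same seed
    always reproduces identical outputs; each generator derives its own
    substream from (seed, generator name).
    """

    seed: int = 0
    noise_sigma: float = 0.0
    concentrations: tuple[float, ...] = PAPER_CONCENTRATIONS_M
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES_K

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream: independent of other generators, reproducible."""
        return np.random.default_rng(
            [int(self.seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())]
        )


def gen_quenching_series(
    ksv_true: float,
    cfg: GeneratorConfig,
    *,
    temperature: float = 293.0,
    f0_true: float = 1000.0,
) -> QuenchingSeries:
    """Quenching titration F = F0 / (1 + Ksv [Q]) with lognormal noise.

    The zero-concentration entry of ``cfg.concentrations`` supplies the
    (noisy) F0 measurement; the positive concentrations form the series.
    """
    if ksv_true < 0:
        raise InvalidInputError("ksv_true must be >= 0")
    rng = cfg.rng("quenching")
    conc = np.asarray(cfg.concentrations, dtype=float)
    pos = conc[conc > 0]
    f_clean = f0_true / (1.0 + ksv_true * pos)
    if cfg.noise_sigma > 0:
        f0 = f0_true * float(np.exp(rng.normal(0.0, cfg.noise_sigma)))
        f = f_clean * np.exp(rng.normal(0.0, cfg.noise_sigma, size=len(pos)))
    else:
        f0, f = f0_true, f_clean
    return QuenchingSeries(
        temperature=temperature, concentrations=pos, f0=f0, f=f
    )


def gen_vant_hoff_dataset(
    delta_h: float, delta_s: float, temperatures=DEFAULT_TEMPERATURES_K
) -> dict[float, float]:
    """Ka(T) = exp(-dH/(R T) + dS/R) with dH in kJ/mol, dS in kJ/(mol K)."""
    out: dict[float, float] = {}
    for t in temperatures:
        t = float(t)
        if t <= 0:
            raise InvalidInputError("temperatures must be positive kelvin")
        out[t] = float(
            np.exp(-delta_h * 1000.0 / (R_GAS * t) + delta_s * 1000.0 / R_GAS)
        )
    return out


def gen_spectrum(
    center: float,
    width: float,
    amplitude: float,
    grid,
    cfg: GeneratorConfig,
    *,
    kind: str = "emission",
    baseline: float = 0.0,
    label: str = "",
) -> Spectrum:
    """Gaussian emission band + additive noise on the given grid (nm)."""
    if width <= 0:
        raise InvalidInputError("width must be positive")
    grid = np.asarray(grid, dtype=float)
    clean = baseline + amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2)
    if cfg.noise_sigma > 0:
        rng = cfg.rng("spectrum")
        clean = clean + rng.normal(
            0.0, cfg.noise_sigma * abs(amplitude), size=len(grid)
        )
    return Spectrum(wavelengths=grid, intensities=clean, kind=kind, label=label)


def gen_cd_spectrum(
    weights: dict[str, float],
    basis: CdBasis | None,
    cfg: GeneratorConfig,
    *,
    label: str = "",
) -> Spectrum:
    """CD spectrum as a weighted basis mixture + additive noise.

    ``weights`` maps structure classes to non-negative fractions summing
    to 1 (missing classes count as 0).
    """
    if basis is None:
        basis = synthetic_basis()
    unknown = set(weights) - set(STRUCTURE_CLASSES)
    if unknown:
        raise InvalidInputError(f"unknown structure classes: {sorted(unknown)}")
    w = np.array([float(weights.get(c, 0.0)) for c in STRUCTURE_CLASSES])
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise InvalidInputError("weights must be non-negative and sum to 1")
    y = basis.matrix() @ w
    if cfg.noise_sigma > 0:
        rng = cfg.rng("cd")
        scale = float(np.max(np.abs(y))) or 1.0
        y = y + rng.normal(0.0, cfg.noise_sigma * scale, size=len(y))
    return Spectrum(
        wavelengths=basis.wavelengths, intensities=y, kind="cd", label=label
    )


def gen_calibration_standards(
    slope: float,
    intercept: float,
    cfg: GeneratorConfig,
    *,
    concentrations=None,
) -> list[tuple[float, float]]:
    """Standard-curve points (conc ug/mL, absorbance) on a line + additive
    noise (sigma interpreted as absolute absorbance units)."""
    if concentrations is None:
        concentrations = np.linspace(0.0, 25.0, 6)
    conc = np.asarray(concentrations, dtype=float)
    absb = slope * conc + intercept
    if cfg.noise_sigma > 0:
        rng = cfg.rng("calibration")
        absb = absb + rng.normal(0.0, cfg.noise_sigma, size=len(conc))
    return list(zip(conc.tolist(), absb.tolist()))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_toy_trajectory(
    n_atoms: int,
    n_frames: int,
    cfg: GeneratorConfig,
    *,
    rigid_motion: bool = True,
    jitter_sigma: float = 0.0,
    box_nm: float = 1.0,
) -> Trajectory:
    """Toy trajectory: a random base structure, optionally rigidly moved
    per frame, with per-atom isotropic Gaussian jitter of ``jitter_sigma``
    nm per coordinate.

    With pure rigid motion all pairwise superposed RMSDs vanish; with
    jitter alone each atom's RMSF converges to jitter_sigma * sqrt(3) over
    many frames.
    """
    if n_atoms < 4:
        raise InvalidInputError("need >= 4 atoms")
    if n_frames < 2:
        raise InvalidInputError("need >= 2 frames")
    if jitter_sigma < 0:
        raise InvalidInputError("jitter_sigma must be >= 0")
    rng = cfg.rng("trajectory")
    base = rng.uniform(0.0, box_nm, size=(n_atoms, 3))
    names = tuple(f"C{i + 1}" for i in range(n_atoms))
    resids = tuple(range(1, n_atoms + 1))
    frames = []
    for _ in range(n_frames):
        xyz = base.copy()
        if rigid_motion:
            rot = _random_rotation(rng)
            trans = rng.uniform(-box_nm, box_nm, size=3)
            xyz = xyz @ rot.T + trans
        if jitter_sigma > 0:
            xyz = xyz + rng.normal(0.0, jitter_sigma, size=xyz.shape)
        frames.append(
            Frame(names, resids, xyz).with_default_annotations()
        )
    return Trajectory(frames=tuple(frames), times=tuple(range(n_frames)))
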