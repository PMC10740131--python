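"""Fluorescence-quenching binding analysis.

Given titrations of a protein's intrinsic fluorescence against increasing
quencher (ligand) concentration at several temperatures, this module
estimates:

* the Stern-Volmer quenching constant ``Ksv`` from the linear plot of
  F0/F versus [Q], and the bimolecular quenching rate constant
  ``Kq = Ksv / tau0`` (tau0 is the unquenched fluorophore lifetime,
  typically ~1e-8 s for tryptophan);
* the apparent binding constant ``Ka`` and number of binding sites ``n``
  from the double-logarithmic plot log10((F0-F)/F) = log10 Ka + n log10 [Q];
* binding enthalpy and entropy from the Van't Hoff regression
  ln Ka = -dH/(R T) + dS/R, and Gibbs energies dG = dH - T dS;
* two standard classifications: the quenching mechanism (static, dynamic
  or combined, from the temperature trend of Ksv and whether Kq exceeds
  the diffusion-controlled collision limit of 2e10 M^-1 s^-1), and the
  dominant noncovalent driving force from the signs of dH and dS
  (Ross-Subramanian convention).

The functional API (``fit_stern_volmer`` & friends) operates on single
series; :class:`QuenchingBindingModel` bundles the full multi-temperature
workflow and its :meth:`~QuenchingBindingModel.fit` returns a
:class:`QuenchingBindingResults` carrying all estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linfit import ols_line
from .exceptions import InvalidInputError, QuenchBindWarning

__all__ = [
    "R_GAS",
    "DIFFUSION_LIMIT",
    "QuenchingSeries",
    "SternVolmerFit",
    "DoubleLogFit",
    "ThermoResult",
    "MechanismCall",
    "fit_stern_volmer",
    "fit_double_log",
    "fit_vant_hoff",
    "compute_gibbs",
    "classify_quenching",
    "classify_forces",
    "QuenchingBindingModel",
    "QuenchingBindingResults",
]

#: Molar gas constant, J/(mol K).
R_GAS = 8.314

#: Maximum diffusion-controlled collision rate constant, M^-1 s^-1.  Kq above
#: this value cannot arise from collisional (dynamic) quenching alone and
#: indicates ground-state complex formation.
DIFFUSION_LIMIT = 2.0e10

#: Default unquenched fluorophore lifetime, seconds (order of magnitude of
#: tryptophan fluorescence decay).
DEFAULT_TAU0 = 1.0e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuenchingSeries:
    """One temperature's quenching titration.

    Parameters
    ----------
    temperature : float
        Kelvin.
    concentrations : sequence of float
        Quencher molar concentrations (M), strictly increasing, all >= 0.
    f0 : float
        Fluorescence intensity without quencher (arbitrary units).
    f : sequence of float
        Intensities paired with ``concentrations`` (same units as ``f0``).
    """

    temperature: float
    concentrations: tuple[float, ...]
    f0: float
    f: tuple[float, ...]

    def __init__(self, temperature, concentrations, f0, f):
        conc = tuple(float(c) for c in concentrations)
        fs = tuple(float(v) for v in f)
        if len(conc) != len(fs):
            raise InvalidInputError(
                f"{len(conc)} concentrations but {len(fs)} intensities"
            )
        if any(c < 0 for c in conc):
            raise InvalidInputError("concentrations must be >= 0")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise InvalidInputError("concentrations must be strictly increasing")
        if not f0 > 0:
            raise InvalidInputError("f0 must be positive")
        if any(v <= 0 for v in fs):
            raise InvalidInputError("all intensities must be positive")
        if not temperature > 0:
            raise InvalidInputError("temperature must be positive kelvin")
        object.__setattr__(self, "temperature", float(temperature))
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "f0", float(f0))
        object.__setattr__(self, "f", fs)

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class SternVolmerFit:
    """Stern-Volmer regression result at one temperature."""

    ksv: float  # M^-1
    kq: float  # M^-1 s^-1
    tau0: float  # s
    r_squared: float
    temperature: float  # K
    intercept: float = 1.0  # fitted F0/F intercept (1.0 when anchored)

    def __post_init__(self):
        if not math.isclose(self.kq * self.tau0, self.ksv, rel_tol=1e-12, abs_tol=0.0):
            raise InvalidInputError("kq must equal ksv / tau0")


@dataclass(frozen=True)
class DoubleLogFit:
    """Double-logarithmic regression result: binding constant and site count."""

    ka: float  # M^-1
    n: float  # binding sites, unitless
    r_squared: float
    temperature: float  # K

    def __post_init__(self):
        if not self.ka > 0:
            raise InvalidInputError("ka must be positive")


@dataclass(frozen=True)
class ThermoResult:
    """Van't Hoff thermodynamics with per-temperature Gibbs energies.

    ``delta_h`` in kJ/mol, ``delta_s`` in kJ/(mol K), each dG in kJ/mol.
    """

    delta_h: float
    delta_s: float
    delta_g_by_temperature: dict[float, float]
    force_label: str
    r_squared: float = float("nan")
    r_gas: float = R_GAS

    def __post_init__(self):
        for t, dg in self.delta_g_by_temperature.items():
            expected = self.delta_h - t * self.delta_s
            if abs(dg - expected) > 1e-6:
                raise InvalidInputError(
                    f"dG({t} K) = {dg} violates dG = dH - T dS (expected {expected})"
                )


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism classification."""

    label: str  # static | dynamic | combined | indeterminate
    ksv_trend: str  # increasing | decreasing | flat
    kq_exceeds_diffusion_limit: bool
    diffusion_limit: float = DIFFUSION_LIMIT

    def __post_init__(self):
        combined = self.ksv_trend == "increasing" and self.kq_exceeds_diffusion_limit
        if (self.label == "combined") != combined:
            raise InvalidInputError(
                "label 'combined' requires increasing ksv and kq above the limit"
            )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fit_stern_volmer(
    series: QuenchingSeries,
    tau0: float = DEFAULT_TAU0,
    *,
    anchored: bool = False,
) -> SternVolmerFit:
    """Fit the Stern-Volmer relation F0/F = 1 + Ksv [Q].

    By default the intercept is a free parameter (slope of F0/F vs [Q]);
    with ``anchored=True`` the line is forced through F0/F = 1 and Ksv is
    the through-origin slope of (F0/F - 1) vs [Q].  ``kq = ksv / tau0``.
    """
    if len(series) < 3:
        raise InvalidInputError("Stern-Volmer fit needs at least 3 points")
    if not tau0 > 0:
        raise InvalidInputError("tau0 must be positive")
    q = np.asarray(series.concentrations)
    ratio = series.f0 / np.asarray(series.f)
    if anchored:
        slope, _, r2 = ols_line(q, ratio - 1.0, through_origin=True)
        intercept = 1.0
    else:
        slope, intercept, r2 = ols_line(q, ratio)
    return SternVolmerFit(
        ksv=slope,
        kq=slope / tau0,
        tau0=tau0,
        r_squared=r2,
        temperature=series.temperature,
        intercept=intercept,
    )


def fit_double_log(series: QuenchingSeries) -> DoubleLogFit:
    """Fit log10((F0-F)/F) = log10 Ka + n log10 [Q].

    Points with F >= F0 (no quenching: the log argument is undefined) are
    rejected with a warning; at least 3 points must survive.
    """
    q = np.asarray(series.concentrations)
    f = np.asarray(series.f)
    keep = (f < series.f0) & (q > 0)
    n_rejected = int(len(q) - keep.sum())
    if n_rejected:
        warnings.warn(
            f"double-log fit: rejected {n_rejected} point(s) with F >= F0 or [Q] == 0",
            QuenchBindWarning,
            stacklevel=2,
        )
    if int(keep.sum()) < 3:
        raise InvalidInputError(
            "double-log fit needs at least 3 points with F < F0 and [Q] > 0"
        )
    x = np.log10(q[keep])
    y = np.log10((series.f0 - f[keep]) / f[keep])
    slope, intercept, r2 = ols_line(x, y)
    return DoubleLogFit(
        ka=10.0**intercept, n=slope, r_squared=r2, temperature=series.temperature
    )


def fit_vant_hoff(
    ka_by_temperature: dict[float, float],
) -> tuple[float, float, float]:
    """Van't Hoff regression of ln Ka on 1/T.

    Returns ``(delta_h, delta_s, r_squared)`` with dH in kJ/mol and dS in
    kJ/(mol K): dH = -slope * R, dS = intercept * R.
    """
    temps = [float(t) for t in ka_by_temperature]
    kas = [float(k) for k in ka_by_temperature.values()]
    if len(temps) < 2:
        raise InvalidInputError("Van't Hoff fit needs >= 2 temperatures")
    if len(set(temps)) != len(temps):
        raise InvalidInputError("duplicate temperatures")
    if any(t <= 0 for t in temps):
        raise InvalidInputError("temperatures must be positive kelvin")
    if any(k <= 0 for k in kas):
        raise InvalidInputError("all Ka must be positive")
    x = 1.0 / np.asarray(temps)
    y = np.log(np.asarray(kas))
    if len(temps) == 2:
        # exact two-point line; polyfit would warn about conditioning
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        slope, intercept, r2 = ols_line(x, y)
    delta_h = -slope * R_GAS / 1000.0
    delta_s = intercept * R_GAS / 1000.0
    return float(delta_h), float(delta_s), float(r2)


def compute_gibbs(
    delta_h: float, delta_s: float, temperatures
) -> dict[float, float]:
    """Gibbs energies dG = dH - T dS (kJ/mol) at each temperature."""
    out: dict[float, float] = {}
    for t in temperatures:
        t = float(t)
        if t <= 0:
            raise InvalidInputError("temperatures must be positive kelvin")
        out[t] = delta_h - t * delta_s
    return out


def _ksv_trend(ksv: list[float], rel_tol: float = 1e-6) -> str:
    """Strict monotonicity of Ksv over temperature; near-equal consecutive
    values (relative 1e-6) count as ties -> flat, as does any mixed trend."""
    diffs = []
    for a, b in zip(ksv, ksv[1:]):
        scale = max(abs(a), abs(b), 1e-300)
        if abs(b - a) <= rel_tol * scale:
            diffs.append(0)
        else:
            diffs.append(1 if b > a else -1)
    if all(d > 0 for d in diffs):
        return "increasing"
    if all(d < 0 for d in diffs):
        return "decreasing"
    return "flat"


def classify_quenching(
    fits: list[SternVolmerFit],
    diffusion_limit: float = DIFFUSION_LIMIT,
) -> MechanismCall:
    """Classify the quenching mechanism from multi-temperature fits.

    Ksv rising with temperature signals collisional (dynamic) quenching;
    Kq above the diffusion-controlled limit signals static complex
    formation; both together -> combined quenching.
    """
    if len(fits) < 2:
        raise InvalidInputError("need fits at >= 2 temperatures")
    fits = sorted(fits, key=lambda f: f.temperature)
    if len({f.temperature for f in fits}) != len(fits):
        raise InvalidInputError("duplicate temperatures among fits")
    trend = _ksv_trend([f.ksv for f in fits])
    exceeds = all(f.kq > diffusion_limit for f in fits)
    if trend == "increasing":
        label = "combined" if exceeds else "dynamic"
    elif trend == "decreasing" and exceeds:
        label = "static"
    else:
        label = "indeterminate"
    return MechanismCall(
        label=label,
        ksv_trend=trend,
        kq_exceeds_diffusion_limit=exceeds,
        diffusion_limit=diffusion_limit,
    )


def classify_forces(delta_h: float, delta_s: float, tol: float = 1.0) -> str:
    """Dominant noncovalent driving force from the signs of dH and dS.

    Ross-Subramanian convention: dH < 0 and dS < 0 -> hydrogen bonding /
    van der Waals; dH > 0 and dS > 0 -> hydrophobic; dH ~ 0 (within
    ``tol`` kJ/mol) or (dH < 0, dS > 0) -> electrostatic.  Combinations
    outside the convention fall back to electrostatic.
    """
    if delta_h < -tol and delta_s < 0:
        return "hydrogen_bond_vdw"
    if delta_h > tol and delta_s > 0:
        return "hydrophobic"
    return "electrostatic"


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class QuenchingBindingModel:
    """Full multi-temperature quenching-binding analysis.

    Parameters
    ----------
    series : sequence of QuenchingSeries
        One titration per temperature (>= 2 temperatures for the
        thermodynamic stage; a single series still yields the per-series
        fits).
    tau0 : float
        Unquenched fluorophore lifetime in seconds.
    diffusion_limit : float
        Threshold for the Kq-based static-quenching call, M^-1 s^-1.
    anchored : bool
        Fix the Stern-Volmer intercept at 1 instead of fitting it.
    force_tol : float
        |dH| band (kJ/mol) treated as "dH ~ 0" in the force classification.

    Examples
    --------
    >>> from quenchbind import synthetic
    >>> cfg = synthetic.GeneratorConfig(seed=0, noise_sigma=0.0)
    >>> series = [synthetic.gen_quenching_series(750.0, cfg, temperature=293.0)]
    >>> res = QuenchingBindingModel(series).fit()
    >>> round(res.stern_volmer[0].ksv)
    750
    """

    def __init__(
        self,
        series,
        tau0: float = DEFAULT_TAU0,
        diffusion_limit: float = DIFFUSION_LIMIT,
        *,
        anchored: bool = False,
        force_tol: float = 1.0,
    ):
        series = list(series)
        if not series:
            raise InvalidInputError("need at least one quenching series")
        temps = [s.temperature for s in series]
        if len(set(temps)) != len(temps):
            raise InvalidInputError("duplicate temperatures among series")
        self.series = sorted(series, key=lambda s: s.temperature)
        self.tau0 = float(tau0)
        self.diffusion_limit = float(diffusion_limit)
        self.anchored = bool(anchored)
        self.force_tol = float(force_tol)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, tau0: float = DEFAULT_TAU0, **kwargs
    ) -> "QuenchingBindingModel":
        """Build from a long-format table with columns
        ``temperature_K, conc_M, intensity``; the conc_M == 0 row of each
        temperature defines F0."""
        required = {"temperature_K", "conc_M", "intensity"}
        if not required.issubset(df.columns):
            raise InvalidInputError(f"dataframe needs columns {sorted(required)}")
        series = []
        for temp, grp in df.groupby("temperature_K"):
            grp = grp.sort_values("conc_M")
            zero = grp[grp["conc_M"] == 0.0]
            if len(zero) != 1:
                raise InvalidInputError(
                    f"temperature {temp}: exactly one conc_M == 0 row must define F0"
                )
            rest = grp[grp["conc_M"] > 0.0]
            series.append(
                QuenchingSeries(
                    temperature=float(temp),
                    concentrations=rest["conc_M"].to_numpy(),
                    f0=float(zero["intensity"].iloc[0]),
                    f=rest["intensity"].to_numpy(),
                )
            )
        return cls(series, tau0=tau0, **kwargs)

    def fit(self) -> "QuenchingBindingResults":
        sv = [
            fit_stern_volmer(s, self.tau0, anchored=self.anchored)
            for s in self.series
        ]
        dl = [fit_double_log(s) for s in self.series]
        thermo = mechanism = None
        if len(self.series) >= 2:
            mechanism = classify_quenching(sv, self.diffusion_limit)
            ka_map = {f.temperature: f.ka for f in dl}
            dh, ds, r2 = fit_vant_hoff(ka_map)
            dg = compute_gibbs(dh, ds, list(ka_map))
            thermo = ThermoResult(
                delta_h=dh,
                delta_s=ds,
                delta_g_by_temperature=dg,
                force_label=classify_forces(dh, ds, self.force_tol),
                r_squared=r2,
            )
        return QuenchingBindingResults(self, sv, dl, thermo, mechanism)


@dataclass
class QuenchingBindingResults:
    """Estimates and diagnostics from :meth:`QuenchingBindingModel.fit`."""

    model: QuenchingBindingModel
    stern_volmer: list[SternVolmerFit]
    double_log: list[DoubleLogFit]
    thermo: ThermoResult | None = None
    mechanism: MechanismCall | None = None

    @property
    def temperatures(self) -> list[float]:
        return [f.temperature for f in self.stern_volmer]

    def to_frame(self) -> pd.DataFrame:
        """Constants table with one column per temperature (the customary
        layout: Ksv, Kq, R1^2, Ka, n, R2^2, dH, dS, dG rows)."""
        cols = {}
        for sv, dl in zip(self.stern_volmer, self.double_log):
            col = {
                "Ksv (M^-1)": sv.ksv,
                "Kq (M^-1 s^-1)": sv.kq,
                "R1^2": sv.r_squared,
                "Ka (M^-1)": dl.ka,
                "n": dl.n,
                "R2^2": dl.r_squared,
            }
            if self.thermo is not None:
                col["dH (kJ/mol)"] = self.thermo.delta_h
                col["dS (kJ/(mol K))"] = self.thermo.delta_s
                col["dG (kJ/mol)"] = self.thermo.delta_g_by_temperature[
                    sv.temperature
                ]
            cols[f"{sv.temperature:g} K"] = col
        return pd.DataFrame(cols)

    def summary(self) -> str:
        lines = ["Quenching binding analysis", "=" * 60]
        lines.append(self.to_frame().to_string(float_format=lambda v: f"{v:.4g}"))
        if self.mechanism is not None:
            m = self.mechanism
            lines.append("")
            lines.append(
                f"Mechanism: {m.label} (Ksv trend {m.ksv_trend}; Kq "
                f"{'exceeds' if m.kq_exceeds_diffusion_limit else 'below'} "
                f"diffusion limit {m.diffusion_limit:.2e} M^-1 s^-1)"
            )
        if self.thermo is not None:
            lines.append(
                f"Driving force: {self.thermo.force_label} "
                f"(dH = {self.thermo.delta_h:.3f} kJ/mol, "
                f"dS = {self.thermo.delta_s:.4f} kJ/(mol K), "
                f"Van't Hoff r^2 = {self.thermo.r_squared:.4f})"
            )
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable report of every fitted quantity."""
        rep = {
            "stern_volmer": [
                {
                    "temperature_K": f.temperature,
                    "ksv_M^-1": f.ksv,
                    "kq_M^-1s^-1": f.kq,
                    "tau0_s": f.tau0,
                    "intercept": f.intercept,
                    "r_squared": f.r_squared,
                }
                for f in self.stern_volmer
            ],
            "double_log": [
                {
                    "temperature_K": f.temperature,
                    "ka_M^-1": f.ka,
                    "n": f.n,
                    "r_squared": f.r_squared,
                }
                for f in self.double_log
            ],
        }
        if self.thermo is not None:
            rep["thermodynamics"] = {
                "delta_h_kJ_mol": self.thermo.delta_h,
                "delta_s_kJ_mol_K": self.thermo.delta_s,
                "r_squared": self.thermo.r_squared,
                "delta_g_kJ_mol": {
                    f"{t:g}": dg
                    for t, dg in self.thermo.delta_g_by_temperature.items()
                },
                "force_label": self.thermo.force_label,
            }
        if self.mechanism is not None:
            rep["mechanism"] = {
                "label": self.mechanism.label,
                "ksv_trend": self.mechanism.ksv_trend,
                "kq_exceeds_diffusion_limit": self.mechanism.kq_exceeds_diffusion_limit,
                "diffusion_limit_M^-1s^-1": self.mechanism.diffusion_limit,
            }
        return rep

    def plot_stern_volmer(self, ax=None):
        """Stern-Volmer plot (F0/F vs [Q]) with fitted lines, one per
        temperature."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s, f in zip(self.model.series, self.stern_volmer):
            q = np.asarray(s.concentrations)
            ax.plot(q, s.f0 / np.asarray(s.f), "o", label=f"{s.temperature:g} K")
            ax.plot(q, f.intercept + f.ksv * q, "-", color=ax.lines[-1].get_color())
        ax.set_xlabel("[Q] (M)")
        ax.set_ylabel("F0 / F")
        ax.legend()
        return ax
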