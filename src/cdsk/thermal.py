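"""Two-state thermal denaturation analysis of CD melting curves.

The native ⇌ denatured equilibrium with melting temperature T_m, van't
Hoff enthalpy ΔH_m and (fixed) heat-capacity change ΔC_p gives, via the
Gibbs–Helmholtz relation, the observed CD signal at temperature T:

    CD(T) = [ (A_N + m_N·T) + (A_D + m_D·T) · K(T) ] / [ 1 + K(T) ]
    K(T)  = exp(y) · (T/T_m)^(ΔC_p/R)
    y     = (1/R) · [ (T_m·ΔC_p − ΔH_m)/T + ΔH_m/T_m − ΔC_p ]

A_N, A_D are the native/denatured baseline amplitudes extrapolated to
T = 0 (Kelvin, since the baselines are linear in the absolute
temperature used throughout) and m_N, m_D their slopes.  The unfolding
free energy at any temperature is

    ΔG(T) = ΔH_m·(1 − T/T_m) − ΔC_p·[(T_m − T) + T·ln(T/T_m)]

which is identically −R·T·ln K(T); ΔG(T_m) = 0 exactly.  Six parameters
(A_N, m_N, A_D, m_D, T_m, ΔH_m) are fitted by nonlinear least squares
with ΔC_p held fixed; for small globular proteins ΔC_p can be estimated
as roughly 50 J/(mol·K) per residue.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import lmfit
import numpy as np

from .errors import (
    ConvergenceWarningError,
    CoverageError,
    InputFormatError,
    InsufficientDataError,
)
from .spectra import _NUMBER_RE, _read_text

#: gas constant, J/(mol·K)
R = 8.314

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class MeltingCurve:
    """CD signal vs. absolute temperature (K), strictly increasing."""

    temperatures: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise InputFormatError("temperatures and values must be 1-D, equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            order = np.argsort(t)
            t, v = t[order], v[order]
            if np.any(np.diff(t) <= 0):
                raise InputFormatError("duplicate temperatures in melting curve")
        if t.size < 10:
            raise InsufficientDataError("melting curve needs at least 10 points")
        if t[-1] - t[0] < 20.0:
            raise InsufficientDataError("melting curve must span at least 20 K")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_celsius(cls, temps_c, values) -> "MeltingCurve":
        return cls(np.asarray(temps_c, dtype=float) + CELSIUS_OFFSET, values)

    def crop(self, tmin: float, tmax: float) -> "MeltingCurve":
        m = (self.temperatures >= tmin) & (self.temperatures <= tmax)
        if m.sum() < 10:
            raise CoverageError("fewer than 10 points in the requested temperature range")
        return MeltingCurve(self.temperatures[m], self.values[m])


def read_melting_curve(source, unit: str = "C") -> MeltingCurve:
    """Read a two-column temperature/CD text file (°C by default)."""
    text = _read_text(source)
    rows = []
    for line in text.splitlines():
        cells = [c for c in re.split(r"[,\s;]+", line.strip()) if c]
        if len(cells) >= 2 and all(_NUMBER_RE.match(c) for c in cells[:2]):
            rows.append((float(cells[0]), float(cells[1])))
    if not rows:
        raise InsufficientDataError("no numeric rows found")
    arr = np.asarray(rows, dtype=float)
    if unit.upper().startswith("C"):
        return MeltingCurve.from_celsius(arr[:, 0], arr[:, 1])
    return MeltingCurve(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class ThermalParams:
    A_N: float  # native baseline amplitude at 0 K (CD units)
    m_N: float  # native baseline slope (CD units / K)
    A_D: float  # denatured baseline amplitude at 0 K
    m_D: float  # denatured baseline slope
    T_m: float  # melting temperature, K
    dH_m: float  # unfolding enthalpy at T_m, J/mol
    dC_p: float = 0.0  # heat-capacity change, J/(mol·K); fixed, not fitted


def _log_K(T: np.ndarray, p: ThermalParams) -> np.ndarray:
    """ln K(T), computed in log space to avoid overflow in exp(y)."""
    y = ((p.T_m * p.dC_p - p.dH_m) / T + p.dH_m / p.T_m - p.dC_p) / R
    return y + (p.dC_p / R) * np.log(T / p.T_m)


def model_cd(T, p: ThermalParams):
    """Evaluate the two-state melting model at temperature(s) T (K)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise InputFormatError("absolute temperature must be positive")
    logK = _log_K(T, p)
    # denatured fraction = K/(1+K) = logistic(ln K), overflow-safe
    fD = np.where(
        logK >= 0,
        1.0 / (1.0 + np.exp(-logK)),
        np.exp(logK) / (1.0 + np.exp(logK)),
    )
    native = p.A_N + p.m_N * T
    denat = p.A_D + p.m_D * T
    out = native * (1.0 - fD) + denat * fD
    return out if out.ndim else float(out)


def delta_g(T, p: ThermalParams):
    """Unfolding free energy ΔG(T) in J/mol (Gibbs–Helmholtz)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or p.T_m <= 0:
        raise InputFormatError("temperatures must be positive")
    out = p.dH_m * (1.0 - T / p.T_m) - p.dC_p * ((p.T_m - T) + T * np.log(T / p.T_m))
    return out if out.ndim else float(out)


def estimate_dcp(n_residues: int) -> float:
    """Rough ΔC_p for a small globular protein: ~50 J/(mol·K) per residue."""
    if n_residues <= 0:
        raise InputFormatError("residue count must be positive")
    return 50.0 * n_residues


@dataclass(frozen=True)
class ThermalFitResult:
    params: ThermalParams
    stderr: dict[str, float | None]
    fitted: np.ndarray  # model values on the fitted temperature grid
    temperatures: np.ndarray
    residual_rmsd: float
    dG_25C: float  # J/mol at 298.15 K
    dG_37C: float  # J/mol at 310.15 K
    converged: bool
    transition_detected: bool


def _initial_guess(t: np.ndarray, v: np.ndarray, dcp: float) -> ThermalParams:
    """Automatic initialization from baseline lines and a van't Hoff slope."""
    n = t.size
    k = max(3, n // 5)
    lo_fit = np.polyfit(t[:k], v[:k], 1)  # native end
    hi_fit = np.polyfit(t[-k:], v[-k:], 1)  # denatured end
    m_N, A_N = lo_fit[0], lo_fit[1]
    m_D, A_D = hi_fit[0], hi_fit[1]
    base_n = np.polyval(lo_fit, t)
    base_d = np.polyval(hi_fit, t)
    denom = base_d - base_n
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(np.abs(denom) > 1e-30, (v - base_n) / denom, 0.5)
    frac = np.clip(frac, 1e-3, 1 - 1e-3)
    # T_m: first crossing of the half-unfolded point
    cross = np.flatnonzero(np.diff(np.sign(frac - 0.5)))
    if cross.size:
        i = cross[0]
        f0, f1 = frac[i] - 0.5, frac[i + 1] - 0.5
        T_m = t[i] + (t[i + 1] - t[i]) * (-f0) / (f1 - f0)
    else:
        T_m = float(t[n // 2])
    # van't Hoff slope of ln K over the transition third
    mask = (frac > 0.15) & (frac < 0.85)
    if mask.sum() >= 3:
        lnK = np.log(frac[mask] / (1 - frac[mask]))
        slope = np.polyfit(1.0 / t[mask], lnK, 1)[0]
        dH = max(50e3, -slope * R)
    else:
        dH = 300e3
    return ThermalParams(A_N, m_N, A_D, m_D, float(T_m), float(dH), dcp)


def fit_melting(
    curve: MeltingCurve,
    dcp: float = 0.0,
    trange: tuple[float, float] | None = None,
    init: ThermalParams | dict | None = None,
) -> ThermalFitResult:
    """Fit the two-state model to a melting curve (ΔC_p fixed, not fitted).

    ``init`` accepts a full ThermalParams or a dict overriding selected
    automatic starting values (e.g. ``{"T_m": 338.0}``), mirroring
    manual re-fitting of a stubborn transition.  A curve without a
    detectable sigmoidal transition is still fitted best-effort but
    flagged unconverged.
    """
    c = curve if trange is None else curve.crop(*trange)
    t, v = c.temperatures, c.values

    guess = _initial_guess(t, v, dcp)
    if isinstance(init, ThermalParams):
        guess = ThermalParams(
            init.A_N, init.m_N, init.A_D, init.m_D, init.T_m, init.dH_m, dcp
        )
    elif isinstance(init, dict):
        d = {f: getattr(guess, f) for f in ("A_N", "m_N", "A_D", "m_D", "T_m", "dH_m")}
        d.update(init)
        guess = ThermalParams(dC_p=dcp, **d)

    # transition detection: gap between the extrapolated native and
    # denatured baselines at mid-range, against baseline noise (with a
    # small relative floor so an exact straight line never "melts")
    k = max(3, t.size // 5)
    noise = float(
        np.std(np.concatenate([
            v[:k] - np.polyval(np.polyfit(t[:k], v[:k], 1), t[:k]),
            v[-k:] - np.polyval(np.polyfit(t[-k:], v[-k:], 1), t[-k:]),
        ]))
    )
    t_mid = float(np.median(t))
    auto = _initial_guess(t, v, dcp)
    gap = abs((auto.A_D + auto.m_D * t_mid) - (auto.A_N + auto.m_N * t_mid))
    floor = 1e-6 * max(float(np.ptp(v)), 1.0)
    transition = bool(gap >= 3.0 * noise + floor)

    pars = lmfit.Parameters()
    pars.add("A_N", value=guess.A_N)
    pars.add("m_N", value=guess.m_N)
    pars.add("A_D", value=guess.A_D)
    pars.add("m_D", value=guess.m_D)
    pars.add("T_m", value=guess.T_m, min=t[0] - 20.0, max=t[-1] + 20.0)
    pars.add("dH_m", value=guess.dH_m, min=1.0)

    def residual(p):
        tp = ThermalParams(
            p["A_N"].value, p["m_N"].value, p["A_D"].value, p["m_D"].value,
            p["T_m"].value, p["dH_m"].value, dcp,
        )
        return model_cd(t, tp) - v

    out = lmfit.minimize(residual, pars, method="leastsq")
    pv = out.params
    params = ThermalParams(
        pv["A_N"].value, pv["m_N"].value, pv["A_D"].value, pv["m_D"].value,
        pv["T_m"].value, pv["dH_m"].value, dcp,
    )
    stderr = {name: (pv[name].stderr if pv[name].stderr is not None else None)
              for name in ("A_N", "m_N", "A_D", "m_D", "T_m", "dH_m")}
    fitted = model_cd(t, params)
    rmsd = float(np.sqrt(np.mean((fitted - v) ** 2)))
    converged = bool(out.success) and transition
    return ThermalFitResult(
        params=params,
        stderr=stderr,
        fitted=fitted,
        temperatures=t,
        residual_rmsd=rmsd,
        dG_25C=float(delta_g(25.0 + CELSIUS_OFFSET, params)),
        dG_37C=float(delta_g(37.0 + CELSIUS_OFFSET, params)),
        converged=converged,
        transition_detected=transition,
    )
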