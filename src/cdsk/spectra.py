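"""Reading, normalizing and comparing far-UV CD spectra.

A :class:`Spectrum` is a wavelength grid plus CD values in one of three
units: molar CD extinction difference Δε (M⁻¹cm⁻¹, per mean residue),
mean residue ellipticity [θ] (deg·cm²·dmol⁻¹), or raw instrument
ellipticity (mdeg).  All deconvolution happens in Δε; the conversions are

    [θ] = 3298 · Δε
    Δε  = θ_mdeg / (32980 · c · l · N_res)

with concentration ``c`` in mol/L, pathlength ``l`` in cm and ``N_res``
the number of peptide residues.

Preprocessing before deconvolution mirrors routine CD practice: a 2 nm
moving-average smoothing on the native grid, then bin-averaging onto a
1 nm grid.  Fit quality is reported two ways: RMSD against the *raw*
spectrum (sensitive to noise) and NRMSD against the *smoothed* spectrum
(reflecting how well the model explains the underlying signal).
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DataError,
    InputFormatError,
    InsufficientDataError,
    NormalizationError,
    ParseError,
    UpsamplingError,
)

#: [θ] per Δε (deg·cm²·dmol⁻¹ per M⁻¹cm⁻¹)
MRE_PER_DELTA_EPSILON = 3298.0
#: mdeg = 32980 · Δε · c(M) · l(cm) · N_res
MDEG_FACTOR = 32980.0

UNITS = ("delta_epsilon", "mre", "mdeg")
#: accepted native pitches in nm
ALLOWED_PITCHES = (0.1, 0.2, 0.5, 1.0)
PITCH_TOL = 1e-6

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


@dataclass(frozen=True)
class SpectrumMeta:
    """Normalization metadata needed to convert mdeg to molar units."""

    concentration: float | None = None  # mol/L
    pathlength: float | None = None  # cm
    residue_count: int | None = None

    def require_complete(self) -> None:
        missing = [
            name
            for name, v in (
                ("concentration", self.concentration),
                ("pathlength", self.pathlength),
                ("residue_count", self.residue_count),
            )
            if v is None
        ]
        if missing:
            raise NormalizationError(
                "mdeg normalization requires " + ", ".join(missing)
            )
        for name, v in (
            ("concentration", self.concentration),
            ("pathlength", self.pathlength),
            ("residue_count", self.residue_count),
        ):
            if v <= 0:
                raise NormalizationError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class Spectrum:
    """An immutable CD spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    unit: str = "delta_epsilon"
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.shape != w.shape:
            raise InputFormatError("wavelengths and values must be 1-D and equal length")
        if w.size >= 2:
            d = np.diff(w)
            if np.all(d > 0):
                pass
            elif np.all(d < 0):
                w, v = w[::-1], v[::-1]
            else:
                raise InputFormatError("wavelength grid must be strictly monotone")
        if self.unit not in UNITS:
            raise InputFormatError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def pitch(self) -> float:
        """Median grid spacing in nm."""
        return float(np.median(np.diff(self.wavelengths)))

    def with_values(self, values: np.ndarray) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float))

    def crop(self, wmin: float, wmax: float) -> "Spectrum":
        """Restrict to wavelengths in [wmin, wmax] (inclusive, small tolerance)."""
        m = (self.wavelengths >= wmin - PITCH_TOL) & (self.wavelengths <= wmax + PITCH_TOL)
        if not m.any():
            raise CoverageError(f"no data in [{wmin}, {wmax}] nm")
        return replace(self, wavelengths=self.wavelengths[m], values=self.values[m])

    def interp_grid_equal(self, other: "Spectrum") -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.wavelengths, other.wavelengths, atol=PITCH_TOL)
        )


@dataclass(frozen=True)
class FitQuality:
    """RMSD on the raw spectrum; NRMSD on the smoothed spectrum."""

    rmsd: float
    nrmsd: float


def _detect_pitch(w: np.ndarray) -> float:
    d = np.diff(w)
    pitch = d[0]
    if not np.all(np.abs(d - pitch) <= PITCH_TOL):
        raise InputFormatError("non-uniform wavelength pitch")
    for p in ALLOWED_PITCHES:
        if abs(pitch - p) <= PITCH_TOL:
            return p
    raise InputFormatError(
        f"pitch {pitch:g} nm not in accepted set {ALLOWED_PITCHES}"
    )


def read_spectrum(
    source,
    unit: str = "delta_epsilon",
    meta: SpectrumMeta | None = None,
) -> Spectrum:
    """Read a two-column wavelength/CD text spectrum.

    Leading non-numeric header lines are skipped automatically.  Accepts
    whitespace- or comma-delimited columns and pitches of 0.1, 0.2, 0.5
    or 1 nm, ascending or descending; the result is stored ascending.

    Parameters
    ----------
    source
        Path, text content, or file-like object.
    unit
        Unit tag of the CD column.
    meta
        Normalization metadata (required later for mdeg data).
    """
    text = _read_text(source)
    lines = text.splitlines()
    rows: list[tuple[float, float]] = []
    in_data = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        cells = [c for c in re.split(r"[,\s;]+", stripped) if c]
        numeric = len(cells) >= 2 and all(_NUMBER_RE.match(c) for c in cells[:2])
        if not numeric:
            if in_data:
                raise ParseError(f"non-numeric cell inside data block at line {lineno}: {line!r}")
            continue  # header line
        in_data = True
        rows.append((float(cells[0]), float(cells[1])))
    if len(rows) < 10:
        raise InsufficientDataError(f"need at least 10 data points, found {len(rows)}")
    arr = np.asarray(rows, dtype=float)
    s = Spectrum(arr[:, 0], arr[:, 1], unit=unit, meta=meta or SpectrumMeta())
    _detect_pitch(s.wavelengths)
    return s


def write_spectrum(s: Spectrum, target=None) -> str:
    """Serialize a spectrum as two tab-separated columns (full precision)."""
    buf = io.StringIO()
    for w, v in zip(s.wavelengths, s.values):
        buf.write(f"{w:.17g}\t{v:.17g}\n")
    text = buf.getvalue()
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w") as fh:
                fh.write(text)
    return text


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if "\n" in s or "\r" in s:
        return s
    with open(s) as fh:
        return fh.read()


def convert_units(s: Spectrum, target: str) -> Spectrum:
    """Convert between Δε, mean residue ellipticity and mdeg.

    All conversions go through Δε; they are exactly invertible.  mdeg
    conversions require complete, positive normalization metadata.
    """
    if target not in UNITS:
        raise InputFormatError(f"unknown target unit {target!r}")
    if s.unit == target:
        return s

    def mdeg_scale() -> float:
        s.meta.require_complete()
        return MDEG_FACTOR * s.meta.concentration * s.meta.pathlength * s.meta.residue_count

    # to Δε
    if s.unit == "delta_epsilon":
        de = s.values
    elif s.unit == "mre":
        de = s.values / MRE_PER_DELTA_EPSILON
    else:  # mdeg
        de = s.values / mdeg_scale()

    if target == "delta_epsilon":
        out = de
    elif target == "mre":
        out = de * MRE_PER_DELTA_EPSILON
    else:
        out = de * mdeg_scale()
    return replace(s, values=np.asarray(out, dtype=float), unit=target)


def smooth(s: Spectrum, window_nm: float = 2.0) -> Spectrum:
    """Moving-average smoothing with a fixed wavelength window.

    Each output value is the unweighted mean of all input points within
    ±window_nm/2 of its wavelength.  The grid is unchanged; at the edges
    the window truncates rather than padding with invented data.
    """
    if window_nm <= 0:
        raise InputFormatError("window_nm must be positive")
    w = s.wavelengths
    half = window_nm / 2.0 + PITCH_TOL
    lo = np.searchsorted(w, w - half, side="left")
    hi = np.searchsorted(w, w + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(s.values)])
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return s.with_values(out)


def regrid(s: Spectrum, pitch_nm: float = 1.0) -> Spectrum:
    """Bin-average onto a coarser uniform grid (default 1 nm).

    Output nodes are the multiples of ``pitch_nm`` spanned by the input;
    each node value is the mean of input points within ±pitch_nm/2 of
    the node.  Interpolation is deliberately not used: coarsening is a
    data average, consistent with :func:`smooth`.
    """
    native = s.pitch
    if native > pitch_nm + PITCH_TOL:
        raise UpsamplingError(
            f"cannot regrid {native:g} nm data to finer/equal target {pitch_nm:g} nm"
        )
    w = s.wavelengths
    start = math.ceil(w[0] / pitch_nm - PITCH_TOL)
    stop = math.floor(w[-1] / pitch_nm + PITCH_TOL)
    if stop < start:
        raise CoverageError("input range spans no grid node")
    nodes = np.arange(start, stop + 1) * pitch_nm
    half = pitch_nm / 2.0 + PITCH_TOL
    lo = np.searchsorted(w, nodes - half, side="left")
    hi = np.searchsorted(w, nodes + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(s.values)])
    out = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
    single = hi - lo == 1
    out[single] = s.values[lo[single]]  # single-point bins stay exact
    return replace(s, wavelengths=nodes, values=out)


def _aligned(a: Spectrum, b: Spectrum, wmin: float, wmax: float):
    ac, bc = a.crop(wmin, wmax), b.crop(wmin, wmax)
    if not ac.interp_grid_equal(bc):
        raise CoverageError("spectra do not share the fit grid on the requested range")
    return ac, bc


def fit_quality(
    exp_raw: Spectrum,
    exp_smoothed: Spectrum,
    fitted: Spectrum,
    wrange: tuple[float, float] | None = None,
) -> FitQuality:
    """Compute RMSD (vs. the raw data) and NRMSD (vs. the smoothed data).

    NRMSD = sqrt( Σ(smoothed − fitted)² / Σ smoothed² ); being computed
    on the smoothed spectrum it reflects model adequacy, while RMSD on
    the raw spectrum stays sensitive to measurement noise.
    """
    if wrange is None:
        wrange = (fitted.wavelengths[0], fitted.wavelengths[-1])
    raw, fit1 = _aligned(exp_raw, fitted, *wrange)
    sm, fit2 = _aligned(exp_smoothed, fitted, *wrange)
    rmsd = float(np.sqrt(np.mean((raw.values - fit1.values) ** 2)))
    denom = float(np.sum(sm.values**2))
    if denom == 0.0:
        raise DataError("NRMSD undefined: smoothed spectrum is identically zero on range")
    nrmsd = float(np.sqrt(np.sum((sm.values - fit2.values) ** 2) / denom))
    return FitQuality(rmsd=rmsd, nrmsd=nrmsd)


@dataclass(frozen=True)
class ScaleScanResult:
    table: pd.DataFrame  # columns: factor, nrmsd, ok
    best_factor: float


def scale_scan(
    s: Spectrum,
    deconvolver: Callable[[Spectrum], float],
    center: float = 1.0,
    n_steps: int = 31,
) -> ScaleScanResult:
    """Scan amplitude-scaling factors and report the NRMSD of each refit.

    Factors are log-uniform on [0.5·center, 2·center]; a "best factor"
    far from 1 flags concentration or normalization errors in the input.
    ``deconvolver`` maps a (rescaled) spectrum to its fit NRMSD; a failing
    factor is flagged in the table and the scan continues.
    """
    if center <= 0:
        raise InputFormatError("center factor must be positive")
    if n_steps < 1:
        raise InputFormatError("n_steps must be >= 1")
    if n_steps == 1:
        factors = np.array([center])
    else:
        factors = np.geomspace(0.5 * center, 2.0 * center, n_steps)
    rows = []
    for f in factors:
        try:
            nr = float(deconvolver(s.with_values(s.values * f)))
            rows.append((f, nr, True))
        except Exception:
            rows.append((f, np.nan, False))
    table = pd.DataFrame(rows, columns=["factor", "nrmsd", "ok"])
    ok = table[table.ok]
    if ok.empty:
        raise DataError("deconvolution failed at every scale factor")
    best = ok.nrmsd.min()
    # ties resolved toward the factor closest to the scan center
    cand = ok[np.isclose(ok.nrmsd, best, rtol=0, atol=0)]
    best_factor = float(cand.factor.iloc[int(np.argmin(np.abs(np.log(cand.factor / center))))])
    return ScaleScanResult(table=table, best_factor=best_factor)


def amplitude_warning(
    s: Spectrum, low: float = 0.1, high: float = 40.0
) -> str | None:
    """Warn when the peak |Δε| looks abnormal (wrong units or normalization)."""
    if s.unit != "delta_epsilon":
        return None
    peak = float(np.max(np.abs(s.values))) if len(s) else 0.0
    if peak < low or peak > high:
        return (
            f"abnormal spectral amplitude: max |Δε| = {peak:.3g} M⁻¹cm⁻¹ "
            f"outside [{low}, {high}]; check units and normalization"
        )
    return None
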