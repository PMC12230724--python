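"""Secondary-structure deconvolution of CD spectra.

The spectral model is quadratic in the composition: the CD signal at
wavelength λ is

    CD_λ = SSᵀ · M_λ · SS

where SS is the vector of eight secondary-structure fractions
(Helix1, Helix2, Anti1, Anti2, Anti3, Parallel, Turn, Others; each ≥ 0,
summing to 1) and M_λ is an 8×8 per-wavelength "basis matrix".  Column i
of M_λ turns, via bᵢ(SS) = SSᵀ·M(:,i)_λ, into an *effective basis
spectrum* for component i that depends on where the protein sits in
secondary-structure space.  When every column of M_λ is constant
(M(:,i)_λ = bᵢ_λ·1) the quadratic form collapses to the classic linear
model CD_λ = Σᵢ bᵢ_λ·SSᵢ, since ΣSSᵢ = 1.

Fitting a measured spectrum means minimizing ½‖SSᵀ·M·SS − CD_exp‖² over
the probability simplex — quartic in SS.  We solve it by a multi-start
alternating scheme: freeze the effective basis at the current SS, solve
the resulting simplex-constrained *linear* problem exactly, re-linearize,
and iterate, with a backtracking safeguard so the true objective never
increases.  Starts cover the 8 simplex vertices plus seeded Dirichlet(1)
draws; the lowest final objective wins (ties → lowest start index).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CoverageError, DataError, InputFormatError
from .simplex import simplex_lstsq
from .spectra import FitQuality, Spectrum, fit_quality

COMPONENTS = (
    "Helix1",
    "Helix2",
    "Anti1",
    "Anti2",
    "Anti3",
    "Parallel",
    "Turn",
    "Others",
)
N_COMPONENTS = len(COMPONENTS)

#: server-style fit-range presets (nm); lower limits adjustable in 5 nm steps
FIT_RANGE_PRESETS = ((175.0, 250.0), (190.0, 250.0), (200.0, 250.0))

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SSVector:
    """Eight nonnegative secondary-structure fractions summing to 1."""

    fractions: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (N_COMPONENTS,):
            raise InputFormatError(f"expected {N_COMPONENTS} fractions, got shape {f.shape}")
        if np.any(f < -_SUM_TOL):
            raise InputFormatError(f"negative fraction in {f}")
        if abs(f.sum() - 1.0) > _SUM_TOL:
            raise InputFormatError(f"fractions sum to {f.sum()!r}, expected 1")
        object.__setattr__(self, "fractions", np.clip(f, 0.0, None))

    def __getitem__(self, name: str) -> float:
        return float(self.fractions[COMPONENTS.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {c: float(v) for c, v in zip(COMPONENTS, self.fractions)}

    def grouped(self) -> dict[str, float]:
        """Coarse sums conventionally reported alongside the 8 components."""
        d = self.as_dict()
        helix = d["Helix1"] + d["Helix2"]
        anti = d["Anti1"] + d["Anti2"] + d["Anti3"]
        return {
            "Helix": helix,
            "Antiparallel": anti,
            "Parallel": d["Parallel"],
            "Beta": anti + d["Parallel"],
            "Turn+Others": d["Turn"] + d["Others"],
        }

    @classmethod
    def from_counts(cls, counts: Sequence[float]) -> "SSVector":
        c = np.asarray(counts, dtype=float)
        total = c.sum()
        if total <= 0:
            raise InputFormatError("cannot normalize zero counts")
        return cls(c / total)


@dataclass(frozen=True)
class BasisMatrixSet:
    """Per-wavelength 8×8 basis matrices on a contiguous 1 nm grid."""

    wavelengths: np.ndarray  # (W,), ascending, 1 nm pitch
    matrices: np.ndarray  # (W, 8, 8)
    provenance: str = "loaded"  # trained | loaded | constant-column

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        m = np.asarray(self.matrices, dtype=float)
        if w.ndim != 1 or m.shape != (w.size, N_COMPONENTS, N_COMPONENTS):
            raise InputFormatError("matrices must have shape (n_wavelengths, 8, 8)")
        if w.size >= 2 and not np.allclose(np.diff(w), 1.0, atol=1e-6):
            raise InputFormatError("basis-matrix grid must be contiguous at 1 nm pitch")
        if not np.all(np.isfinite(m)):
            raise InputFormatError("basis matrices contain non-finite entries")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "matrices", m)

    def _range_slice(self, wrange: tuple[float, float] | None):
        if wrange is None:
            return slice(None)
        wmin, wmax = wrange
        w = self.wavelengths
        if wmin < w[0] - 1e-6 or wmax > w[-1] + 1e-6:
            raise CoverageError(
                f"range [{wmin}, {wmax}] outside model grid [{w[0]}, {w[-1]}]"
            )
        i0 = int(np.searchsorted(w, wmin - 1e-6))
        i1 = int(np.searchsorted(w, wmax + 1e-6))
        return slice(i0, i1)

    def effective_basis(
        self, ss: np.ndarray, wrange: tuple[float, float] | None = None
    ) -> np.ndarray:
        """B[λ, i] = SSᵀ·M(:,i)_λ — composition-dependent basis spectra."""
        sl = self._range_slice(wrange)
        return np.einsum("wji,j->wi", self.matrices[sl], ss)

    def is_constant_column(self, tol: float = 1e-10) -> bool:
        return bool(np.all(np.abs(self.matrices - self.matrices[:, :1, :]) <= tol))

    @classmethod
    def constant_column(
        cls, wavelengths: np.ndarray, basis: np.ndarray
    ) -> "BasisMatrixSet":
        """Build the degenerate set encoding fixed basis spectra b (W, 8)."""
        basis = np.asarray(basis, dtype=float)
        m = np.repeat(basis[:, None, :], N_COMPONENTS, axis=1)
        return cls(wavelengths, m, provenance="constant-column")

    # ---- on-disk format: header + one row per wavelength (64 entries) ----

    def to_text(self) -> str:
        buf = io.StringIO()
        cols = "\t".join(
            f"m{j + 1}{i + 1}" for j in range(N_COMPONENTS) for i in range(N_COMPONENTS)
        )
        buf.write(f"wavelength\t{cols}\n")
        for w, m in zip(self.wavelengths, self.matrices):
            row = "\t".join(f"{v:.17g}" for v in m.ravel())
            buf.write(f"{w:.17g}\t{row}\n")
        return buf.getvalue()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, source, provenance: str = "loaded") -> "BasisMatrixSet":
        text = source.read() if hasattr(source, "read") else None
        if text is None:
            s = str(source)
            if "\n" in s:
                text = s
            else:
                with open(s) as fh:
                    text = fh.read()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("wavelength"):
            raise InputFormatError("basis-matrix file must start with a header row")
        rows = []
        for ln in lines[1:]:
            cells = ln.split()
            if len(cells) != 1 + N_COMPONENTS * N_COMPONENTS:
                raise InputFormatError(
                    f"expected {1 + N_COMPONENTS**2} columns, got {len(cells)}"
                )
            rows.append([float(c) for c in cells])
        arr = np.asarray(rows, dtype=float)
        mats = arr[:, 1:].reshape(-1, N_COMPONENTS, N_COMPONENTS)
        return cls(arr[:, 0], mats, provenance=provenance)


def evaluate_model(
    m: BasisMatrixSet, ss: SSVector, wrange: tuple[float, float] | None = None
) -> Spectrum:
    """Evaluate CD_λ = SSᵀ·M_λ·SS on the (sub)grid."""
    sl = m._range_slice(wrange)
    f = ss.fractions
    values = np.einsum("i,wij,j->w", f, m.matrices[sl], f)
    return Spectrum(m.wavelengths[sl], values, unit="delta_epsilon")


@dataclass(frozen=True)
class LinearFitResult:
    ss: SSVector
    objective: float
    rank_deficient: bool


def linear_fit(
    exp: Spectrum,
    basis: np.ndarray,
    wrange: tuple[float, float] | None = None,
) -> LinearFitResult:
    """Simplex-constrained linear unmixing against fixed basis spectra.

    ``basis`` has shape (W, 8) on the spectrum's grid (or its restriction
    to ``wrange``).  Rank-deficient bases yield the minimum-norm optimum,
    flagged in the result.
    """
    s = exp if wrange is None else exp.crop(*wrange)
    B = np.asarray(basis, dtype=float)
    if B.shape != (len(s), N_COMPONENTS):
        raise CoverageError(
            f"basis shape {B.shape} does not match fit grid of {len(s)} wavelengths"
        )
    fit = simplex_lstsq(B, s.values)
    return LinearFitResult(SSVector(fit.x), fit.objective, fit.rank_deficient)


@dataclass(frozen=True)
class DeconvResult:
    ss: SSVector
    fitted: Spectrum
    quality: FitQuality
    wrange: tuple[float, float]
    converged: bool
    n_starts_used: int
    objective: float = field(default=np.nan)


def _objective(m: BasisMatrixSet, ss: np.ndarray, cd: np.ndarray, sl) -> float:
    pred = np.einsum("i,wij,j->w", ss, m.matrices[sl], ss)
    return 0.5 * float(np.sum((pred - cd) ** 2))


def fit_secondary_structure(
    exp: Spectrum,
    m: BasisMatrixSet,
    wrange: tuple[float, float] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 200,
    raw: Spectrum | None = None,
) -> DeconvResult:
    """Fit the eight secondary-structure fractions to a CD spectrum.

    ``exp`` must be in Δε units, smoothed and on the model's 1 nm grid.
    The quartic objective ½‖SSᵀ·M·SS − CD‖² is minimized by the
    alternating scheme described in the module docstring.  ``raw``, when
    given, supplies the un-smoothed spectrum for the RMSD part of the
    reported fit quality.
    """
    if exp.unit != "delta_epsilon":
        raise InputFormatError("deconvolution requires Δε units; convert first")
    if wrange is None:
        wrange = (
            max(exp.wavelengths[0], m.wavelengths[0]),
            min(exp.wavelengths[-1], m.wavelengths[-1]),
        )
    s = exp.crop(*wrange)
    sl = m._range_slice((s.wavelengths[0], s.wavelengths[-1]))
    if m.wavelengths[sl].size != len(s) or not np.allclose(
        m.wavelengths[sl], s.wavelengths, atol=1e-6
    ):
        raise CoverageError("spectrum grid does not align with the model's 1 nm grid")
    cd = s.values
    if not np.all(np.isfinite(cd)):
        raise DataError("non-finite CD values inside the fit range")

    rng = np.random.default_rng(seed)
    starts = [np.eye(N_COMPONENTS)[i] for i in range(N_COMPONENTS)]
    n_extra = max(0, n_starts - N_COMPONENTS)
    for _ in range(n_extra):
        starts.append(rng.dirichlet(np.ones(N_COMPONENTS)))
    starts = starts[:n_starts]

    best_ss, best_obj, best_conv = None, np.inf, False
    for ss0 in starts:
        ss = ss0.copy()
        obj = _objective(m, ss, cd, sl)
        converged = False
        for _ in range(max_iter):
            B = np.einsum("wji,j->wi", m.matrices[sl], ss)
            step = simplex_lstsq(B, cd).x
            cand = step
            new_obj = _objective(m, cand, cd, sl)
            # backtrack along the simplex segment so the quartic objective
            # is non-increasing even though the linearization is local
            t = 1.0
            while new_obj > obj + 1e-15 and t > 1e-8:
                t *= 0.5
                cand = (1 - t) * ss + t * step
                new_obj = _objective(m, cand, cd, sl)
            if new_obj > obj + 1e-15:
                converged = True  # no descent direction left
                break
            if obj - new_obj <= tol * max(1.0, obj):
                ss, obj = cand, new_obj
                converged = True
                break
            ss, obj = cand, new_obj
        if obj < best_obj - 0.0:
            best_ss, best_obj, best_conv = ss, obj, converged

    ss = SSVector(best_ss / best_ss.sum())
    fitted = evaluate_model(m, ss, (s.wavelengths[0], s.wavelengths[-1]))
    quality = fit_quality(raw if raw is not None else s, s, fitted)
    return DeconvResult(
        ss=ss,
        fitted=fitted,
        quality=quality,
        wrange=(float(s.wavelengths[0]), float(s.wavelengths[-1])),
        converged=best_conv,
        n_starts_used=len(starts),
        objective=best_obj,
    )
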