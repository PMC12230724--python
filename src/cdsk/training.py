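"""Training basis matrices from a reference set of (composition, spectrum) pairs.

Given n reference proteins with known secondary-structure vectors SS_j
and CD spectra, the classic fixed basis spectra come from the linear
least-squares problem at each wavelength λ:

    min ½‖SS_ref·b_λ − CD_ref,λ‖²                              (fixed basis)

The composition-dependent model refines this: for every component i a
*sequence of subsets* of the reference set is built by greedily leaving
out, one protein at a time, the protein whose removal most improves the
component-i RMSD of the simplex-constrained deconvolution of the FULL
reference set (using the fixed-basis model recomputed on the remaining
subset).  Each greedy step contributes one observation pairing the mean
composition of the retained subset with that subset's fixed-basis value
b_i,λ; regressing these observations on composition,

    min Σ_s (SS̄_sᵀ·M(:,i)_λ − b_i,λ(s))²   (+ small ridge)

yields column i of the basis matrix M_λ.  The regression is parametrized
as M(:,i) = c·1 + d with d ⊥ 1, so that a degenerate trace (no removals,
or constant b across steps) collapses *exactly* to the fixed-basis
column — the quadratic model can only refine, never lose, the linear one
on its training observations.

How the per-subset b values are paired with compositions is genuinely
open; the mean-of-retained-subset pairing used here is this package's
documented choice (see docs/methods.md) and alternative pairings can be
plugged in via the ``pair_fn`` hook of :func:`train_basis_matrices`.
"""

from __future__ import annotations

import csv
import io
import json
import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .deconv import (
    COMPONENTS,
    N_COMPONENTS,
    BasisMatrixSet,
    SSVector,
    fit_secondary_structure,
)
from .errors import CoverageError, InputFormatError
from .simplex import simplex_lstsq, simplex_lstsq_batch
from .spectra import Spectrum, read_spectrum, write_spectrum


@dataclass(frozen=True)
class ReferenceEntry:
    id: str
    ss: SSVector
    spectrum: Spectrum  # Δε on the shared grid


@dataclass(frozen=True)
class ReferenceSet:
    """Reference proteins with known composition and CD spectrum.

    Entries are sorted by id on construction so that training is
    invariant to the order records appear on disk.
    """

    entries: tuple[ReferenceEntry, ...]

    def __post_init__(self):
        entries = tuple(sorted(self.entries, key=lambda e: e.id))
        ids = [e.id for e in entries]
        if len(set(ids)) != len(ids):
            raise InputFormatError("duplicate ids in reference set")
        if entries:
            grid = entries[0].spectrum.wavelengths
            for e in entries[1:]:
                if not np.allclose(e.spectrum.wavelengths, grid, atol=1e-6):
                    raise InputFormatError(
                        f"reference entry {e.id} is not on the shared wavelength grid"
                    )
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.entries[0].spectrum.wavelengths

    def ss_matrix(self) -> np.ndarray:
        """n×8 matrix of secondary-structure contents."""
        return np.array([e.ss.fractions for e in self.entries])

    def cd_matrix(self) -> np.ndarray:
        """n×W matrix of CD values."""
        return np.array([e.spectrum.values for e in self.entries])

    def subset(self, indices: Sequence[int]) -> "ReferenceSet":
        return ReferenceSet(tuple(self.entries[i] for i in indices))

    # ---- manifest CSV + per-protein spectrum files ----

    def save(self, directory: str, manifest_name: str = "manifest.csv") -> str:
        os.makedirs(directory, exist_ok=True)
        path = os.path.join(directory, manifest_name)
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["id"] + [f"ss{i + 1}" for i in range(N_COMPONENTS)] + ["spectrum_path"])
            for e in self.entries:
                spath = f"{e.id}.txt"
                write_spectrum(e.spectrum, os.path.join(directory, spath))
                wr.writerow([e.id] + [f"{v:.17g}" for v in e.ss.fractions] + [spath])
        return path

    @classmethod
    def load(cls, manifest_path: str) -> "ReferenceSet":
        base = os.path.dirname(os.path.abspath(manifest_path))
        entries = []
        with open(manifest_path, newline="") as fh:
            rd = csv.DictReader(fh)
            for row in rd:
                ss = SSVector(np.array([float(row[f"ss{i + 1}"]) for i in range(N_COMPONENTS)]))
                spec = read_spectrum(os.path.join(base, row["spectrum_path"]))
                entries.append(ReferenceEntry(row["id"], ss, spec))
        return cls(tuple(entries))


@dataclass(frozen=True)
class BasisSolveResult:
    b: np.ndarray  # 8 CD values at one wavelength
    residual_norm: float
    rank: int


def solve_basis_spectra(ref: ReferenceSet, lam: float) -> BasisSolveResult:
    """Fixed-basis values at one wavelength (unconstrained least squares).

    Rank-deficient systems (e.g. all proteins sharing one composition)
    return the minimum-norm solution; the rank is reported.
    """
    w = ref.wavelengths
    idx = np.flatnonzero(np.abs(w - lam) <= 1e-6)
    if idx.size == 0:
        raise CoverageError(f"wavelength {lam} nm not on the reference grid")
    S = ref.ss_matrix()
    y = ref.cd_matrix()[:, idx[0]]
    b, res, rank, _ = np.linalg.lstsq(S, y, rcond=None)
    residual = float(np.linalg.norm(S @ b - y))
    return BasisSolveResult(b=b, residual_norm=residual, rank=int(rank))


def _solve_basis_all(S: np.ndarray, CD: np.ndarray) -> np.ndarray:
    """Minimum-norm least squares basis for all wavelengths at once: (8, W)."""
    B, *_ = np.linalg.lstsq(S, CD, rcond=None)
    return B


def _component_rmsd(S_true: np.ndarray, CD: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Per-component RMSD of simplex-constrained refits of every spectrum.

    ``basis`` is (8, W); each spectrum is unmixed against basis.T and the
    recovered fractions compared with the known compositions.
    """
    preds = simplex_lstsq_batch(basis.T, CD)
    return np.sqrt(np.mean((preds - S_true) ** 2, axis=0))


@dataclass(frozen=True)
class GreedyStep:
    removed_id: str | None  # None for the initial full-set step
    mean_ss: np.ndarray  # composition of the retained subset
    b: np.ndarray  # fixed-basis values of the retained subset; (8,) or (8, W)
    metric: float  # full-set component RMSD after this step


@dataclass(frozen=True)
class GreedyTrace:
    component: int
    removed_ids: tuple[str, ...]
    steps: tuple[GreedyStep, ...]


def greedy_subset(
    ref: ReferenceSet,
    component: int,
    lam: float | None = None,
    evaluator: Callable[[np.ndarray], float] | None = None,
    max_removed: int | None = None,
) -> GreedyTrace:
    """Greedy leave-out refinement of the reference subset for one component.

    At each step the single protein whose removal most improves the
    component RMSD of the full-set deconvolution (under the subset's
    fixed-basis model) is dropped; the trace stops when no removal
    improves the metric or ``max_removed`` is reached.  ``evaluator``
    may replace the built-in metric (it receives the retained indices
    and returns the score to minimize).  When ``lam`` is given the
    per-step b values are scalars at that wavelength, otherwise full
    (8, W) arrays.

    Deterministic: candidates are scanned in id order and strict
    improvement is required, so repeated runs give identical traces.
    """
    n = len(ref)
    if max_removed is None:
        max_removed = max(0, n - N_COMPONENTS - 1)
    if max_removed >= n - N_COMPONENTS:
        raise InputFormatError("max_removed must leave at least 8 proteins (need n-8)")
    S = ref.ss_matrix()
    CD = ref.cd_matrix()
    if lam is not None:
        w = ref.wavelengths
        col = np.flatnonzero(np.abs(w - lam) <= 1e-6)
        if col.size == 0:
            raise CoverageError(f"wavelength {lam} nm not on the reference grid")
        col = col[0]

    def default_eval(retained: np.ndarray) -> float:
        basis = _solve_basis_all(S[retained], CD[retained])
        return float(_component_rmsd(S, CD, basis)[component])

    ev = evaluator or default_eval

    def record(retained: np.ndarray, removed_id, metric) -> GreedyStep:
        basis = _solve_basis_all(S[retained], CD[retained])
        b = basis[:, col] if lam is not None else basis
        return GreedyStep(removed_id, S[retained].mean(axis=0), b, metric)

    retained = np.arange(n)
    current = ev(retained)
    steps = [record(retained, None, current)]
    removed: list[str] = []
    for _ in range(max_removed):
        best_j, best_metric = None, current
        for pos in range(retained.size):
            cand = np.delete(retained, pos)
            metric = ev(cand)
            if metric < best_metric - 1e-12:
                best_j, best_metric = pos, metric
        if best_j is None:
            break
        removed.append(ref.entries[retained[best_j]].id)
        retained = np.delete(retained, best_j)
        current = best_metric
        steps.append(record(retained, removed[-1], current))
    return GreedyTrace(component=component, removed_ids=tuple(removed), steps=tuple(steps))


def fit_matrix_column(
    pairs: Sequence[tuple[np.ndarray, float]],
    lam: float | None = None,
    ridge: float = 1e-8,
) -> tuple[np.ndarray, bool]:
    """Regress effective-basis values on composition: one column of M_λ.

    The column is parametrized as m = c·1 + d with d ⊥ 1 (the constant
    part is unidentifiable otherwise, since compositions sum to 1); a
    small ridge on d stabilizes near-collinear compositions and shrinks
    degenerate traces exactly onto the constant column.  Returns
    (column, flagged) where ``flagged`` marks under-determined fits
    (< 8 pairs).
    """
    if len(pairs) == 0:
        raise InputFormatError("fit_matrix_column requires at least one pair")
    S = np.array([np.asarray(p[0], dtype=float) for p in pairs])
    b = np.array([float(p[1]) for p in pairs])
    flagged = len(pairs) < N_COMPONENTS
    if np.ptp(b) == 0.0:
        # constant target: the constant column is an exact, minimum-norm optimum
        return np.full(N_COMPONENTS, b[0]), flagged
    # orthonormal basis of the hyperplane {d : d·1 = 0}
    Q, _ = np.linalg.qr(
        np.eye(N_COMPONENTS) - np.full((N_COMPONENTS, N_COMPONENTS), 1.0 / N_COMPONENTS)
    )
    Q = Q[:, : N_COMPONENTS - 1]
    X = np.hstack([np.ones((len(pairs), 1)), S @ Q])
    # ridge on the d-block only
    P = np.eye(N_COMPONENTS)
    P[0, 0] = 0.0
    beta = np.linalg.solve(X.T @ X + ridge * P, X.T @ b)
    column = beta[0] * np.ones(N_COMPONENTS) + Q @ beta[1:]
    return column, flagged


@dataclass(frozen=True)
class TrainConfig:
    """Training knobs.

    max_removed
        Cap on greedy leave-out steps per component (the trace also stops
        as soon as no removal improves the metric).
    ridge
        Ridge on the direction part of the Eq.-3 regression.
    validate
        Gate the quadratic refinement by a 2-fold, protein-level
        cross-validation against the fixed-basis model.  The candidate
        is adopted as a whole only when CV shows it no worse for every
        component and better by ``accept_margin`` for at least one;
        otherwise the result is exactly the constant-column model.
        All-or-nothing because switching even one column changes every
        fitted fraction.  The gate keeps the composition-dependent
        refinement honest: extra model freedom is adopted only where
        held-out data supports it.
    accept_margin
        Required relative improvement (0.08 = 8% lower CV RMSD).
    pair_fn
        Alternative pairing of greedy steps with (composition, b) used
        by the Eq.-3 regression; default pairs the mean composition of
        the retained subset with that subset's basis value.
    """

    max_removed: int = 10
    ridge: float = 1e-8
    validate: bool = True
    accept_margin: float = 0.08
    n_starts_eval: int = 12
    seed: int = 0
    pair_fn: Callable[[GreedyStep], tuple[np.ndarray, np.ndarray]] | None = None


@dataclass
class TrainingReport:
    removed_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)
    greedy_metric: dict[str, list[float]] = field(default_factory=dict)
    accepted_components: dict[str, bool] = field(default_factory=dict)
    cv_rmsd_candidate: dict[str, float] = field(default_factory=dict)
    cv_rmsd_fixed: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            raise TypeError(type(x))

        return json.dumps(self.__dict__, default=conv, indent=2)


def _candidate_matrices(
    ref: ReferenceSet,
    config: TrainConfig,
    report: TrainingReport | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ungated quadratic columns for all components; also the fixed basis.

    Returns (M_candidate (W,8,8), fixed_basis (8,W)).
    """
    W = ref.wavelengths.size
    M = np.empty((W, N_COMPONENTS, N_COMPONENTS))
    fixed = _solve_basis_all(ref.ss_matrix(), ref.cd_matrix())
    max_removed = max(0, min(config.max_removed, len(ref) - N_COMPONENTS - 1))
    for i in range(N_COMPONENTS):
        trace = greedy_subset(ref, i, lam=None, max_removed=max_removed)
        if report is not None:
            report.removed_ids[COMPONENTS[i]] = trace.removed_ids
            report.greedy_metric[COMPONENTS[i]] = [s.metric for s in trace.steps]
        mean_ss = np.array([s.mean_ss for s in trace.steps])  # (steps, 8)
        b_i = np.array([s.b[i] for s in trace.steps])  # (steps, W)
        for wi in range(W):
            if config.pair_fn is not None:
                pairs = [config.pair_fn(s) for s in trace.steps]
                pairs = [(p[0], p[1][wi]) for p in pairs]
            else:
                pairs = list(zip(mean_ss, b_i[:, wi]))
            column, _ = fit_matrix_column(pairs, ridge=config.ridge)
            M[wi, :, i] = column
    return M, fixed


def _quartic_rmsd(
    model: BasisMatrixSet, ref: ReferenceSet, n_starts: int, seed: int
) -> np.ndarray:
    errs = []
    for e in ref.entries:
        res = fit_secondary_structure(e.spectrum, model, n_starts=n_starts, seed=seed)
        errs.append(res.ss.fractions - e.ss.fractions)
    return np.sqrt(np.mean(np.square(errs), axis=0))


def train_basis_matrices(
    ref: ReferenceSet,
    config: TrainConfig | None = None,
    report: TrainingReport | None = None,
) -> BasisMatrixSet:
    """Train a full basis-matrix set (see module docstring for the scheme)."""
    config = config or TrainConfig()
    if len(ref) < N_COMPONENTS:
        raise InputFormatError("training requires at least 8 reference proteins")
    M, fixed = _candidate_matrices(ref, config, report)

    accept = np.ones(N_COMPONENTS, dtype=bool)
    if config.validate and config.max_removed > 0 and len(ref) >= 2 * (N_COMPONENTS + 2):
        cv_cand = np.zeros((2, N_COMPONENTS))
        cv_fixed = np.zeros((2, N_COMPONENTS))
        idx = np.arange(len(ref))
        folds = (idx[::2], idx[1::2])
        for f, (tr_idx, te_idx) in enumerate(((folds[0], folds[1]), (folds[1], folds[0]))):
            train_part, test_part = ref.subset(tr_idx), ref.subset(te_idx)
            Mc, fb = _candidate_matrices(train_part, config)
            cand_model = BasisMatrixSet(ref.wavelengths, Mc, provenance="trained")
            fixed_model = BasisMatrixSet.constant_column(ref.wavelengths, fb.T)
            cv_cand[f] = _quartic_rmsd(cand_model, test_part, config.n_starts_eval, config.seed)
            cv_fixed[f] = _quartic_rmsd(fixed_model, test_part, config.n_starts_eval, config.seed)
        cand_rmsd = np.sqrt(np.mean(cv_cand**2, axis=0))
        fixed_rmsd = np.sqrt(np.mean(cv_fixed**2, axis=0))
        # all-or-nothing: switching even one column changes every fitted
        # fraction, so the refinement must not hurt any component in CV
        # and must clearly help at least one
        take = bool(
            np.all(cand_rmsd <= fixed_rmsd)
            and np.any(cand_rmsd <= (1.0 - config.accept_margin) * fixed_rmsd)
        )
        accept[:] = take
        if report is not None:
            for i, c in enumerate(COMPONENTS):
                report.accepted_components[c] = take
                report.cv_rmsd_candidate[c] = float(cand_rmsd[i])
                report.cv_rmsd_fixed[c] = float(fixed_rmsd[i])
    elif report is not None:
        for c in COMPONENTS:
            report.accepted_components[c] = True

    for i in range(N_COMPONENTS):
        if not accept[i]:
            M[:, :, i] = fixed[i][:, None]
    return BasisMatrixSet(ref.wavelengths, M, provenance="trained")


def evaluate_reference_rmsd(
    model: BasisMatrixSet,
    ref: ReferenceSet,
    wrange: tuple[float, float] | None = None,
    n_starts: int = 12,
    seed: int = 0,
) -> np.ndarray:
    """Per-component RMSD of full quartic refits of every reference spectrum."""
    errs = []
    for e in ref.entries:
        res = fit_secondary_structure(
            e.spectrum, model, wrange=wrange, n_starts=n_starts, seed=seed
        )
        errs.append(res.ss.fractions - e.ss.fractions)
    return np.sqrt(np.mean(np.square(errs), axis=0))


def loo_crossval_rmsd(
    ref: ReferenceSet,
    config: TrainConfig | None = None,
    fixed_basis: bool = False,
    n_starts: int = 12,
    seed: int = 0,
) -> np.ndarray:
    """Leave-one-out cross-validated per-component RMSD of a model family."""
    errs = []
    for k in range(len(ref)):
        train = ref.subset([j for j in range(len(ref)) if j != k])
        if fixed_basis:
            basis = _solve_basis_all(train.ss_matrix(), train.cd_matrix())
            model = BasisMatrixSet.constant_column(train.wavelengths, basis.T)
        else:
            model = train_basis_matrices(train, config)
        e = ref.entries[k]
        res = fit_secondary_structure(e.spectrum, model, n_starts=n_starts, seed=seed)
        errs.append(res.ss.fractions - e.ss.fractions)
    return np.sqrt(np.mean(np.square(errs), axis=0))


def fixed_basis_model(ref: ReferenceSet) -> BasisMatrixSet:
    """The constant-column model solved on the full reference set."""
    basis = _solve_basis_all(ref.ss_matrix(), ref.cd_matrix())
    return BasisMatrixSet.constant_column(ref.wavelengths, basis.T)
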