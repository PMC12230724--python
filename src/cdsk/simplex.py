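"""Least squares over the probability simplex.

Solves min ½‖B·x − y‖² subject to x ≥ 0 and Σx = 1, the inner problem of
every spectral unmixing step in this package.  The dimension is tiny
(8 secondary-structure components), so exactness is cheap: an
active-set iteration on the equality-constrained KKT system, verified by
primal and dual feasibility; if it stalls (cycling is possible in
principle) the solver falls back to exact enumeration of all 2⁸−1 faces
of the simplex.

Batch variants share the Gram matrix G = BᵀB across many right-hand
sides, which is what makes the greedy training loops affordable.

Rank-deficient systems return the minimum-norm optimum and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

_FEAS_TOL = 1e-10


@dataclass(frozen=True)
class SimplexFit:
    x: np.ndarray
    objective: float  # ½‖Bx − y‖²
    rank_deficient: bool
    exhaustive: bool  # True when the enumeration fallback was needed


def _kkt_normal(G: np.ndarray, h: np.ndarray, support: np.ndarray):
    """Minimizer of ½xᵀGx − hᵀx with Σx = 1 restricted to the support.

    Returns (x_full, multiplier, rank_deficient) or None when the KKT
    system cannot be solved at all.
    """
    k = support.size
    n = G.shape[0]
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G[np.ix_(support, support)]
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    rhs = np.zeros(k + 1)
    rhs[:k] = h[support]
    rhs[k] = 1.0
    try:
        sol = np.linalg.solve(A, rhs)
        rank_def = False
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        rank_def = True
    if not np.all(np.isfinite(sol)):
        return None
    x = np.zeros(n)
    x[support] = sol[:k]
    return x, float(sol[k]), rank_def


def _solve_normal(G: np.ndarray, h: np.ndarray, tol: float) -> tuple[np.ndarray, bool, bool]:
    """Active-set solve of the simplex QP in normal-equation form."""
    n = G.shape[0]
    support = np.arange(n)
    seen: set[tuple[int, ...]] = set()
    for _ in range(8 * n):
        key = tuple(support)
        if key in seen:
            break  # cycling: hand over to enumeration
        seen.add(key)
        res = _kkt_normal(G, h, support)
        if res is None:
            break
        x, mu, rank_def = res
        neg = support[x[support] < -tol]
        if neg.size:
            worst = neg[np.argmin(x[neg])]
            support = support[support != worst]
            if support.size == 0:
                break
            continue
        grad = G @ x - h + mu
        inactive = np.setdiff1d(np.arange(n), support, assume_unique=False)
        viol = inactive[grad[inactive] < -tol]
        if viol.size == 0:
            x = np.clip(x, 0.0, None)
            s = x.sum()
            if s > 0:
                return x / s, rank_def, True
            break
        support = np.sort(np.append(support, viol[np.argmin(grad[viol])]))
    return None, False, False  # type: ignore[return-value]


def _enumerate_normal(G: np.ndarray, h: np.ndarray, tol: float):
    """Exact fallback: best feasible KKT point over every simplex face."""
    n = G.shape[0]
    best = None
    for k in range(1, n + 1):
        for combo in combinations(range(n), k):
            res = _kkt_normal(G, h, np.array(combo))
            if res is None:
                continue
            x, _, rank_def = res
            if np.any(x < -tol):
                continue
            x = np.clip(x, 0.0, None)
            s = x.sum()
            if s <= 0:
                continue
            x = x / s
            obj = 0.5 * float(x @ G @ x) - float(h @ x)
            if best is None or obj < best[1]:
                best = (x, obj, rank_def)
    if best is None:  # pragma: no cover - finite inputs always yield a face
        x = np.full(n, 1.0 / n)
        best = (x, 0.5 * float(x @ G @ x) - float(h @ x), True)
    return best


def simplex_lstsq_normal(G: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, bool, bool]:
    """Solve the simplex QP given G = BᵀB and h = Bᵀy.

    Returns (x, rank_deficient, exhaustive_used).
    """
    scale = max(1.0, float(np.abs(G).max()), float(np.abs(h).max()))
    tol = _FEAS_TOL * scale
    x, rank_def, ok = _solve_normal(G, h, tol)
    if ok:
        return x, rank_def, False
    x, _, rank_def = _enumerate_normal(G, h, tol)
    return x, rank_def, True


def simplex_lstsq(B: np.ndarray, y: np.ndarray) -> SimplexFit:
    """Exact simplex-constrained linear least squares (see module docstring)."""
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    G = B.T @ B
    h = B.T @ y
    x, rank_def, exhaustive = simplex_lstsq_normal(G, h)
    obj = 0.5 * float(np.sum((B @ x - y) ** 2))
    return SimplexFit(x, obj, rank_def, exhaustive)


def simplex_lstsq_batch(B: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve min ‖B·x − yⱼ‖² on the simplex for every row yⱼ of Y.

    Shares the Gram matrix across right-hand sides; returns (n, 8).
    """
    B = np.asarray(B, dtype=float)
    Y = np.asarray(Y, dtype=float)
    G = B.T @ B
    H = Y @ B  # (n, 8)
    out = np.empty((Y.shape[0], B.shape[1]))
    for j in range(Y.shape[0]):
        out[j], _, _ = simplex_lstsq_normal(G, H[j])
    return out
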