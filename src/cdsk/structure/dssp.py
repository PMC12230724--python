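"""Kabsch–Sander hydrogen-bond based secondary-structure assignment.

The backbone amide hydrogen is reconstructed at 1 Å from N opposite the
preceding C=O direction, and the electrostatic bond energy between the
C=O of residue i and the N–H of residue j is

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   [kcal/mol]

with an H-bond assigned when E < −0.5 kcal/mol.  From the bond pattern:

* 4-turns at i−1 and i make residues i..i+3 α-helical (H);
* bridges follow the parallel/antiparallel patterns
    parallel(i,j):      [HB(i−1→j) ∧ HB(j→i+1)] ∨ [HB(j−1→i) ∧ HB(i→j+1)]
    antiparallel(i,j):  [HB(i→j) ∧ HB(j→i)] ∨ [HB(i−1→j+1) ∧ HB(j−1→i+1)]
  (HB(a→b): C=O of a accepts from N–H of b); consecutive bridges join
  into ladders, whose residues are strand (E).  Isolated single bridges
  stay out of E (they land in "Others" downstream, configurable).
* residues spanned by any 3-, 4- or 5-turn and not otherwise assigned
  are turns (T).

3₁₀ and π helices are not promoted to H here; they fall through to
"Others" in the eight-component mapping, which is the configurable
default of :func:`~cdsk.structure.classify.ss_composition`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parse import BackboneArrays, StructureModel

#: 0.084 e² · 332 kcal·Å/(mol·e²)
_Q = 0.084 * 332.0
HBOND_CUTOFF = -0.5  # kcal/mol
_MIN_SEP = 2  # no bonds between a residue and itself or its direct neighbor


@dataclass(frozen=True)
class Bridge:
    i: int
    j: int
    sense: str  # "parallel" | "antiparallel"


@dataclass(frozen=True)
class DsspAssignment:
    """Per-residue DSSP classes plus the bridge-partner map."""

    labels: tuple[str, ...]  # 'H', 'E', 'T' or '-'
    partners: dict[int, tuple[tuple[int, str], ...]]  # residue -> ((partner, sense), ...)
    bridges: tuple[Bridge, ...]
    ladders: tuple[tuple[Bridge, ...], ...]
    backbone: BackboneArrays

    def partner_of(self, i: int) -> tuple[tuple[int, str], ...]:
        return self.partners.get(i, ())


def _amide_hydrogens(bb: BackboneArrays) -> np.ndarray:
    """H positions (NaN where undefined: chain starts and prolines)."""
    n = len(bb)
    H = np.full((n, 3), np.nan)
    for i in range(n):
        if not bb.linked_prev[i] or bb.names[i] == "PRO":
            continue
        co = bb.C[i - 1] - bb.O[i - 1]
        norm = np.linalg.norm(co)
        if norm > 0:
            H[i] = bb.N[i] + co / norm
    return H


def hbond_energy_matrix(bb: BackboneArrays) -> np.ndarray:
    """E[i, j]: C=O of i with N–H of j (kcal/mol; +inf where undefined)."""
    n = len(bb)
    H = _amide_hydrogens(bb)

    def dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        r_on = dist(bb.O, bb.N)
        r_ch = dist(bb.C, H)
        r_oh = dist(bb.O, H)
        r_cn = dist(bb.C, bb.N)
        E = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    E = np.where(np.isfinite(E), E, np.inf)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    same_chain = bb.chain_index[:, None] == bb.chain_index[None, :]
    E[(sep < _MIN_SEP) & same_chain] = np.inf
    np.fill_diagonal(E, np.inf)
    return E


def _contiguous(bb: BackboneArrays, a: int, b: int) -> bool:
    """Residues a..b form one peptide-bonded stretch of one chain."""
    if a < 0 or b >= len(bb):
        return False
    return bool(np.all(bb.linked_prev[a + 1 : b + 1]))


def assign_dssp(model: StructureModel) -> DsspAssignment:
    """Assign DSSP classes {H, E, T, -} and the bridge-partner map."""
    bb = model.backbone_arrays()
    n = len(bb)
    E = hbond_energy_matrix(bb)
    hb = E < HBOND_CUTOFF  # hb[i, j]: CO(i) ... HN(j)

    def HB(a: int, b: int) -> bool:
        return 0 <= a < n and 0 <= b < n and bool(hb[a, b])

    # --- n-turns and helices ---
    turn_span = np.zeros(n, dtype=bool)
    four_turn = np.zeros(n, dtype=bool)
    for i in range(n):
        for nn in (3, 4, 5):
            j = i + nn
            if j < n and _contiguous(bb, i, j) and hb[i, j]:
                turn_span[i + 1 : j] = True
                if nn == 4:
                    four_turn[i] = True
    helix = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if four_turn[i - 1] and four_turn[i]:
            helix[i : i + 4] = True

    # --- bridges ---
    bridges: list[Bridge] = []
    for i in range(n):
        for j in range(i + 1, n):
            if bb.chain_index[i] == bb.chain_index[j] and j - i < 3:
                continue
            par = (
                (HB(i - 1, j) and HB(j, i + 1) and _contiguous(bb, i - 1, i + 1))
                or (HB(j - 1, i) and HB(i, j + 1) and _contiguous(bb, j - 1, j + 1))
            )
            anti = (HB(i, j) and HB(j, i)) or (
                HB(i - 1, j + 1)
                and HB(j - 1, i + 1)
                and _contiguous(bb, i - 1, i + 1)
                and _contiguous(bb, j - 1, j + 1)
            )
            if par:
                bridges.append(Bridge(i, j, "parallel"))
            elif anti:
                bridges.append(Bridge(i, j, "antiparallel"))

    # --- ladders: chains of consecutive bridges of one sense ---
    ladders: list[list[Bridge]] = []
    used = [False] * len(bridges)
    bykey = {(b.i, b.j, b.sense): k for k, b in enumerate(bridges)}
    for k, b in enumerate(bridges):
        if used[k]:
            continue
        ladder = [b]
        used[k] = True
        step = 1 if b.sense == "parallel" else -1
        cur = b
        while True:
            nxt = bykey.get((cur.i + 1, cur.j + step, cur.sense))
            if nxt is None or used[nxt]:
                break
            used[nxt] = True
            cur = bridges[nxt]
            ladder.append(cur)
        ladders.append(ladder)

    strand = np.zeros(n, dtype=bool)
    partners: dict[int, list[tuple[int, str]]] = {}
    for ladder in ladders:
        if len(ladder) < 2:
            continue  # isolated bridge: DSSP 'B', not extended strand
        for b in ladder:
            strand[b.i] = strand[b.j] = True
            partners.setdefault(b.i, []).append((b.j, b.sense))
            partners.setdefault(b.j, []).append((b.i, b.sense))

    labels = []
    for i in range(n):
        if strand[i]:
            labels.append("E")  # strand precedence over helix (rare overlap)
        elif helix[i]:
            labels.append("H")
        elif turn_span[i]:
            labels.append("T")
        else:
            labels.append("-")
    return DsspAssignment(
        labels=tuple(labels),
        partners={k: tuple(v) for k, v in partners.items()},
        bridges=tuple(bridges),
        ladders=tuple(tuple(l) for l in ladders),
        backbone=bb,
    )
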