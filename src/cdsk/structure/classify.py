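"""Mapping DSSP classes onto the eight CD-relevant components.

Helices are split into a regular middle (Helix1) and the two residues at
each end (Helix2), whose backbone geometry — and hence CD contribution —
is distorted.  Strand residues separate by ladder sense: parallel sheets
are one component; antiparallel residues are binned by the local twist
of the sheet, measured per residue as the signed dihedral between the
Cα(i−1)→Cα(i+1) chain vector and the (sense-aligned) chain vector of its
bridge partner, about the inter-strand axis.  Right-hand twist is
positive.  Default bin edges t1 = 3°, t2 = 23° give:

    twist <  t1        → Anti1  (left-hand twisted)
    t1 ≤ twist < t2    → Anti2  (relaxed, slightly right-hand twisted)
    twist ≥ t2         → Anti3  (right-hand twisted)

Both thresholds and the angle convention are implementation choices
exposed in the API.  DSSP turns map to Turn; everything else — including
3₁₀/π helices and isolated β-bridges under the defaults — to Others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..deconv import COMPONENTS, SSVector
from ..errors import ContentError
from .dssp import DsspAssignment, assign_dssp
from .parse import StructureModel

DEFAULT_T1 = 3.0
DEFAULT_T2 = 23.0


@dataclass(frozen=True)
class ResidueAssignment:
    """Per-residue eight-component labels and β-twist angles."""

    labels: tuple[str, ...]  # one of COMPONENTS per residue
    twist: tuple[float | None, ...]  # degrees, β residues only
    dssp: DsspAssignment

    def to_frame(self) -> pd.DataFrame:
        bb = self.dssp.backbone
        return pd.DataFrame(
            {
                "chain": [bb.chain_ids[c] for c in bb.chain_index],
                "seq_id": bb.seq_ids,
                "icode": bb.icodes,
                "residue": bb.names,
                "dssp": self.dssp.labels,
                "component": self.labels,
                "twist_deg": [np.nan if t is None else t for t in self.twist],
            }
        )


def split_helix(dssp_labels) -> list[str | None]:
    """Split maximal H runs into Helix1 (middle) and Helix2 (2+2 ends).

    Runs of length ≤ 4 are entirely Helix2; longer runs give their first
    two and last two residues to Helix2 and the middle L−4 to Helix1.
    Non-helix positions map to None.
    """
    labels = list(dssp_labels)
    out: list[str | None] = [None] * len(labels)
    i = 0
    while i < len(labels):
        if labels[i] != "H":
            i += 1
            continue
        j = i
        while j < len(labels) and labels[j] == "H":
            j += 1
        L = j - i
        for k in range(i, j):
            if L <= 4:
                out[k] = "Helix2"
            elif k < i + 2 or k >= j - 2:
                out[k] = "Helix2"
            else:
                out[k] = "Helix1"
        i = j
    return out


def _twist_angle(bb, i: int, j: int, sense: str) -> float | None:
    """Signed dihedral (degrees) between chain vectors of bridge partners.

    Chain vector of residue r is Cα(r+1) − Cα(r−1); for antiparallel
    partners the second vector is flipped so a flat sheet reads 0°.  The
    rotation is measured about the inter-strand axis Cα(i)→Cα(j);
    right-hand twist positive.
    """
    n = len(bb)
    if not (0 < i < n - 1 and 0 < j < n - 1):
        return None
    if not (bb.linked_prev[i] and bb.linked_prev[i + 1]):
        return None
    if not (bb.linked_prev[j] and bb.linked_prev[j + 1]):
        return None
    v1 = bb.CA[i + 1] - bb.CA[i - 1]
    v2 = bb.CA[j + 1] - bb.CA[j - 1]
    if sense == "antiparallel":
        v2 = -v2
    axis = bb.CA[j] - bb.CA[i]
    na = np.linalg.norm(axis)
    if na == 0:
        return None
    a = axis / na
    p1 = v1 - (v1 @ a) * a
    p2 = v2 - (v2 @ a) * a
    if np.linalg.norm(p1) == 0 or np.linalg.norm(p2) == 0:
        return None
    ang = np.degrees(np.arctan2(np.cross(p2, p1) @ a, p1 @ p2))
    return float(ang)


def classify_beta(
    model_or_dssp,
    partners: dict | None = None,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
) -> tuple[dict[int, str], dict[int, float]]:
    """Bin strand residues into Parallel / Anti1 / Anti2 / Anti3.

    Accepts either a StructureModel (DSSP is run) or a precomputed
    :class:`DsspAssignment`; ``partners`` may override the bridge-partner
    map (e.g. from a synthetic fixture of known topology).  Residues with
    any parallel-sense partner are Parallel; purely antiparallel residues
    are binned by their mean twist over partners.  Strand residues whose
    twist is undefined (strand termini) inherit the mean twist of their
    ladder, or of the whole sheet if the ladder gives none.

    Returns (labels, twists) keyed by flat residue index.
    """
    if t1 >= t2:
        raise ValueError(f"need t1 < t2, got {t1} >= {t2}")
    if isinstance(model_or_dssp, DsspAssignment):
        dssp = model_or_dssp
    else:
        dssp = assign_dssp(model_or_dssp)
    bb = dssp.backbone
    pmap = {k: tuple(v) for k, v in (partners or dssp.partners).items()}

    raw_twist: dict[int, float] = {}
    sense_of: dict[int, str] = {}
    for i, plist in pmap.items():
        senses = {s for _, s in plist}
        sense_of[i] = "parallel" if "parallel" in senses else "antiparallel"
        angs = [
            t
            for j, s in plist
            if (t := _twist_angle(bb, i, j, s)) is not None
        ]
        if angs:
            raw_twist[i] = float(np.mean(angs))

    anti_all = [raw_twist[i] for i in raw_twist if sense_of[i] == "antiparallel"]
    mean_anti = float(np.mean(anti_all)) if anti_all else 0.0

    labels: dict[int, str] = {}
    twists: dict[int, float] = {}
    for i, sense in sense_of.items():
        if sense == "parallel":
            labels[i] = "Parallel"
            twists[i] = raw_twist.get(i, np.nan)
            continue
        tw = raw_twist.get(i)
        if tw is None:
            # strand terminus: inherit the mean twist of its ladder
            mates = []
            for ladder in dssp.ladders:
                if any(i in (b.i, b.j) for b in ladder):
                    for b in ladder:
                        for r in (b.i, b.j):
                            if r != i and r in raw_twist and sense_of.get(r) == "antiparallel":
                                mates.append(raw_twist[r])
            tw = float(np.mean(mates)) if mates else mean_anti
        twists[i] = tw
        if tw < t1:
            labels[i] = "Anti1"
        elif tw < t2:
            labels[i] = "Anti2"
        else:
            labels[i] = "Anti3"
    return labels, twists


def ss_composition(
    model: StructureModel,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
    bridge_to_others: bool = True,
) -> tuple[SSVector, ResidueAssignment]:
    """Eight-component composition of a structure, plus per-residue detail.

    Fractions are counts over all backbone-complete residues; DSSP turns
    map to Turn and everything unassigned to Others.  With
    ``bridge_to_others=False`` isolated β-bridge residues join the sheet
    components instead of Others.
    """
    dssp = assign_dssp(model)
    n = len(dssp.labels)
    if n == 0:
        raise ContentError("no assignable residues")

    partners = dict(dssp.partners)
    if not bridge_to_others:
        for ladder in dssp.ladders:
            if len(ladder) == 1:
                b = ladder[0]
                partners[b.i] = tuple(partners.get(b.i, ())) + ((b.j, b.sense),)
                partners[b.j] = tuple(partners.get(b.j, ())) + ((b.i, b.sense),)
    beta_labels, beta_twists = classify_beta(dssp, partners, t1=t1, t2=t2)
    helix_labels = split_helix(dssp.labels)

    strand_set = {
        i for i, lab in enumerate(dssp.labels) if lab == "E"
    } | (set() if bridge_to_others else set(beta_labels))

    labels: list[str] = []
    twists: list[float | None] = []
    for i in range(n):
        if i in strand_set and i in beta_labels:
            labels.append(beta_labels[i])
            twists.append(beta_twists.get(i))
        elif dssp.labels[i] == "H":
            labels.append(helix_labels[i])
            twists.append(None)
        elif dssp.labels[i] == "T":
            labels.append("Turn")
            twists.append(None)
        else:
            labels.append("Others")
            twists.append(None)
    counts = [labels.count(c) for c in COMPONENTS]
    ss = SSVector.from_counts(counts)
    return ss, ResidueAssignment(tuple(labels), tuple(twists), dssp)
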