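"""PDB / mmCIF parsing into a minimal backbone model.

Only what secondary-structure assignment needs is retained: per-residue
N, CA, C, O coordinates of the first model, altloc 'A' (or blank),
standard amino acids only.  Residues with incomplete backbones are
dropped (counted, reported).  Parsing is delegated to gemmi, which
handles both formats and their dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from ..errors import ContentError, InputFormatError

BACKBONE = ("N", "CA", "C", "O")
#: maximum C(i)–N(i+1) distance treated as a peptide bond (Å)
PEPTIDE_BOND_MAX = 2.5


@dataclass(frozen=True)
class Residue:
    name: str
    seq_id: int
    icode: str
    atoms: dict[str, np.ndarray]  # name -> xyz (Å)


@dataclass(frozen=True)
class Chain:
    id: str
    residues: tuple[Residue, ...]


@dataclass(frozen=True)
class StructureModel:
    chains: tuple[Chain, ...]
    dropped_residues: int = 0
    source_format: str = "pdb"

    def __post_init__(self):
        if not any(ch.residues for ch in self.chains):
            raise ContentError("no protein chain with complete backbone residues")

    @property
    def n_residues(self) -> int:
        return sum(len(ch.residues) for ch in self.chains)

    def backbone_arrays(self) -> "BackboneArrays":
        return BackboneArrays.from_model(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transform (used to test invariance of assignments)."""
        Rm = np.asarray(rotation, dtype=float)
        tv = np.asarray(translation, dtype=float)
        chains = tuple(
            Chain(
                ch.id,
                tuple(
                    Residue(
                        r.name,
                        r.seq_id,
                        r.icode,
                        {k: v @ Rm.T + tv for k, v in r.atoms.items()},
                    )
                    for r in ch.residues
                ),
            )
            for ch in self.chains
        )
        return StructureModel(chains, self.dropped_residues, self.source_format)


@dataclass(frozen=True)
class BackboneArrays:
    """Flattened per-residue backbone coordinates across all chains."""

    chain_index: np.ndarray  # (n,)
    chain_ids: tuple[str, ...]
    seq_ids: np.ndarray
    icodes: tuple[str, ...]
    names: tuple[str, ...]
    N: np.ndarray  # (n, 3)
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray
    linked_prev: np.ndarray = field(default=None)  # peptide bond to residue i-1

    @classmethod
    def from_model(cls, model: StructureModel) -> "BackboneArrays":
        rows = []
        for ci, ch in enumerate(model.chains):
            for r in ch.residues:
                rows.append((ci, ch.id, r))
        n = len(rows)
        N = np.empty((n, 3))
        CA = np.empty((n, 3))
        C = np.empty((n, 3))
        O = np.empty((n, 3))
        chain_index = np.empty(n, dtype=int)
        seq_ids = np.empty(n, dtype=int)
        icodes, names = [], []
        for i, (ci, _, r) in enumerate(rows):
            chain_index[i] = ci
            seq_ids[i] = r.seq_id
            icodes.append(r.icode)
            names.append(r.name)
            N[i], CA[i], C[i], O[i] = (r.atoms[a] for a in BACKBONE)
        linked = np.zeros(n, dtype=bool)
        for i in range(1, n):
            if chain_index[i] == chain_index[i - 1]:
                linked[i] = np.linalg.norm(N[i] - C[i - 1]) <= PEPTIDE_BOND_MAX
        return cls(
            chain_index=chain_index,
            chain_ids=tuple(ch.id for ch in model.chains),
            seq_ids=seq_ids,
            icodes=tuple(icodes),
            names=tuple(names),
            N=N,
            CA=CA,
            C=C,
            O=O,
            linked_prev=linked,
        )

    def __len__(self) -> int:
        return self.chain_index.size


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def parse_structure(source, fmt: str | None = None) -> StructureModel:
    """Parse a PDB or mmCIF structure (path or file content).

    ``fmt`` may be "pdb" or "mmcif"; when omitted it is inferred from
    the file extension or, for raw text, from the content.  Multi-model
    entries use the first model; alternate locations keep 'A'/blank.
    """
    text, path = None, None
    s = str(source) if not hasattr(source, "read") else source.read()
    if not s.strip():
        raise ContentError("empty structure input")
    if "\n" in s:
        text = s
    else:
        path = s
        with open(path) as fh:
            text = fh.read()
    if fmt is None:
        if path is not None and path.lower().endswith((".cif", ".mmcif")):
            fmt = "mmcif"
        elif path is not None and path.lower().endswith((".pdb", ".ent")):
            fmt = "pdb"
        else:
            head = text.lstrip()[:500]
            fmt = "mmcif" if head.startswith("data_") or "_atom_site." in head else "pdb"
    fmt = fmt.lower()
    if fmt in ("mmcif", "cif"):
        try:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        except Exception as exc:
            raise InputFormatError(f"mmCIF parse failure: {exc}") from exc
    elif fmt == "pdb":
        try:
            st = gemmi.read_pdb_string(text)
        except Exception as exc:
            raise InputFormatError(f"PDB parse failure: {exc}") from exc
    else:
        raise InputFormatError(f"unknown structure format {fmt!r}")

    st.setup_entities()
    if len(st) == 0:
        raise ContentError("structure contains no model")
    model = st[0]
    chains = []
    dropped = 0
    for ch in model:
        residues = []
        for res in ch:
            if not _is_amino_acid(res.name):
                continue
            atoms: dict[str, np.ndarray] = {}
            for at in res:
                if at.name in BACKBONE and at.altloc in ("", "\0", "A") and at.name not in atoms:
                    atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
            if all(a in atoms for a in BACKBONE):
                residues.append(
                    Residue(res.name, res.seqid.num, res.seqid.icode.strip(), atoms)
                )
            else:
                dropped += 1
        if residues:
            chains.append(Chain(ch.name, tuple(residues)))
    return StructureModel(tuple(chains), dropped_residues=dropped, source_format=fmt)
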