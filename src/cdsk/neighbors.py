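"""Nearest-neighbor engines over secondary-structure space.

Fold prediction: every protein structure is a point in the 8-dimensional
space of secondary-structure fractions, labeled with a 4-level
hierarchical fold code (class.architecture.topology.homology, CATH
style).  Three search modes operate on Euclidean distance in that space:

* ``closest_k`` — the k nearest database structures, ranked;
* ``radius_search`` — all structures within per-component error radii
  (an axis-aligned box, one radius per component, reflecting the
  per-component uncertainty of CD deconvolution), tallied by fold label
  frequency at each hierarchy level;
* ``wknn_predict`` — weighted k-nearest-neighbor label scores per level,
  default kernel w(d) = 1/(d+ε).

Order/disorder classification is a separate k-NN over CD values at a
wavelength triplet (197/206/233 nm or 212/217/225 nm) under *cosine*
distance, which makes the decision scale-invariant — concentration
errors do not change the verdict.  Ties in the 10-neighbor vote resolve
conservatively to "disordered" and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .deconv import N_COMPONENTS, SSVector
from .errors import DataError, InputFormatError
from .spectra import Spectrum

LEVELS = ("class", "architecture", "topology", "homology")
WAVELENGTH_SETS = ((197.0, 206.0, 233.0), (212.0, 217.0, 225.0))


def _parse_label(label: str) -> tuple[str, str, str, str]:
    parts = label.split(".")
    if len(parts) != 4 or not all(parts):
        raise InputFormatError(f"fold label {label!r} must have 4 dot-separated levels")
    return tuple(parts)


@dataclass(frozen=True)
class FoldDB:
    """Searchable records of (id, 8-component composition, length, fold label)."""

    ids: tuple[str, ...]
    ss: np.ndarray  # (n, 8)
    chain_lengths: np.ndarray  # (n,)
    labels: tuple[str, ...]

    def __post_init__(self):
        ss = np.asarray(self.ss, dtype=float)
        if ss.ndim != 2 or ss.shape[1] != N_COMPONENTS:
            raise InputFormatError("ss must be (n, 8)")
        n = ss.shape[0]
        if not (len(self.ids) == n == len(self.labels)):
            raise InputFormatError("inconsistent record counts")
        for lab in self.labels:
            _parse_label(lab)
        object.__setattr__(self, "ss", ss)
        object.__setattr__(
            self, "chain_lengths", np.asarray(self.chain_lengths, dtype=int)
        )

    def __len__(self) -> int:
        return len(self.ids)

    def label_prefix(self, level: int) -> list[str]:
        """Dot-joined label prefixes at hierarchy level 1..4."""
        return [".".join(lab.split(".")[:level]) for lab in self.labels]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "id": self.ids,
                **{f"ss{i + 1}": self.ss[:, i] for i in range(N_COMPONENTS)},
                "chain_length": self.chain_lengths,
                "label": self.labels,
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FoldDB":
        df = pd.read_csv(path, dtype={"id": str, "label": str})
        ss = df[[f"ss{i + 1}" for i in range(N_COMPONENTS)]].to_numpy(dtype=float)
        return cls(
            tuple(df["id"]), ss, df["chain_length"].to_numpy(), tuple(df["label"])
        )


@dataclass(frozen=True)
class ErrorRadii:
    """Per-component search radii (dimensionless fractions), all positive.

    The intended scale is 1.5× the per-component RMSD of the CD
    deconvolution on the training report's cross-validation — supply it
    from your own trained model's statistics.
    """

    radii: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        if r.shape != (N_COMPONENTS,):
            raise InputFormatError("need 8 radii")
        if np.any(r <= 0):
            raise InputFormatError("radii must all be positive")
        object.__setattr__(self, "radii", r)

    @classmethod
    def from_component_rmsd(cls, rmsd: np.ndarray, factor: float = 1.5) -> "ErrorRadii":
        return cls(factor * np.asarray(rmsd, dtype=float))


def _query_array(query) -> np.ndarray:
    if isinstance(query, SSVector):
        return query.fractions
    return np.asarray(query, dtype=float)


def closest_k(query, db: FoldDB, k: int) -> pd.DataFrame:
    """The k nearest records by Euclidean distance; ties break by id."""
    if len(db) == 0:
        raise InputFormatError("empty fold database")
    if not 1 <= k <= len(db):
        raise InputFormatError(f"k={k} outside 1..{len(db)}")
    q = _query_array(query)
    d = np.linalg.norm(db.ss - q, axis=1)
    order = np.lexsort((np.asarray(db.ids, dtype=object), d))[:k]
    return pd.DataFrame(
        {
            "id": [db.ids[i] for i in order],
            "distance": d[order],
            "label": [db.labels[i] for i in order],
            "chain_length": db.chain_lengths[order],
        }
    )


def radius_search(query, db: FoldDB, radii: ErrorRadii) -> dict[str, pd.DataFrame]:
    """Box search within per-component radii; frequency tables per level.

    A record hits iff |query_i − ss_i| ≤ radius_i for every component.
    Zero hits is a legitimate outcome (empty tables).
    """
    q = _query_array(query)
    hits = np.flatnonzero(np.all(np.abs(db.ss - q) <= radii.radii, axis=1))
    out: dict[str, pd.DataFrame] = {}
    for lev, name in enumerate(LEVELS, start=1):
        prefixes = [".".join(db.labels[i].split(".")[:lev]) for i in hits]
        counts = pd.Series(prefixes, dtype=object).value_counts()
        df = counts.rename_axis("label").reset_index(name="count")
        df = df.sort_values(["count", "label"], ascending=[False, True]).reset_index(
            drop=True
        )
        out[name] = df
    return out


def wknn_predict(
    query,
    db: FoldDB,
    k: int = 15,
    weight: Callable[[np.ndarray], np.ndarray] | None = None,
    eps: float = 1e-9,
) -> dict[str, pd.DataFrame]:
    """Weighted k-NN fold scores at every hierarchy level.

    score(label ℓ, level v) = Σ over the k nearest neighbors whose
    level-v prefix is ℓ of w(distance); default w(d) = 1/(d+ε).
    """
    if weight is None:
        weight = lambda d: 1.0 / (d + eps)  # noqa: E731
    nn = closest_k(query, db, k)
    w = weight(nn["distance"].to_numpy())
    out: dict[str, pd.DataFrame] = {}
    for lev, name in enumerate(LEVELS, start=1):
        prefixes = [".".join(lab.split(".")[:lev]) for lab in nn["label"]]
        df = (
            pd.DataFrame({"label": prefixes, "score": w})
            .groupby("label", as_index=False)["score"]
            .sum()
            .sort_values(["score", "label"], ascending=[False, True])
            .reset_index(drop=True)
        )
        out[name] = df
    return out


@dataclass(frozen=True)
class DisorderReference:
    """Labeled CD triplets for order/disorder k-NN classification."""

    ids: tuple[str, ...]
    triplets: np.ndarray  # (n, 3)
    labels: tuple[str, ...]  # "ordered" | "disordered"
    wavelength_set: tuple[float, float, float] = WAVELENGTH_SETS[0]

    def __post_init__(self):
        t = np.asarray(self.triplets, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3:
            raise InputFormatError("triplets must be (n, 3)")
        if len(self.ids) != t.shape[0] or len(self.labels) != t.shape[0]:
            raise InputFormatError("inconsistent record counts")
        bad = set(self.labels) - {"ordered", "disordered"}
        if bad:
            raise InputFormatError(f"unknown disorder labels {bad}")
        ws = tuple(float(x) for x in self.wavelength_set)
        if ws not in WAVELENGTH_SETS:
            raise InputFormatError(
                f"wavelength set {ws} not one of {WAVELENGTH_SETS}"
            )
        object.__setattr__(self, "triplets", t)
        object.__setattr__(self, "wavelength_set", ws)

    def to_csv(self, path) -> None:
        w = self.wavelength_set
        df = pd.DataFrame(
            {
                "id": self.ids,
                **{f"cd_{int(w[i])}nm": self.triplets[:, i] for i in range(3)},
                "label": self.labels,
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "DisorderReference":
        df = pd.read_csv(path, dtype={"id": str, "label": str})
        wl_cols = [c for c in df.columns if c.startswith("cd_")]
        ws = tuple(sorted(float(c[3:-2]) for c in wl_cols))
        cols = [f"cd_{int(w)}nm" for w in ws]
        return cls(
            tuple(df["id"]),
            df[cols].to_numpy(dtype=float),
            tuple(df["label"]),
            wavelength_set=ws,
        )


def triplet_from_spectrum(
    s: Spectrum, wavelength_set: Sequence[float]
) -> np.ndarray:
    """Extract the CD values at a wavelength triplet from a full spectrum."""
    vals = []
    for wl in wavelength_set:
        idx = np.flatnonzero(np.abs(s.wavelengths - wl) <= 1e-6)
        if idx.size == 0:
            raise DataError(f"spectrum has no point at {wl} nm")
        vals.append(s.values[idx[0]])
    return np.asarray(vals, dtype=float)


@dataclass(frozen=True)
class DisorderCall:
    label: str
    votes: dict[str, int]
    tie: bool
    neighbors: pd.DataFrame = field(repr=False)


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("cosine distance undefined for a zero-norm triplet")
    return float(1.0 - float(a @ b) / (na * nb))


def classify_disorder(
    query,
    ref: DisorderReference,
    k: int = 10,
) -> DisorderCall:
    """Majority vote of the k cosine-nearest reference triplets.

    ``query`` is a 3-vector on the reference's wavelength set, or a full
    :class:`~cdsk.spectra.Spectrum` from which the triplet is extracted.
    A split vote resolves to "disordered" (the conservative call for
    follow-up) and is flagged.
    """
    if isinstance(query, Spectrum):
        q = triplet_from_spectrum(query, ref.wavelength_set)
    else:
        q = np.asarray(query, dtype=float)
    if q.shape != (3,):
        raise InputFormatError("query triplet must have 3 values")
    if np.linalg.norm(q) == 0:
        raise DataError("cosine distance undefined for a zero-norm triplet")
    norms = np.linalg.norm(ref.triplets, axis=1)
    if np.any(norms == 0):
        raise DataError("reference contains a zero-norm triplet")
    d = 1.0 - (ref.triplets @ q) / (norms * np.linalg.norm(q))
    k = min(k, len(ref.ids))
    order = np.lexsort((np.asarray(ref.ids, dtype=object), d))[:k]
    nn = pd.DataFrame(
        {
            "id": [ref.ids[i] for i in order],
            "distance": d[order],
            "label": [ref.labels[i] for i in order],
        }
    )
    votes = {
        "ordered": int((nn["label"] == "ordered").sum()),
        "disordered": int((nn["label"] == "disordered").sum()),
    }
    tie = votes["ordered"] == votes["disordered"]
    label = "disordered" if votes["disordered"] >= votes["ordered"] else "ordered"
    return DisorderCall(label=label, votes=votes, tie=tie, neighbors=nn)
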