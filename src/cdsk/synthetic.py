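"""Seeded generators for every synthetic dataset the suite works with.

Real reference CD databases, fold-space snapshots and structure archives
are large and external; this module emulates their statistical shape so
that every pipeline — training, deconvolution, fold search, disorder
classification, melting-curve fitting, structure assignment — can be
exercised end-to-end with known ground truth:

* ground-truth basis matrices built from sums of Gaussian CD bands per
  component, with a tunable off-diagonal coupling (coupling = 0 gives a
  constant-column, i.e. purely linear, model);
* reference sets of Dirichlet-sampled compositions spanning helix-rich,
  β-rich and disorder-like corners of the simplex, with spectra from
  the ground-truth model plus Gaussian noise;
* idealized PDB/mmCIF structures (α-helix, antiparallel/parallel
  two-strand sheets with an imposed twist, coil) built from internal
  coordinates;
* two-state melting curves; clustered fold databases with hierarchical
  labels; cosine-separated ordered/disordered triplet references.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import gemmi
import numpy as np

from .deconv import COMPONENTS, N_COMPONENTS, BasisMatrixSet, SSVector, evaluate_model
from .errors import InputFormatError
from .neighbors import DisorderReference, FoldDB
from .spectra import Spectrum
from .thermal import MeltingCurve, ThermalParams, model_cd
from .training import ReferenceEntry, ReferenceSet

# ---------------------------------------------------------------------------
# basis-matrix ground truth
# ---------------------------------------------------------------------------

#: canonical far-UV band shapes per component: (center nm, width nm, Δε)
_BAND_TEMPLATES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "Helix1": ((192, 8, 11.0), (208, 9, -9.0), (222, 10, -10.0)),
    "Helix2": ((190, 8, 5.0), (205, 9, -4.0), (222, 10, -3.0)),
    "Anti1": ((185, 8, 3.0), (200, 10, -6.0), (225, 12, 1.5)),
    "Anti2": ((195, 8, 6.0), (217, 10, -5.0)),
    "Anti3": ((198, 8, 7.0), (220, 10, -4.5), (231, 8, 1.0)),
    "Parallel": ((197, 9, 4.0), (215, 11, -4.0)),
    "Turn": ((188, 9, -3.0), (205, 10, 2.0), (222, 12, -1.0)),
    "Others": ((198, 7, -7.0), (218, 12, 1.0)),
}

#: Dirichlet concentration vectors spanning the composition space
DEFAULT_ALPHAS: tuple[tuple[float, ...], ...] = (
    (6.0, 2.0, 0.5, 0.5, 0.5, 0.5, 1.0, 1.5),  # helix-rich
    (0.5, 0.5, 1.5, 2.0, 2.0, 1.5, 1.0, 1.5),  # β-rich
    (0.3, 0.3, 0.5, 0.7, 1.0, 0.4, 1.2, 4.0),  # disorder-like
)


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_proteins: int = 50
    wavelength_range: tuple[float, float] = (190.0, 250.0)
    noise_sigma: float = 0.01  # fraction of each spectrum's peak |Δε|
    alphas: tuple[tuple[float, ...], ...] = DEFAULT_ALPHAS
    coupling: float = 0.3
    #: "seeded": band centers/widths/amplitudes drawn from the seed
    #: (components generically distinguishable); "canonical": fixed
    #: far-UV-like templates (components nearly collinear, as real CD
    #: basis spectra are — a deliberately hard setting)
    band_mode: str = "seeded"

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InputFormatError("noise_sigma must be >= 0")
        if self.band_mode not in ("seeded", "canonical"):
            raise InputFormatError(f"unknown band_mode {self.band_mode!r}")


def _gaussian_band(w: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((w - center) / width) ** 2)


def gen_basis_truth(config: SynthConfig) -> BasisMatrixSet:
    """Ground-truth basis matrices from Gaussian bands + seeded coupling.

    Column i is b_i(λ)·1 plus, for coupling > 0, a per-row perturbation
    built from two seeded Gaussian bands, so the effective basis of
    component i genuinely depends on the overall composition.  With
    coupling = 0 the result is exactly constant-column.
    """
    rng = np.random.default_rng(config.seed)
    w = np.arange(config.wavelength_range[0], config.wavelength_range[1] + 0.5)
    W = w.size
    M = np.empty((W, N_COMPONENTS, N_COMPONENTS))
    for i, comp in enumerate(COMPONENTS):
        b = np.zeros(W)
        if config.band_mode == "seeded":
            # one signature band at a component-specific position keeps the
            # eight basis spectra mutually identifiable for any seed; two
            # smaller seeded bands add component-specific fine structure
            span = w[-1] - w[0]
            sig_center = w[0] + span * (0.08 + 0.84 * i / (N_COMPONENTS - 1)) + rng.uniform(-2.0, 2.0)
            b += _gaussian_band(
                w, sig_center, rng.uniform(5.0, 8.0),
                rng.uniform(6.0, 11.0) * rng.choice([-1.0, 1.0]),
            )
            for _ in range(2):
                center = rng.uniform(w[0], w[-1])
                width = rng.uniform(6.0, 14.0)
                amp = rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0])
                b += _gaussian_band(w, center, width, amp)
        else:
            for center, width, amp in _BAND_TEMPLATES[comp]:
                b += _gaussian_band(w, center, width, amp)
        scale = 0.15 * np.max(np.abs(b))
        for j in range(N_COMPONENTS):
            pert = np.zeros(W)
            # perturbation bands drawn even when coupling == 0 so that the
            # random stream (and hence everything downstream) is unchanged
            # when only the coupling strength differs between configs
            for _ in range(2):
                c = rng.uniform(w[0], w[-1])
                wd = rng.uniform(6.0, 14.0)
                a = rng.normal(0.0, scale)
                pert += _gaussian_band(w, c, wd, a)
            M[:, j, i] = b + config.coupling * pert
    return BasisMatrixSet(w, M, provenance="trained" if config.coupling else "constant-column")


def sample_ss(rng: np.random.Generator, alphas=DEFAULT_ALPHAS) -> SSVector:
    """One composition from the Dirichlet mixture."""
    alpha = alphas[rng.integers(len(alphas))]
    return SSVector(rng.dirichlet(np.asarray(alpha, dtype=float)))


def gen_reference_set(
    config: SynthConfig, truth: BasisMatrixSet | None = None
) -> ReferenceSet:
    """Reference proteins with spectra from the ground-truth model + noise."""
    if truth is None:
        truth = gen_basis_truth(config)
    rng = np.random.default_rng(config.seed + 1)
    entries = []
    for k in range(config.n_proteins):
        ss = sample_ss(rng, config.alphas)
        clean = evaluate_model(truth, ss)
        peak = float(np.max(np.abs(clean.values))) or 1.0
        noise = rng.normal(0.0, config.noise_sigma * peak, size=len(clean))
        spec = Spectrum(clean.wavelengths, clean.values + noise)
        entries.append(ReferenceEntry(f"syn-{k:04d}", ss, spec))
    return ReferenceSet(tuple(entries))


# ---------------------------------------------------------------------------
# idealized structures
# ---------------------------------------------------------------------------

# standard backbone geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from frame (A, B, C)."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    nv = np.cross(b - a, bc)
    nv /= np.linalg.norm(nv)
    mv = np.cross(nv, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * mv + d[2] * nv


def build_backbone(
    phis: Sequence[float], psis: Sequence[float], omega: float = 180.0
) -> list[dict[str, np.ndarray]]:
    """Backbone atoms of a chain from (φ, ψ) lists and ideal bond geometry."""
    L = len(phis)
    if L != len(psis) or L < 2:
        raise InputFormatError("need matching phi/psi lists of length >= 2")
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    c0 = _place(np.array([0.0, 1.0, 0.0]), n0, ca0, _B_CA_C, _A_N_CA_C, 0.0)
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, L):
        prev = res[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psis[i - 1])
        ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, omega)
        c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phis[i])
        res.append({"N": n, "CA": ca, "C": c})
    for i, r in enumerate(res):
        psi = psis[i]
        r["O"] = _place(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return res


def _coords_array(chain: list[dict[str, np.ndarray]]) -> np.ndarray:
    return np.array([r[a] for r in chain for a in ("N", "CA", "C", "O")])


def _apply(chain, fn):
    return [{k: fn(v) for k, v in r.items()} for r in chain]


def _align_to_x(chain):
    """Rotate/translate so the Cα trace runs along +x through the origin."""
    cas = np.array([r["CA"] for r in chain])
    center = cas.mean(axis=0)
    d = cas[-1] - cas[0]
    d /= np.linalg.norm(d)
    # rotation taking d -> x̂ (stable for any non-antiparallel d)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(d, x)
    s, c = np.linalg.norm(v), float(d @ x)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([-1.0, 1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    moved = _apply(chain, lambda p: (p - center) @ R.T)
    # flatten residual tilt: put mean N->H/C=O direction into the xy-plane
    os = np.array([r["O"] - r["C"] for r in moved])
    signs = np.sign(os[:, 1]) if np.any(np.abs(os[:, 1]) > 1e-9) else np.ones(len(os))
    mean_dir = (os * signs[:, None]).mean(axis=0)
    ang = math.atan2(mean_dir[2], mean_dir[1])
    ca, sa = math.cos(-ang), math.sin(-ang)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    return _apply(moved, lambda p: p @ Rx.T)


@dataclass(frozen=True)
class StructureFixture:
    """Generated structure plus the ground truth the generator knows."""

    chains: tuple[tuple[dict, ...], ...]  # chains -> residues -> atom dict
    kind: str
    twist_deg: float = 0.0
    partner_pairs: tuple[tuple[int, int, str], ...] = ()  # flat residue indices

    def to_pdb(self) -> str:
        return self._gemmi_structure().make_pdb_string()

    def to_mmcif(self) -> str:
        return self._gemmi_structure().make_mmcif_document().as_string()

    def _gemmi_structure(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = f"cdsk synthetic {self.kind}"
        mdl = gemmi.Model("1")
        for ci, chain in enumerate(self.chains):
            ch = gemmi.Chain(chr(ord("A") + ci))
            for ri, res in enumerate(chain, start=1):
                r = gemmi.Residue()
                r.name = "ALA"
                r.seqid = gemmi.SeqId(ri, " ")
                for aname in ("N", "CA", "C", "O"):
                    at = gemmi.Atom()
                    at.name = aname
                    at.element = gemmi.Element(aname[0])
                    p = res[aname]
                    at.pos = gemmi.Position(float(p[0]), float(p[1]), float(p[2]))
                    at.occ = 1.0
                    r.add_atom(at)
                ch.add_residue(r)
            mdl.add_chain(ch)
        st.add_model(mdl)
        st.setup_entities()
        return st


def _ks_bridges(chains: list[list[dict]]) -> list[tuple[int, int, str]]:
    """Bridge list of a coordinate set, via the production assigner."""
    from .structure.dssp import assign_dssp
    from .structure.parse import Chain as PChain
    from .structure.parse import Residue as PResidue
    from .structure.parse import StructureModel

    pchains = []
    for ci, chain in enumerate(chains):
        residues = tuple(
            PResidue("ALA", ri + 1, "", {k: np.asarray(v) for k, v in r.items()})
            for ri, r in enumerate(chain)
        )
        pchains.append(PChain(chr(ord("A") + ci), residues))
    dssp = assign_dssp(StructureModel(tuple(pchains)))
    return [(b.i, b.j, b.sense) for b in dssp.bridges]


def _ribbon_twist(chains, rate: float):
    """Twist the whole sheet about its central x-axis (rad/Å)."""
    allc = np.vstack([_coords_array(c) for c in chains])
    x0 = allc[:, 0].mean()
    y0 = allc[:, 1].mean()
    z0 = allc[:, 2].mean()

    def fn(p):
        a = rate * (p[0] - x0)
        ca, sa = math.cos(a), math.sin(a)
        y, z = p[1] - y0, p[2] - z0
        return np.array([p[0], y0 + ca * y - sa * z, z0 + sa * y + ca * z])

    return [_apply(c, fn) for c in chains]


def _register_sheet(strand1, sense: str):
    """Place a second strand so Kabsch–Sander bridges of ``sense`` form.

    The partner strand is the (flipped, for antiparallel) copy of strand
    1 shifted across the sheet; the inter-strand distance and the shift
    along the strand axis are scanned on a deterministic grid and the
    placement maximizing the number of bridges of the requested sense
    wins.
    """
    if sense == "antiparallel":
        # 180° about z: reverses the chain direction and turns the
        # N-H / C=O groups to face the first strand
        base = _apply(strand1, lambda p: np.array([-p[0], -p[1], p[2]]))
    else:
        # 180° about x: same direction, donors/acceptors facing
        base = _apply(strand1, lambda p: np.array([p[0], -p[1], -p[2]]))
    best = None
    for d in np.arange(4.2, 5.61, 0.1):
        for off in np.arange(-3.5, 3.51, 0.25):
            cand = _apply(base, lambda p: p + np.array([off, d, 0.0]))
            bridges = [b for b in _ks_bridges([strand1, cand]) if b[2] == sense]
            score = len(bridges)
            if best is None or score > best[0]:
                best = (score, d, off, cand, bridges)
    if best is None or best[0] == 0:
        raise InputFormatError(f"could not register a {sense} sheet")
    _, d, off, strand2, bridges = best
    return strand2, bridges


def gen_structure(
    kind: str,
    length: int = 12,
    fmt: str = "pdb",
    twist_deg: float = 0.0,
    seed: int = 0,
) -> str:
    """Serialized idealized structure; see :func:`gen_structure_fixture`."""
    fx = gen_structure_fixture(kind, length=length, twist_deg=twist_deg, seed=seed)
    if fmt == "pdb":
        return fx.to_pdb()
    if fmt in ("mmcif", "cif"):
        return fx.to_mmcif()
    raise InputFormatError(f"unknown structure format {fmt!r}")


def gen_structure_fixture(
    kind: str,
    length: int = 12,
    twist_deg: float = 0.0,
    seed: int = 0,
) -> StructureFixture:
    """Build an idealized structure with known ground truth.

    Kinds: ``helix`` (φ=−57°, ψ=−47°), ``antiparallel_sheet`` /
    ``parallel_sheet`` (two fully extended strands registered so
    hydrogen-bonded bridges form; ``twist_deg`` imposes a ribbon twist
    about the strand axis, calibrated so the reported inter-strand twist
    angle matches), and ``coil`` (seeded polyproline-II-like dihedrals).
    """
    if length < 4:
        raise InputFormatError("length must be >= 4")
    if kind == "helix":
        chain = build_backbone([-57.0] * length, [-47.0] * length)
        return StructureFixture((tuple(chain),), kind)
    if kind == "coil":
        rng = np.random.default_rng(seed)
        phis = rng.uniform(-100.0, -55.0, size=length)
        psis = rng.uniform(120.0, 170.0, size=length)
        chain = build_backbone(list(phis), list(psis))
        return StructureFixture((tuple(chain),), kind)
    if kind in ("antiparallel_sheet", "parallel_sheet"):
        sense = "antiparallel" if kind.startswith("anti") else "parallel"
        strand1 = _align_to_x(build_backbone([180.0] * length, [180.0] * length))
        strand2, _ = _register_sheet(strand1, sense)
        chains = [strand1, strand2]
        if twist_deg:
            cas1 = np.array([r["CA"] for r in strand1])
            cas2 = np.array([r["CA"] for r in strand2])
            d = abs(float(cas2[:, 1].mean() - cas1[:, 1].mean()))
            rate = math.radians(twist_deg) / d
            chains = _ribbon_twist(chains, rate)
        bridges = [b for b in _ks_bridges(chains) if b[2] == sense]
        return StructureFixture(
            tuple(tuple(c) for c in chains),
            kind,
            twist_deg=twist_deg,
            partner_pairs=tuple(bridges),
        )
    raise InputFormatError(f"unknown structure kind {kind!r}")


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------


def gen_melting_curve(
    p: ThermalParams,
    grid: np.ndarray | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> MeltingCurve:
    """Two-state melting curve with noise scaled to the transition amplitude."""
    if grid is None:
        grid = np.arange(293.15, 363.16, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 250.0 or grid.max() > 400.0:
        raise InputFormatError("temperature grid must lie within 250-400 K")
    clean = model_cd(grid, p)
    amp = abs((p.A_D + p.m_D * p.T_m) - (p.A_N + p.m_N * p.T_m))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma * amp, size=grid.size) if sigma > 0 else 0.0
    return MeltingCurve(grid, clean + noise)


# ---------------------------------------------------------------------------
# fold database and disorder reference
# ---------------------------------------------------------------------------

#: default fold clusters: label -> centroid composition
DEFAULT_FOLDS: dict[str, tuple[float, ...]] = {
    "1.10.8.10": (0.45, 0.25, 0.01, 0.02, 0.02, 0.02, 0.08, 0.15),
    "1.20.5.170": (0.38, 0.22, 0.02, 0.03, 0.03, 0.02, 0.10, 0.20),
    "2.40.50.100": (0.02, 0.03, 0.10, 0.20, 0.15, 0.05, 0.15, 0.30),
    "2.60.40.10": (0.01, 0.04, 0.05, 0.25, 0.20, 0.02, 0.13, 0.30),
    "3.40.50.720": (0.20, 0.15, 0.02, 0.05, 0.03, 0.15, 0.12, 0.28),
    "3.30.70.330": (0.15, 0.12, 0.04, 0.10, 0.08, 0.10, 0.13, 0.28),
    "4.10.220.10": (0.05, 0.08, 0.02, 0.05, 0.05, 0.02, 0.20, 0.53),
}


@dataclass(frozen=True)
class FoldSpaceConfig:
    seed: int = 0
    n_per_fold: int = 40
    concentration: float = 150.0  # Dirichlet concentration around centroids
    folds: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FOLDS)
    )


def gen_fold_db(config: FoldSpaceConfig) -> FoldDB:
    """Clustered fold database with 4-level hierarchical labels."""
    rng = np.random.default_rng(config.seed)
    ids, ss, lengths, labels = [], [], [], []
    for label in sorted(config.folds):
        centroid = np.asarray(config.folds[label], dtype=float)
        centroid = centroid / centroid.sum()
        alpha = np.maximum(centroid * config.concentration, 1e-3)
        for k in range(config.n_per_fold):
            ids.append(f"{label}:{k:03d}")
            ss.append(rng.dirichlet(alpha))
            lengths.append(int(rng.integers(60, 400)))
            labels.append(label)
    return FoldDB(tuple(ids), np.array(ss), np.array(lengths), tuple(labels))


@dataclass(frozen=True)
class DisorderConfig:
    seed: int = 0
    n_per_class: int = 131  # two classes
    spread: float = 0.12  # angular spread of each cone
    wavelength_set: tuple[float, float, float] = (197.0, 206.0, 233.0)
    ordered_direction: tuple[float, float, float] = (2.0, -6.0, -1.0)
    disordered_direction: tuple[float, float, float] = (-9.0, -4.0, 0.5)


def gen_disorder_ref(config: DisorderConfig) -> DisorderReference:
    """Ordered/disordered triplets drawn in two cosine-separated cones.

    Magnitudes vary over more than an order of magnitude so nothing but
    the direction of the triplet is informative — matching the cosine
    metric of the classifier.
    """
    rng = np.random.default_rng(config.seed)
    ids, triplets, labels = [], [], []
    for label, direction in (
        ("ordered", config.ordered_direction),
        ("disordered", config.disordered_direction),
    ):
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        for k in range(config.n_per_class):
            v = u + config.spread * rng.normal(size=3)
            v /= np.linalg.norm(v)
            scale = float(np.exp(rng.uniform(np.log(0.5), np.log(15.0))))
            ids.append(f"{label[:3]}-{k:04d}")
            triplets.append(scale * v)
            labels.append(label)
    return DisorderReference(
        tuple(ids), np.array(triplets), tuple(labels), config.wavelength_set
    )
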