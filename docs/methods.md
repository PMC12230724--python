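# Methods

This note documents the models implemented in `cdsk`, their
assumptions, the numerical choices behind them, and the design
decisions that were genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The spectral model

A protein CD spectrum in Δε units (M⁻¹cm⁻¹ per mean residue) is modeled
at each wavelength λ as a quadratic form in the secondary-structure
vector SS (eight nonnegative fractions summing to 1, in the fixed order
Helix1, Helix2, Anti1, Anti2, Anti3, Parallel, Turn, Others):

    CD_λ = SSᵀ · M_λ · SS

Column *i* of M_λ defines the effective basis spectrum of component *i*
via b_i(SS) = SSᵀ·M(:,i)_λ, so the per-component spectral contribution
drifts with the protein's overall composition — the physical motivation
being that "the" β-sheet or turn spectrum of a helix-rich protein
differs from that of a β-rich one. When every column is constant,
M(:,i)_λ = b_i·1, the quadratic form collapses (because ΣSS = 1) to the
classic linear fixed-basis model CD_λ = Σᵢ b_{i,λ}·SSᵢ. Only the
symmetric part of M_λ affects the quadratic form; matrices are stored
as produced and the quadratic form is evaluated directly, which is
algebraically identical to symmetrizing.

**Units.** All deconvolution happens in Δε. Conversions:
[θ] = 3298·Δε (mean residue ellipticity, deg·cm²·dmol⁻¹) and
Δε = θ_mdeg/(32980·c·l·N_res) with c in mol/L, l in cm, N_res the
residue count. These constants are fixed package conventions,
documented here because unit tags alone do not determine them.

## Fitting: the inverse problem

Given M, fitting minimizes ½‖SSᵀ·M·SS − CD_exp‖² over the probability
simplex — a quartic program. The solver alternates:

1. freeze the effective basis B[λ,i] = SSᵀ·M(:,i)_λ at the current SS;
2. solve the simplex-constrained *linear* least-squares problem exactly;
3. backtrack along the simplex segment between the old and new iterate
   whenever the true quartic objective would increase (so the objective
   is non-increasing by construction);
4. stop when the objective improves by less than 1e-10 (relative) or
   after 200 iterations.

This runs from 20 starts — the 8 simplex vertices plus 12 seeded
Dirichlet(1) draws — and keeps the lowest final objective, ties going
to the lowest start index. The multimodality of the quartic objective
is real; on synthetic instances 20 starts recover interior optima to
~1e-5, but pathological matrices could in principle defeat any fixed
start budget, which is why the start count and seed are arguments.

The inner problem, min ½‖B·x − y‖² with x ≥ 0, Σx = 1, is solved
*exactly* by an active-set iteration on the equality-constrained KKT
system (dimension 8), with primal and dual feasibility verified at the
solution; if the iteration stalls, the solver enumerates all 255 faces
of the simplex, which is exact by construction. Rank-deficient systems
return the minimum-norm optimum and are flagged. The test suite checks
this solver against an independent projected-gradient (FISTA) oracle
with an exact simplex projection; a generic SLSQP oracle was rejected
because at 1e-6 agreement its own convergence error dominates.

**Fit quality.** Two numbers are reported. RMSD is computed against the
*raw* (un-smoothed) spectrum and stays sensitive to measurement noise;
NRMSD = sqrt(Σ(smoothed−fitted)²/Σ smoothed²) is computed against the
*smoothed* spectrum and reflects how well the model explains the
underlying signal. They are asserted to differ in exactly this way in
the tests.

**Preprocessing.** Spectra are smoothed by an unweighted moving average
over a 2 nm window on the native grid (0.1/0.2/0.5/1 nm pitches
accepted), then bin-averaged onto a 1 nm grid; the window truncates at
the range edges rather than padding. Whether to smooth before or after
coarsening is an open convention; this package smooths on the native
grid first, which uses all measured points. Note that windowed
averaging is not exactly invertible: on a noise-free spectrum the 2 nm
window introduces a small systematic distortion (second-derivative
bias), which matters only when asserting exact round-trip recovery —
the worked example therefore disables smoothing on already-clean 1 nm
data. Amplitude-scaling scans refit the spectrum at 31 log-uniform
factors spanning [0.5, 2]× a center factor; the granularity is a
package choice.

## Training

Given n reference proteins with known SS and spectra on a shared 1 nm
grid (n ≥ 8, entries sorted by id so training is order-invariant):

* **Fixed basis.** For each λ, unconstrained least squares
  min ½‖SS_ref·b_λ − CD_ref,λ‖² (minimum-norm on rank deficiency)
  gives the constant-column model.
* **Greedy subsets.** For each component *i*, proteins are left out one
  at a time: each step removes the protein whose removal most improves
  the component-*i* RMSD of the simplex-constrained deconvolution of
  the *full* reference set under the subset's fixed-basis model,
  stopping when no removal improves or after `max_removed` steps
  (default 10; the removal metric uses raw full-set RMSD). The Eq.-2
  residual is non-increasing along any removal trace, which the tests
  assert.
* **Column regression.** Each greedy step contributes one observation
  pairing the mean composition of the retained subset with that
  subset's basis value b_{i,λ}; regressing these observations on
  composition gives column *i* of M_λ. The column is parametrized as
  c·1 + d with d ⊥ 1 (the constant direction is unidentifiable on the
  simplex) and a ridge of 1e-8 on d. A degenerate trace (no removals,
  or constant b) collapses *exactly* to the constant column. How the
  per-subset b values pair with compositions is the central ambiguity
  of the procedure; the subset-mean pairing is this package's
  documented choice and alternatives can be injected via
  `TrainConfig.pair_fn`.
* **Validation gate.** The greedy traces move the subset means only
  slightly, so the regression can capture noise as easily as signal.
  The quadratic candidate is therefore adopted only after a 2-fold,
  protein-level cross-validation against the fixed basis: it must be no
  worse for *every* component and better by ≥ 8% for at least one.
  The gate is all-or-nothing because switching even one column changes
  every fitted fraction. When the gate rejects — the typical outcome at
  the sample sizes the tests exercise (30–100 proteins) — the trained
  model *is* the constant-column model, which is the honest answer:
  extra model freedom is adopted only where held-out data supports it.
  The training report records the traces, the CV numbers and the gate
  decision.

## Secondary structure from 3D structures

PDB and mmCIF files are parsed with gemmi (first model, altloc
'A'/blank, standard amino acids, complete N/CA/C/O backbones; dropped
residues are counted). Assignment is a Kabsch–Sander implementation:

* amide H reconstructed at 1 Å from N along the preceding C→O
  direction (prolines and chain starts have no donor);
* bond energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
  kcal/mol, bond if E < −0.5; self and directly bonded neighbors
  excluded;
* α-helix from two consecutive 4-turns; bridges from the standard
  parallel/antiparallel patterns; consecutive bridges join into
  ladders, and ladder residues are strand (E). Isolated single bridges
  and 3₁₀/π helices are *not* promoted — they land in "Others" by
  default, switchable in `ss_composition`;
* turns are residues spanned by any 3-/4-/5-turn not otherwise
  assigned. In the rare overlap of helix and strand patterns, strand
  wins (package convention).

The eight components then follow: maximal H runs of length L ≥ 5 give
their middle L−4 residues to Helix1 and two residues at each end to
Helix2 (L ≤ 4 is all Helix2). Strand residues with any parallel-sense
partner are Parallel. Antiparallel residues get a per-residue twist:
the signed dihedral between their chain vector Cα(i−1)→Cα(i+1) and the
sense-aligned chain vector of the bridge partner, measured about the
inter-strand axis Cα(i)→Cα(j); a flat sheet reads 0° and a
right-hand-rule ribbon twist about the strand axis reads positive.
Twist bins default to t1 = 3° and t2 = 23° (< t1 → Anti1, < t2 →
Anti2, ≥ t2 → Anti3); both the angle convention and the thresholds are
implementation choices exposed as parameters, since the three groups
are defined structurally but no universal angle formula exists. Strand
termini whose twist is undefined inherit their ladder's mean twist.

## Fold and disorder nearest neighbors

Fold search operates on Euclidean distance in the 8-dimensional
composition space; chain length is carried as metadata but does not
enter any distance. Three modes: the k closest records (ties broken by
id); a per-component *box* search (|Δ_i| ≤ radius_i for all i, radii
meant to be set from 1.5× the per-component deconvolution RMSD of your
own trained model) tallied into label-frequency tables at each of the
four hierarchy levels; and weighted k-NN with the kernel w(d) =
1/(d+1e-9) (pluggable — the kernel is a convention, not a derivation).
The box reading of "within the expected error in each component" is a
package choice; a Euclidean ball would also be defensible and the box
keeps per-component error semantics.

Order/disorder classification reduces a spectrum to its CD values at
one of two wavelength triplets and votes among the 10 cosine-nearest
reference records. Cosine distance makes the call invariant to positive
rescaling — deliberate, since concentration errors rescale spectra. A
5–5 tie resolves to "disordered" (the conservative call for follow-up)
and is flagged.

## Thermal denaturation

The two-state native ⇌ denatured model with linear baselines:

    CD(T) = [(A_N + m_N·T) + (A_D + m_D·T)·K(T)] / [1 + K(T)]
    K(T)  = exp(y)·(T/T_m)^(ΔC_p/R),
    y     = (1/R)·[(T_m·ΔC_p − ΔH_m)/T + ΔH_m/T_m − ΔC_p]

with R = 8.314 J/(mol·K). K is evaluated in log space (overflow-safe),
and ΔG(T) = ΔH_m(1 − T/T_m) − ΔC_p[(T_m − T) + T·ln(T/T_m)] is
identically −RT·ln K — an internal consistency the tests assert to
1e-9. A_N/A_D are the baseline intercepts at 0 K, since the baselines
are linear in the absolute temperature used throughout; reports also
give T_m in °C. ΔC_p is held fixed (never fitted; ~50 J/(mol·K) per
residue is offered as a rough globular-protein estimate).
Six parameters are fitted by Levenberg–Marquardt (lmfit) with automatic
initialization: native/denatured baselines from lines through the
coolest/hottest 20% of points, T_m from the half-unfolded crossing of
the baseline-normalized signal, ΔH_m from a van't Hoff slope over the
transition region. Standard errors come from the linearized covariance
at the optimum. A curve whose baseline gap at mid-range is below 3× the
baseline noise (plus a small relative floor, so an exact straight line
never "melts") is flagged as having no detectable transition; the
best-effort parameters are still returned. Recovery quality is
quantified in the tests as the ensemble root-mean-square error over
seeded noisy curves (T_m and ΔH_m), because per-curve worst-case error
at 1% noise is bounded below by the information in the data.

## Extinction coefficients

Additive schemes at 214 nm and 205 nm:
ε = Σ side chains + (L−1)·peptide bond + disulfide corrections, where
each disulfide replaces two reduced-cysteine terms with one cystine
term. The numeric coefficients are transcribed into versioned JSON
constants files (`cdsk/data/epsilon_*.json`) with their literature
source embedded; the 214 nm scheme does not distinguish cystine from
two cysteines, so its cystine entry is the neutral 2× value. Terminal
corrections are not applied. Nonstandard letters are rejected unless an
explicit mapping is supplied.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (config, seed).

* **Basis-matrix truth**: each component's base spectrum is a sum of
  Gaussian bands. By default one *signature* band sits at a
  component-specific position (staggered across the range, jittered by
  the seed) plus two smaller seeded bands — this keeps the eight
  spectra mutually identifiable for any seed, which the recovery
  properties presume. A "canonical" mode instead uses fixed
  far-UV-like templates whose components are nearly collinear, as real
  CD basis spectra are; it is the deliberately hard setting. Coupling
  strength scales seeded per-row perturbations of each column;
  coupling = 0 is exactly constant-column.
* **Reference sets**: compositions from a three-component Dirichlet
  mixture covering helix-rich, β-rich and disorder-like corners;
  spectra from the truth model plus Gaussian noise scaled to each
  spectrum's peak (default σ = 1%).
* **Structures**: backbones built by natural-extension (NeRF) placement
  from ideal bond geometry. Helix: φ = −57°, ψ = −47°. Sheets: two
  fully extended strands, the partner placed by a deterministic scan
  over inter-strand distance and register that maximizes the number of
  hydrogen-bonded bridges of the requested sense (as judged by the
  package's own assigner); twist is imposed as a ribbon twist about
  the strand axis at a rate calibrated so the read-out inter-strand
  twist angle matches the request (edge residues read slightly less).
  Coil: seeded polyproline-II-like dihedrals.
* **Fold databases**: Dirichlet clusters around per-fold centroid
  compositions with 4-level labels; **disorder references**: two
  cosine-separated cones with magnitudes spanning >1 order of
  magnitude so only direction is informative.

What passing tests on these data show: the estimators recover the
models they assume, the solvers are exact, the procedures are
deterministic and the conventions are self-consistent. What they do
not show: performance on real CD spectra, which carry aromatic
side-chain contributions, scattering and linear-dichroism artifacts,
baseline errors, and basis-spectrum variability beyond the quadratic
model — none of which the generators simulate.

## Problem sizes and defaults

The suite exercises training at n = 30/50/100 reference proteins on a
190–250 nm grid with max_removed = 10, deconvolution recovery over 50
proteins with 20 starts, thermal recovery over 200 curves (100 in the
acceptance script) at 0.5 K pitch over 20–90 °C, and neighbor searches
over ~1000-record databases — sizes chosen so the full pipeline runs
comfortably on a laptop while leaving every statistical conclusion
unchanged at larger n.

## Known limitations

* The eight components do not cover polyproline-II helices, specific
  turn types or 3₁₀ helices; aromatic contributions are ignored.
* The quartic fit is non-convex; the multi-start budget trades runtime
  against the (small) risk of a missed global optimum.
* The greedy-subset training signal is weak at desk-scale reference
  sizes; the validation gate then keeps the fixed basis, so benefits
  of the quadratic model materialize only with larger, more
  heterogeneous reference sets.
* The structure assigner implements minimal DSSP (no β-bulges, no
  helix kink handling); idealized fixtures do not exercise those cases.
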