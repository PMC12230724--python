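"""Basis-matrix training: per-wavelength solves, greedy subsets, regression."""

import numpy as np
import pytest

from cdsk.deconv import BasisMatrixSet, SSVector, evaluate_model
from cdsk.errors import CoverageError, InputFormatError
from cdsk.spectra import Spectrum
from cdsk.synthetic import SynthConfig, gen_basis_truth, gen_reference_set
from cdsk.training import (
    ReferenceEntry,
    ReferenceSet,
    TrainConfig,
    TrainingReport,
    fit_matrix_column,
    fixed_basis_model,
    greedy_subset,
    solve_basis_spectra,
    train_basis_matrices,
)


def build_refset(S, CD, w):
    entries = tuple(
        ReferenceEntry(f"p{j:03d}", SSVector(S[j]), Spectrum(w, CD[j]))
        for j in range(S.shape[0])
    )
    return ReferenceSet(entries)


@pytest.fixture()
def linear_refset(rng):
    """12 proteins whose spectra are exact simplex mixes of 8 basis spectra."""
    w = np.arange(200.0, 241.0)
    basis = rng.normal(size=(8, w.size)) * 4.0
    S = np.vstack([np.eye(8), rng.dirichlet(np.ones(8), size=4)])
    CD = S @ basis
    return build_refset(S, CD, w), basis


class TestSolveBasisSpectra:
    def test_exact_system_recovered(self, linear_refset):
        ref, basis = linear_refset
        for lam in (200.0, 220.0, 240.0):
            res = solve_basis_spectra(ref, lam)
            wi = int(lam - 200)
            assert np.allclose(res.b, basis[:, wi], atol=1e-10)
            assert res.rank == 8
            assert res.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_rank_reported_minimum_norm(self, rng):
        w = np.arange(200.0, 231.0)
        ss = rng.dirichlet(np.ones(8))
        S = np.tile(ss, (10, 1))
        CD = np.tile(rng.normal(size=w.size), (10, 1))
        ref = build_refset(S, CD, w)
        res = solve_basis_spectra(ref, 210.0)
        assert res.rank == 1
        # minimum-norm least squares: b lies along ss
        assert np.allclose(res.b, ss * (ss @ res.b) / (ss @ ss), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        w = np.arange(200.0, 231.0)
        S = rng.dirichlet(np.ones(8), size=30)
        CD = rng.normal(size=(30, w.size))
        ref = build_refset(S, CD, w)
        res = solve_basis_spectra(ref, 215.0)
        oracle = np.linalg.solve(S.T @ S, S.T @ CD[:, 15])
        assert np.allclose(res.b, oracle, atol=1e-8)

    def test_off_grid_wavelength_rejected(self, linear_refset):
        ref, _ = linear_refset
        with pytest.raises(CoverageError):
            solve_basis_spectra(ref, 180.0)


class TestGreedySubset:
    def test_gross_outlier_removed_first(self, rng):
        w = np.arange(200.0, 241.0)
        basis = rng.normal(size=(8, w.size)) * 4.0
        S = np.vstack([np.eye(8), rng.dirichlet(np.ones(8), size=8)])
        CD = S @ basis
        CD[12] += 40.0  # spectrum inconsistent with its composition
        ref = build_refset(S, CD, w)
        outlier_id = ref.ids[12]
        trace = greedy_subset(ref, component=0, max_removed=3)
        assert trace.removed_ids[0] == outlier_id

    def test_consistent_noise_free_set_removes_nothing(self, linear_refset):
        ref, _ = linear_refset
        trace = greedy_subset(ref, component=2, max_removed=3)
        assert trace.removed_ids == ()

    def test_trace_is_deterministic(self, rng):
        cfg = SynthConfig(seed=11, n_proteins=14, noise_sigma=0.02)
        ref = gen_reference_set(cfg)
        t1 = greedy_subset(ref, 1, max_removed=4)
        t2 = greedy_subset(ref, 1, max_removed=4)
        assert t1.removed_ids == t2.removed_ids
        assert all(
            np.array_equal(a.b, b.b) for a, b in zip(t1.steps, t2.steps)
        )

    def test_eq2_residual_non_increasing_along_trace(self, rng):
        cfg = SynthConfig(seed=13, n_proteins=14, noise_sigma=0.05)
        ref = gen_reference_set(cfg)
        trace = greedy_subset(ref, 0, max_removed=5)
        S, CD = ref.ss_matrix(), ref.cd_matrix()
        ids = list(ref.ids)
        retained = list(range(len(ref)))
        prev = None
        for step in trace.steps:
            if step.removed_id is not None:
                retained.remove(ids.index(step.removed_id))
            b, *_ = np.linalg.lstsq(S[retained], CD[retained][:, 10], rcond=None)
            resid = float(np.linalg.norm(S[retained] @ b - CD[retained][:, 10]))
            if prev is not None:
                assert resid <= prev + 1e-9
            prev = resid

    def test_max_removed_must_leave_eight(self, linear_refset):
        ref, _ = linear_refset
        with pytest.raises(InputFormatError):
            greedy_subset(ref, 0, max_removed=len(ref) - 8)


class TestFitMatrixColumn:
    def test_constant_target_gives_constant_column(self, rng):
        pairs = [(rng.dirichlet(np.ones(8)), 2.5) for _ in range(10)]
        col, flagged = fit_matrix_column(pairs)
        assert np.allclose(col, 2.5)
        assert not flagged

    def test_known_column_recovered(self, rng):
        m_true = rng.normal(size=8)
        S = np.vstack([np.eye(8), rng.dirichlet(np.ones(8), size=12)])
        pairs = [(s, float(s @ m_true)) for s in S]
        col, _ = fit_matrix_column(pairs)
        # the column is identifiable only up to its action on the simplex
        test = rng.dirichlet(np.ones(8), size=50)
        assert np.allclose(test @ col, test @ m_true, atol=1e-6)

    def test_objective_matches_qr_oracle(self, rng):
        S = rng.dirichlet(np.ones(8), size=20)
        b = rng.normal(size=20)
        col, _ = fit_matrix_column(pairs := list(zip(S, b)), ridge=1e-12)
        # QR-based unconstrained oracle on the same parametrization
        Q, _ = np.linalg.qr(np.eye(8) - np.full((8, 8), 1.0 / 8.0))
        X = np.hstack([np.ones((20, 1)), S @ Q[:, :7]])
        beta, *_ = np.linalg.lstsq(X, b, rcond=None)
        oracle_obj = float(np.sum((X @ beta - b) ** 2))
        mine_obj = float(np.sum((S @ col - b) ** 2))
        assert mine_obj <= oracle_obj + 1e-8

    def test_few_pairs_flagged(self, rng):
        pairs = [(rng.dirichlet(np.ones(8)), float(rng.normal())) for _ in range(3)]
        _, flagged = fit_matrix_column(pairs)
        assert flagged

    def test_empty_pairs_rejected(self):
        with pytest.raises(InputFormatError):
            fit_matrix_column([])


class TestTrainBasisMatrices:
    def test_max_removed_zero_collapses_to_fixed_basis(self, small_refset):
        model = train_basis_matrices(small_refset, TrainConfig(max_removed=0))
        fixed = fixed_basis_model(small_refset)
        assert np.allclose(model.matrices, fixed.matrices, atol=1e-12)
        assert model.is_constant_column(tol=1e-9)

    def test_entry_order_invariance(self, rng):
        cfg = SynthConfig(seed=21, n_proteins=12, noise_sigma=0.01)
        ref = gen_reference_set(cfg)
        shuffled = ReferenceSet(tuple(rng.permutation(np.array(ref.entries, dtype=object))))
        m1 = train_basis_matrices(ref, TrainConfig(max_removed=2, validate=False))
        m2 = train_basis_matrices(shuffled, TrainConfig(max_removed=2, validate=False))
        assert np.array_equal(m1.matrices, m2.matrices)

    def test_repeat_runs_byte_identical(self):
        cfg = SynthConfig(seed=23, n_proteins=12, noise_sigma=0.01)
        ref = gen_reference_set(cfg)
        t1 = train_basis_matrices(ref, TrainConfig(max_removed=2, validate=False)).to_text()
        t2 = train_basis_matrices(ref, TrainConfig(max_removed=2, validate=False)).to_text()
        assert t1 == t2

    def test_validation_gate_reported(self):
        cfg = SynthConfig(seed=25, n_proteins=24, noise_sigma=0.01)
        ref = gen_reference_set(cfg)
        from cdsk.deconv import COMPONENTS

        report = TrainingReport()
        train_basis_matrices(ref, TrainConfig(max_removed=3), report)
        assert set(report.accepted_components) == set(COMPONENTS)
        # all-or-nothing gate
        assert len(set(report.accepted_components.values())) == 1


class TestReferenceSetIO:
    def test_manifest_round_trip(self, small_refset, tmp_path):
        small_refset.save(tmp_path)
        back = ReferenceSet.load(tmp_path / "manifest.csv")
        assert back.ids == small_refset.ids
        for a, b in zip(back.entries, small_refset.entries):
            assert np.array_equal(a.ss.fractions, b.ss.fractions)
            assert np.array_equal(a.spectrum.values, b.spectrum.values)

    def test_duplicate_ids_rejected(self, small_refset):
        e = small_refset.entries[0]
        with pytest.raises(InputFormatError):
            ReferenceSet(small_refset.entries + (e,))
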