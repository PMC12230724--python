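"""Spectrum I/O, unit conversion, smoothing, regridding and fit metrics."""

import io

import numpy as np
import pytest

from cdsk.errors import (
    DataError,
    InputFormatError,
    InsufficientDataError,
    NormalizationError,
    ParseError,
    UpsamplingError,
)
from cdsk.spectra import (
    MDEG_FACTOR,
    MRE_PER_DELTA_EPSILON,
    Spectrum,
    SpectrumMeta,
    convert_units,
    fit_quality,
    read_spectrum,
    regrid,
    scale_scan,
    smooth,
    write_spectrum,
)


def make_spectrum(n=40, pitch=1.0, start=200.0, seed=0, unit="delta_epsilon"):
    rng = np.random.default_rng(seed)
    w = start + pitch * np.arange(n)
    return Spectrum(w, rng.normal(size=n), unit=unit)


class TestReadSpectrum:
    def test_header_lines_are_skipped(self):
        text = "Instrument X\nsample: lysozyme\nnm  CD\n" + "\n".join(
            f"{250 - i} {0.1 * i:.3f}" for i in range(30)
        )
        s = read_spectrum(text)
        assert len(s) == 30
        # descending input stored ascending
        assert s.wavelengths[0] == 221 and s.wavelengths[-1] == 250
        assert s.values[-1] == 0.0

    @pytest.mark.parametrize("pitch", [0.1, 0.2, 0.5, 1.0])
    def test_accepted_pitches(self, pitch):
        text = "\n".join(f"{200 + pitch * i:.4f}, {i}" for i in range(25))
        s = read_spectrum(text)
        assert s.pitch == pytest.approx(pitch, abs=1e-9)

    def test_disallowed_pitch_rejected(self):
        text = "\n".join(f"{200 + 0.3 * i:.4f} 1.0" for i in range(25))
        with pytest.raises(InputFormatError):
            read_spectrum(text)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            read_spectrum("\n".join(f"{200 + i} 1.0" for i in range(5)))

    def test_non_numeric_cell_names_line(self):
        rows = [f"{200 + i} 1.0" for i in range(15)]
        rows[7] = "207 oops"
        with pytest.raises(ParseError, match="line 8"):
            read_spectrum("\n".join(rows))

    def test_write_read_round_trip_is_exact(self, rng):
        s = Spectrum(200.0 + np.arange(30), rng.normal(size=30))
        text = write_spectrum(s)
        back = read_spectrum(io.StringIO(text))
        assert np.array_equal(back.wavelengths, s.wavelengths)
        assert np.array_equal(back.values, s.values)


class TestConvertUnits:
    def test_delta_epsilon_to_mre_constant(self):
        s = Spectrum(200.0 + np.arange(10), np.ones(10))
        assert convert_units(s, "mre").values[0] == pytest.approx(
            MRE_PER_DELTA_EPSILON
        )

    def test_mdeg_formula(self):
        meta = SpectrumMeta(concentration=1.0, pathlength=1.0, residue_count=1)
        s = Spectrum(200.0 + np.arange(10), np.full(10, MDEG_FACTOR), unit="mdeg", meta=meta)
        assert convert_units(s, "delta_epsilon").values[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("a", ["delta_epsilon", "mre", "mdeg"])
    @pytest.mark.parametrize("b", ["delta_epsilon", "mre", "mdeg"])
    def test_round_trip_all_pairs(self, a, b, rng):
        meta = SpectrumMeta(concentration=2e-5, pathlength=0.1, residue_count=129)
        s = Spectrum(200.0 + np.arange(20), rng.normal(size=20), unit=a, meta=meta)
        back = convert_units(convert_units(s, b), a)
        assert np.allclose(back.values, s.values, rtol=1e-12, atol=0)

    def test_mdeg_requires_meta(self):
        s = make_spectrum(unit="mdeg")
        with pytest.raises(NormalizationError, match="concentration"):
            convert_units(s, "delta_epsilon")

    def test_nonpositive_meta_rejected(self):
        meta = SpectrumMeta(concentration=-1.0, pathlength=1.0, residue_count=10)
        s = Spectrum(200.0 + np.arange(10), np.ones(10), unit="mdeg", meta=meta)
        with pytest.raises(NormalizationError):
            convert_units(s, "mre")


class TestSmooth:
    def test_constant_unchanged(self):
        s = Spectrum(200.0 + np.arange(20), np.full(20, 3.3))
        assert np.allclose(smooth(s).values, 3.3)

    def test_linear_unchanged_in_interior(self):
        s = Spectrum(200.0 + np.arange(20), 2.0 * np.arange(20.0))
        out = smooth(s, window_nm=2.0)
        assert np.allclose(out.values[1:-1], s.values[1:-1])

    def test_matches_brute_force(self, rng):
        s = Spectrum(200.0 + 0.5 * np.arange(60), rng.normal(size=60))
        out = smooth(s, window_nm=2.0)
        for i, w0 in enumerate(s.wavelengths):
            mask = np.abs(s.wavelengths - w0) <= 1.0 + 1e-9
            assert out.values[i] == pytest.approx(s.values[mask].mean(), abs=1e-12)

    def test_linearity(self, rng):
        w = 200.0 + np.arange(30)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a, b = 2.5, -1.3
        lhs = smooth(Spectrum(w, a * x + b * y)).values
        rhs = a * smooth(Spectrum(w, x)).values + b * smooth(Spectrum(w, y)).values
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestRegrid:
    def test_identity_at_native_pitch(self, rng):
        s = make_spectrum(n=30, pitch=1.0, seed=3)
        out = regrid(s, 1.0)
        assert np.array_equal(out.values, s.values)

    def test_linear_ramp_hits_nodes(self):
        w = 200.0 + 0.1 * np.arange(101)
        s = Spectrum(w, 3.0 * w - 550.0)
        out = regrid(s, 1.0)
        # interior nodes: the bin mean of a linear ramp is the node value
        assert np.allclose(out.values[1:-1], 3.0 * out.wavelengths[1:-1] - 550.0, atol=1e-9)

    def test_matches_brute_force_bin_mean(self, rng):
        w = 200.0 + 0.2 * np.arange(120)
        s = Spectrum(w, rng.normal(size=120))
        out = regrid(s, 1.0)
        for i, node in enumerate(out.wavelengths):
            mask = np.abs(w - node) <= 0.5 + 1e-9
            assert out.values[i] == pytest.approx(s.values[mask].mean(), abs=1e-12)

    def test_upsampling_rejected(self):
        s = make_spectrum(pitch=1.0)
        with pytest.raises(UpsamplingError):
            regrid(s, 0.5)

    def test_linearity(self, rng):
        w = 200.0 + 0.5 * np.arange(40)
        x, y = rng.normal(size=40), rng.normal(size=40)
        lhs = regrid(Spectrum(w, 2.0 * x - 0.5 * y), 1.0).values
        rhs = 2.0 * regrid(Spectrum(w, x), 1.0).values - 0.5 * regrid(Spectrum(w, y), 1.0).values
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestFitQuality:
    def test_identical_spectra_give_zero(self):
        s = make_spectrum(seed=5)
        q = fit_quality(s, s, s)
        assert q.rmsd == 0.0 and q.nrmsd == 0.0

    def test_rmsd_uses_raw_nrmsd_uses_smoothed(self, rng):
        w = 200.0 + np.arange(20)
        smoothed = Spectrum(w, rng.normal(size=20))
        raw = Spectrum(w, smoothed.values + rng.normal(size=20))
        fitted = Spectrum(w, smoothed.values.copy())
        q = fit_quality(raw, smoothed, fitted)
        assert q.nrmsd == 0.0
        assert q.rmsd > 0.0

    def test_matches_hand_formula(self, rng):
        w = 200.0 + np.arange(25)
        raw = Spectrum(w, rng.normal(size=25))
        sm = Spectrum(w, rng.normal(size=25))
        fit = Spectrum(w, rng.normal(size=25))
        q = fit_quality(raw, sm, fit)
        assert q.rmsd == pytest.approx(np.sqrt(np.mean((raw.values - fit.values) ** 2)))
        assert q.nrmsd == pytest.approx(
            np.sqrt(np.sum((sm.values - fit.values) ** 2) / np.sum(sm.values**2))
        )

    def test_nrmsd_scale_invariant(self, rng):
        w = 200.0 + np.arange(25)
        sm = Spectrum(w, rng.normal(size=25))
        fit = Spectrum(w, rng.normal(size=25))
        q1 = fit_quality(sm, sm, fit)
        q2 = fit_quality(
            Spectrum(w, 7.0 * sm.values), Spectrum(w, 7.0 * sm.values), Spectrum(w, 7.0 * fit.values)
        )
        assert q2.nrmsd == pytest.approx(q1.nrmsd, rel=1e-12)

    def test_zero_smoothed_is_error(self):
        w = 200.0 + np.arange(20)
        z = Spectrum(w, np.zeros(20))
        s = Spectrum(w, np.ones(20))
        with pytest.raises(DataError):
            fit_quality(s, z, s)


class TestScaleScan:
    def test_single_step_evaluates_center_only(self):
        s = make_spectrum(seed=6)
        res = scale_scan(s, lambda x: float(np.sum(x.values**2)), center=1.7, n_steps=1)
        assert len(res.table) == 1
        assert res.best_factor == pytest.approx(1.7)

    def test_premultiplied_spectrum_recovers_inverse_factor(self, truth_model, exact_spectrum):
        from cdsk.deconv import fit_secondary_structure

        ss, spec = exact_spectrum
        scaled = spec.with_values(spec.values * 1.3)

        def nrmsd_of(s):
            return fit_secondary_structure(s, truth_model, n_starts=6, seed=0).quality.nrmsd

        res = scale_scan(scaled, nrmsd_of, center=1.0, n_steps=31)
        # grid resolution of a 31-step log scan over [0.5, 2]
        step = (2.0 / 0.5) ** (1.0 / 30.0)
        assert abs(np.log(res.best_factor * 1.3)) <= np.log(step) * 1.01

    def test_exactly_representable_spectrum_prefers_unity(self, truth_model, exact_spectrum):
        from cdsk.deconv import fit_secondary_structure

        ss, spec = exact_spectrum

        def nrmsd_of(s):
            return fit_secondary_structure(s, truth_model, n_starts=6, seed=0).quality.nrmsd

        res = scale_scan(spec, nrmsd_of, center=1.0, n_steps=15)
        step = (2.0 / 0.5) ** (1.0 / 14.0)
        assert abs(np.log(res.best_factor)) <= np.log(step) * 1.01

    def test_failing_factor_is_flagged_and_scan_continues(self):
        s = make_spectrum(seed=7)
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] == 3:
                raise RuntimeError("boom")
            return float(np.sum(x.values**2))

        res = scale_scan(s, flaky, n_steps=7)
        assert (~res.table.ok).sum() == 1
        assert len(res.table) == 7
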