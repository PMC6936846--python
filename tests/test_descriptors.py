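import numpy as np
import pytest
from sklearn.base import clone

from octshape import (
    ContourShapeTransformer,
    CurvatureCorrection,
    EyeRecord,
    ScanSpec,
    condition_signal,
    correct_curvature,
    describe_bscan,
    fit_quadratic,
    residual_signal,
    spectrum,
    synth_contour,
    vertex_curvature,
)
from octshape.descriptors import (
    DescriptorError,
    SingularCorrectionError,
    N_FFT,
)

from conftest import make_parabola_contour


def dft_moduli_oracle(signal, bins):
    """Direct O(N^2) DFT by definition."""
    n = len(signal)
    i = np.arange(n)
    return np.array([
        abs(np.sum(signal * np.exp(-2j * np.pi * k * i / n))) for k in bins
    ])


def normal_equations_oracle(x, z):
    """Quadratic LS coefficients from an explicit 3x3 normal-equation solve."""
    design = np.vander(x, 3)
    return np.linalg.solve(design.T @ design, design.T @ z)


class TestQuadraticFit:
    def test_exact_parabola_recovered(self):
        c = make_parabola_contour(a=0.1, b=0.0, c=0.0)
        fit = fit_quadratic(c)
        assert fit.a == pytest.approx(0.1, abs=1e-9)
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_straight_line_degenerate_quadratic(self):
        c = make_parabola_contour(a=0.0, b=2.0, c=1.0, n=100)
        fit = fit_quadratic(c)
        assert fit.a == pytest.approx(0.0, abs=1e-9)
        assert fit.b == pytest.approx(2.0, abs=1e-9)
        assert fit.c == pytest.approx(1.0, abs=1e-9)

    def test_against_normal_equations_oracle(self):
        spec = ScanSpec()
        from octshape import BScanContour
        contour = BScanContour(
            eye=EyeRecord(eye_id="e", axial_length_mm=24.0), region="macula",
            cube_id="c", scan_index=0,
            x_mm=np.arange(1024) * spec.dx_mm,
            z_mm=0.05 * (np.arange(1024) * spec.dx_mm) ** 2
            + 0.01 * np.sin(2 * np.pi * np.arange(1024) * spec.dx_mm / 3),
            dx_mm=spec.dx_mm,
        )
        fit = fit_quadratic(contour)
        a_o, b_o, c_o = normal_equations_oracle(contour.x_mm, contour.z_mm)
        assert fit.a == pytest.approx(a_o, abs=1e-9)
        assert fit.a == pytest.approx(0.05, abs=1e-3)


class TestVertexCurvature:
    @pytest.mark.parametrize("a, expected", [
        (0.1, 0.2), (0.0, 0.0), (-0.015, -0.03),
    ])
    def test_k_is_twice_leading_coefficient(self, a, expected):
        from octshape import QuadraticFit

        assert vertex_curvature(QuadraticFit(a=a, b=0, c=0, rss=0)) == \
            pytest.approx(expected)

    def test_noise_free_parabola_recovery_sweep(self, rng):
        for a in rng.uniform(-0.05, 0.05, size=25):
            contour = make_parabola_contour(a=a, b=0.1, c=1.0)
            k = vertex_curvature(fit_quadratic(contour))
            assert abs(k - 2 * a) < 1e-9


class TestCurvatureCorrection:
    def test_zero_table_is_identity(self):
        corr = CurvatureCorrection.zero()
        for k_raw in (0.05, -0.02, 0.1):
            for al in (21.0, 24.5, 36.9):
                assert correct_curvature(k_raw, al, corr) == pytest.approx(k_raw)

    def test_radius_arithmetic(self):
        corr = CurvatureCorrection([(21.0, 2.0), (24.0, 2.0), (28.0, 2.0)])
        # r = 1/0.1 = 10; K = 1/(10 - 2) = 0.125
        assert correct_curvature(0.1, 24.0, corr) == pytest.approx(0.125)

    def test_linear_table_interpolated_by_poly(self):
        table = [(al, 0.1 * (al - 21)) for al in range(21, 29)]
        corr = CurvatureCorrection(table)
        # closed-form line through the table
        assert corr.delta_r(24.5) == pytest.approx(0.35, abs=1e-9)
        assert corr.fit_rms < 1e-12

    def test_zero_curvature_unchanged(self):
        corr = CurvatureCorrection([(21.0, 1.0), (24.0, 1.5), (28.0, 2.0)])
        assert correct_curvature(0.0, 24.0, corr) == 0.0

    def test_singular_correction_flagged(self):
        corr = CurvatureCorrection([(21.0, 10.0), (24.0, 10.0), (28.0, 10.0)])
        with pytest.raises(SingularCorrectionError):
            correct_curvature(0.1, 24.0, corr)  # r = 10 == delta r


class TestResidualSignal:
    def test_exact_parabola_residual_is_zero(self):
        c = make_parabola_contour(a=0.02, b=0.1, c=0.5)
        fit = fit_quadratic(c)
        assert np.max(np.abs(residual_signal(c, fit))) < 1e-10

    def test_sinusoid_recovered(self):
        spec = ScanSpec()
        x = np.arange(1024) * spec.dx_mm
        wave = 0.05 * np.sin(2 * np.pi * 5 * np.arange(1024) / 1024)
        from octshape import BScanContour

        c = BScanContour(
            eye=EyeRecord(eye_id="e", axial_length_mm=24.0), region="macula",
            cube_id="c", scan_index=0, x_mm=x,
            z_mm=0.02 * x**2 + wave, dx_mm=spec.dx_mm,
        )
        resid = residual_signal(c, fit_quadratic(c))
        # the fit absorbs a little of the sinusoid, so the residual matches
        # the wave up to a smooth quadratic discrepancy
        assert np.max(np.abs(resid - wave)) < 0.2 * 0.05
        leftover = resid - wave
        quad = np.polyval(np.polyfit(x, leftover, 2), x)
        assert np.max(np.abs(leftover - quad)) < 1e-9

    def test_residual_mean_is_zero(self, rng):
        spec = ScanSpec()
        x = np.arange(600) * spec.dx_mm
        from octshape import BScanContour

        c = BScanContour(
            eye=EyeRecord(eye_id="e", axial_length_mm=24.0), region="macula",
            cube_id="c", scan_index=0, x_mm=x,
            z_mm=rng.normal(1.0, 0.05, size=600), dx_mm=spec.dx_mm,
        )
        resid = residual_signal(c, fit_quadratic(c))
        assert abs(resid.mean()) < 1e-9


class TestConditionSignal:
    def test_short_signal_zero_padded(self):
        sig, n = condition_signal(np.ones(1000))
        assert sig.shape == (1024,) and n == 1000
        assert np.all(sig[:1000] == 1) and np.all(sig[1000:] == 0)

    def test_long_signal_symmetric_cut(self):
        sig, n = condition_signal(np.arange(1030, dtype=float))
        assert n == 1024
        assert sig[0] == 3 and sig[-1] == 1026  # drop 3 from each end

    def test_exact_length_unchanged(self):
        x = np.arange(1024, dtype=float)
        sig, n = condition_signal(x)
        assert n == 1024 and np.array_equal(sig, x)

    def test_odd_excess_cut(self):
        sig, _ = condition_signal(np.arange(1031, dtype=float))
        assert sig[0] == 3 and sig[-1] == 1026  # floor from start, rest from end


class TestSpectrum:
    def test_zero_signal_zero_moduli(self):
        s = spectrum(np.zeros(N_FFT), n_signal=1024)
        assert np.all(s.moduli == 0)

    def test_full_window_sinusoid_reads_its_amplitude(self):
        i = np.arange(1024)
        sig = 0.1 * np.sin(2 * np.pi * 5 * i / 1024)
        s = spectrum(sig, n_signal=1024)
        assert s.moduli[5] == pytest.approx(0.1, abs=1e-9)
        others = np.delete(s.moduli, 5)
        assert np.all(others < 1e-9)

    def test_half_window_sinusoid_against_dense_oracle(self):
        i = np.arange(1024)
        sig = 0.1 * np.sin(2 * np.pi * 5 * i / 1024)
        sig[512:] = 0.0
        s = spectrum(sig, n_signal=512)
        oracle = (2 / 512) * dft_moduli_oracle(sig, range(30))
        np.testing.assert_allclose(s.moduli, oracle, atol=1e-9)
        # length correction keeps the bin-5 neighbourhood near amplitude scale
        assert abs(s.moduli[3:8].sum() - 0.2) / 0.2 < 0.15

    @pytest.mark.parametrize("normalization, factor", [
        ("amplitude", 2 / 512), ("inverse_n", 1 / 512), ("fft_length", 2.0),
    ])
    def test_normalization_variants(self, normalization, factor, rng):
        sig = np.zeros(1024)
        sig[:512] = rng.normal(0, 0.01, 512)
        s = spectrum(sig, n_signal=512, normalization=normalization)
        raw = dft_moduli_oracle(sig, range(30))
        np.testing.assert_allclose(s.moduli, factor * raw, atol=1e-12)


class TestDescriptorInvariances:
    def _contour_with_padding_offset(self, offset_px, rng):
        spec = ScanSpec()
        n = 600
        i = np.arange(offset_px, offset_px + n)
        x = i * spec.dx_mm
        z = 0.013 * (x - x.mean()) ** 2 \
            + 0.04 * np.sin(2 * np.pi * 5 * x / spec.width_mm + 0.7) + 1.0
        from octshape import BScanContour

        return BScanContour(
            eye=EyeRecord(eye_id="e", axial_length_mm=24.0), region="macula",
            cube_id="c", scan_index=0, x_mm=x, z_mm=z, dx_mm=spec.dx_mm,
        )

    def test_vertical_translation_invariance(self, rng):
        c = self._contour_with_padding_offset(100, rng)
        d1 = describe_bscan(c, CurvatureCorrection.zero())
        c2 = self._contour_with_padding_offset(100, rng)
        c2.z_mm = c2.z_mm + 0.37
        d2 = describe_bscan(c2, CurvatureCorrection.zero())
        assert np.max(np.abs(d1.spectrum.moduli - d2.spectrum.moduli)) < 1e-6
        assert d1.K == pytest.approx(d2.K, abs=1e-9)

    def test_tilt_ramp_absorbed_by_fit(self, rng):
        c1 = self._contour_with_padding_offset(50, rng)
        c2 = self._contour_with_padding_offset(50, rng)
        c2.z_mm = c2.z_mm + 0.2 * c2.x_mm
        d1 = describe_bscan(c1, CurvatureCorrection.zero())
        d2 = describe_bscan(c2, CurvatureCorrection.zero())
        assert np.max(np.abs(d1.spectrum.moduli - d2.spectrum.moduli)) < 1e-9

    def test_residual_amplitude_homogeneity(self, rng):
        spec = ScanSpec()
        x = np.arange(700) * spec.dx_mm
        wave = 0.02 * np.sin(2 * np.pi * 7 * x / spec.width_mm + 1.1)
        from octshape import BScanContour

        def contour(scale):
            return BScanContour(
                eye=EyeRecord(eye_id="e", axial_length_mm=24.0),
                region="macula", cube_id="c", scan_index=0, x_mm=x,
                z_mm=0.01 * x**2 + scale * wave + 0.5, dx_mm=spec.dx_mm,
            )

        m1 = describe_bscan(contour(1.0), CurvatureCorrection.zero()).spectrum.moduli
        m2 = describe_bscan(contour(2.0), CurvatureCorrection.zero()).spectrum.moduli
        np.testing.assert_allclose(m2, 2 * m1, atol=1e-9)


class TestDescribeBScan:
    def test_exact_parabola_composition(self):
        c = make_parabola_contour(a=0.013)
        d = describe_bscan(c, CurvatureCorrection.zero())
        assert d.K == pytest.approx(0.026, abs=1e-9)
        assert np.all(d.spectrum.moduli < 1e-9)

    def test_flat_contour(self):
        c = make_parabola_contour(a=0.0, b=0.0, c=1.0)
        d = describe_bscan(c, CurvatureCorrection.zero())
        assert d.K == pytest.approx(0.0, abs=1e-12)
        assert np.all(d.spectrum.moduli < 1e-12)

    def test_two_injected_sinusoids_measured(self):
        spec = ScanSpec()
        x = np.arange(1024) * spec.dx_mm
        z = (0.013 * (x - 4.5) ** 2 + 1.0
             + 0.04 * np.sin(2 * np.pi * 3 * x / 9.0 + 0.3)
             + 0.02 * np.sin(2 * np.pi * 11 * x / 9.0 + 2.1))
        from octshape import BScanContour

        c = BScanContour(
            eye=EyeRecord(eye_id="e", axial_length_mm=24.0), region="macula",
            cube_id="c", scan_index=0, x_mm=x, z_mm=z, dx_mm=spec.dx_mm,
        )
        d = describe_bscan(c, CurvatureCorrection.zero())
        # injected amplitudes recovered up to the share absorbed by the fit
        assert d.spectrum.moduli[3] == pytest.approx(0.04, rel=0.1)
        assert d.spectrum.moduli[11] == pytest.approx(0.02, rel=0.1)
        # the fit-absorbed remainder is smooth with 1/k-decaying spectrum,
        # well below the injected amplitudes at every other bin
        others = np.delete(d.spectrum.moduli, [3, 11])
        assert np.all(others < 0.01)
        # dual route: pipeline moduli equal the direct-summation DFT of the
        # conditioned residual
        from octshape import condition_signal, fit_quadratic, residual_signal

        sig, n_signal = condition_signal(residual_signal(c, fit_quadratic(c)))
        oracle = (2 / n_signal) * dft_moduli_oracle(sig, range(30))
        np.testing.assert_allclose(d.spectrum.moduli, oracle, atol=1e-9)


class TestContourShapeTransformer:
    def test_sklearn_clone_and_params(self):
        t = ContourShapeTransformer(normalization="inverse_n")
        t2 = clone(t)
        assert t2.get_params()["normalization"] == "inverse_n"

    def test_transform_schema_and_values(self, small_synth, small_descriptors):
        df = small_descriptors
        assert len(df) == small_synth.cohort.n_scans
        assert {"eye_id", "region", "K", "m0", "m29", "sum_bins"} <= set(df.columns)
        mods = df[[f"m{k}" for k in range(30)]].to_numpy()
        assert np.all(mods >= 0) and np.all(np.isfinite(mods))
        np.testing.assert_allclose(df["sum_bins"], mods.sum(axis=1), rtol=1e-12)

    def test_invalid_normalization_rejected(self):
        with pytest.raises(DescriptorError):
            ContourShapeTransformer(normalization="bogus").fit(None)
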