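import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flavoquant import (
    NoiseSpec,
    TightBindingParams,
    TitrationPoint,
    TitrationProtocol,
    TitrationSeries,
    complex_concentration,
    concentrations_at_point,
    fit_titration,
    generate_titration,
    predicted_fluorescence,
    subtract_control,
)
from conftest import bisect_complex


class TestDilutionBookkeeping:
    def test_before_first_addition(self, protocol):
        assert concentrations_at_point(protocol, 0) == (200.0, 0.0)

    def test_first_addition(self, protocol):
        ft, at = concentrations_at_point(protocol, 1)
        assert ft == pytest.approx(200 * 1300 / 1305)
        assert at == pytest.approx(5000 * 5 / 1305)

    def test_final_addition(self, protocol):
        ft, at = concentrations_at_point(protocol, 50)
        assert ft == pytest.approx(200 * 1300 / 1550)   # 167.74 nM
        assert at == pytest.approx(5000 * 250 / 1550)   # 806.45 nM

    def test_total_added_volume(self, protocol):
        assert protocol.total_added_volume == 250.0

    @pytest.mark.parametrize("i", [-1, 51])
    def test_out_of_range_index(self, protocol, i):
        with pytest.raises(IndexError):
            concentrations_at_point(protocol, i)

    def test_invalid_protocol(self):
        with pytest.raises(ValueError):
            TitrationProtocol(v0=0)


class TestComplexConcentration:
    def test_no_binder(self):
        assert complex_concentration(100.0, 0.0, 18.0) == 0.0

    def test_symmetric_unit_case(self):
        # ft = at = kd = 1: c^2 - 3c + 1 = 0, physical root (3 - sqrt 5)/2
        assert complex_concentration(1.0, 1.0, 1.0) == pytest.approx(
            (3 - np.sqrt(5)) / 2, rel=1e-12)

    def test_endpoint_of_standard_titration(self):
        c = complex_concentration(167.74, 806.45, 18.0)
        assert c == pytest.approx(bisect_complex(167.74, 806.45, 18.0), rel=1e-9)
        assert c == pytest.approx(163.18, abs=0.01)

    def test_kd_must_be_positive(self):
        with pytest.raises(ValueError):
            complex_concentration(1.0, 1.0, 0.0)

    @given(
        ft=st.floats(1e-3, 1e4),
        at=st.floats(0.0, 1e4),
        kd=st.floats(1e-3, 1e5),
    )
    @settings(max_examples=200)
    def test_matches_bisection_oracle(self, ft, at, kd):
        c = complex_concentration(ft, at, kd)
        ref = bisect_complex(ft, at, kd)
        assert c == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @given(ft=st.floats(1e-3, 1e3), at=st.floats(0, 1e3), kd=st.floats(1e-3, 1e4))
    def test_bounded_by_limiting_species(self, ft, at, kd):
        c = complex_concentration(ft, at, kd)
        assert 0.0 <= c <= min(ft, at) + 1e-12

    def test_monotone_in_apo_and_kd(self):
        ats = np.linspace(0, 500, 40)
        c_of_at = complex_concentration(200.0, ats, 18.0)
        assert np.all(np.diff(c_of_at) >= -1e-12)
        kds = np.linspace(1.0, 500.0, 40)
        c_of_kd = np.array([complex_concentration(200.0, 300.0, k) for k in kds])
        assert np.all(np.diff(c_of_kd) <= 1e-12)


class TestPredictedFluorescence:
    def test_weak_binding_limit(self, tight_params):
        weak = TightBindingParams(kd=1e12, f_flavin=tight_params.f_flavin,
                                  f_complex=tight_params.f_complex, f_apo=tight_params.f_apo)
        f = predicted_fluorescence(weak, 200.0, 300.0)
        assert f == pytest.approx(weak.f_flavin * 200 + weak.f_apo * 300, rel=1e-6)

    def test_algebraic_collapse_with_equal_factors(self):
        p = TightBindingParams(kd=18.0, f_flavin=1.0, f_complex=1.0, f_apo=1.0)
        c = complex_concentration(200.0, 300.0, 18.0)
        assert predicted_fluorescence(p, 200.0, 300.0) == pytest.approx(200 + 300 - c)

    def test_plug_in_example(self, tight_params):
        # endpoint of the standard schedule with quenching factors
        f = predicted_fluorescence(tight_params, 167.74, 806.45)
        c = complex_concentration(167.74, 806.45, 18.0)
        expected = 1.0 * (167.74 - c) + 0.02 * c + 0.01 * (806.45 - c)
        assert f == pytest.approx(expected, rel=1e-12)
        assert f == pytest.approx(14.26, abs=0.01)

    def test_reduces_to_line_when_complex_as_bright_as_flavin(self, protocol):
        p = TightBindingParams(kd=18.0, f_flavin=1.0, f_complex=1.0, f_apo=0.0)
        pts = [concentrations_at_point(protocol, i) for i in range(51)]
        f = np.array([predicted_fluorescence(p, ft, at) for ft, at in pts])
        ft = np.array([x[0] for x in pts])
        # F = ft exactly: binding is then spectroscopically invisible
        assert np.allclose(f, ft, rtol=1e-12)


class TestFitTitration:
    def test_noiseless_recovery(self, tight_params, noiseless_series):
        fit = fit_titration(noiseless_series)
        assert fit.converged
        assert fit.params.kd == pytest.approx(tight_params.kd, rel=1e-3)
        assert fit.params.f_flavin == pytest.approx(tight_params.f_flavin, rel=1e-3)
        assert fit.params.f_complex == pytest.approx(tight_params.f_complex, rel=1e-3)
        assert fit.params.f_apo == pytest.approx(tight_params.f_apo, rel=1e-3)
        assert fit.residual_sum_of_squares < 1e-12

    def test_sampling_distribution_covers_truth(self, tight_params, protocol):
        """With 1% proportional noise the fitted K_D scatter straddles truth."""
        kds = []
        for seed in range(40):
            series = generate_titration(
                tight_params, protocol, NoiseSpec("proportional", 0.01, seed))
            kds.append(fit_titration(series).params.kd)
        lo, hi = np.percentile(kds, [2.5, 97.5])
        assert lo < tight_params.kd < hi
        assert np.median(kds) == pytest.approx(tight_params.kd, rel=0.05)

    def test_too_few_points(self, tight_params):
        pts = [TitrationPoint(200.0, 10.0 * i, 100.0) for i in range(5)]
        with pytest.raises(ValueError, match="at least 8"):
            fit_titration(TitrationSeries(pts))

    def test_degenerate_series(self):
        pts = [TitrationPoint(200.0, 0.0, 200.0) for _ in range(10)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_titration(TitrationSeries(pts))

    def test_weak_binder_flagged(self, protocol):
        """A riboflavin-like binder (K_D far above the probe concentration)
        produces an unidentifiable K_D and a warning."""
        weak = TightBindingParams(kd=5e4, f_flavin=1.0, f_complex=0.02, f_apo=0.01)
        series = generate_titration(weak, protocol, NoiseSpec("proportional", 0.01, 3))
        with pytest.warns(UserWarning, match="poorly identified"):
            fit = fit_titration(series)
        assert not fit.kd_identifiable()


class TestControlSubtraction:
    @staticmethod
    def _series(fl):
        return TitrationSeries(
            TitrationPoint(200.0, 10.0 * i, f) for i, f in enumerate(fl))

    def test_zero_control_is_identity(self):
        s = self._series([10.0, 9.0, 8.0])
        out = subtract_control(s, self._series([0.0, 0.0, 0.0]))
        assert np.allclose(out.fluorescence, s.fluorescence)
        assert np.allclose(out.flavin_total, s.flavin_total)

    def test_self_subtraction_is_zero(self):
        s = self._series([10.0, 9.0, 8.0])
        assert np.allclose(subtract_control(s, s).fluorescence, 0.0)

    def test_pointwise_difference(self):
        out = subtract_control(self._series([10.0, 9.0, 8.0]),
                               self._series([1.0, 1.0, 1.0]))
        assert np.allclose(out.fluorescence, [9.0, 8.0, 7.0])

    def test_mismatched_grids_rejected(self):
        s = self._series([10.0, 9.0, 8.0])
        c = TitrationSeries(
            TitrationPoint(200.0, 15.0 * i, 1.0) for i in range(3))
        with pytest.raises(ValueError, match="grid"):
            subtract_control(s, c)
        with pytest.raises(ValueError, match="length"):
            subtract_control(s, self._series([1.0, 1.0]))
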