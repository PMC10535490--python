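import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icmsas import (Peak, PeakReport, ScatteringCurve, assign_harmonics,
                    bragg_spacing, detect_peaks, fit_match_point,
                    integrate_band, porod_slope)


class TestIntegrateBand:
    def test_rectangle(self, flat_curve):
        assert integrate_band(flat_curve, 0.0065, 0.009) == \
            pytest.approx(2.0 * 0.0025)

    def test_linear_closed_form(self):
        q = np.linspace(0.1, 1.0, 500)
        c = ScatteringCurve(q, q, np.zeros_like(q) + 0.1)
        assert integrate_band(c, 0.1, 1.0) == \
            pytest.approx(0.5 * (1.0 ** 2 - 0.1 ** 2), rel=1e-5)

    def test_dense_linear_vs_antiderivative(self):
        q = np.linspace(0.01, 0.6, 1000)
        a, b = 3.0, 0.7
        c = ScatteringCurve(q, a * q + b, np.zeros_like(q))
        lo, hi = 0.02, 0.55
        exact = a / 2 * (hi ** 2 - lo ** 2) + b * (hi - lo)
        assert integrate_band(c, lo, hi) == pytest.approx(exact, rel=1e-4)

    def test_disjoint_band_rejected(self, flat_curve):
        with pytest.raises(ValueError):
            integrate_band(flat_curve, 0.7, 0.9)


def _abs_linear_series(mp=96.7, k=2.0, fractions=(0, 20, 40, 60, 80, 100)):
    q = np.linspace(0.006, 0.01, 30)
    out = []
    for f in fractions:
        v = k * abs(f - mp)
        out.append((f, ScatteringCurve(q, np.full(30, v ** 2),
                                       np.full(30, 1.0))))
    return out


class TestFitMatchPoint:
    def test_exact_absolute_linear_data(self):
        fit = fit_match_point(_abs_linear_series())
        assert fit.match_point == pytest.approx(96.7, abs=1e-4)

    def test_invariant_to_intensity_scaling(self):
        s1 = _abs_linear_series(k=1.0)
        s2 = [(f, ScatteringCurve(c.q, 100.0 * c.intensity, c.sigma))
              for f, c in s1]
        assert fit_match_point(s2).match_point == \
            pytest.approx(fit_match_point(s1).match_point, abs=1e-6)

    def test_match_point_beyond_measured_range_found(self):
        fit = fit_match_point(_abs_linear_series(mp=110.0))
        assert fit.match_point == pytest.approx(110.0, abs=0.01)

    def test_needs_three_distinct_fractions(self):
        with pytest.raises(ValueError):
            fit_match_point(_abs_linear_series(fractions=(0, 100)))

    def test_no_contrast_variation_rejected(self):
        q = np.linspace(0.006, 0.01, 30)
        series = [(f, ScatteringCurve(q, np.zeros(30), np.ones(30)))
                  for f in (0, 50, 100)]
        with pytest.raises(ValueError, match="contrast"):
            fit_match_point(series)


class TestPorodSlope:
    @pytest.mark.parametrize("exponent", [-4.0, -1.0, -2.5])
    def test_exact_power_law_recovered(self, exponent):
        q = np.geomspace(0.01, 0.5, 200)
        c = ScatteringCurve(q, 7.0 * q ** exponent, np.zeros_like(q))
        fit = porod_slope(c, (0.02, 0.4))
        assert fit.slope == pytest.approx(exponent, abs=1e-9)

    def test_fractal_dimension_only_in_mass_fractal_regime(self):
        q = np.geomspace(0.01, 0.5, 100)
        d25 = porod_slope(ScatteringCurve(q, q ** -2.5, np.zeros_like(q)),
                          (0.02, 0.4))
        d4 = porod_slope(ScatteringCurve(q, q ** -4.0, np.zeros_like(q)),
                         (0.02, 0.4))
        assert d25.fractal_dimension == pytest.approx(2.5)
        assert d4.fractal_dimension is None

    def test_nonpositive_intensity_rejected(self):
        q = np.geomspace(0.01, 0.5, 100)
        i = q ** -2.0
        i[50] = -1.0
        with pytest.raises(ValueError):
            porod_slope(ScatteringCurve(q, i, np.zeros_like(q)), (0.02, 0.4))


def _peaky_curve(peaks, widths=0.002, background=lambda q: 1e-4 * q ** -2.4,
                 flat=0.01, n=400):
    q = np.geomspace(0.008, 0.8, n)
    i = background(q) + flat
    for qp, amp in peaks:
        i = i + amp * np.exp(-0.5 * ((q - qp) / widths) ** 2)
    return ScatteringCurve(q, i, np.sqrt(i))


class TestDetectPeaks:
    def test_pure_power_law_has_no_peaks(self):
        rep = detect_peaks(_peaky_curve([]), 0.05)
        assert rep.peaks == []

    def test_interference_pair_recovered_within_grid_resolution(self):
        c = _peaky_curve([(0.025, 0.5), (0.050, 0.2)])
        rep = detect_peaks(c, 0.05)
        pos = rep.positions
        assert len(pos) == 2
        assert pos[0] == pytest.approx(0.025, abs=0.001)
        assert pos[1] == pytest.approx(0.050, abs=0.001)

    def test_single_gaussian_on_flat_background(self):
        c = _peaky_curve([(0.4, 0.05)], widths=0.05,
                         background=lambda q: np.zeros_like(q), flat=0.01)
        rep = detect_peaks(c, 0.05)
        assert len(rep.peaks) == 1
        assert rep.peaks[0].q == pytest.approx(0.4, abs=0.01)

    @settings(derandomize=True, max_examples=20)
    @given(prom=st.floats(0.01, 1.0), slope=st.floats(-3.0, -1.0))
    def test_monotone_curves_never_yield_peaks(self, prom, slope):
        q = np.geomspace(0.01, 0.5, 100)
        c = ScatteringCurve(q, 5.0 * q ** slope + 0.02, np.zeros_like(q))
        assert detect_peaks(c, prom).peaks == []

    def test_short_curves_rejected(self):
        q = np.geomspace(0.01, 0.5, 10)
        with pytest.raises(ValueError):
            detect_peaks(ScatteringCurve(q, q ** -2, np.zeros_like(q)))


class TestBraggSpacing:
    def test_first_order_peak_gives_251_angstroms(self):
        assert bragg_spacing(0.025) == pytest.approx(251.3, abs=0.1)

    def test_identity_at_two_pi(self):
        assert bragg_spacing(2 * np.pi) == pytest.approx(1.0)

    def test_second_order(self):
        assert bragg_spacing(0.05) == pytest.approx(125.66, abs=0.01)

    def test_roundtrip_with_inverse(self):
        for d in (10.0, 251.0, 4.7):
            assert bragg_spacing(2 * np.pi / d) == pytest.approx(d)

    def test_nonpositive_q_rejected(self):
        with pytest.raises(ValueError):
            bragg_spacing(0.0)


def _report(qs):
    return PeakReport([Peak(q, 1.0, 0.01) for q in sorted(qs)])


class TestAssignHarmonics:
    def test_first_and_second_order_give_251(self):
        rep = assign_harmonics(_report([0.025, 0.050]))
        assert [p.order for p in rep.peaks] == [1, 2]
        assert rep.periodicity == pytest.approx(251.3, rel=0.01)

    def test_single_peak_is_fundamental(self):
        rep = assign_harmonics(_report([0.03]))
        assert rep.peaks[0].order == 1
        assert rep.periodicity == pytest.approx(2 * np.pi / 0.03)

    def test_inconsistent_peak_left_unassigned(self):
        rep = assign_harmonics(_report([0.025, 0.040, 0.050]), tol=0.05)
        orders = {round(p.q, 3): p.order for p in rep.peaks}
        assert orders[0.025] == 1
        assert orders[0.050] == 2
        assert orders[0.040] is None

    def test_empty_report_passes_through(self):
        rep = assign_harmonics(PeakReport([]))
        assert rep.peaks == [] and rep.periodicity is None
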