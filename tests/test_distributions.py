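import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import starchcld as sc
from starchcld.distributions import snv_normalize_distribution


def linear_cal(mh, slope=-0.5, intercept=3.0, vel_range=(0.0, 8.0)):
    return sc.CalibrationCurve(
        coefficients=np.array([slope, intercept]), order=1, vel_range=vel_range,
        rh_range=(0.01, 1000.0), residual_rms=0.0, mh=mh)


class TestBaselineCorrect:
    def test_exact_line_goes_to_zero(self):
        v = np.linspace(0, 10, 200)
        chrom = sc.Chromatogram(v, 2.0 + 0.3 * v)
        out = sc.baseline_correct(chrom)
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)

    def test_gaussian_on_zero_baseline_unchanged(self):
        v = np.linspace(0, 10, 500)
        sig = np.exp(-0.5 * ((v - 5) / 0.3) ** 2)
        out = sc.baseline_correct(sc.Chromatogram(v, sig))
        np.testing.assert_allclose(out.signal, sig, atol=1e-9)

    def test_simulated_drift_removed(self, fixtures):
        """Known injected drift: corrected peak area within 1% of the
        drift-free run's area."""
        cld, instrument = fixtures["pea_cameor"]
        clean = sc.simulate_trace(cld, instrument.quiet())
        drifted = sc.simulate_trace(
            cld, instrument.replace(noise_sigma=0.0, drift_slope=0.05))
        corrected = sc.baseline_correct(drifted)
        area_clean = np.trapezoid(clean.signal, clean.elution_volume)
        area_corr = np.trapezoid(corrected.signal, corrected.elution_volume)
        assert area_corr == pytest.approx(area_clean, rel=0.01)

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 0.3])
    def test_out_of_range_anchor_fraction_rejected(self, fraction):
        v = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="anchor_fraction"):
            sc.baseline_correct(sc.Chromatogram(v, v), anchor_fraction=fraction)


class TestWeightFromTrace:
    def test_constant_signal_constant_weight(self, mh):
        """Constant signal c through slope -b calibration gives w = c/b."""
        v = np.linspace(1.0, 5.0, 100)
        chrom = sc.Chromatogram(v, np.full_like(v, 3.0))
        dist = sc.weight_distribution_from_trace(chrom, linear_cal(mh, slope=-0.5))
        np.testing.assert_allclose(dist.w, 3.0 / 0.5, rtol=1e-12)
        assert np.all(np.diff(dist.grid) > 0)

    def test_zero_signal_zero_distribution(self, mh):
        v = np.linspace(1.0, 5.0, 64)
        dist = sc.weight_distribution_from_trace(
            sc.Chromatogram(v, np.zeros_like(v)), linear_cal(mh))
        np.testing.assert_array_equal(dist.w, 0.0)

    def test_mass_conservation_change_of_variables(self, fixtures, calibration):
        """Trapezoidal area of w over log10Rh equals the trace area over
        V_el within 1% (change of variables)."""
        cld, instrument = fixtures["barley_tipple"]
        trace = sc.simulate_trace(cld, instrument.quiet())
        dist = sc.weight_distribution_from_trace(trace, calibration)
        area_v = np.trapezoid(trace.signal, trace.elution_volume)
        area_w = np.trapezoid(dist.w, dist.grid)
        assert area_w == pytest.approx(area_v, rel=0.01)

    def test_extrapolated_mask_carried(self, fixtures, calibration):
        cld, instrument = fixtures["barley_tipple"]
        trace = sc.simulate_trace(cld, instrument.quiet())
        dist = sc.weight_distribution_from_trace(trace, calibration)
        # The fixture spans DP 6-10,000 while the standards stop near
        # Rh 29.6 nm (DP ~4365), so part of the high-DP tail must be flagged,
        # as is the sub-342 Da end of the sampling window.
        assert dist.extrapolated.any()
        assert not dist.extrapolated.all()
        lo, hi = np.log10(calibration.rh_range)
        interior = dist.grid[~dist.extrapolated]
        assert interior.min() > lo - 0.05 and interior.max() < hi + 0.05
        assert dist.grid[dist.extrapolated].max() > hi


class TestDpCoordinate:
    def test_affine_slope_three_over_one_plus_alpha(self, mh):
        grid = np.linspace(-0.3, 1.4, 40)
        dist = sc.WeightDistribution(coord="log10_rh", grid=grid, w=np.ones(40))
        out = sc.to_dp_coordinate(dist, mh, monomer_mass=162.2)
        slopes = np.diff(out.grid) / np.diff(grid)
        np.testing.assert_allclose(slopes, 3.0 / (1.0 + mh.alpha), rtol=1e-9)

    def test_dp100_round_trip(self, mh):
        rh = sc.hydrodynamic_radius(100 * 162.2, mh)
        grid = np.array([np.log10(rh) + d for d in (-0.2, -0.1, 0.0, 0.1, 0.2)])
        dist = sc.WeightDistribution(coord="log10_rh", grid=grid, w=np.ones(5))
        out = sc.to_dp_coordinate(dist, mh, monomer_mass=162.2)
        assert 10.0 ** out.grid[2] == pytest.approx(100.0, rel=1e-9)

    def test_shape_preserved_up_to_constant(self, mh):
        rng = np.random.default_rng(3)
        grid = np.linspace(-0.3, 1.4, 64)
        w = rng.random(64)
        out = sc.to_dp_coordinate(
            sc.WeightDistribution(coord="log10_rh", grid=grid, w=w), mh, 162.2)
        ratio = out.w / w
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)
        assert np.array_equal(np.argsort(out.w), np.argsort(w))

    def test_wrong_coordinate_kind_rejected(self, mh):
        dist = sc.WeightDistribution(
            coord="log10_dp", grid=np.linspace(1, 2, 8), w=np.ones(8))
        with pytest.raises(ValueError, match="log10_rh"):
            sc.to_dp_coordinate(dist, mh, 162.2)


class TestWeightNumberTransforms:
    def test_unit_dp_weight_equals_number(self):
        dist = sc.WeightDistribution(
            coord="log10_dp", grid=np.array([0.0, 1.0]), w=np.array([0.7, 1.0]))
        out = sc.weight_to_number(dist)
        assert out.n[0] == pytest.approx(0.7)       # X = 1 -> N = w
        assert out.n[1] == pytest.approx(0.01)      # X = 10, w = 1 -> 0.01

    @given(hnp.arrays(float, 30, elements=st.floats(0.0, 1e3)))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_machine_precision(self, w):
        grid = np.linspace(0.8, 4.0, 30)
        dist = sc.WeightDistribution(coord="log10_dp", grid=grid, w=w)
        back = sc.number_to_weight(sc.weight_to_number(dist))
        np.testing.assert_allclose(back.w, dist.w, rtol=1e-15, atol=1e-300)
        np.testing.assert_allclose(back.grid, dist.grid, rtol=1e-15)

    def test_constant_number_gives_quadratic_weight(self):
        x = np.linspace(10.0, 100.0, 50)
        out = sc.number_to_weight(sc.NumberDistribution(x=x, n=np.ones(50)))
        np.testing.assert_allclose(out.w, x ** 2, rtol=1e-14)


class TestSnv:
    def test_three_points(self):
        np.testing.assert_allclose(sc.snv_normalize([1.0, 2.0, 3.0]), [-1, 0, 1])

    @given(hnp.arrays(float, st.integers(3, 200),
                      elements=st.floats(-1e6, 1e6, allow_nan=False)))
    @settings(max_examples=100, deadline=None)
    def test_output_mean_zero_sd_one(self, values):
        if np.std(values, ddof=1) < 1e-9:
            return
        out = sc.snv_normalize(values)
        assert abs(np.mean(out)) < 1e-9
        assert np.std(out, ddof=1) == pytest.approx(1.0, abs=1e-9)

    @given(a=st.floats(0.01, 100), b=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        values = np.array([0.3, 1.7, -2.2, 5.5, 0.0, 4.1])
        np.testing.assert_allclose(
            sc.snv_normalize(a * values + b), sc.snv_normalize(values),
            rtol=1e-9, atol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            sc.snv_normalize(np.full(10, 3.3))


class TestAreaNormalize:
    def _rect(self, height=1.0):
        return sc.WeightDistribution(
            coord="log10_dp", grid=np.linspace(1.0, 3.0, 101),
            w=np.full(101, height))

    def test_unit_rectangle_height(self):
        out = sc.area_normalize(self._rect(7.0))
        np.testing.assert_allclose(out.w, 0.5, rtol=1e-12)  # width-2 rectangle

    def test_idempotent_and_scale_invariant(self):
        once = sc.area_normalize(self._rect(3.0))
        twice = sc.area_normalize(once)
        scaled = sc.area_normalize(self._rect(21.0))
        np.testing.assert_allclose(twice.w, once.w, rtol=1e-12)
        np.testing.assert_allclose(scaled.w, once.w, rtol=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            sc.area_normalize(self._rect(0.0))


class TestResampleUniform:
    def test_clips_to_min_dp_and_uniform_grid(self):
        grid = np.linspace(0.0, 4.0, 333)
        dist = sc.WeightDistribution(coord="log10_dp", grid=grid, w=np.exp(-grid))
        out = sc.resample_uniform(dist, n=200, min_dp=6.0)
        assert out.grid[0] == pytest.approx(np.log10(6.0))
        steps = np.diff(out.grid)
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_snv_distribution_tagged(self):
        dist = sc.WeightDistribution(
            coord="log10_dp", grid=np.linspace(1, 3, 50),
            w=np.sin(np.linspace(0, 3, 50)) + 2)
        out = snv_normalize_distribution(dist)
        assert out.normalization == "snv"
        assert abs(out.w.mean()) < 1e-12
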