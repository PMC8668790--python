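import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import enamelseason as es
from enamelseason.core import InputSeries, ToothGeometry
from enamelseason.errors import OutOfRangeError, ResolutionError
from enamelseason.forward_model import (
    build_averaging_matrix,
    build_kernel,
    forward_profile,
    kernel_support_mm,
    position_to_months,
)
from enamelseason.synthetic_data import monthly_to_input, synth_water_year

geometries = st.builds(
    ToothGeometry,
    la=st.floats(2.0, 12.0),
    lm=st.floats(5.0, 20.0),
    fi=st.floats(0.05, 0.95),
    sample_length=st.floats(0.5, 3.0),
    depth_fraction=st.floats(0.3, 1.0),
    growth_rate=st.floats(20.0, 45.0),
)


def sine_input(lo=-2.0, hi=45.0, step=0.1, amplitude=5.58, mean=7.9, wavelength=30.0):
    pos = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    return InputSeries(pos, mean - amplitude * np.cos(2 * np.pi * pos / wavelength))


def kernel_oracle_prediction(geometry, input_series, center, fine=0.005):
    """Direct Riemann-sum evaluation of the triple-boxcar average.

    Independent of the discrete kernel machinery: integrates the
    continuous input over the apposition, maturation and drill windows.
    """
    wa = geometry.la * geometry.depth_fraction
    u = np.arange(center - geometry.sample_length / 2, center + geometry.sample_length / 2, fine)
    m = lambda x: np.interp(x, input_series.positions, input_series.values)
    total = 0.0
    for ui in u:
        xa = np.arange(ui, ui + wa, fine)
        xm = np.arange(ui, ui + geometry.lm, fine)
        total += geometry.fi * m(xa).mean() + (1 - geometry.fi) * m(xm).mean()
    return total / u.size


class TestKernel:
    def test_degenerate_geometry_is_identity_spike(self):
        step = 0.1
        g = ToothGeometry(la=step / 0.75, lm=step, fi=1 - 1e-9, sample_length=step)
        kernel, offset = build_kernel(g, step)
        assert offset == 0
        np.testing.assert_allclose(kernel, [1.0])

    def test_default_geometry_support(self, geometry):
        kernel, offset = build_kernel(geometry, 0.1)
        span = (kernel.size - 1) * 0.1
        expected = max(geometry.la * 0.75, geometry.lm) + geometry.sample_length
        assert span == pytest.approx(expected, abs=0.2)
        assert offset == pytest.approx(-geometry.sample_length / 2 / 0.1, abs=1)

    @given(g=geometries)
    @settings(derandomize=True, max_examples=50)
    def test_kernel_normalized_for_random_geometries(self, g):
        kernel, _ = build_kernel(g, 0.05)
        assert abs(kernel.sum() - 1.0) < 1e-9
        assert (kernel >= 0).all()

    def test_matches_continuous_convolution_oracle(self, geometry):
        inp = sine_input(step=0.05)
        prof = forward_profile(inp, geometry, [10.0, 16.0, 22.0])
        for center, value in zip(prof.positions, prof.replicate_means()):
            oracle = kernel_oracle_prediction(geometry, inp, center)
            assert value == pytest.approx(oracle, abs=0.02)

    def test_step_too_coarse_raises(self, geometry):
        with pytest.raises(ResolutionError):
            build_kernel(geometry, 2.0)


class TestAveragingMatrix:
    def test_rows_sum_to_one_for_random_geometries(self):
        rng = np.random.default_rng(42)
        inp = sine_input()
        for _ in range(50):
            g = ToothGeometry(
                la=rng.uniform(2, 12),
                lm=rng.uniform(5, 20),
                fi=rng.uniform(0.05, 0.95),
                sample_length=rng.uniform(0.5, 3),
                depth_fraction=rng.uniform(0.3, 1.0),
            )
            centers = np.sort(rng.uniform(0.0, 40.0, rng.integers(3, 12)))
            matrix = build_averaging_matrix(g, inp, centers)
            np.testing.assert_allclose(matrix.weights.sum(axis=1), 1.0, atol=1e-9)
            assert (matrix.weights >= 0).all()

    def test_constant_input_reproduced_exactly(self, geometry):
        inp = InputSeries(np.arange(0, 40, 0.1), np.full(400, 14.0))
        prof = forward_profile(inp, geometry, [2.0, 10.0, 20.0])
        np.testing.assert_allclose(prof.replicate_means(), 14.0, atol=1e-9)

    def test_interior_rows_equal_kernel(self, geometry):
        inp = sine_input()
        kernel, offset = build_kernel(geometry, 0.1)
        matrix = build_averaging_matrix(geometry, inp, [12.0])
        row = matrix.weights[0]
        i0 = int(round((12.0 - inp.positions[0]) / 0.1)) + offset
        np.testing.assert_allclose(row[i0 : i0 + kernel.size], kernel, atol=1e-12)
        assert row[:i0].sum() == 0 and row[i0 + kernel.size :].sum() == 0

    def test_center_outside_grid_raises(self, geometry):
        inp = sine_input(lo=0.0, hi=20.0)
        with pytest.raises(OutOfRangeError):
            build_averaging_matrix(geometry, inp, [25.0])


class TestForwardProfile:
    def test_never_exceeds_input_extrema(self, geometry):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = rng.uniform(5, 20, 430)
            inp = InputSeries(-2.0 + 0.1 * np.arange(430), vals)
            out = forward_profile(inp, geometry, [5.0, 15.0, 25.0]).replicate_means()
            assert out.min() >= vals.min() - 1e-9
            assert out.max() <= vals.max() + 1e-9

    def test_linear_in_input(self, geometry):
        pos = -2.0 + 0.1 * np.arange(430)
        rng = np.random.default_rng(4)
        m1, m2 = rng.uniform(0, 20, (2, 430))
        centers = [5.0, 12.0, 20.0]
        f = lambda v: forward_profile(
            InputSeries(pos, v), geometry, centers
        ).replicate_means()
        combo = f(0.3 * m1 + 1.7 * m2)
        np.testing.assert_allclose(combo, 0.3 * f(m1) + 1.7 * f(m2), atol=1e-9)

    def test_sinusoid_is_damped(self, geometry):
        inp = sine_input()
        out = forward_profile(inp, geometry, 4.0 + 2.0 * np.arange(12)).replicate_means()
        assert np.ptp(out) < 11.16

    def test_grid_convergence_on_halving(self, geometry):
        water = synth_water_year()
        monthly = es.water_to_phosphate(water.values)
        centers = 1.0 + 2.0 * np.arange(12)
        outs = {}
        for step in (0.1, 0.05):
            inp = monthly_to_input(monthly, geometry, -1.0, 40.0, 1.0, step=step)
            outs[step] = forward_profile(inp, geometry, centers).replicate_means()
        assert np.max(np.abs(outs[0.1] - outs[0.05])) < 0.01

    def test_identity_limit(self):
        step = 0.1
        g = ToothGeometry(la=step / 0.75, lm=step, fi=1 - 1e-9, sample_length=step)
        inp = sine_input(step=step)
        centers = inp.positions[50:400:25]
        out = forward_profile(inp, g, centers).replicate_means()
        np.testing.assert_allclose(out, inp.values[50:400:25], atol=1e-6)

    @pytest.mark.parametrize("param", ["lm", "sample_length"])
    def test_monotone_damping(self, param):
        """Wider maturation or drill windows never amplify a seasonal cycle."""
        water = synth_water_year()
        monthly = es.water_to_phosphate(water.values)
        centers = 1.0 + 2.0 * np.arange(12)
        values = {"lm": [8.0, 10.6, 13.3, 16.0], "sample_length": [1.0, 2.0, 3.0]}
        amps = []
        for v in values[param]:
            g = ToothGeometry(**{param: v})
            inp = monthly_to_input(monthly, g, -4.0, 45.0, 1.0)
            amps.append(np.ptp(forward_profile(inp, g, centers).replicate_means()))
        assert all(b <= a + 1e-9 for a, b in zip(amps, amps[1:]))


class TestPositionToMonths:
    @pytest.mark.parametrize(
        "span, rate, months", [(30.0, 30.0, 12.0), (45.0, 30.0, 18.0), (0.0, 30.0, 0.0)]
    )
    def test_span_to_months(self, span, rate, months):
        g = ToothGeometry(growth_rate=rate)
        out = position_to_months(np.array([5.0, 5.0 + span]), g)
        assert out[-1] == pytest.approx(months)
        assert out[0] == 0.0

    def test_inverse_proportional_to_growth_rate(self):
        pos = np.array([0.0, 10.0, 21.0])
        slow = position_to_months(pos, ToothGeometry(growth_rate=15.0))
        fast = position_to_months(pos, ToothGeometry(growth_rate=30.0))
        np.testing.assert_allclose(slow, 2.0 * fast)
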