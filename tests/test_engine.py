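"""TG-43 forward engine: geometry factor, interpolation, dose equations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from brachydose.engine import (along_away_table, dose_rate_1d, dose_rate_2d,
                               geometry_factor, interp_parameters)
from brachydose.fixtures import reference_parameters


def line_source_G_numeric(r, theta_deg, L):
    """Independent oracle: (1/L) integral dl / d(l)^2 along the segment."""
    th = np.radians(theta_deg)
    y, z = r * np.sin(th), r * np.cos(th)
    val, _ = quad(lambda l: 1.0 / ((z - l) ** 2 + y**2), -L / 2, L / 2,
                  limit=500, epsabs=1e-14, epsrel=1e-13)
    return val / L


class TestGeometryFactor:
    def test_point_source_limit(self):
        assert geometry_factor(2.0, 37.0, 0.0) == pytest.approx(0.25)

    def test_transverse_closed_form(self):
        # beta = 2 arctan(L / 2r) at theta = 90
        expected = 2 * np.arctan(0.05) / 0.1
        assert geometry_factor(1.0, 90.0, 0.1) == pytest.approx(expected, rel=1e-12)
        assert geometry_factor(1.0, 90.0, 0.1) == pytest.approx(0.999168, abs=5e-7)

    def test_on_axis_degenerate_form(self):
        assert geometry_factor(1.0, 0.0, 0.1) == pytest.approx(
            1.0 / (1 - 0.0025), rel=1e-12)
        assert geometry_factor(1.0, 180.0, 0.1) == pytest.approx(
            1.0 / (1 - 0.0025), rel=1e-12)

    @pytest.mark.parametrize("r, theta, L", [
        (1.0, 90.0, 0.1), (0.25, 5.0, 0.2), (10.0, 0.01, 0.2),
        (2.0, 150.0, 0.1), (0.25, 90.0, 0.2), (5.0, 45.0, 0.15),
    ])
    def test_matches_numerical_integration(self, r, theta, L):
        assert geometry_factor(r, theta, L) == pytest.approx(
            line_source_G_numeric(r, theta, L), rel=1e-9)

    @given(st.floats(0.25, 10.0), st.floats(0.0, 180.0))
    def test_mirror_symmetry(self, r, theta):
        assert geometry_factor(r, theta, 0.2) == pytest.approx(
            geometry_factor(r, 180.0 - theta, 0.2), rel=1e-12)

    @given(st.floats(0.25, 10.0), st.floats(1.0, 179.0))
    def test_point_source_limit_bound(self, r, theta):
        """|G L / G 0 - 1| < L^2 / (2 r^2) uniformly for r >= 0.25."""
        L = 0.1
        rel = abs(geometry_factor(r, theta, L) * r**2 - 1.0)
        assert rel < L**2 / (2 * r**2)

    def test_field_point_on_segment_rejected(self):
        with pytest.raises(ValueError):
            geometry_factor(0.04, 0.0, 0.1)
        with pytest.raises(ValueError):
            geometry_factor(1.0, 90.0, -0.1)


class TestInterpolation:
    def test_exact_at_table_nodes(self, fixtures):
        params = reference_parameters("1_2", fixtures)
        for r in (1.0, 2.0, 10.0):
            g, F = interp_parameters(params, r, 90.0)
            assert F == 1.0
        g, _ = interp_parameters(params, 1.0)
        assert g == 1.0
        g, F = interp_parameters(params, 2.0, 140.0)
        assert g == pytest.approx(0.981, abs=1e-12)
        assert F == pytest.approx(0.983, abs=1e-12)

    def test_theta_clamped_outside_table(self, fixtures):
        params = reference_parameters("1_2", fixtures)
        _, f_edge = interp_parameters(params, 5.0, 175.0)
        _, f_beyond = interp_parameters(params, 5.0, 179.0)
        assert f_beyond == pytest.approx(f_edge, rel=1e-12)

    def test_r_outside_table_rejected(self, fixtures):
        params = reference_parameters("1_2", fixtures)
        with pytest.raises(ValueError):
            interp_parameters(params, 12.0)
        g, _ = interp_parameters(params, 12.0, 90.0, extrapolate=True)
        assert g > 0


class TestDoseRates:
    def test_reference_point_returns_lambda(self, fixtures):
        params = reference_parameters("1_2", fixtures)
        assert dose_rate_2d(params, 1.0, 1.0, 90.0) == pytest.approx(1.115)
        assert dose_rate_2d(params, 0.0, 1.0, 90.0) == 0.0

    def test_transverse_chain_at_2cm(self, fixtures):
        """Lambda x g(2) x G-ratio reproduces the hand-evaluated 0.2736."""
        params = reference_parameters("1_2", fixtures)
        assert dose_rate_2d(params, 1.0, 2.0, 90.0) == pytest.approx(0.2736,
                                                                     abs=5e-5)

    def test_1d_equation_uses_phi_an(self, fixtures):
        params = reference_parameters("1_2", fixtures)
        # phi_an(2 cm) = 0.993 from the packaged table
        expected = 0.993 * dose_rate_2d(params, 1.0, 2.0, 90.0)
        assert dose_rate_1d(params, 1.0, 2.0) == pytest.approx(expected, rel=1e-9)
        assert dose_rate_1d(params, 1.0, 2.0) == pytest.approx(0.2717, abs=5e-5)

    def test_linear_in_sk(self, fixtures):
        params = reference_parameters("3", fixtures)
        d1 = dose_rate_2d(params, 1.0, 3.0, 40.0)
        assert dose_rate_2d(params, 2.5, 3.0, 40.0) == pytest.approx(2.5 * d1)

    def test_continuous_across_nodes(self, fixtures):
        params = reference_parameters("1_2", fixtures)
        eps = 1e-9
        for r, th in [(2.0, 90.0), (3.0, 120.0)]:
            lo = dose_rate_2d(params, 1.0, r - eps, th)
            hi = dose_rate_2d(params, 1.0, r + eps, th)
            assert lo == pytest.approx(hi, rel=1e-6)


class TestAlongAway:
    def test_reference_cell_is_lambda(self, fixtures):
        params = reference_parameters("1_2", fixtures)
        tab = along_away_table(params, y_grid=[1.0], z_grid=[0.0])
        assert tab.values[0, 0] == pytest.approx(1.115)

    def test_full_qa_grid_finite_and_positive(self, fixtures):
        params = reference_parameters("1_2", fixtures)
        y = [0.0, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0]
        z = [-10, -5, -2, -1, 0, 1, 2, 5, 10]
        tab = along_away_table(params, y, z)
        finite = np.isfinite(tab.values)
        assert finite.sum() > 0
        assert np.all(tab.values[finite] > 0)
        # the in-source cell (0, 0) and r > 10 corners are missing
        assert not np.isfinite(tab.values[z.index(0), y.index(0.0)])
        assert not np.isfinite(tab.values[z.index(10), y.index(10.0)])

    def test_symmetric_in_z_with_symmetrized_F(self, synthetic_params):
        tab = along_away_table(synthetic_params, [0.5, 1.0, 3.0],
                               [-5, -2, -1, 1, 2, 5])
        np.testing.assert_allclose(tab.values, tab.values[::-1], rtol=1e-9)
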