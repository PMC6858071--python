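"""Forward PDE model: death function, operator limits, analytic oracles,
conservation, positivity, and grid convergence."""

import numpy as np
import pytest

from phenodrift import ModelParameters, PhenotypeDensity, ToleranceGrid, death_rate, simulate
from phenodrift.forward import assemble_operator, rhs


def gaussian_pulse(grid, center, width=0.3):
    values = np.exp(-0.5 * ((grid.x - center) / width) ** 2)
    return PhenotypeDensity(grid, values / values.sum())


class TestDeathRate:
    @pytest.mark.parametrize(
        "x, F, alpha, b, expected",
        [
            (5.0, 4.0, 0.3, 0.5, 0.0),  # at/above threshold: no death
            (4.0, 4.0, 0.3, 0.5, 0.0),
            (0.0, 4.0, 0.202, 0.770, 0.808),
            (2.0, 4.0, 0.2, 0.770, 0.492),
        ],
    )
    def test_values(self, x, F, alpha, b, expected):
        assert np.isclose(death_rate(x, F, alpha, b), expected)

    def test_positive_below_threshold(self):
        x = np.linspace(0, 3.99, 50)
        assert np.all(death_rate(x, 4.0, 0.1, 1.0) > 0)


class TestOperator:
    def test_growth_only_reduces_to_scaling(self):
        grid = ToleranceGrid(2.0, 0.01)
        f = rhs(grid, ModelParameters(r_c=0.3))
        y = np.linspace(1, 2, grid.n_bins)
        assert np.allclose(f(0.0, y), 0.3 * y)

    def test_diffusion_conserves_mass_discretely(self):
        grid = ToleranceGrid(2.0, 0.01)
        f = rhs(grid, ModelParameters(r_c=0.0, D=0.05))
        y = np.random.default_rng(1).uniform(size=grid.n_bins)
        assert abs(f(0.0, y).sum()) < 1e-9 * y.sum()

    @pytest.mark.parametrize("v", [0.3, -0.3])
    def test_advection_conserves_mass_discretely(self, v):
        grid = ToleranceGrid(2.0, 0.01)
        f = rhs(grid, ModelParameters(r_c=0.0, v=v))
        y = np.random.default_rng(2).uniform(size=grid.n_bins)
        assert abs(f(0.0, y).sum()) < 1e-9 * y.sum()

    def test_operator_is_banded_consistent(self):
        grid = ToleranceGrid(1.0, 0.1)
        p = ModelParameters(r_c=0.1, alpha=0.2, b=0.5, D=0.01, v=0.05, F=0.5)
        ab = assemble_operator(grid, p)
        f = rhs(grid, p)
        y = np.random.default_rng(3).uniform(size=grid.n_bins)
        dense = np.zeros((grid.n_bins, grid.n_bins))
        n = grid.n_bins
        for j in range(n):
            dense[j, j] = ab[1][j]
            if j > 0:
                dense[j - 1, j] = ab[0][j]
            if j < n - 1:
                dense[j + 1, j] = ab[2][j]
        assert np.allclose(dense @ y, f(0.0, y))


class TestSimulateOracles:
    def test_pure_exponential_growth(self):
        grid = ToleranceGrid(4.0, 0.01)
        init = gaussian_pulse(grid, 2.0)
        out = simulate(init, ModelParameters(r_c=0.2), [0.0, 5.0])
        assert np.allclose(out.densities[1], init.values * np.e, rtol=1e-6)

    def test_growth_death_closed_form_per_bin(self):
        """With D = v = 0 each bin evolves independently at rate r − H(x)."""
        grid = ToleranceGrid(8.0, 0.02)
        p = ModelParameters(r_c=0.2, alpha=0.15, b=0.6, F=4.0)
        init = PhenotypeDensity(grid, np.full(grid.n_bins, 50.0))
        t = 6.0
        out = simulate(init, p, [0.0, t])
        expected = init.values * np.exp((p.r_c - death_rate(grid.x, p.F, p.alpha, p.b)) * t)
        assert np.allclose(out.densities[1], expected, rtol=1e-6)

    def test_diffusion_heat_kernel_variance(self):
        grid = ToleranceGrid(12.0, 0.01)
        init = PhenotypeDensity(grid, np.zeros(grid.n_bins))
        init.values[grid.index_of(4.0)] = 1.0
        D, t = 0.02, 10.0
        out = simulate(init, ModelParameters(r_c=0.0, D=D), [0.0, t])
        d = out.densities[1]
        m = np.dot(grid.x, d) / d.sum()
        var = np.dot((grid.x - m) ** 2, d) / d.sum()
        assert np.isclose(var, 2 * D * t, rtol=0.02)
        assert np.isclose(d.sum(), 1.0, rtol=1e-6)

    def test_advection_translation(self):
        grid = ToleranceGrid(12.0, 0.01)
        init = gaussian_pulse(grid, 6.0)
        v, t = 0.285, 7.0
        out = simulate(init, ModelParameters(r_c=0.0, v=v), [0.0, t])
        d = out.densities[1]
        center = np.dot(grid.x, d) / d.sum()
        assert abs(center - (6.0 - v * t)) <= grid.dx + 0.02  # upwind smearing tolerated
        assert np.isclose(d.sum(), 1.0, rtol=1e-6)

    def test_mass_conserved_over_24h_transitions_only(self):
        grid = ToleranceGrid(12.0, 0.01)
        init = gaussian_pulse(grid, 6.0, width=0.5)
        out = simulate(init, ModelParameters(r_c=0.0, D=0.05, v=0.1), [0.0, 24.0])
        assert np.isclose(out.densities[1].sum(), 1.0, rtol=1e-6)

    def test_advection_sign_convention_lowers_mean_tolerance(self):
        grid = ToleranceGrid(12.0, 0.01)
        init = gaussian_pulse(grid, 6.0, width=0.5)
        out = simulate(init, ModelParameters(r_c=0.0, v=0.2), [0.0, 2.0, 4.0, 8.0])
        means = [np.dot(grid.x, d) / d.sum() for d in out.densities]
        assert np.all(np.diff(means) < 0)

    def test_positivity(self):
        grid = ToleranceGrid(12.0, 0.01)
        init = gaussian_pulse(grid, 4.0)
        out = simulate(
            init, ModelParameters(r_c=0.1, alpha=0.2, b=0.7, D=0.02, v=0.05, F=4.0), [0.0, 20.0]
        )
        assert np.all(out.densities >= 0)


class TestGridConvergence:
    def test_halving_dx_changes_binned_output_little(self):
        from phenodrift import bin_to_data_resolution, make_initial_distribution

        p = ModelParameters(r_c=0.195, alpha=0.202, b=0.770, D=0.019, F=4.0)
        levels = np.arange(0.0, 11.0)
        out = {}
        for dx in (0.02, 0.01):
            grid = ToleranceGrid(12.0, dx)
            init = make_initial_distribution(grid, N_total=3e6)
            res = simulate(init, p, [0.0, 18.0])
            out[dx] = bin_to_data_resolution(res.at(18.0), levels).counts
        rel = np.abs(out[0.02] - out[0.01]) / (np.abs(out[0.01]) + 1.0)
        assert rel.max() < 0.005


class TestValidation:
    def test_times_must_start_at_zero(self):
        grid = ToleranceGrid(2.0, 0.01)
        init = gaussian_pulse(grid, 1.0)
        with pytest.raises(ValueError, match="clock"):
            simulate(init, ModelParameters(r_c=0.1), [1.0, 2.0])

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(r_c=0.1, b=1.5)
        with pytest.raises(ValueError):
            ModelParameters(r_c=0.1, alpha=-0.1)
        with pytest.raises(ValueError):
            ModelParameters(r_c=-0.1)
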