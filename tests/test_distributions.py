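"""Cumulative/density transforms, detection-limit extension, averaging,
spline interpolation, and binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenodrift import (
    CumulativeDistribution,
    DistributionSeries,
    PhenotypeDensity,
    ToleranceGrid,
    apply_detection_limit_extension,
    average_replicates,
    bin_to_data_resolution,
    cumulative_to_density,
    density_to_cumulative,
    interpolate_initial_condition,
    monotonize,
)
from phenodrift.distributions import EXTENSION_CFU_PER_ML


def series_from_rows(rows, condition="selection", substrate="methanol"):
    frame = pd.DataFrame(rows, columns=["replicate", "time_h", "tolerance_mM", "cfu_per_ml"])
    return DistributionSeries(condition, substrate, frame)


class TestCumulativeDensityTransform:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([100, 60, 10, 0], [40, 50, 10, 0]),
            ([5, 5, 5], [0, 0, 5]),
            ([7, 0], [7, 0]),
        ],
    )
    def test_differencing(self, counts, expected):
        cum = CumulativeDistribution(np.arange(len(counts), dtype=float), counts)
        assert np.allclose(cumulative_to_density(cum), expected)

    def test_non_monotone_rejected(self):
        cum = CumulativeDistribution([0.0, 1.0, 2.0], [100, 110, 0])
        with pytest.raises(ValueError, match="monotonize"):
            cumulative_to_density(cum)

    def test_inverse(self):
        levels = np.arange(4.0)
        cum = density_to_cumulative(np.array([40.0, 50, 10, 0]), levels)
        assert np.allclose(cum.counts, [100, 60, 10, 0])
        zero = density_to_cumulative(np.zeros(4), levels)
        assert np.allclose(zero.counts, 0)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            density_to_cumulative(np.array([1.0, -0.5, 0.0]), np.arange(3.0))

    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=15)
    )
    @settings(deadline=None, max_examples=50)
    def test_round_trip_identity(self, density):
        """Differencing and accumulating are exact mutual inverses."""
        density = np.asarray(density)
        levels = np.arange(density.size, dtype=float)
        cum = density_to_cumulative(density, levels)
        assert np.allclose(cumulative_to_density(cum), density, rtol=1e-12, atol=1e-6)
        back = density_to_cumulative(cumulative_to_density(cum), levels)
        assert np.allclose(back.counts, cum.counts, rtol=1e-12, atol=1e-6)

    def test_density_total_equals_cumulative_at_zero(self):
        cum = CumulativeDistribution(np.arange(5.0), [90.0, 40, 12, 3, 1])
        assert np.isclose(cumulative_to_density(cum).sum(), 90.0)


class TestDetectionLimitExtension:
    def rows(self, values_by_rep, time=2.0):
        rows = []
        for rep, values in values_by_rep.items():
            for lv, v in enumerate(values):
                rows.append((rep, time, float(lv * 2), float(v)))
        return rows

    def test_gap_below_observation_filled(self):
        # level 6 mM (index 3) all-zero but level 8 mM has a colony: rule (a)
        s = series_from_rows(
            self.rows({"r1": [100, 50, 10, 0, 5], "r2": [90, 40, 8, 0, 0], "r3": [95, 45, 9, 0, 0]})
        )
        out = apply_detection_limit_extension(s)
        at6 = out.frame[np.isclose(out.frame["tolerance_mM"], 6.0)]
        assert np.isclose(at6["cfu_per_ml"].sum(), EXTENSION_CFU_PER_ML)
        assert int((at6["cfu_per_ml"] > 0).sum()) == 1

    def test_first_level_beyond_last_observation(self):
        # last observation at 4 mM: 6 mM gets the colony, 8+ stay zero: rule (b)
        s = series_from_rows(
            self.rows({"r1": [100, 50, 10, 0, 0], "r2": [90, 40, 8, 0, 0], "r3": [95, 45, 9, 0, 0]})
        )
        out = apply_detection_limit_extension(s)
        at6 = out.frame[np.isclose(out.frame["tolerance_mM"], 6.0)]
        at8 = out.frame[np.isclose(out.frame["tolerance_mM"], 8.0)]
        assert np.isclose(at6["cfu_per_ml"].sum(), EXTENSION_CFU_PER_ML)
        assert np.isclose(at8["cfu_per_ml"].sum(), 0.0)

    def test_all_nonzero_unchanged(self):
        s = series_from_rows(
            self.rows({"r1": [100, 50, 10, 5, 2], "r2": [90, 40, 8, 4, 1], "r3": [95, 45, 9, 5, 2]})
        )
        out = apply_detection_limit_extension(s)
        pd.testing.assert_frame_equal(out.frame, s.frame)

    def test_idempotent(self):
        s = series_from_rows(
            self.rows({"r1": [100, 50, 10, 0, 0], "r2": [90, 40, 8, 0, 0], "r3": [95, 45, 9, 0, 0]})
        )
        once = apply_detection_limit_extension(s)
        twice = apply_detection_limit_extension(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_single_nonzero_replicate_blocks_extension(self):
        # one replicate saw a colony at 6 mM: not "all replicates zero"
        s = series_from_rows(
            self.rows({"r1": [100, 50, 10, 3, 0], "r2": [90, 40, 8, 0, 0], "r3": [95, 45, 9, 0, 0]})
        )
        out = apply_detection_limit_extension(s)
        at6 = out.frame[np.isclose(out.frame["tolerance_mM"], 6.0)]
        assert np.isclose(at6["cfu_per_ml"].sum(), 3.0)


class TestAverageReplicates:
    def test_extension_example_average(self):
        """One extended replicate at 90.9 CFU/mL averages to 30.3 over three."""
        rows = []
        for rep, v in [("r1", EXTENSION_CFU_PER_ML), ("r2", 0.0), ("r3", 0.0)]:
            rows += [(rep, 2.0, 0.0, 1000.0), (rep, 2.0, 1.0, v)]
        out = average_replicates(series_from_rows(rows))
        at1 = out.at(2.0).counts[1]
        assert np.isclose(at1, EXTENSION_CFU_PER_ML / 3)
        assert np.isclose(at1, 30.3, atol=0.01)

    def test_plain_mean(self):
        rows = []
        for rep, v in [("r1", 10.0), ("r2", 20.0), ("r3", 30.0)]:
            rows += [(rep, 0.0, 0.0, 100.0), (rep, 0.0, 1.0, v)]
        out = average_replicates(series_from_rows(rows))
        assert np.isclose(out.at(0.0).counts[1], 20.0)
        assert out.replicates == ["mean"]

    def test_mismatched_ladders_rejected(self):
        rows = [("r1", 0.0, 0.0, 5.0), ("r1", 0.0, 1.0, 2.0), ("r2", 0.0, 0.0, 5.0)]
        with pytest.raises(ValueError, match="ladder"):
            series_from_rows(rows)


class TestInterpolation:
    def coarse(self):
        levels = np.arange(0.0, 7.0)
        counts = 2e6 * 10.0 ** (-levels)  # exponential tolerance distribution
        return CumulativeDistribution(levels, counts)

    def test_knots_reproduced_and_monotone(self):
        grid = ToleranceGrid(8.0, 0.01)
        den = interpolate_initial_condition(self.coarse(), grid)
        fine_cum = np.cumsum(den.values[::-1])[::-1]
        for lv, c in zip(self.coarse().levels, self.coarse().counts):
            assert np.isclose(fine_cum[grid.index_of(lv)], c, rtol=1e-9)
        assert np.all(np.diff(fine_cum) <= 1e-9 * fine_cum[0])

    def test_mass_equals_level0_count(self):
        grid = ToleranceGrid(8.0, 0.01)
        den = interpolate_initial_condition(self.coarse(), grid)
        assert np.isclose(den.total, self.coarse().counts[0], rtol=1e-12)

    def test_non_monotone_rejected(self):
        cum = CumulativeDistribution([0.0, 1.0, 2.0], [10.0, 12.0, 1.0])
        grid = ToleranceGrid(4.0, 0.01)
        with pytest.raises(ValueError, match="monotonize"):
            interpolate_initial_condition(cum, grid)
        # and monotonizing first makes it acceptable
        interpolate_initial_condition(monotonize(cum), grid)

    def test_narrow_grid_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            interpolate_initial_condition(self.coarse(), ToleranceGrid(4.0, 0.01))


class TestBinning:
    def test_uniform_density_split(self):
        grid = ToleranceGrid(3.0, 0.01)
        values = np.zeros(grid.n_bins)
        in_range = grid.x < 2.0  # uniform over [0, 2)
        values[in_range] = 100.0 / in_range.sum()
        cum = bin_to_data_resolution(PhenotypeDensity(grid, values), np.array([0.0, 1.0, 2.0]))
        assert np.allclose(cum.counts, [100.0, 50.0, 0.0])

    def test_mass_conserved(self):
        grid = ToleranceGrid(12.0, 0.01)
        rng = np.random.default_rng(0)
        values = rng.uniform(size=grid.n_bins)
        cum = bin_to_data_resolution(PhenotypeDensity(grid, values), np.arange(0.0, 11.0))
        assert np.isclose(cum.counts[0], values.sum(), rtol=1e-12)

    def test_misaligned_levels_rejected(self):
        grid = ToleranceGrid(12.0, 0.01)
        with pytest.raises(ValueError, match="grid"):
            bin_to_data_resolution(
                PhenotypeDensity(grid, np.ones(grid.n_bins)), np.array([0.0, 1.0035])
            )

    def test_round_trip_through_spline(self):
        """Interpolate a coarse distribution to the fine grid, then re-bin:
        the original counts return to well under 1% relative error."""
        levels = np.arange(0.0, 7.0)
        counts = 2e6 * 10.0 ** (-levels)
        cum = CumulativeDistribution(levels, counts)
        grid = ToleranceGrid(8.0, 0.01)
        den = interpolate_initial_condition(cum, grid)
        back = bin_to_data_resolution(den, levels)
        assert np.allclose(back.counts, counts, rtol=1e-9)
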