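"""Monthly-to-anomaly preprocessing, derived indices and masks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from droughtthresh.cubes import MonthlyCube
from droughtthresh.preprocessing import (
    aridity_index,
    block_aggregate,
    compute_kndvi,
    detrend,
    mask_invalid,
    season_mean,
)


def monthly(values, indicator="NDVI", grid=None):
    return MonthlyCube(np.asarray(values, dtype=float), indicator=indicator, grid=grid)


class TestKndvi:
    @pytest.mark.parametrize(
        "ndvi, expected",
        [
            (0.0, 0.0),
            (0.5, np.tanh(0.25)),  # 0.24492 from an independent evaluator
            (1.0, np.tanh(1.0)),  # 0.76159
        ],
    )
    def test_values(self, ndvi, expected):
        assert compute_kndvi(ndvi) == pytest.approx(expected, abs=1e-5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_kndvi(1.2)

    def test_missing_propagates(self):
        out = compute_kndvi(np.array([0.3, np.nan]))
        assert np.isfinite(out[0]) and np.isnan(out[1])

    @given(st.floats(min_value=-1.0, max_value=1.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_range_and_symmetry(self, x):
        v = compute_kndvi(x)
        assert 0.0 <= v <= np.tanh(1.0)
        assert v == pytest.approx(compute_kndvi(-x))


class TestMasking:
    def test_ndvi_low_values_removed_boundary_kept(self):
        vals = np.full((1, 3, 12), 0.5)
        vals[0, 0, 0] = 0.05
        vals[0, 0, 1] = 0.1
        out = mask_invalid(monthly(vals, "NDVI"))
        assert np.isnan(out.values[0, 0, 0])  # < 0.1 removed
        assert out.values[0, 0, 1] == 0.1  # boundary kept (strict <)

    def test_nirv_zero_removed(self):
        vals = np.full((1, 3, 12), 0.2)
        vals[0, 1, 3] = 0.0
        out = mask_invalid(monthly(vals, "NIRv"))
        assert np.isnan(out.values[0, 1, 3])

    def test_other_indicator_untouched(self):
        vals = np.full((1, 3, 12), -5.0)
        out = mask_invalid(monthly(vals, "SMsurf"))
        np.testing.assert_array_equal(out.values, vals)

    def test_unknown_indicator_with_required_rule(self):
        with pytest.raises(ValueError):
            mask_invalid(monthly(np.zeros((1, 3, 12)), "XYZ"), require_rule=True)

    def test_masking_never_changes_unmasked_values(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-0.5, 1.0, (4, 5, 12))
        out = mask_invalid(monthly(vals, "NDVI"))
        keep = vals >= 0.1
        np.testing.assert_array_equal(out.values[keep], vals[keep])


class TestSeasonMean:
    def test_constant_cube_any_mask(self):
        vals = np.full((2, 4, 12), 3.25)
        mask = np.zeros((2, 12), dtype=bool)
        mask[:, 4:9] = True
        np.testing.assert_allclose(season_mean(monthly(vals), mask), 3.25)

    def test_single_month_mask_returns_that_month(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(1, 3, 12))
        mask = np.zeros((1, 12), dtype=bool)
        mask[0, 5] = True  # June
        np.testing.assert_allclose(season_mean(monthly(vals), mask)[0], vals[0, :, 5])

    def test_hand_average(self):
        vals = np.full((1, 3, 12), np.nan)
        vals[0, :, 3:6] = [1.0, 2.0, 3.0]
        mask = np.zeros((1, 12), dtype=bool)
        mask[0, 3:6] = True
        np.testing.assert_allclose(season_mean(monthly(vals), mask), 2.0)

    def test_all_missing_year_is_missing(self):
        vals = np.full((1, 3, 12), 1.0)
        vals[0, 1, :] = np.nan
        mask = np.ones((1, 12), dtype=bool)
        out = season_mean(monthly(vals), mask)
        assert np.isnan(out[0, 1]) and np.isfinite(out[0, 0])

    def test_empty_month_set_names_cell(self):
        mask = np.ones((2, 12), dtype=bool)
        mask[1] = False
        with pytest.raises(ValueError, match="1"):
            season_mean(monthly(np.ones((2, 3, 12))), mask)


class TestDetrend:
    def test_linear_series_to_zero(self):
        t = np.arange(10)
        out = detrend(2.0 + 0.5 * t)
        assert np.all(np.abs(out.values) < 1e-9)

    def test_constant_series_to_zero(self):
        out = detrend(np.full(8, 3.0))
        assert np.all(np.abs(out.values) < 1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(3, 12)) + 0.3 * np.arange(12)
        out = detrend(y)
        t = np.arange(12, dtype=float)
        X = np.column_stack([np.ones(12), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y.T)
        np.testing.assert_allclose(out.values, y - (X @ beta).T, atol=1e-10)

    def test_residual_slope_zero(self):
        rng = np.random.default_rng(3)
        out = detrend(rng.normal(size=(2, 15)))
        t = np.arange(15)
        for row in out.values:
            assert abs(np.polyfit(t, row, 1)[0]) < 1e-9

    def test_missing_years_stay_missing(self):
        y = np.array([1.0, np.nan, 2.0, 3.0, np.nan, 5.0])
        out = detrend(y)
        assert np.isnan(out.values[0, [1, 4]]).all()
        assert np.isfinite(out.values[0, [0, 2, 3, 5]]).all()

    def test_too_few_years_flagged_not_abort(self):
        y = np.array([[1.0, np.nan, np.nan, 2.0], [1.0, 2.0, 3.0, 4.0]])
        out = detrend(y)
        assert not out.usable[0] and out.usable[1]
        assert np.isnan(out.values[0]).all()

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(2, 10))
        once = detrend(y).values
        twice = detrend(once).values
        np.testing.assert_allclose(once, twice, atol=1e-9)


class TestAridity:
    def test_zero_precip_is_arid(self):
        rec = aridity_index(np.zeros(5), np.full(5, 1000.0))
        assert rec.aridity == 0.0 and rec.label == "arid"

    def test_boundary_half_is_semi_humid(self):
        rec = aridity_index(np.full(18, 500.0), np.full(18, 1000.0))
        assert rec.aridity == pytest.approx(0.5)
        assert rec.label == "semi-humid"

    def test_boundary_065_is_humid(self):
        rec = aridity_index(np.full(3, 650.0), np.full(3, 1000.0))
        assert rec.label == "humid"

    @pytest.mark.parametrize("ai, label", [(0.1, "arid"), (0.3, "semi-arid"), (0.6, "semi-humid"), (1.2, "humid")])
    def test_classes(self, ai, label):
        assert aridity_index(np.full(2, ai), np.ones(2)).label == label

    def test_nonpositive_pet_rejected(self):
        with pytest.raises(ValueError):
            aridity_index(np.ones(3), np.array([1.0, 0.0, 2.0]))


class TestBlockAggregate:
    def test_uniform_field_unchanged(self):
        out = block_aggregate(np.full((4, 4), 2.0), 2)
        np.testing.assert_allclose(out, 2.0)

    def test_hand_average(self):
        fine = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert block_aggregate(fine, 2)[0, 0] == pytest.approx(2.5)

    def test_all_missing_block_missing(self):
        fine = np.full((2, 2), np.nan)
        assert np.isnan(block_aggregate(fine, 2)[0, 0])

    def test_partial_missing_uses_remaining(self):
        fine = np.array([[1.0, np.nan], [3.0, np.nan]])
        assert block_aggregate(fine, 2)[0, 0] == pytest.approx(2.0)

    def test_edge_blocks_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            out = block_aggregate(np.ones((5, 5)), 2)
        assert out.shape == (2, 2)

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            block_aggregate(np.ones((4, 4)), 0)

    def test_commutes_with_season_mean_on_complete_data(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(4, 4, 3, 12))  # (lat, lon, year, month)
        mask = np.zeros((16, 12), dtype=bool)
        mask[:, 5:8] = True
        fine_cube = monthly(vals.reshape(16, 3, 12), "LAI")
        sm_then_agg = block_aggregate(
            season_mean(fine_cube, mask).reshape(4, 4, 3), 2
        )
        coarse_vals = block_aggregate(vals, 2).reshape(4, 3, 12)
        agg_then_sm = season_mean(monthly(coarse_vals, "LAI"), mask[:4])
        np.testing.assert_allclose(sm_then_agg.reshape(4, 3), agg_then_sm, atol=1e-9)
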