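import numpy as np
import pytest

from lcmort import (MortalityDataError, MortalitySurface, RateSurface,
                    apply_source_scaling, central_rates,
                    fill_missing_by_spline, read_mortality_csv,
                    rescale_exposure_base, write_surface)

from conftest import write_csv_pair


class TestReadWrite:
    def test_missing_cell_is_masked(self, tmp_path):
        dp, ep = write_csv_pair(
            tmp_path,
            [(0, 10, 9), (1, None, 4), (2, 8, 7)],
            [(0, 1000, 1000), (1, 2000, 2000), (2, 1500, 1500)],
        )
        s = read_mortality_csv(dp, ep)
        assert s.observed_mask.sum() == 5
        assert not s.observed_mask[1, 0]

    def test_na_token_is_masked(self, tmp_path):
        dp, ep = write_csv_pair(
            tmp_path,
            [(0, 10, 9), (1, "NA", 4), (2, 8, 7)],
            [(0, 1000, 1000), (1, 2000, 2000), (2, 1500, 1500)],
        )
        assert read_mortality_csv(dp, ep).observed_mask.sum() == 5

    def test_round_trip_identity(self, tmp_path, small_surface):
        write_surface(small_surface, tmp_path / "d.csv", tmp_path / "e.csv")
        back = read_mortality_csv(tmp_path / "d.csv", tmp_path / "e.csv")
        np.testing.assert_array_equal(back.ages, small_surface.ages)
        np.testing.assert_array_equal(back.years, small_surface.years)
        np.testing.assert_allclose(back.deaths, small_surface.deaths)
        np.testing.assert_allclose(back.exposures, small_surface.exposures)
        np.testing.assert_array_equal(back.observed_mask, small_surface.observed_mask)

    def test_negative_count_names_cell(self, tmp_path):
        dp, ep = write_csv_pair(
            tmp_path,
            [(0, 10, 9), (1, -3, 4), (2, 8, 7)],
            [(0, 1000, 1000), (1, 2000, 2000), (2, 1500, 1500)],
        )
        with pytest.raises(MortalityDataError, match="age 1.*2000"):
            read_mortality_csv(dp, ep)

    def test_non_numeric_cell_rejected(self, tmp_path):
        dp, ep = write_csv_pair(
            tmp_path,
            [(0, 10, 9), (1, "oops", 4), (2, 8, 7)],
            [(0, 1000, 1000), (1, 2000, 2000), (2, 1500, 1500)],
        )
        with pytest.raises(MortalityDataError, match="non-numeric"):
            read_mortality_csv(dp, ep)

    def test_mismatched_grids_rejected(self, tmp_path):
        dp, _ = write_csv_pair(tmp_path, [(0, 1, 1), (1, 1, 1)],
                               [(0, 9, 9), (1, 9, 9)])
        ep2 = tmp_path / "e2.csv"
        ep2.write_text("age,2000,2001\n0,9,9\n1,9,9\n2,9,9\n")
        with pytest.raises(MortalityDataError, match="identical age and year"):
            read_mortality_csv(dp, ep2)


class TestScaling:
    def test_census_factor(self, small_surface):
        small_surface.deaths[0, 0] = 5000.0
        out = apply_source_scaling(small_surface, {2000: 1000})
        assert out.deaths[0, 0] == 5.0
        # untouched year
        np.testing.assert_array_equal(out.deaths[:, 1], small_surface.deaths[:, 1])

    def test_percent_sample_factor(self, small_surface):
        small_surface.deaths[2, 1] = 120.0
        assert apply_source_scaling(small_surface, {2001: 10}).deaths[2, 1] == 12.0

    def test_empty_map_is_identity(self, small_surface):
        out = apply_source_scaling(small_surface, {})
        np.testing.assert_array_equal(out.deaths, small_surface.deaths)
        np.testing.assert_array_equal(out.exposures, small_surface.exposures)

    def test_rates_invariant_under_scaling(self, small_surface):
        before = central_rates(small_surface).rates
        after = central_rates(apply_source_scaling(small_surface, {2000: 1000, 2001: 10}))
        np.testing.assert_allclose(after.rates, before, rtol=1e-12)

    @pytest.mark.parametrize("bad", [{2000: 0}, {2000: -2}, {1990: 10}])
    def test_bad_factor_or_year(self, small_surface, bad):
        with pytest.raises(MortalityDataError):
            apply_source_scaling(small_surface, bad)

    def test_exposure_base_renormalisation(self, small_surface):
        out = rescale_exposure_base(small_surface, base=1e6)
        np.testing.assert_allclose(out.exposures.sum(axis=0), [1e6, 1e6])
        np.testing.assert_allclose(central_rates(out).rates,
                                   central_rates(small_surface).rates, rtol=1e-12)


class TestCentralRates:
    def test_simple_division(self, small_surface):
        assert central_rates(small_surface).rates[0, 0] == pytest.approx(0.01)

    def test_zero_deaths_flagged_log_undefined(self, small_surface):
        small_surface.deaths[1, 1] = 0.0
        rs = central_rates(small_surface)
        assert rs.rates[1, 1] == 0.0
        assert np.isnan(rs.log_rates[1, 1])

    def test_masked_cell_undefined(self, small_surface):
        small_surface.observed_mask[2, 0] = False
        rs = central_rates(small_surface)
        assert np.isnan(rs.rates[2, 0])
        assert np.isnan(rs.log_rates[2, 0])

    def test_zero_exposure_rejected(self, small_surface):
        small_surface.exposures[0, 0] = 0.0
        with pytest.raises(MortalityDataError):
            central_rates(small_surface)


def _rate_surface_from_log(ages, log_col):
    lr = np.asarray(log_col, dtype=float)[:, None]
    return RateSurface(
        ages=np.asarray(ages), years=np.array([2000]),
        rates=np.exp(lr), log_rates=lr,
        observed_mask=np.isfinite(lr),
    )


class TestSplineFill:
    def test_interior_cubic_reproduced(self):
        ages = np.arange(41)
        poly = lambda x: -5 + 0.01 * x + 0.002 * x**2 - 3e-5 * x**3
        log_col = poly(ages.astype(float))
        log_col[20] = np.nan
        out = fill_missing_by_spline(_rate_surface_from_log(ages, log_col))
        assert out.log_rates[20, 0] == pytest.approx(poly(20.0), rel=1e-6)
        assert out.imputed_mask[20, 0]

    def test_no_flags_is_identity(self):
        ages = np.arange(10)
        rs = _rate_surface_from_log(ages, -5 + 0.05 * ages)
        out = fill_missing_by_spline(rs)
        np.testing.assert_array_equal(out.log_rates, rs.log_rates)
        assert not out.imputed_mask.any()

    def test_observed_cells_bit_identical(self):
        ages = np.arange(30)
        log_col = -6 + 0.04 * ages.astype(float)
        log_col[[7, 15]] = np.nan
        rs = _rate_surface_from_log(ages, log_col)
        out = fill_missing_by_spline(rs)
        keep = np.isfinite(log_col)
        np.testing.assert_array_equal(out.log_rates[keep, 0], log_col[keep])

    def test_too_few_knots_names_year(self):
        log_col = np.array([-5.0, -4.9, np.nan, -4.7, np.nan])
        rs = _rate_surface_from_log(np.arange(5), log_col)
        rs.log_rates[4, 0] = np.nan
        rs.rates[4, 0] = np.nan
        with pytest.raises(MortalityDataError, match="2000"):
            fill_missing_by_spline(rs)

    def test_monotone_column_stays_in_range(self):
        # spline overshoot check: filled values within the observed range
        # (10% of the column range slack)
        ages = np.arange(25)
        log_col = np.sort(-8 + 4 * np.random.default_rng(0).random(25))
        lo, hi = log_col.min(), log_col.max()
        log_col[[5, 12, 18]] = np.nan
        out = fill_missing_by_spline(_rate_surface_from_log(ages, log_col))
        slack = 0.1 * (hi - lo)
        filled = out.log_rates[[5, 12, 18], 0]
        assert np.all(filled >= lo - slack) and np.all(filled <= hi + slack)

    def test_boundary_below_uses_nearest_knot(self):
        ages = np.arange(10)
        log_col = -6 + 0.1 * ages.astype(float)
        log_col[0] = np.nan
        out = fill_missing_by_spline(_rate_surface_from_log(ages, log_col))
        assert out.log_rates[0, 0] == log_col[1]

    def test_old_age_block_left_unfilled(self):
        ages = np.arange(15)
        log_col = -6 + 0.1 * ages.astype(float)
        log_col[12:] = np.nan
        out = fill_missing_by_spline(_rate_surface_from_log(ages, log_col))
        assert np.all(np.isnan(out.log_rates[12:, 0]))
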