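"""Fast-ice metric unit behaviour against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icehab import (
    ClassParams,
    IceScapeConfig,
    boxcar_smooth,
    compute_fastice_metrics,
    fit_annual_fourier,
    generate_icescape,
    persistence,
    timing_to_code,
    volatility,
)
from icehab.metrics import (
    block_aggregate,
    fastice_extent,
    fastice_trend,
    mask_and_aggregate,
)


def _dates(n, start="2010-03-01"):
    return np.datetime64(start, "D") + 15 * np.arange(n)


class TestBoxcar:
    def test_constant_series_unchanged(self):
        out = boxcar_smooth(np.full(10, 0.7), 3)
        np.testing.assert_allclose(out, 0.7)

    def test_alternating_series_interior(self):
        out = boxcar_smooth(np.array([0.0, 1, 0, 1, 0, 1]), 3)
        np.testing.assert_allclose(out[1:-1], [1 / 3, 2 / 3, 1 / 3, 2 / 3])
        # shrinking window at the edges: mean of the two available points
        np.testing.assert_allclose(out[[0, -1]], [0.5, 0.5])

    def test_window_one_is_identity(self):
        x = np.linspace(0, 1, 7)
        np.testing.assert_array_equal(boxcar_smooth(x, 1), x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            boxcar_smooth(np.zeros(8), 4)

    @given(st.integers(1, 4))
    def test_mean_preserved_for_constant(self, half):
        w = 2 * half + 1
        out = boxcar_smooth(np.full(12, 0.25), w)
        np.testing.assert_allclose(out, 0.25)

    def test_missing_values_excluded(self):
        x = np.array([0.0, np.nan, 1.0, 1.0, 1.0])
        out = boxcar_smooth(x, 3)
        np.testing.assert_allclose(out[0], 0.0)  # only the first point available
        np.testing.assert_allclose(out[1], 0.5)  # mean of 0 and 1


class TestVolatility:
    def test_constant_is_zero(self):
        assert volatility(np.full(24, 0.6)) == pytest.approx(0.0)

    def test_alternating_is_two_thirds(self):
        x = np.array([0.0, 1.0] * 20)
        # interior residual is +/- 2/3 everywhere for the 0/1 square wave
        assert volatility(x) == pytest.approx(2 / 3)

    def test_smooth_annual_cycle_leaks_little(self):
        t = 15.0 * np.arange(192)
        x = 0.5 + 0.4 * np.sin(2 * np.pi * t / 365.0)
        # brute-force reference computed the same way confirms v << amplitude
        assert volatility(x) < 0.05 * 0.4

    def test_bounded_on_fraction_series(self):
        rng = np.random.default_rng(0)
        x = rng.random((48, 50))
        v = volatility(x)
        assert np.all((v >= 0) & (v <= 1))


class TestPersistence:
    def test_extremes_and_half(self):
        assert persistence(np.ones(10)) == pytest.approx(100.0)
        assert persistence(np.zeros(10)) == pytest.approx(0.0)
        assert persistence(np.array([1.0] * 5 + [0.0] * 5)) == pytest.approx(50.0)


class TestAnnualFourier:
    def test_phase_recovery_noiseless(self):
        """Peak day recovered within half an epoch on a clean sinusoid."""
        n = 192
        dates = _dates(n)
        doy = (
            dates - dates.astype("datetime64[Y]").astype("datetime64[D]")
        ).astype(int) + 1
        peak_doy = 258.0  # Sep 15
        x = 0.5 + 0.4 * np.sin(2 * np.pi * (doy - (peak_doy - 365.25 / 4)) / 365.25)
        fit = fit_annual_fourier(x, dates)
        assert abs(fit.peak_doy[0] - peak_doy) <= 8
        assert abs(fit.trough_doy[0] - (peak_doy - 182)) <= 9

    def test_magnitude_matches_smoothed_range_oracle(self):
        """Magnitude equals the annual range of the 13-point-smoothed series.

        The 13-point (~195-day) boxcar attenuates a pure annual harmonic;
        the oracle smooths the same series directly and takes its range.
        """
        n = 192
        dates = _dates(n)
        t = 15.0 * np.arange(n)
        x = 0.5 + 0.4 * np.sin(2 * np.pi * t / 365.25)
        fit = fit_annual_fourier(x, dates)
        oracle = np.ptp(boxcar_smooth(x, 13)[6:-6])  # full-window interior range
        assert fit.magnitude[0] == pytest.approx(oracle, abs=0.02)

    def test_constant_series_zero_magnitude(self):
        fit = fit_annual_fourier(np.full(48, 0.3), _dates(48))
        assert fit.magnitude[0] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(fit.peak_doy[0])

    def test_two_harmonic_series_reproduced_exactly(self):
        """Order-4 fit nests a two-harmonic signal: residual ~ 0 (no smoothing)."""
        n = 96
        dates = _dates(n)
        t = 15.0 * np.arange(n)
        w = 2 * np.pi * t / 365.25
        x = 0.5 + 0.2 * np.cos(w) + 0.1 * np.sin(2 * w)
        fit = fit_annual_fourier(x, dates, smooth_window=1)
        resid = x - fit.curve(t)[:, 0]
        assert np.sqrt(np.mean(resid**2)) < 1e-6

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            fit_annual_fourier(np.zeros(10), _dates(10))


class TestTimingCodes:
    @pytest.mark.parametrize(
        "doy,kind,expected",
        [
            (258, "max", 0.0),  # Sep 15, median
            (349, "max", 5.0),  # Dec 15, late
            (196, "max", -5.0),  # Jul 15, early
            (74, "min", 0.0),  # Mar 15, median
            (349, "min", -5.0),  # Dec 15, early
            (135, "min", 5.0),  # May 15, late
        ],
    )
    def test_anchor_days(self, doy, kind, expected):
        assert timing_to_code(doy, kind, 0.6) == pytest.approx(expected)

    def test_low_magnitude_discards_timing(self):
        assert timing_to_code(349, "max", 0.2) == 0.0
        assert timing_to_code(349, "max", 0.39999) == 0.0
        assert timing_to_code(349, "max", 0.4) == pytest.approx(5.0)

    @given(st.floats(1, 366), st.sampled_from(["max", "min"]))
    def test_codes_clamped(self, doy, kind):
        code = timing_to_code(doy, kind, 1.0)
        assert -5.0 <= code <= 5.0


class TestTrend:
    def test_constant_series_zero(self):
        assert fastice_trend(np.full(48, 0.4), _dates(48)) == pytest.approx(0.0)

    def test_linear_ramp_slope(self):
        n = 192  # 8 years
        dates = _dates(n)
        t_years = 15.0 * np.arange(n) / 365.25
        x = 0.1 * t_years  # 0 -> ~0.8 over 8 years
        assert fastice_trend(x, dates) == pytest.approx(0.1, rel=1e-9)

    def test_whole_year_sinusoid_near_zero(self):
        # the OLS slope of a sinusoid over whole cycles decays as T^-2:
        # |slope| ~ 6*A*p/(pi*T^2); 20 years at A=0.1 puts it below 1e-3/yr
        n = 20 * 24
        t = 15.0 * np.arange(n)
        x = 0.5 + 0.1 * np.sin(2 * np.pi * t / 360.0)
        assert abs(fastice_trend(x, _dates(n))) < 1e-3


class TestExtent:
    def _stack(self, values, years=1):
        from icehab.synthetic import IceTimeSeriesGrid

        n = years * 24
        vals = np.broadcast_to(values, (n,) + values.shape[-2:]).copy()
        return IceTimeSeriesGrid(
            values=vals,
            epoch_dates=_dates(n, "2010-01-01"),
            mask=np.zeros(values.shape[-2:], dtype=bool),
            cell_km=5.0,
        )

    def test_contiguous_band_width(self):
        field = np.zeros((8, 3))
        field[:4, 1] = 1.0  # 4 contiguous cells from the coast in column 1
        ext = fastice_extent(self._stack(field))
        assert np.all(ext[:4, 1] == 20.0)
        assert np.all(ext[4:, 1] == 0.0) and np.all(ext[:, [0, 2]] == 0.0)

    def test_ice_free_october(self):
        ext = fastice_extent(self._stack(np.zeros((4, 4))))
        assert np.all(ext == 0.0)

    def test_median_across_years(self):
        from icehab.synthetic import IceTimeSeriesGrid

        n = 3 * 24
        dates = _dates(n, "2010-01-01")
        months = pd.DatetimeIndex(dates).month
        days = pd.DatetimeIndex(dates).day
        vals = np.zeros((n, 8, 1))
        widths = [2, 4, 6]  # 10, 20, 30 km in successive Octobers
        oct_idx = np.nonzero((months == 10) & (days <= 15))[0]
        for i, w in zip(oct_idx, widths):
            vals[i, :w, 0] = 1.0
        stack = IceTimeSeriesGrid(
            values=vals, epoch_dates=dates, mask=np.zeros((8, 1), bool), cell_km=5.0
        )
        ext = fastice_extent(stack)
        assert ext[0, 0] == 20.0  # median of 10, 20, 30

    def test_no_october_epoch_raises(self):
        from icehab.synthetic import IceTimeSeriesGrid

        stack = IceTimeSeriesGrid(
            values=np.zeros((4, 2, 2)),
            epoch_dates=_dates(4, "2010-03-01"),
            mask=np.zeros((2, 2), bool),
            cell_km=5.0,
        )
        with pytest.raises(ValueError, match="October"):
            fastice_extent(stack)


class TestAggregation:
    def test_constant_block_mean(self):
        arr = np.full((10, 10), 0.37)
        np.testing.assert_allclose(block_aggregate(arr, 5), 0.37)

    def test_partial_valid_block(self):
        arr = np.full((2, 2), np.nan)
        arr[0, 0], arr[0, 1] = 0.2, 0.4
        assert block_aggregate(arr, 2)[0, 0] == pytest.approx(0.3)

    def test_all_masked_input_fully_masked_output(self):
        from icehab.metrics import FastIceMetrics

        z = np.zeros((4, 4))
        m = FastIceMetrics(
            persistence=z, volatility=z, timing_max_code=z, timing_min_code=z,
            magnitude=z, trend=z, extent_km=z, cell_km=5.0,
        )
        out = mask_and_aggregate(m, 2)
        assert not out.valid.any()

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            block_aggregate(np.zeros((4, 4)), 2.5)


class TestGridMetrics:
    def test_magnitude_zero_at_persistence_extremes(self):
        classes = tuple(
            ClassParams(p, 0.0, 258.0, 0.0, 0.0) for p in (0.0, 1.0, 0.5)
        )
        cfg = IceScapeConfig(
            grid_shape=(4, 120), years=2, n_classes=3, class_params=classes, seed=0
        )
        grid, truth = generate_icescape(cfg)
        mets = compute_fastice_metrics(grid)
        full = truth.class_map == 1
        # 0%-persistence pixels are masked entirely; 100% pixels have magnitude 0
        assert not mets.valid[truth.class_map == 0].any()
        np.testing.assert_allclose(mets.magnitude[full], 0.0, atol=1e-9)
        np.testing.assert_allclose(mets.persistence[full], 100.0)
        np.testing.assert_allclose(mets.timing_max_code[full], 0.0)

    def test_bell_shape_over_persistence_sweep(self):
        """Volatility and magnitude peak at intermediate realized persistence.

        The series is clip(m + A sin + noise, 0, 1) with the offset m swept
        beyond [0, 1]: clipping removes both cycle and noise at the
        extremes, which is exactly why the metrics vanish at realized
        persistence 0 and 100%.
        """
        rng = np.random.default_rng(7)
        n = 8 * 24
        t = 15.0 * np.arange(n)
        cyc = 0.45 * np.sin(2 * np.pi * t / 365.25)
        offsets = np.linspace(-0.7, 1.7, 13)
        pers, vol, mag = [], [], []
        dates = _dates(n)
        for m in offsets:
            x = np.clip(m + cyc + 0.05 * rng.standard_normal(n), 0.0, 1.0)
            pers.append(persistence(x))
            vol.append(volatility(x))
            mag.append(fit_annual_fourier(x, dates).magnitude[0])
        pers, vol, mag = map(np.array, (pers, vol, mag))
        assert pers[0] == 0.0 and pers[-1] == 100.0
        # metrics vanish at the persistence extremes ...
        assert vol[0] < 1e-6 and vol[-1] < 1e-6
        assert mag[0] < 1e-6 and mag[-1] < 1e-6
        # ... and peak at intermediate persistence
        mid = (pers > 20) & (pers < 80)
        assert vol[mid].min() > 5 * max(vol[0], vol[-1], 1e-4)
        assert mag[mid].min() > 0.2

    def test_pixel_permutation_equivariance(self):
        """Metrics are strictly per-pixel: permuting columns permutes outputs."""
        cfg = IceScapeConfig(grid_shape=(4, 120), years=2, seed=6, n_classes=5)
        grid, _ = generate_icescape(cfg)
        mets = compute_fastice_metrics(grid)
        perm = np.random.default_rng(0).permutation(grid.values.shape[2])
        import dataclasses

        grid2 = dataclasses.replace(grid, values=grid.values[:, :, perm],
                                    mask=grid.mask[:, perm])
        mets2 = compute_fastice_metrics(grid2)
        for name in ("persistence", "volatility", "magnitude", "trend",
                     "timing_max_code", "timing_min_code"):
            np.testing.assert_allclose(
                getattr(mets, name)[:, perm], getattr(mets2, name), equal_nan=True
            )
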