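"""Per-pixel landfast-ice metrics from a 15-day raster time series.

Seven metrics are derived per pixel: volatility (RMS of the
high-frequency residual after removing a 3-point, ~45-day boxcar),
persistence (mean ice residence, %), timing of the seasonal maximum and
minimum (coded -5..+5 around fixed anchor dates), magnitude of the
annual cycle (range of a 4th-order annual Fourier fit to 13-point
smoothed data), the linear trend (fraction per year), and the October
fast-ice extent (km, median of annual coastal band widths).  All are
per-pixel quantities; aggregation to a coarser analysis grid is a plain
block mean of valid pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .synthetic import IceTimeSeriesGrid

__all__ = [
    "FastIceMetrics",
    "boxcar_smooth",
    "volatility",
    "persistence",
    "fit_annual_fourier",
    "timing_to_code",
    "fastice_trend",
    "fastice_extent",
    "block_aggregate",
    "mask_and_aggregate",
    "compute_fastice_metrics",
]

PERSISTENCE_MASK_THRESHOLD = 1e-6
MAGNITUDE_TIMING_FLOOR = 0.4
ANNUAL_PERIOD_DAYS = 365.25

# anchor (early, median, late) days of year; codes -5, 0, +5
_TIMING_ANCHORS = {
    "max": (196.0, 258.0, 349.0),  # Jul 15, Sep 15, Dec 15
    "min": (349.0, 74.0, 135.0),  # Dec 15, Mar 15, May 15
}


def _as_time_major(series: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        return arr[:, None], True
    if arr.ndim == 2:
        return arr, False
    raise ValueError("series must be 1-D or (time, pixel) 2-D")


def boxcar_smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the time axis.

    Edges use the mean of the points available inside the (shrinking)
    window; missing values (NaN) are excluded from the averages.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 1:
        raise ValueError("window must be >= 1")
    arr, squeeze = _as_time_major(series)
    if window > arr.shape[0]:
        raise ValueError("window longer than series")
    valid = np.isfinite(arr)
    filled = np.where(valid, arr, 0.0)
    sums = uniform_filter1d(filled, size=window, axis=0, mode="constant", cval=0.0) * window
    counts = uniform_filter1d(valid.astype(float), size=window, axis=0, mode="constant") * window
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.round(counts) > 0, sums / counts, np.nan)
    return out[:, 0] if squeeze else out


def volatility(series: np.ndarray) -> np.ndarray | float:
    """RMS of the residual from a 3-point boxcar, over interior epochs.

    The 3-point smoother removes the seasonal (low-frequency) signal;
    the residual's root mean square measures short-timescale (~1 month)
    variability, in [0, 1] for fraction-valued series.
    """
    arr, squeeze = _as_time_major(series)
    if arr.shape[0] < 3:
        raise ValueError("series must have at least 3 epochs")
    resid = arr - boxcar_smooth(arr, 3)
    interior = resid[1:-1]
    with np.errstate(invalid="ignore"):
        out = np.sqrt(np.nanmean(interior**2, axis=0))
    return float(out[0]) if squeeze else out


def persistence(series: np.ndarray) -> np.ndarray | float:
    """Mean fast-ice residence over valid epochs, as a percentage."""
    arr, squeeze = _as_time_major(series)
    with np.errstate(invalid="ignore"):
        out = 100.0 * np.nanmean(arr, axis=0)
    return float(out[0]) if squeeze else out


@dataclass
class FourierFit:
    """Annual 4th-order Fourier fit of a (smoothed) fast-ice series."""

    coeffs: np.ndarray  # (2*order+1, n_pix)
    magnitude: np.ndarray  # fitted annual range, clipped to [0, 1]
    peak_doy: np.ndarray  # day of year of fitted maximum (NaN if flat)
    trough_doy: np.ndarray  # day of year of fitted minimum (NaN if flat)
    order: int

    def curve(self, t_days: np.ndarray) -> np.ndarray:
        A = _fourier_design(np.asarray(t_days, dtype=float), self.order)
        return A @ self.coeffs


def _fourier_design(t_days: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(t_days)]
    for h in range(1, order + 1):
        w = 2.0 * np.pi * h * t_days / ANNUAL_PERIOD_DAYS
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def fit_annual_fourier(
    series: np.ndarray,
    epoch_dates: np.ndarray,
    order: int = 4,
    smooth_window: int = 13,
) -> FourierFit:
    """Least-squares annual Fourier fit to 13-point boxcar-smoothed data.

    The model a0 + sum_h [a_h cos(2 pi h t/365.25) + b_h sin(...)] for
    h = 1..order is linear in its coefficients, so an ordinary linear
    least-squares solve reaches the same optimum as an iterative
    Levenberg-Marquardt minimiser.  The fitted curve is evaluated at
    daily resolution over one folded year to locate the climatological
    day of maximum and minimum (ties break to the earliest day) and the
    annual magnitude (max - min, clipped to [0, 1]).
    """
    arr, _ = _as_time_major(series)
    n_epochs, n_pix = arr.shape
    if n_epochs < 2 * (2 * order + 1):
        raise ValueError("series too short for the requested Fourier order")

    smooth = boxcar_smooth(arr, min(smooth_window, n_epochs - (1 - n_epochs % 2)))
    dates = np.asarray(epoch_dates, dtype="datetime64[D]")
    t_days = (dates - dates[0]).astype(int).astype(float)
    A = _fourier_design(t_days, order)

    finite = np.isfinite(smooth)
    all_valid = finite.all(axis=0)
    never_valid = ~finite.any(axis=0)
    coeffs = np.full((A.shape[1], n_pix), np.nan)
    if all_valid.any():
        sol, *_ = np.linalg.lstsq(A, smooth[:, all_valid], rcond=None)
        coeffs[:, all_valid] = sol
    # pixels with partially missing epochs are fit on their own valid rows
    for j in np.nonzero(~all_valid & ~never_valid)[0]:
        rows_j = finite[:, j]
        if rows_j.sum() >= A.shape[1]:
            coeffs[:, j], *_ = np.linalg.lstsq(A[rows_j], smooth[rows_j, j], rcond=None)

    # fold one year at daily resolution, anchored at the series start
    t_eval = np.arange(365.0)
    curve = _fourier_design(t_eval, order) @ coeffs  # (365, n_pix)
    start_doy = (dates[0] - dates[0].astype("datetime64[Y]").astype("datetime64[D]")).astype(int) + 1
    doy = (start_doy - 1 + np.arange(365)) % 365 + 1

    rng_ = curve.max(axis=0) - curve.min(axis=0)
    magnitude = np.clip(rng_, 0.0, 1.0)
    peak = doy[np.argmax(curve, axis=0)].astype(float)
    trough = doy[np.argmin(curve, axis=0)].astype(float)
    flat = ~(rng_ >= 1e-12)  # True also where the fit itself is NaN
    peak[flat] = np.nan
    trough[flat] = np.nan
    return FourierFit(coeffs=coeffs, magnitude=magnitude, peak_doy=peak, trough_doy=trough, order=order)


def timing_to_code(
    day_of_year: np.ndarray | float, kind: str, magnitude: np.ndarray | float
) -> np.ndarray | float:
    """Map a timing day-of-year to the -5..+5 seasonal code.

    Piecewise-linear between the anchor dates (maximum: Jul 15 -> -5,
    Sep 15 -> 0, Dec 15 -> +5; minimum: Dec 15 -> -5, Mar 15 -> 0,
    May 15 -> +5), clamped to [-5, 5].  Timings are discarded
    (multiplied by 0) wherever the annual-cycle magnitude is below 0.4,
    since timing is noisy where the cycle is weak.
    """
    if kind not in _TIMING_ANCHORS:
        raise ValueError("kind must be 'max' or 'min'")
    early, median, late = _TIMING_ANCHORS[kind]
    doy = np.asarray(day_of_year, dtype=float)
    mag = np.asarray(magnitude, dtype=float)

    # signed circular offset from the median anchor, in (-182.5, 182.5]
    delta = (doy - median + 182.5) % 365.0 - 182.5
    early_span = (median - early) % 365.0
    late_span = (late - median) % 365.0
    code = np.where(delta < 0, 5.0 * delta / early_span, 5.0 * delta / late_span)
    code = np.clip(code, -5.0, 5.0)
    code = np.where(np.isnan(doy), 0.0, code)
    code = code * (mag >= MAGNITUDE_TIMING_FLOOR)
    return float(code) if code.ndim == 0 else code


def fastice_trend(series: np.ndarray, epoch_dates: np.ndarray) -> np.ndarray | float:
    """OLS slope of ice fraction against time, in fraction per year."""
    arr, squeeze = _as_time_major(series)
    dates = np.asarray(epoch_dates, dtype="datetime64[D]")
    t_years = (dates - dates[0]).astype(int).astype(float) / ANNUAL_PERIOD_DAYS

    valid = np.isfinite(arr)
    n = valid.sum(axis=0)
    t = np.where(valid, t_years[:, None], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = np.nanmean(t, axis=0)
        ybar = np.nanmean(arr, axis=0)
        cov = np.nansum((t - tbar) * (arr - ybar), axis=0)
        var = np.nansum((t - tbar) ** 2, axis=0)
        slope = np.where((n >= 3) & (var > 0), cov / var, np.nan)
    return float(slope[0]) if squeeze else slope


def fastice_extent(stack: IceTimeSeriesGrid, threshold: float = 0.5) -> np.ndarray:
    """October fast-ice extent (km) per cell.

    For each year the first epoch falling in Oct 1-15 is binarized at
    ``threshold``; along every grid column the width of the contiguous
    ice band attached to the coast (row 0) is measured in km and
    assigned to each cell inside the band (0 outside).  The per-cell
    extent is the median of these annual fields.
    """
    dates = pd.DatetimeIndex(stack.epoch_dates)
    in_window = (dates.month == 10) & (dates.day <= 15)
    oct_idx = []
    for year in sorted(set(dates.year)):
        sel = np.nonzero(in_window & (dates.year == year))[0]
        if sel.size:
            oct_idx.append(sel[0])
    if not oct_idx:
        raise ValueError("stack contains no first-half-of-October epoch")

    annual = []
    for i in oct_idx:
        binary = (stack.values[i] >= threshold) & ~stack.mask
        band = np.cumprod(binary, axis=0)  # 1 while contiguous from coast
        width_km = band.sum(axis=0) * stack.cell_km
        annual.append(band * width_km[None, :])
    return np.median(np.stack(annual), axis=0)


def block_aggregate(arr: np.ndarray, factor: int) -> np.ndarray:
    """Block mean of valid (finite) values over factor x factor tiles.

    Dimensions not divisible by ``factor`` are padded with missing
    values; a block with no valid pixel is NaN.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("aggregation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return np.asarray(arr, dtype=float).copy()
    r, c = arr.shape
    rp, cp = -r % factor, -c % factor
    padded = np.pad(np.asarray(arr, dtype=float), ((0, rp), (0, cp)), constant_values=np.nan)
    blocks = padded.reshape(padded.shape[0] // factor, factor, padded.shape[1] // factor, factor)
    with np.errstate(invalid="ignore"):
        return np.nanmean(blocks, axis=(1, 3))


@dataclass
class FastIceMetrics:
    """The seven fast-ice metrics on the analysis grid.

    Masked cells (land, or persistence below 1e-6) are NaN everywhere.
    """

    persistence: np.ndarray  # %
    volatility: np.ndarray  # [0, 1]
    timing_max_code: np.ndarray  # [-5, 5]
    timing_min_code: np.ndarray  # [-5, 5]
    magnitude: np.ndarray  # [0, 1]
    trend: np.ndarray  # fraction / year
    extent_km: np.ndarray  # km
    cell_km: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.persistence)

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = self.persistence.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        df = pd.DataFrame(
            {
                "cell_id": np.arange(rows * cols),
                "row": rr.ravel(),
                "col": cc.ravel(),
                "x_km": (cc.ravel() + 0.5) * self.cell_km,
                "y_km": (rr.ravel() + 0.5) * self.cell_km,
            }
        )
        for f in fields(self):
            if f.name != "cell_km":
                df[f.name] = getattr(self, f.name).ravel()
        return df


def mask_and_aggregate(metrics: FastIceMetrics, factor: int) -> FastIceMetrics:
    """Mask near-zero-persistence pixels and block-aggregate to a coarser grid."""
    masked = {}
    drop = ~(metrics.persistence >= 100.0 * PERSISTENCE_MASK_THRESHOLD)
    for f in fields(metrics):
        if f.name == "cell_km":
            continue
        arr = getattr(metrics, f.name).copy()
        arr[drop] = np.nan
        masked[f.name] = block_aggregate(arr, factor)
    return FastIceMetrics(cell_km=metrics.cell_km * factor, **masked)


def compute_fastice_metrics(stack: IceTimeSeriesGrid, agg_factor: int = 1) -> FastIceMetrics:
    """All seven metrics from a stack, masked and aggregated.

    Pixels under the stack mask are excluded up front; pixels whose
    persistence falls below 1e-6 (fraction scale) are masked afterwards,
    and everything is block-averaged by ``agg_factor`` (1 = analysis
    grid equals the native grid).
    """
    n_epochs = stack.values.shape[0]
    rows, cols = stack.shape
    flat = stack.values.reshape(n_epochs, rows * cols).astype(float).copy()
    flat[:, stack.mask.ravel()] = np.nan

    pers = persistence(flat).reshape(rows, cols)
    vol = volatility(flat).reshape(rows, cols)
    fit = fit_annual_fourier(flat, stack.epoch_dates)
    mag = fit.magnitude.reshape(rows, cols)
    tmax = timing_to_code(fit.peak_doy, "max", fit.magnitude).reshape(rows, cols)
    tmin = timing_to_code(fit.trough_doy, "min", fit.magnitude).reshape(rows, cols)
    trend = fastice_trend(flat, stack.epoch_dates).reshape(rows, cols)
    extent = fastice_extent(stack)
    extent = np.where(stack.mask, np.nan, extent)

    native = FastIceMetrics(
        persistence=pers,
        volatility=vol,
        timing_max_code=tmax,
        timing_min_code=tmin,
        magnitude=mag,
        trend=trend,
        extent_km=extent,
        cell_km=stack.cell_km,
    )
    return mask_and_aggregate(native, agg_factor)
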