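"""Synthetic circum-Antarctic icescape generator.

Produces a fully synthetic analogue of the inputs the habitat analysis
consumes: a landfast-ice fraction raster stack at 15-day cadence, a
shelf-slope bathymetry grid, and colony point sets for emperor penguins,
Adélie penguins and Weddell seals.  Every pixel belongs to a latent
habitat class (a longitudinal band) with its own seasonal-cycle
parameters, so downstream clustering can be scored against known truth.

The per-pixel fast-ice fraction series is

    f(t) = clip(m + A * sin(2*pi*(d(t) - phase)/365) + e(t), 0, 1)

where ``m`` is the class mean persistence, ``A`` the seasonal amplitude,
``d(t)`` the day of year, and ``e(t)`` an AR(1) noise process.  Breakout
events additionally zero a short contiguous run of epochs with a
per-year probability, mimicking sudden fast-ice loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassParams",
    "IceScapeConfig",
    "IceTimeSeriesGrid",
    "SyntheticTruth",
    "generate_icescape",
    "generate_bathymetry",
]


@dataclass(frozen=True)
class ClassParams:
    """Seasonal fast-ice parameters of one latent habitat class.

    persistence_mean : annual-mean ice fraction in [0, 1]
    amplitude        : seasonal cycle amplitude in [0, 1]
    peak_doy         : day of year at which the cycle peaks
    noise_sd         : stationary s.d. of the AR(1) noise
    breakout_prob    : probability per pixel-year of a breakout event
    """

    persistence_mean: float
    amplitude: float
    peak_doy: float
    noise_sd: float
    breakout_prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence_mean <= 1.0:
            raise ValueError("persistence_mean must lie in [0, 1]")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")
        if not 0.0 <= self.breakout_prob <= 1.0:
            raise ValueError("breakout_prob must lie in [0, 1]")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")


#: Default latent classes.  Chosen to span the qualitative regimes seen
#: around the continent — mid-persistence / weak-cycle (Weddell-like),
#: quiet low-persistence ice (Ross-like), an early-peaking strong
#: annual cycle, a volatile late-peaking breakout regime (West
#: Antarctic-like), and near-permanent multiyear ice (East
#: Antarctic-like) — and so that every pair of classes is well
#: separated on at least one metric (persistence, volatility, cycle
#: magnitude, peak timing or extent) relative to its within-class
#: spread, making the latent bands recoverable by the full pipeline.
DEFAULT_CLASSES: tuple[ClassParams, ...] = (
    ClassParams(0.50, 0.48, 200.0, 0.06, 0.2),
    ClassParams(0.50, 0.48, 316.0, 0.06, 0.2),
    ClassParams(0.20, 0.10, 258.0, 0.04, 0.1),
    ClassParams(0.35, 0.15, 285.0, 0.18, 0.7),
    ClassParams(0.85, 0.20, 258.0, 0.03, 0.05),
)


@dataclass(frozen=True)
class IceScapeConfig:
    """Configuration of the synthetic icescape.

    The grid is a regular km-grid with row 0 at the coast and depth
    increasing away from it; no map projection is involved.  Defaults
    give a 15-day cadence over 8 annual cycles and ~50 emperor colonies
    spaced ~220 km apart along an 11,000 km synthetic coastline, each
    within one 5-km grid cell.
    """

    grid_shape: tuple[int, int] = (32, 3520)
    cell_km: float = 5.0
    years: int = 8
    epochs_per_year: int = 24
    n_classes: int = 5
    class_params: tuple[ClassParams, ...] = DEFAULT_CLASSES
    colony_spacing_km: float = 220.0
    adelie_spacing_km: float = 150.0
    weddell_spacing_km: float = 100.0
    colony_jitter_km: float = 1.5
    #: scatter of emperor colony positions along the coast, as a fraction
    #: of the nominal spacing (colonies are only approximately evenly
    #: spaced); 0 gives a perfectly regular array
    colony_spacing_jitter: float = 0.15
    ar1_coef: float = 0.5
    breakout_len_range: tuple[int, int] = (2, 6)
    #: offshore extent of the fast-ice zone: ice fraction ramps linearly
    #: from full at decay_start to zero at decay_end (km from the coast),
    #: so cells beyond the zone are masked by the persistence rule, as
    #: real landfast ice is confined to the coastal margin
    ice_decay_start_km: float = 80.0
    ice_decay_end_km: float = 130.0
    start_date: str = "2010-03-01"
    # bathymetry profile: gentle shelf, steep break band, gentle rise beyond
    bathy_profile: str = "shelf_break"  # or "linear" or "flat"
    coast_depth_m: float = -50.0
    shelf_edge_depth_m: float = -500.0
    break_start_km: float = 60.0
    break_end_km: float = 90.0
    break_bottom_depth_m: float = -2500.0
    max_depth_m: float = -3200.0
    lateral_amplitude: float = 0.05
    #: per-class depth scaling of the shelf profile: the latent regions
    #: differ in shelf geometry (width/depth of the break), as real
    #: Antarctic sectors do, so depth, slope and isobath distance carry
    #: regional signal rather than pure noise
    class_depth_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs_per_year < 4:
            raise ValueError("epochs_per_year must be >= 4")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if len(self.class_params) != self.n_classes:
            raise ValueError(
                f"need {self.n_classes} class_params, got {len(self.class_params)}"
            )
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in [0, 1)")
        lo, hi = self.breakout_len_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid breakout_len_range")
        if not self.ice_decay_end_km > self.ice_decay_start_km > 0:
            raise ValueError("need ice_decay_end_km > ice_decay_start_km > 0")
        if (
            self.class_depth_factors is not None
            and len(self.class_depth_factors) != self.n_classes
        ):
            raise ValueError(
                f"need {self.n_classes} class_depth_factors, "
                f"got {len(self.class_depth_factors)}"
            )

    @property
    def n_epochs(self) -> int:
        return self.years * self.epochs_per_year

    def replace(self, **kw) -> "IceScapeConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class IceTimeSeriesGrid:
    """A fast-ice fraction raster stack at 15-day cadence.

    values      : float array (epoch, row, col), fractions in [0, 1]
    epoch_dates : np.datetime64[D] per epoch, strictly increasing, 15-day step
    mask        : True where a pixel is land / off-domain
    cell_km     : grid spacing; cell centroids sit at ((col+.5), (row+.5))*cell_km,
                  row 0 being the coast
    """

    values: np.ndarray
    epoch_dates: np.ndarray
    mask: np.ndarray
    cell_km: float

    def __post_init__(self) -> None:
        steps = np.diff(self.epoch_dates).astype("timedelta64[D]").astype(int)
        if len(steps) and not np.all(steps == 15):
            raise ValueError("epoch_dates must increase in 15-day steps")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def cell_centroids_km(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centroid coordinates in km, each of shape (rows, cols)."""
        rows, cols = self.shape
        y = (np.arange(rows) + 0.5) * self.cell_km
        x = (np.arange(cols) + 0.5) * self.cell_km
        return np.meshgrid(x, y)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated icescape (for recovery scoring)."""

    class_map: np.ndarray  # int latent class id per pixel
    colony_points: pd.DataFrame  # columns: species, x_km, y_km, class_id
    true_params: tuple[ClassParams, ...]


def _colony_positions(length_km: float, spacing_km: float, offset_km: float) -> np.ndarray:
    """Regular 1-D positions along the coast, first at offset_km."""
    if length_km - offset_km < spacing_km:
        raise ValueError(
            f"domain of {length_km:.0f} km cannot hold >= 2 colonies "
            f"spaced {spacing_km:.0f} km apart"
        )
    return np.arange(offset_km, length_km, spacing_km)


def _place_colonies(config: IceScapeConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Colony points for the three species along the coast row.

    Emperor colonies are jittered by at most ``colony_jitter_km`` from a
    cell centroid of the coast row so that each colony marks exactly one
    presence cell under the 3-km presence rule.
    """
    rows, cols = config.grid_shape
    length_km = cols * config.cell_km
    records = []

    emp_x = _colony_positions(length_km, config.colony_spacing_km, config.colony_spacing_km / 2)
    emp_x = emp_x + rng.uniform(
        -config.colony_spacing_jitter, config.colony_spacing_jitter, size=emp_x.size
    ) * config.colony_spacing_km
    emp_x = np.clip(emp_x, 0.0, length_km - 1e-9)
    # snap to nearest centroid, then jitter within +/- colony_jitter_km
    cent = (np.floor(emp_x / config.cell_km) + 0.5) * config.cell_km
    j = config.colony_jitter_km
    ex = cent + rng.uniform(-j, j, size=cent.size)
    ey = 0.5 * config.cell_km + rng.uniform(-j, j, size=cent.size)
    for x, y in zip(ex, ey):
        records.append(("emperor", x, y))

    for species, spacing, offset in (
        ("adelie", config.adelie_spacing_km, 60.0),
        ("weddell", config.weddell_spacing_km, 30.0),
    ):
        pos = _colony_positions(length_km, spacing, offset)
        px = pos + rng.uniform(-10.0, 10.0, size=pos.size)
        py = rng.uniform(0.0, 2.0, size=pos.size) * config.cell_km
        for x, y in zip(px, py):
            records.append((species, x, y))

    df = pd.DataFrame(records, columns=["species", "x_km", "y_km"])
    band_width = cols // config.n_classes
    col_idx = np.clip((df["x_km"] / config.cell_km).astype(int), 0, cols - 1)
    df["class_id"] = np.minimum(col_idx // band_width, config.n_classes - 1)
    return df


def _apply_breakouts(
    values: np.ndarray, config: IceScapeConfig, probs: np.ndarray, rng: np.random.Generator
) -> None:
    """Zero random contiguous epoch runs in-place; one event max per pixel-year."""
    n_epochs, n_pix = values.shape
    epy = config.epochs_per_year
    lo, hi = config.breakout_len_range
    for year in range(config.years):
        occur = rng.random(n_pix) < probs
        if not occur.any():
            continue
        pix = np.nonzero(occur)[0]
        start = year * epy + rng.integers(0, epy, size=pix.size)
        length = rng.integers(lo, hi + 1, size=pix.size)
        for off in range(hi):
            sel = off < length
            t = np.minimum(start[sel] + off, n_epochs - 1)
            values[t, pix[sel]] = 0.0


def generate_icescape(config: IceScapeConfig) -> tuple[IceTimeSeriesGrid, SyntheticTruth]:
    """Generate a synthetic fast-ice stack plus its ground truth.

    Pixels are partitioned into ``n_classes`` contiguous longitudinal
    bands; each band follows its class's seasonal cycle with independent
    AR(1) noise and breakout events per pixel.  Fixed seed implies
    byte-identical output.
    """
    rows, cols = config.grid_shape
    n_pix = rows * cols
    n_epochs = config.n_epochs
    rng = np.random.default_rng(config.seed)

    start = np.datetime64(config.start_date, "D")
    epoch_dates = start + 15 * np.arange(n_epochs)
    start_doy = (
        start - start.astype("datetime64[Y]").astype("datetime64[D]")
    ).astype(int) + 1

    band_width = cols // config.n_classes
    class_of_col = np.minimum(np.arange(cols) // band_width, config.n_classes - 1)
    class_map = np.broadcast_to(class_of_col, (rows, cols)).copy()
    class_flat = class_map.ravel()

    pers = np.array([p.persistence_mean for p in config.class_params])[class_flat]
    amp = np.array([p.amplitude for p in config.class_params])[class_flat]
    peak = np.array([p.peak_doy for p in config.class_params])[class_flat]
    sd = np.array([p.noise_sd for p in config.class_params])[class_flat]
    bprob = np.array([p.breakout_prob for p in config.class_params])[class_flat]

    # seasonal cycle peaking at peak_doy (365-day convention)
    t_days = start_doy - 1 + 15.0 * np.arange(n_epochs)
    phase = peak - 365.0 / 4.0
    seasonal = amp[None, :] * np.sin(
        2.0 * np.pi * (t_days[:, None] - phase[None, :]) / 365.0
    )

    # stationary AR(1) noise, innovation scaled so marginal s.d. = noise_sd
    rho = config.ar1_coef
    innov_scale = np.sqrt(1.0 - rho**2)
    noise = np.empty((n_epochs, n_pix))
    e = sd * rng.standard_normal(n_pix)
    noise[0] = e
    for t in range(1, n_epochs):
        e = rho * e + innov_scale * sd * rng.standard_normal(n_pix)
        noise[t] = e

    values = np.clip(pers[None, :] + seasonal + noise, 0.0, 1.0)
    # offshore decay of the fast-ice zone (1 at the coast, 0 beyond decay_end)
    y_km = (np.arange(rows) + 0.5) * config.cell_km
    zone = np.clip(
        (config.ice_decay_end_km - y_km)
        / (config.ice_decay_end_km - config.ice_decay_start_km),
        0.0,
        1.0,
    )
    values *= np.broadcast_to(zone[:, None], (rows, cols)).ravel()[None, :]
    _apply_breakouts(values, config, bprob, rng)

    colonies = _place_colonies(config, rng)

    grid = IceTimeSeriesGrid(
        values=values.reshape(n_epochs, rows, cols),
        epoch_dates=epoch_dates,
        mask=np.zeros((rows, cols), dtype=bool),
        cell_km=config.cell_km,
    )
    truth = SyntheticTruth(
        class_map=class_map,
        colony_points=colonies,
        true_params=tuple(config.class_params),
    )
    return grid, truth


def generate_bathymetry(config: IceScapeConfig) -> np.ndarray:
    """Depth grid (m, negative below sea level) on the icescape grid.

    ``shelf_break`` profile: a gentle continental shelf from the coast,
    a steep break band between ``break_start_km`` and ``break_end_km``
    crossing the -800 m level, and a gentle abyssal ramp beyond.  A
    smooth lateral modulation makes depth, slope and isobath distance
    vary along-shore (so no covariate is degenerate on the coast row).
    ``linear`` is a plain ramp from 0 at the coast to ``max_depth_m``;
    ``flat`` is constant ``coast_depth_m`` (degenerate on purpose, for
    testing the no-isobath error path).
    """
    rows, cols = config.grid_shape
    y_km = (np.arange(rows) + 0.5) * config.cell_km
    x_km = (np.arange(cols) + 0.5) * config.cell_km
    length_km = cols * config.cell_km

    if config.bathy_profile == "flat":
        return np.full((rows, cols), config.coast_depth_m)
    if config.bathy_profile == "linear":
        prof = config.max_depth_m * y_km / y_km[-1]
        return np.broadcast_to(prof[:, None], (rows, cols)).copy()
    if config.bathy_profile != "shelf_break":
        raise ValueError(f"unknown bathy_profile {config.bathy_profile!r}")

    prof = np.interp(
        y_km,
        [0.0, config.break_start_km, config.break_end_km, y_km[-1]],
        [
            config.coast_depth_m,
            config.shelf_edge_depth_m,
            config.break_bottom_depth_m,
            config.max_depth_m,
        ],
    )
    lateral = 1.0 + config.lateral_amplitude * np.sin(2.0 * np.pi * 3.0 * x_km / length_km)
    band_width = cols // config.n_classes
    class_of_col = np.minimum(np.arange(cols) // band_width, config.n_classes - 1)
    factors = np.asarray(resolve_depth_factors(config))[class_of_col]
    return prof[:, None] * (lateral * factors)[None, :]


def resolve_depth_factors(config: IceScapeConfig) -> tuple[float, ...]:
    """Per-class shelf depth factors; auto-interleaved when not given.

    The automatic rule spreads factors over [0.75, 1.25] and interleaves
    them (middle, lowest, highest, ...) so neighbouring bands get
    contrasting shelf geometry.
    """
    if config.class_depth_factors is not None:
        return tuple(config.class_depth_factors)
    n = config.n_classes
    if n == 1:
        return (1.0,)
    base = list(np.linspace(0.75, 1.25, n))
    out = []
    lo, hi = 0, n - 1
    out.append(base[n // 2])
    used = {n // 2}
    while len(out) < n:
        if lo in used:
            lo += 1
            continue
        out.append(base[lo]); used.add(lo)
        if len(out) == n:
            break
        if hi in used:
            hi -= 1
            continue
        out.append(base[hi]); used.add(hi)
    return tuple(out)
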