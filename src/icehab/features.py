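"""Geographic and biological covariates, and the 13-variable feature table.

Per 5-km cell the analysis uses seven fast-ice metrics plus depth (m),
bathymetric slope (degrees), distance to the -800 m isobath (km, a proxy
for the shelf-break foraging zone), and distances to the nearest
emperor-penguin, Adélie-penguin and Weddell-seal colony (km).  Presence
cells are those whose centroid lies within 3 km of an emperor colony;
all other fast-ice cells are absences.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

from .metrics import FastIceMetrics, block_aggregate

__all__ = [
    "FEATURE_COLUMNS",
    "slope_degrees",
    "aggregate_bathy",
    "distance_to_isobath",
    "haversine_km",
    "nearest_colony_distance",
    "label_presence",
    "build_feature_table",
    "absence_buffer_filter",
]

EARTH_RADIUS_KM = 6371.0
PRESENCE_RADIUS_KM = 3.0

#: Column order of the 13 analysis variables.
FEATURE_COLUMNS = [
    "persistence",
    "volatility",
    "timing_max_code",
    "timing_min_code",
    "magnitude",
    "trend",
    "extent_km",
    "depth_m",
    "slope_deg",
    "dist_isobath800_km",
    "dist_emperor_km",
    "dist_adelie_km",
    "dist_weddell_km",
]


def slope_degrees(depth: np.ndarray, cell_km: float) -> np.ndarray:
    """Bathymetric slope in degrees from a regular depth grid.

    Central finite differences of depth (m) over the cell spacing (m);
    slope = atan(|grad z|) in degrees.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.ndim != 2 or min(depth.shape) < 2:
        raise ValueError("depth grid must be 2-D with at least 2 cells per axis")
    spacing_m = cell_km * 1000.0
    gy, gx = np.gradient(depth, spacing_m)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def aggregate_bathy(depth: np.ndarray, factor: int = 10) -> np.ndarray:
    """Block-mean a fine bathymetry grid to the analysis resolution."""
    return block_aggregate(depth, factor)


def distance_to_isobath(
    depth: np.ndarray, cell_km: float, level: float = -800.0
) -> np.ndarray:
    """Distance (km) from every cell centroid to the depth contour at ``level``.

    The contour is traced with linear interpolation along cell edges; the
    distance is planar (km-grid convention) to the nearest contour vertex.
    """
    depth = np.asarray(depth, dtype=float)
    contours = measure.find_contours(depth, level)
    if not contours:
        raise ValueError(f"depth grid never crosses the {level} m level")
    verts = np.vstack(contours)  # fractional (row, col) index coordinates
    tree = cKDTree(verts)
    rows, cols = depth.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist_idx, _ = tree.query(pts)
    return dist_idx.reshape(rows, cols) * cell_km


def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km (R = 6371 km), for lon/lat inputs."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def nearest_colony_distance(
    cell_xy: np.ndarray, colony_xy: np.ndarray, exclude_nearest: np.ndarray | None = None
) -> np.ndarray:
    """Planar distance (km) from each cell to its nearest colony.

    Where ``exclude_nearest`` is True for a cell, the closest colony is
    skipped and the distance to the second-closest returned — used for
    the distance-to-nearest-emperor variable at presence cells, whose
    defining colony would otherwise make the variable trivially ~0.
    """
    colony_xy = np.atleast_2d(np.asarray(colony_xy, dtype=float))
    if colony_xy.shape[0] == 0:
        raise ValueError("empty colony set")
    tree = cKDTree(colony_xy)
    cell_xy = np.atleast_2d(np.asarray(cell_xy, dtype=float))
    if exclude_nearest is None:
        dist, _ = tree.query(cell_xy)
        return dist
    if colony_xy.shape[0] < 2:
        raise ValueError("cannot exclude the nearest colony with fewer than 2 colonies")
    dist2, _ = tree.query(cell_xy, k=2)
    excl = np.asarray(exclude_nearest, dtype=bool)
    return np.where(excl, dist2[:, 1], dist2[:, 0])


def label_presence(
    cell_xy: np.ndarray, emperor_xy: np.ndarray, radius_km: float = PRESENCE_RADIUS_KM
) -> np.ndarray:
    """True for cells whose centroid is within ``radius_km`` of any emperor colony."""
    emperor_xy = np.atleast_2d(np.asarray(emperor_xy, dtype=float))
    cell_tree = cKDTree(np.atleast_2d(np.asarray(cell_xy, dtype=float)))
    near = cell_tree.query_ball_point(emperor_xy, r=radius_km)
    flags = np.zeros(len(cell_xy), dtype=bool)
    orphaned = 0
    for idx in near:
        if idx:
            flags[idx] = True
        else:
            orphaned += 1
    if orphaned:
        warnings.warn(
            f"{orphaned} emperor colony(ies) lie farther than {radius_km} km "
            "from every cell centroid and mark no presence cell",
            stacklevel=2,
        )
    return flags


def build_feature_table(
    metrics: FastIceMetrics,
    depth: np.ndarray,
    colonies: pd.DataFrame,
    isobath_level: float = -800.0,
    presence_radius_km: float = PRESENCE_RADIUS_KM,
) -> pd.DataFrame:
    """Assemble the 13-variable habitat feature table on the analysis grid.

    ``colonies`` needs columns species ('emperor'/'adelie'/'weddell'),
    x_km, y_km.  Cells with any missing variable (masked ice pixels) are
    dropped.  Returns one row per retained cell with cell_id, row, col,
    x_km, y_km, is_presence and the 13 variables in FEATURE_COLUMNS order.
    """
    df = metrics.to_dataframe()
    cell_km = metrics.cell_km
    df["depth_m"] = np.asarray(depth, dtype=float).ravel()
    df["slope_deg"] = slope_degrees(depth, cell_km).ravel()
    df["dist_isobath800_km"] = distance_to_isobath(depth, cell_km, isobath_level).ravel()

    cell_xy = df[["x_km", "y_km"]].to_numpy()
    by_species = {
        sp: g[["x_km", "y_km"]].to_numpy() for sp, g in colonies.groupby("species")
    }
    for sp in ("emperor", "adelie", "weddell"):
        if sp not in by_species:
            raise ValueError(f"no colonies of species {sp!r}")

    is_presence = label_presence(cell_xy, by_species["emperor"], presence_radius_km)
    df["is_presence"] = is_presence
    df["dist_emperor_km"] = nearest_colony_distance(
        cell_xy, by_species["emperor"], exclude_nearest=is_presence
    )
    df["dist_adelie_km"] = nearest_colony_distance(cell_xy, by_species["adelie"])
    df["dist_weddell_km"] = nearest_colony_distance(cell_xy, by_species["weddell"])

    keep = ["cell_id", "row", "col", "x_km", "y_km", "is_presence"] + FEATURE_COLUMNS
    out = df[keep].dropna(subset=FEATURE_COLUMNS).reset_index(drop=True)
    return out


def absence_buffer_filter(
    table: pd.DataFrame, emperor_xy: np.ndarray, buffer_km: float
) -> pd.DataFrame:
    """Drop absence rows within ``buffer_km`` of any emperor colony.

    Presence rows are never dropped.  A buffer below the 3-km presence
    radius would contradict the presence definition and only triggers a
    warning (nothing can be inside it that is not already presence).
    """
    if buffer_km < PRESENCE_RADIUS_KM:
        warnings.warn(
            f"buffer {buffer_km} km is below the {PRESENCE_RADIUS_KM} km presence radius",
            stacklevel=2,
        )
    if buffer_km <= 0:
        return table.copy()
    dist = nearest_colony_distance(table[["x_km", "y_km"]].to_numpy(), emperor_xy)
    drop = (~table["is_presence"].to_numpy()) & (dist < buffer_km)
    return table.loc[~drop].reset_index(drop=True)
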