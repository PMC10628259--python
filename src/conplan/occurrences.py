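"""Occurrence-record cleaning operators.

Three generic operators used when preparing point records for distribution
modeling: grid-and-thin (one record per species per cell), a single-pass
k-nearest-neighbour mean-distance outlier filter, and truncation of a
suitability surface to a buffered range polygon. Distances are Euclidean in
projected grid units (the pipeline assumes an equal-area-style projection).
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .core import Grid

logger = logging.getLogger(__name__)


def grid_and_thin(points: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Thin occurrence points to one presence per species per grid cell.

    Cell membership uses half-open intervals per axis (a point exactly on a
    boundary belongs to the higher-index cell). Points outside the grid are
    dropped with a logged count. Returns a DataFrame of unique
    (species_id, row, col) presences.
    """
    if points.empty:
        logger.warning("grid_and_thin: empty input")
        return pd.DataFrame(columns=["species_id", "row", "col"])
    row, col = grid.point_to_cell(points["x"].to_numpy(), points["y"].to_numpy())
    inside = grid.contains(row, col)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("grid_and_thin: dropped %d out-of-grid points", n_dropped)
    out = pd.DataFrame({
        "species_id": points["species_id"].to_numpy()[inside],
        "row": row[inside],
        "col": col[inside],
    })
    return (out.drop_duplicates()
               .sort_values(["species_id", "row", "col"])
               .reset_index(drop=True))


def knn_outlier_filter(
    points: pd.DataFrame,
    max_mean_dist: Union[float, Mapping[str, float]],
    k: int = 3,
    groups: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Remove spatial outliers by mean distance to the k nearest conspecifics.

    A point is removed when the mean Euclidean distance to its ``k`` nearest
    other points of the same species exceeds the threshold. The pass is
    single-shot (distances are computed once on the full input, so coincident
    duplicate outliers are judged against the same neighbourhood and removed
    together). Species with ``<= k`` points pass through unchanged, since the
    statistic is undefined for them.

    ``max_mean_dist`` may be a scalar or a per-group mapping; ``groups`` then
    maps species_id to group name.
    """
    if k < 1:
        raise ValueError("k must be >= 1")

    def threshold_for(sid: str) -> float:
        if isinstance(max_mean_dist, Mapping):
            if groups is None:
                raise ValueError("groups mapping required with per-group thresholds")
            return float(max_mean_dist[groups[sid]])
        return float(max_mean_dist)

    if not isinstance(max_mean_dist, Mapping) and float(max_mean_dist) <= 0:
        raise ValueError("max_mean_dist must be positive")

    keep_parts = []
    for sid, sub in points.groupby("species_id", sort=False):
        if len(sub) <= k:
            keep_parts.append(sub)
            continue
        thr = threshold_for(sid)
        if thr <= 0:
            raise ValueError("max_mean_dist must be positive")
        xy = sub[["x", "y"]].to_numpy(float)
        tree = cKDTree(xy)
        # k+1 neighbours: the nearest is the point itself (distance 0).
        dists, _ = tree.query(xy, k=k + 1)
        mean_dist = dists[:, 1:].mean(axis=1)
        removed = mean_dist > thr
        if removed.any():
            logger.info("knn_outlier_filter: %s removed %d/%d points",
                        sid, int(removed.sum()), len(sub))
        keep_parts.append(sub[~removed])
    if not keep_parts:
        return points.iloc[0:0]
    return pd.concat(keep_parts).sort_index()


def buffer_range_truncate(
    suitability: np.ndarray,
    range_polygon: shapely.Geometry,
    buffer: float,
    grid: Grid,
) -> np.ndarray:
    """Zero suitability outside the range polygon dilated by ``buffer``.

    Cell membership is decided by the cell center; cells whose centers fall
    on the dilated boundary are kept. Used to stop bias-corrected or
    future-climate projections from inventing long-distance colonisation
    (the planning default is a 500 km-equivalent buffer).
    """
    if buffer < 0:
        raise ValueError("buffer must be nonnegative")
    suitability = np.asarray(suitability, dtype=float)
    if suitability.shape != grid.shape:
        raise ValueError("suitability raster does not match grid")
    if range_polygon.is_empty:
        import warnings
        warnings.warn("buffer_range_truncate: empty polygon, returning zeros")
        return np.zeros_like(suitability)
    dilated = range_polygon.buffer(buffer) if buffer > 0 else range_polygon
    x, y = grid.cell_centers()
    centers = shapely.points(x.ravel(), y.ravel())
    inside = shapely.covers(dilated, centers).reshape(grid.shape)
    return np.where(inside, suitability, 0.0)
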