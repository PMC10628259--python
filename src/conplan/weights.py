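"""Species weights and weighted feature layers for planning scenarios.

Builds the inputs the prioritizer consumes: climate "win-win" combined
layers (current/future overlap weighted highest), kingdom-balanced scenario
weights, at-risk subsets under national or global assessment schemes,
fair-proportion evolutionary distinctiveness, functional distinctiveness via
Gower distance -> principal coordinates -> leave-one-out hull contribution,
and transnational (weighted-endemism) weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import SuitabilityStack

NATIONAL_AT_RISK = frozenset({"special_concern", "threatened", "endangered"})
GLOBAL_AT_RISK = frozenset({"vulnerable", "endangered", "critically_endangered"})

#: Default win-win coefficients (overlap, current-only, future-only). The
#: strict ordering w_both > w_now > w_fut > 0 encodes the confidence ranking
#: of cell types; the magnitudes are a package default, fully configurable.
DEFAULT_WINWIN = (0.5, 0.35, 0.15)


@dataclass
class FeatureLayer:
    """Per-species combined rasters fed to the prioritizer."""

    stack: SuitabilityStack
    provenance: dict = field(default_factory=dict)


def _check_aligned(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"rasters not aligned: {a.shape} vs {b.shape}")


def ensemble_average(pred_a: np.ndarray, pred_b: np.ndarray,
                     weights: tuple[float, float] = (0.7, 0.3)) -> np.ndarray:
    """Cellwise weighted mean of two model predictions.

    The default 0.7/0.3 weighting favours the algorithm with the stronger
    sampling-bias correction.
    """
    pred_a = np.asarray(pred_a, float)
    pred_b = np.asarray(pred_b, float)
    _check_aligned(pred_a, pred_b)
    wa, wb = weights
    if wa < 0 or wb < 0 or not np.isclose(wa + wb, 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    return wa * pred_a + wb * pred_b


def winwin_combine(current: SuitabilityStack, future: SuitabilityStack,
                   coeffs: tuple[float, float, float] = DEFAULT_WINWIN) -> FeatureLayer:
    """Combine current and future suitability into climate-robust layers.

    Per cell: ``c = w_both * min(cur, fut) + w_now * cur + w_fut * fut``,
    then rescaled so each species' maximum is 1. Cells inside both the
    current and future range score highest (candidate climate refugia),
    current-only cells next, future-only cells lowest but still positive.
    """
    w_both, w_now, w_fut = coeffs
    if not (w_both > w_now > w_fut > 0):
        raise ValueError("win-win coefficients must satisfy w_both > w_now > w_fut > 0")
    _check_aligned(current.values, future.values)
    if current.species_ids != future.species_ids:
        raise ValueError("current and future stacks must list the same species")
    cur, fut = current.values, future.values
    c = w_both * np.minimum(cur, fut) + w_now * cur + w_fut * fut
    peak = c.reshape(c.shape[0], -1).max(axis=1)
    scale = np.where(peak > 0, peak, 1.0)
    c = c / scale[:, None, None]
    return FeatureLayer(
        stack=SuitabilityStack(c, list(current.species_ids)),
        provenance={"coeffs": tuple(coeffs), "time_slices": ("current", "future")},
    )


def kingdom_balance(table: pd.DataFrame,
                    kingdom_totals: Optional[Mapping[str, float]] = None,
                    weight_col: str = "weight") -> pd.DataFrame:
    """Rescale weights so each kingdom's weights sum to its allotted total.

    By default every kingdom present receives an equal share of a unit
    total, so no taxonomic kingdom dominates by species count alone.
    Relative weights within a kingdom are preserved.
    """
    if table.empty:
        raise ValueError("cannot balance an empty weight table")
    out = table.copy()
    kingdoms = out["kingdom"].unique()
    if kingdom_totals is None:
        kingdom_totals = {k: 1.0 / len(kingdoms) for k in kingdoms}
    for k in kingdoms:
        sel = out["kingdom"] == k
        total = out.loc[sel, weight_col].sum()
        if total <= 0:
            raise ValueError(f"kingdom {k!r} has all-zero weights")
        out.loc[sel, weight_col] *= kingdom_totals.get(k, 0.0) / total
    return out


def subset_by_status(table: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Keep only at-risk species under the chosen assessment scheme.

    ``scheme`` is "national" (statuses special concern / threatened /
    endangered) or "global" (vulnerable / endangered / critically
    endangered). Weights are re-balanced across the kingdoms that remain.
    """
    if scheme == "national":
        col, allowed = "status_national", NATIONAL_AT_RISK
    elif scheme == "global":
        col, allowed = "status_global", GLOBAL_AT_RISK
    else:
        raise ValueError("scheme must be 'national' or 'global'")
    sub = table[table[col].isin(allowed)].copy()
    if sub.empty:
        raise ValueError(f"no species at risk under the {scheme} scheme; "
                         "scenario undefined")
    return kingdom_balance(sub)


def fair_proportion_ed(tree: dendropy.Tree) -> pd.Series:
    """Fair-proportion evolutionary distinctiveness per tip.

    Each branch's length is divided equally among its descendant tips; a
    tip's score is the sum of its shares along the path to the root. The
    scores sum to the total tree length.
    """
    if not tree.is_rooted:
        raise ValueError("fair-proportion ED requires a rooted tree")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    scores = {label: 0.0 for label in labels}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._fp_tips = [node.taxon.label]
        else:
            node._fp_tips = [t for ch in node.child_nodes() for t in ch._fp_tips]
        length = node.edge.length or 0.0
        if length < 0:
            raise ValueError("negative branch length")
        if node.parent_node is not None and length > 0:
            share = length / len(node._fp_tips)
            for t in node._fp_tips:
                scores[t] += share
    return pd.Series(scores, name="ed")


def gower_distance(traits: pd.DataFrame) -> np.ndarray:
    """Gower distance matrix over mixed numeric/categorical trait columns.

    Numeric columns are range-normalized; categorical columns contribute a
    0/1 mismatch. Constant columns are dropped with a warning.
    """
    numeric, categorical = [], []
    for col in traits.columns:
        series = traits[col]
        if pd.api.types.is_numeric_dtype(series):
            if series.max() > series.min():
                numeric.append(col)
            else:
                warnings.warn(f"dropping constant trait column {col!r}")
        else:
            if series.nunique() > 1:
                categorical.append(col)
            else:
                warnings.warn(f"dropping constant trait column {col!r}")
    if not numeric and not categorical:
        raise ValueError("all trait columns are constant")
    n = len(traits)
    total = np.zeros((n, n))
    for col in numeric:
        v = traits[col].to_numpy(float)
        rng = v.max() - v.min()
        total += np.abs(v[:, None] - v[None, :]) / rng
    for col in categorical:
        v = traits[col].to_numpy()
        total += (v[:, None] != v[None, :]).astype(float)
    return total / (len(numeric) + len(categorical))


def _hull_measure(points: np.ndarray) -> float:
    """Area of the convex hull of 2-D points; falls back to the spread of
    the first axis when the points are (near-)collinear."""
    from scipy.spatial import ConvexHull, QhullError

    if len(points) < 3:
        return float(np.ptp(points[:, 0]))
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return float(np.ptp(points[:, 0]))


def functional_distinctiveness(traits: pd.DataFrame,
                               kingdom: Optional[pd.Series] = None) -> pd.Series:
    """Leave-one-out trait-space contribution scores, summing to 1 per kingdom.

    Pipeline: Gower distance on normalized traits -> principal-coordinates
    embedding (first two axes) -> each species' contribution is the decrease
    in the occupied 2-D region (convex-hull area) when it is left out.
    Negative deltas (interior species) clip to 0; scores are normalized to
    sum to 1 within each kingdom so kingdoms weigh evenly downstream.
    """
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa

    if kingdom is None:
        kingdom = pd.Series("all", index=traits.index)
    kingdom = kingdom.reindex(traits.index)
    out = pd.Series(0.0, index=traits.index, name="fd")
    for k, idx in traits.groupby(kingdom).groups.items():
        sub = traits.loc[idx]
        if len(sub) < 4:
            raise ValueError(f"kingdom {k!r} needs >= 4 species for a 2-D embedding")
        dm = gower_distance(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # negative-eigenvalue notices
            ord_res = pcoa(DistanceMatrix(dm, ids=[str(i) for i in range(len(sub))]),
                           number_of_dimensions=2)
        pts = ord_res.samples.to_numpy()[:, :2]
        full = _hull_measure(pts)
        deltas = np.empty(len(sub))
        for i in range(len(sub)):
            loo = _hull_measure(np.delete(pts, i, axis=0))
            deltas[i] = full - loo
        deltas = np.clip(deltas, 0.0, None)
        if deltas.sum() <= 0:
            warnings.warn(f"kingdom {k!r}: degenerate trait space, uniform scores")
            deltas[:] = 1.0
        out.loc[idx] = deltas / deltas.sum()
    return out


def endemism_weight(focal_stack: SuitabilityStack,
                    total_stack: SuitabilityStack) -> pd.Series:
    """Share of each species' total range that falls in the focal region.

    ``share_j = sum(focal suitabilities) / sum(total-extent suitabilities)``,
    in [0, 1]. Species with zero total range are an error.
    """
    if focal_stack.species_ids != total_stack.species_ids:
        raise ValueError("stacks must list the same species in the same order")
    focal = focal_stack.flat().sum(axis=1)
    total = total_stack.flat().sum(axis=1)
    if (total <= 0).any():
        bad = [s for s, t in zip(total_stack.species_ids, total) if t <= 0]
        raise ValueError(f"zero total range for species {bad[:5]}")
    share = focal / total
    if (share > 1 + 1e-9).any():
        raise ValueError("focal range exceeds total range; check extents")
    return pd.Series(np.clip(share, 0.0, 1.0),
                     index=focal_stack.species_ids, name="endemism_share")


def scenario_weights(species_table: pd.DataFrame,
                     source: str = "uniform",
                     fd: Optional[pd.Series] = None,
                     pd_scores: Optional[pd.Series] = None) -> pd.DataFrame:
    """Build a kingdom-balanced weight table from one weight source.

    ``source`` is one of uniform / endemism / fd / pd. The returned table
    has a ``weight`` column whose within-kingdom sums are equal.
    """
    out = species_table.copy()
    if source == "uniform":
        out["weight"] = 1.0
    elif source == "endemism":
        out["weight"] = out["endemism_share"].to_numpy(float)
    elif source == "fd":
        if fd is None:
            raise ValueError("fd scores required for source='fd'")
        out["weight"] = fd.reindex(out["species_id"]).to_numpy(float)
    elif source == "pd":
        if pd_scores is None:
            raise ValueError("pd scores required for source='pd'")
        out["weight"] = pd_scores.reindex(out["species_id"]).to_numpy(float)
    else:
        raise ValueError(f"unknown weight source {source!r}")
    if out["weight"].isna().any():
        raise ValueError("weight source missing values for some species")
    return kingdom_balance(out)
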