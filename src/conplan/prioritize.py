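"""Greedy marginal-loss spatial prioritization (core-area family).

Ranks land by iteratively removing the remaining cell whose loss of retained
conservation value is smallest, in the style of core-area Zonation. The
default rule scores a cell by the species for which it holds the largest
weighted share of remaining range:

    delta_i = max_j  w_j * c_ij / Q_j,    Q_j = sum over remaining cells of c_ij

An additive-benefit alternative (sum over species) is provided. A
hierarchical mask forces already-protected cells to outrank all free cells:
free cells are removed first, protected cells last, and the removal position
divided by the number of ranked cells gives the priority rank in (0, 1].

The implementation caches marginal losses in a lazy min-heap. Because Q_j
only decreases, cached losses are lower bounds of current losses, so a
popped entry re-evaluated against the current state and confirmed freshest
is exactly the cell the naive full-recomputation algorithm would pick, with
ties broken toward the lowest flattened cell index.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .core import EXCLUDED, FREE, PROTECTED, MaskStack, RankMap, SuitabilityStack

RULES = ("caz", "abf")


def coverage_to_class(coverage: np.ndarray, hfi: np.ndarray,
                      excluded: np.ndarray,
                      protected_threshold: float = 0.43,
                      hfi_threshold: float = 10.0,
                      subregions: Optional[np.ndarray] = None) -> MaskStack:
    """Classify cells as excluded / free / protected.

    A cell is excluded when its excluded flag is set or its human-footprint
    value is strictly above ``hfi_threshold``; otherwise it is protected when
    fractional protected-area coverage is at least ``protected_threshold``
    (inclusive), else free.
    """
    coverage = np.asarray(coverage, float)
    hfi = np.asarray(hfi, float)
    excluded = np.asarray(excluded).astype(bool)
    if coverage.shape != hfi.shape or coverage.shape != excluded.shape:
        raise ValueError("mask input rasters are not aligned")
    cls = np.full(coverage.shape, FREE, dtype=np.int8)
    cls[coverage >= protected_threshold] = PROTECTED
    cls[excluded | (hfi > hfi_threshold)] = EXCLUDED
    return MaskStack(cell_class=cls, subregions=subregions)


@dataclass
class PrioritizerState:
    """Mutable state of a greedy run over one ranking domain."""

    features: sparse.csc_array          # (n_species, n_cells), full-grid columns
    weights: np.ndarray                 # (n_species,)
    Q: np.ndarray                       # per-species remaining totals
    remaining: np.ndarray               # boolean over flattened cells
    rule: str = "caz"

    def cell_column(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        start, end = self.features.indptr[i], self.features.indptr[i + 1]
        return self.features.indices[start:end], self.features.data[start:end]


def marginal_loss(state: PrioritizerState, cell: int) -> float:
    """Loss of retained value if ``cell`` were removed now.

    Species whose remaining total Q_j is zero contribute nothing.
    """
    if not state.remaining.any():
        raise ValueError("remaining cell set is empty")
    if not state.remaining[cell]:
        raise ValueError("cell is not in the remaining set")
    rows, vals = state.cell_column(cell)
    return _loss(rows, vals, state.weights, state.Q, state.rule)


def _loss(rows: np.ndarray, vals: np.ndarray, w: np.ndarray, Q: np.ndarray,
          rule: str) -> float:
    if rows.size == 0:
        return 0.0
    q = Q[rows]
    ok = q > 0
    if not ok.any():
        return 0.0
    terms = w[rows[ok]] * vals[ok] / q[ok]
    return float(terms.max() if rule == "caz" else terms.sum())


def _greedy_phase(state: PrioritizerState, cells: np.ndarray) -> list[int]:
    """Remove all ``cells`` in greedy order, mutating state; returns order.

    Lazy-heap schedule; exact tie-break toward the lowest cell index.
    """
    if cells.size == 0:
        return []
    heap = []
    stamp = {}
    for i in cells:
        rows, vals = state.cell_column(int(i))
        heap.append((_loss(rows, vals, state.weights, state.Q, state.rule), int(i)))
        stamp[int(i)] = 0
    heapq.heapify(heap)
    order: list[int] = []
    step = 0
    features = state.features
    while heap:
        delta, i = heapq.heappop(heap)
        if stamp[i] < step:
            rows, vals = state.cell_column(i)
            stamp[i] = step
            heapq.heappush(heap, (_loss(rows, vals, state.weights, state.Q,
                                        state.rule), i))
            continue
        order.append(i)
        state.remaining[i] = False
        rows, vals = state.cell_column(i)
        if rows.size:
            q = state.Q
            q[rows] = np.maximum(q[rows] - vals, 0.0)
        step += 1
    return order


def _prepare(features: SuitabilityStack, weights) -> tuple[sparse.csc_array, np.ndarray]:
    flat = features.flat()
    if (flat < 0).any():
        raise ValueError("feature values must be nonnegative")
    if isinstance(weights, pd.Series):
        weights = weights.reindex(features.species_ids).to_numpy(float)
    w = np.asarray(weights, float)
    if w.shape != (features.n_species,):
        raise ValueError("weights length must match species count")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    return sparse.csc_array(flat), w


def greedy_rank(features: SuitabilityStack, weights, mask: MaskStack,
                rule: str = "caz") -> RankMap:
    """Rank every non-excluded cell by greedy marginal-loss removal.

    Free cells are removed (ranked lowest) before any protected cell, so
    every protected cell outranks every free cell. Rank = removal position /
    number of ranked cells, in (0, 1].
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    if mask.cell_class.shape != features.shape:
        raise ValueError("mask and features are not aligned")
    csc, w = _prepare(features, weights)
    cls = mask.cell_class.ravel()
    free = np.flatnonzero(cls == FREE)
    prot = np.flatnonzero(cls == PROTECTED)
    n_ranked = free.size + prot.size
    if free.size == 0 and prot.size == 0:
        raise ValueError("no available cells to rank")

    remaining = (cls != EXCLUDED)
    Q = np.zeros(features.n_species)
    avail_idx = np.flatnonzero(remaining)
    Q += np.asarray(csc[:, avail_idx].sum(axis=1)).ravel()
    if not (Q > 0).any():
        warnings.warn("all-zero feature stack: ranks are pure tie-break order")
    state = PrioritizerState(features=csc, weights=w, Q=Q, remaining=remaining,
                             rule=rule)
    order = _greedy_phase(state, free) + _greedy_phase(state, prot)

    rank = np.full(cls.shape, np.nan)
    positions = np.arange(1, n_ranked + 1, dtype=float) / n_ranked
    rank[np.asarray(order, dtype=int)] = positions
    return RankMap(rank=rank.reshape(features.shape),
                   metadata={"rule": rule, "tie_break": "lowest_index",
                             "hierarchical": True, "domain": "whole"})


def subregion_rank(features: SuitabilityStack, weights, mask: MaskStack,
                   subregions: Optional[np.ndarray] = None,
                   rule: str = "caz") -> RankMap:
    """Independent prioritization per subregion, stitched into one map.

    Each subregion sees only its own cells: per-species remaining totals Q_j
    are computed within the subregion, so each region prioritizes the
    species and endemism specific to it. Ranks are normalized to (0, 1]
    within each subregion before stitching, which makes a common top-
    fraction threshold select the top fraction of every subregion.
    """
    if subregions is None:
        subregions = mask.subregions
    if subregions is None:
        raise ValueError("subregion labels required")
    subregions = np.asarray(subregions)
    if subregions.shape != features.shape:
        raise ValueError("subregion raster is not aligned")
    cls = mask.cell_class
    rank = np.full(cls.shape, np.nan).ravel()
    for label in np.unique(subregions):
        in_sub = (subregions == label)
        sub_cls = np.where(in_sub, cls, EXCLUDED).astype(np.int8)
        if not (sub_cls != EXCLUDED).any():
            warnings.warn(f"subregion {label!r} has no available cells; skipped")
            continue
        sub_mask = MaskStack(cell_class=sub_cls)
        sub_rank = greedy_rank(features, weights, sub_mask, rule=rule)
        flat = sub_rank.rank.ravel()
        got = np.isfinite(flat)
        rank[got] = flat[got]
    return RankMap(rank=rank.reshape(cls.shape),
                   metadata={"rule": rule, "tie_break": "lowest_index",
                             "hierarchical": True, "domain": "subregion"})


def _quota(fraction: float, n: int) -> int:
    # ceiling with a guard against float fuzz (0.3 * N must not round up).
    return int(math.ceil(fraction * n - 1e-9))


def top_fraction(rank_map: RankMap, fraction: float = 0.30,
                 mask: Optional[MaskStack] = None,
                 subregions: Optional[np.ndarray] = None) -> np.ndarray:
    """Binary selection of the top ``fraction`` of ranked cells.

    Uses a ceiling quota ("protect at least"). With ``subregions`` given,
    the quota applies within every subregion (the map must then hold
    within-subregion ranks); a subregion whose protected share already
    exceeds the fraction keeps all its protected cells (the quota expands,
    since protected land cannot be deselected). In the whole-domain
    hierarchical case a fraction smaller than the protected share is an
    error instead.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    rank = rank_map.rank
    finite = np.isfinite(rank)
    protected = mask.protected if mask is not None else None
    selection = np.zeros(rank.shape, dtype=bool)
    if subregions is None:
        domains = [finite]
    else:
        subregions = np.asarray(subregions)
        domains = [finite & (subregions == lab) for lab in np.unique(subregions)]
    for dom in domains:
        n = int(dom.sum())
        if n == 0:
            continue
        k = _quota(fraction, n)
        if protected is not None:
            n_prot = int((protected & dom).sum())
            if k < n_prot:
                if subregions is None:
                    raise ValueError(
                        "fraction selects fewer cells than are already "
                        "protected; hierarchical selection undefined")
                k = n_prot
        vals = rank[dom]
        cutoff = np.partition(vals, n - k)[n - k]
        selection |= dom & (rank >= cutoff)
    return selection


def subregion_share(selection: np.ndarray, subregions: np.ndarray,
                    mask: Optional[MaskStack] = None) -> pd.Series:
    """Selected share of each subregion's non-excluded cells."""
    selection = np.asarray(selection, bool)
    subregions = np.asarray(subregions)
    if selection.shape != subregions.shape:
        raise ValueError("selection and subregion labels are not aligned")
    eligible = mask.available if mask is not None else np.ones(selection.shape, bool)
    shares = {}
    for lab in np.unique(subregions):
        dom = (subregions == lab) & eligible
        n = int(dom.sum())
        shares[lab] = float((selection & dom).sum()) / n if n else np.nan
    return pd.Series(shares, name="share")
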