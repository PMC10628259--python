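"""Scenario evaluation: Species Protection Index, weighted-endemism capture,
and trade-offs against a reference scenario.

A species' range is the sum of its suitability values over the evaluation
domain. Protection targets scale with rarity: the commonest decile of
species needs only 10% of its range protected, the rarest decile needs
100%, and targets for species in between are linear in log range size. A
species is "protected" by a selection when its protected range fraction
meets or exceeds its target; the SPI of a selection is the percentage of
species protected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import SuitabilityStack

TARGET_COMMON = 0.10   # protected-range target for the commonest decile
TARGET_RARE = 1.0      # target for the rarest decile


def range_size(stack: SuitabilityStack,
               domain: Optional[np.ndarray] = None) -> pd.Series:
    """Per-species range size: sum of suitabilities over the domain."""
    flat = stack.flat()
    if domain is not None:
        domain = np.asarray(domain, bool).ravel()
        if domain.size != flat.shape[1]:
            raise ValueError("domain mask is not aligned with the stack")
        flat = flat[:, domain]
    if not np.isfinite(flat).all():
        raise ValueError("suitability stack contains non-finite values")
    return pd.Series(flat.sum(axis=1), index=stack.species_ids, name="range_size")


def spi_targets(range_sizes: pd.Series,
                pivots: Optional[tuple[float, float]] = None,
                percentiles: tuple[float, float] = (10.0, 90.0)) -> pd.Series:
    """Rarity-scaled protection targets in [0.10, 1.0].

    With R10 and R90 the 10th and 90th percentiles of range size (linear
    interpolation between order statistics): T = 1.0 below R10, 0.10 above
    R90, and linear in ln(R) between the pivots. ``pivots`` overrides the
    percentile computation when given.
    """
    r = np.asarray(range_sizes, float)
    if (r <= 0).any():
        raise ValueError("all range sizes must be positive")
    if pivots is None:
        if r.size < 10:
            warnings.warn("fewer than 10 species: percentile pivots unstable")
        lo, hi = np.percentile(r, percentiles)
    else:
        lo, hi = pivots
    if not hi > lo:
        warnings.warn("degenerate pivots (R10 == R90): mid targets set to 0.10")
        t = np.where(r <= lo, TARGET_RARE, TARGET_COMMON)
    else:
        frac = (np.log(r) - np.log(lo)) / (np.log(hi) - np.log(lo))
        t = TARGET_RARE + (TARGET_COMMON - TARGET_RARE) * frac
        t = np.clip(t, TARGET_COMMON, TARGET_RARE)
    index = range_sizes.index if isinstance(range_sizes, pd.Series) else None
    return pd.Series(t, index=index, name="target")


@dataclass
class ProtectionReport:
    """Per-species protection assessment plus aggregate indicators."""

    per_species: pd.DataFrame        # range_size, target, protected_fraction, protected
    spi: float                       # % of species protected, 0..100
    spi_by_group: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    spi_by_status: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    capture: Optional[float] = None  # weighted-endemism capture %, 0..100

    @property
    def n_protected(self) -> int:
        return int(self.per_species["protected"].sum())

    def to_csv(self, path) -> None:
        self.per_species.to_csv(path)


def assess_protection(stack: SuitabilityStack, selection: np.ndarray,
                      targets: pd.Series,
                      species_table: Optional[pd.DataFrame] = None,
                      domain: Optional[np.ndarray] = None) -> ProtectionReport:
    """Score a binary selection against per-species targets.

    ``f_j`` is the share of species j's range inside the selection; the
    species counts as protected when ``f_j >= T_j``. Species with zero range
    in the domain are flagged and dropped from the SPI denominator.
    """
    flat = stack.flat()
    sel = np.asarray(selection, bool).ravel()
    if sel.size != flat.shape[1]:
        raise ValueError("selection is not aligned with the stack")
    if domain is not None:
        domain = np.asarray(domain, bool).ravel()
        sel = sel & domain
        totals = flat[:, domain].sum(axis=1)
    else:
        totals = flat.sum(axis=1)
    inside = flat[:, sel].sum(axis=1)

    absent = totals <= 0
    if absent.any():
        warnings.warn(f"{int(absent.sum())} species absent from the evaluation "
                      "domain; excluded from SPI")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(absent, np.nan, inside / np.where(absent, 1.0, totals))
    t = targets.reindex(stack.species_ids).to_numpy(float)
    protected = ~absent & (frac >= t)

    per_species = pd.DataFrame({
        "range_size": totals,
        "target": t,
        "protected_fraction": frac,
        "protected": protected,
        "in_domain": ~absent,
    }, index=pd.Index(stack.species_ids, name="species_id"))

    n_eval = int((~absent).sum())
    spi = 100.0 * protected.sum() / n_eval if n_eval else 0.0

    by_group = pd.Series(dtype=float)
    by_status = pd.Series(dtype=float)
    if species_table is not None:
        meta = species_table.set_index("species_id").reindex(stack.species_ids)
        meta = meta.drop(columns=[c for c in meta.columns if c in per_species.columns])
        frame = per_species[per_species["in_domain"]].join(meta)
        by_group = (frame.groupby("group")["protected"].mean() * 100.0)
        rows = {}
        if "status_national" in meta:
            from .weights import NATIONAL_AT_RISK
            sub = frame[frame["status_national"].isin(NATIONAL_AT_RISK)]
            rows["at_risk_national"] = 100.0 * sub["protected"].mean() if len(sub) else np.nan
        if "status_global" in meta:
            from .weights import GLOBAL_AT_RISK
            sub = frame[frame["status_global"].isin(GLOBAL_AT_RISK)]
            rows["at_risk_global"] = 100.0 * sub["protected"].mean() if len(sub) else np.nan
        by_status = pd.Series(rows, dtype=float)

    return ProtectionReport(per_species=per_species, spi=float(spi),
                            spi_by_group=by_group, spi_by_status=by_status)


def weighted_endemism(stack: SuitabilityStack,
                      domain: Optional[np.ndarray] = None) -> np.ndarray:
    """Weighted-endemism raster: WE_i = sum_j p_ij / R_j.

    Each species contributes exactly 1 summed over the domain, so the raster
    total equals the species count and a selection's WE sum reads as
    "species-equivalents captured".
    """
    flat = stack.flat()
    dom = (np.asarray(domain, bool).ravel() if domain is not None
           else np.ones(flat.shape[1], bool))
    totals = flat[:, dom].sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("all species must have positive range in the domain")
    we = (flat / totals[:, None]).sum(axis=0)
    we[~dom] = np.nan
    return we.reshape(stack.shape)


def biodiversity_capture(we: np.ndarray, selection: np.ndarray,
                         n_species: int) -> float:
    """Percent of total biodiversity (weighted endemism) inside a selection."""
    we = np.asarray(we, float).ravel()
    sel = np.asarray(selection, bool).ravel()
    total = np.nansum(np.where(sel, we, 0.0))
    return float(100.0 * total / n_species)


def tradeoff(n_alt: float, n_ref: float) -> tuple[float, float]:
    """Relative protection and trade-off of an alternative vs a reference.

    ``relative = 100 * n_alt / n_ref`` and ``tradeoff = relative - 100``
    (negative when the alternative protects fewer species). Scale-invariant:
    counts and percentages give identical results.
    """
    if n_ref <= 0:
        raise ValueError("reference count must be positive")
    relative = 100.0 * n_alt / n_ref
    return relative, relative - 100.0


def facet_tradeoff(protected_flags: pd.Series, contributions: pd.Series) -> float:
    """Protected share of total facet diversity, in percent.

    ``100 * sum of contributions of protected species / sum of all
    contributions`` for a functional- or phylogenetic-distinctiveness
    vector aligned to the same species.
    """
    flags = protected_flags.reindex(contributions.index)
    if flags.isna().any():
        raise ValueError("protected flags missing for some species")
    c = contributions.to_numpy(float)
    if (c < 0).any():
        raise ValueError("contributions must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("contributions sum to zero")
    return float(100.0 * c[flags.to_numpy(bool)].sum() / total)
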