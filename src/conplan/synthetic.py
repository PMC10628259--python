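"""Seeded synthetic landscapes with the statistical structure of a
continental conservation-planning problem.

The generator emulates, at desk scale, the features the planning analysis
assumes of its inputs: probabilistic, spatially autocorrelated habitat-
suitability surfaces (isotropic Gaussian bumps around a range centroid);
a strong richness gradient toward the "south" edge (row 0); a heavy-tailed
(lognormal) range-size distribution; a poleward displacement plus optional
contraction of future ranges; clustered pre-protected patches covering a
target share of cells at the 0.43 coverage threshold, placed preferentially
away from the richness gradient; a human-footprint surface that is high
where people (and species) are; and spatially biased occurrence sampling.

One global seed fans out to per-component child generators by fixed offsets,
so components are independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

from .core import Grid, SuitabilityStack

GROUP_KINGDOM = {
    "bird": "vertebrate",
    "mammal": "vertebrate",
    "amphibian_reptile": "vertebrate",
    "plant": "plant",
    "butterfly": "butterfly",
}

#: Scaled-down species pool keeping the real national pool's strong plant
#: dominance (vertebrates : plants : butterflies roughly 1 : 5 : 0.3).
DEFAULT_GROUP_COUNTS = {
    "bird": 25,
    "mammal": 15,
    "amphibian_reptile": 10,
    "plant": 230,
    "butterfly": 20,
}

NATIONAL_STATUSES_AT_RISK = ("special_concern", "threatened", "endangered")
GLOBAL_STATUSES_AT_RISK = ("vulnerable", "endangered", "critically_endangered")

# Fixed child-seed offsets (one per stochastic component).
_OFF_SPECIES = 11
_OFF_COVERAGE = 23
_OFF_HFI = 37
_OFF_EXCLUDED = 41
_OFF_SUBREGIONS = 53
_OFF_TRAITS = 67
_OFF_TREE = 79
_OFF_STATUS = 97
_OFF_OCCURRENCES = 113


@dataclass
class SyntheticConfig:
    grid_rows: int = 100
    grid_cols: int = 100
    n_species_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS))
    #: (mu, sigma) of ln(range size in cells); median e^mu cells per range.
    range_size_lognormal_params: tuple[float, float] = (5.0, 1.0)
    #: Strength of the southward richness gradient (0 = uniform centroids).
    gradient_strength: float = 3.0
    #: Poleward displacement of future range centroids, in cells.
    shift_cells: int = 8
    #: Future range width multiplier (<1 contracts ranges under warming).
    future_width_multiplier: float = 1.0
    protected_fraction: float = 0.15
    excluded_fraction: float = 0.06
    #: How strongly protected patches concentrate away from the gradient
    #: (toward the pole); 0 = uniform placement. Mild by default so no
    #: subregion starts above the 30% expansion quota.
    protected_placement_bias: float = 1.0
    n_subregions_political: int = 8
    n_subregions_ecological: int = 6
    sampling_bias_strength: float = 2.0
    #: Suitability values below this are truncated to 0 (sparse ranges).
    suitability_floor: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        for group, n in self.n_species_per_group.items():
            if group not in GROUP_KINGDOM:
                raise ValueError(f"unknown species group {group!r}")
            if n < 0:
                raise ValueError("species counts must be nonnegative")
        if sum(self.n_species_per_group.values()) == 0:
            raise ValueError("at least one species required")
        if not (0 <= self.protected_fraction <= 1 and 0 <= self.excluded_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.protected_fraction + self.excluded_fraction >= 1:
            raise ValueError("protected_fraction + excluded_fraction must be < 1")
        if self.gradient_strength < 0 or self.sampling_bias_strength < 0:
            raise ValueError("strength parameters must be nonnegative")
        if self.shift_cells < 0:
            raise ValueError("shift_cells must be nonnegative")
        if self.n_subregions_political <= 0 or self.n_subregions_ecological <= 0:
            raise ValueError("subregion counts must be positive")


@dataclass
class LandscapeBundle:
    grid: Grid
    suitability_current: SuitabilityStack
    suitability_future: SuitabilityStack
    coverage_raster: np.ndarray
    hfi_raster: np.ndarray
    excluded_raster: np.ndarray
    subregions_political: np.ndarray
    subregions_ecological: np.ndarray
    species_table: pd.DataFrame
    traits: pd.DataFrame
    tree: dendropy.Tree
    newick: str
    occurrences: Optional[pd.DataFrame] = None
    config: Optional[SyntheticConfig] = None


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


def _biased_unit(rng: np.random.Generator, n: int, strength: float,
                 toward_one: bool) -> np.ndarray:
    """Sample u in [0, 1) with density proportional to exp(±strength*u).

    ``toward_one=False`` concentrates mass near 0 (the south edge);
    strength 0 reduces to the uniform distribution.
    """
    v = rng.random(n)
    if strength == 0:
        return v
    g = float(strength)
    if toward_one:
        return np.log1p(v * np.expm1(g)) / g
    return -np.log1p(-v * (-np.expm1(-g))) / g


def _gaussian_bump(nrow: int, ncol: int, rc: float, cc: float, sigma: float,
                   floor: float) -> tuple[np.ndarray, float]:
    """Truncated Gaussian bump on the grid.

    Returns the (nrow, ncol) raster and the bump's total mass on an
    unclipped extent (same floor truncation), used for endemism shares.
    """
    half = 4.0 * sigma
    out = np.zeros((nrow, ncol))
    r0, r1 = int(np.floor(rc - half)), int(np.ceil(rc + half)) + 1
    c0, c1 = int(np.floor(cc - half)), int(np.ceil(cc + half)) + 1
    rr = np.arange(r0, r1, dtype=float)
    cols = np.arange(c0, c1, dtype=float)
    v = np.exp(-((rr[:, None] - rc) ** 2 + (cols[None, :] - cc) ** 2)
               / (2.0 * sigma * sigma))
    v[v < floor] = 0.0
    total = float(v.sum())
    gr0, gr1 = max(r0, 0), min(r1, nrow)
    gc0, gc1 = max(c0, 0), min(c1, ncol)
    if gr0 < gr1 and gc0 < gc1:
        out[gr0:gr1, gc0:gc1] = v[gr0 - r0:gr1 - r0, gc0 - c0:gc1 - c0]
    return out, total


def _patch_field(nrow: int, ncol: int, centers_r: np.ndarray, centers_c: np.ndarray,
                 radii: np.ndarray) -> np.ndarray:
    """Smooth clustered field: per cell the max over Gaussian patches."""
    rows = np.arange(nrow, dtype=float)[:, None]
    cols = np.arange(ncol, dtype=float)[None, :]
    out = np.zeros((nrow, ncol))
    for rc, cc, rad in zip(centers_r, centers_c, radii):
        d2 = (rows - rc) ** 2 + (cols - cc) ** 2
        np.maximum(out, np.exp(-d2 / (2.0 * rad * rad)), out=out)
    return out


def _random_newick(ids: list[str], rng: np.random.Generator) -> str:
    """Random sequential-join subtree over ``ids`` (no trailing semicolon)."""
    if len(ids) == 1:
        return f"{ids[0]}:0.1"
    nodes = [(sid, 0.0) for sid in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (n2, h2) = nodes.pop(j)
        (n1, h1) = nodes.pop(i)
        height = max(h1, h2) + rng.exponential(0.5) + 0.05
        merged = f"({n1}:{height - h1:.6f},{n2}:{height - h2:.6f})"
        nodes.append((merged, height))
    return nodes[0][0]


def generate_landscape(config: SyntheticConfig) -> LandscapeBundle:
    """Generate a complete, seeded synthetic planning landscape."""
    config.validate()
    nrow, ncol = config.grid_rows, config.grid_cols
    n_cells = nrow * ncol
    grid = Grid(nrow, ncol)
    floor = config.suitability_floor

    # --- species ranges ---------------------------------------------------
    groups = [g for g, n in sorted(config.n_species_per_group.items())
              for _ in range(n)]
    species_ids = []
    counters: dict[str, int] = {}
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        species_ids.append(f"{g}_{counters[g]:04d}")
    n_species = len(species_ids)

    rng_sp = _rng(config.seed, _OFF_SPECIES)
    mu, sig = config.range_size_lognormal_params
    # Centroid rows concentrate toward the south edge (row 0).
    rows_u = _biased_unit(rng_sp, n_species, config.gradient_strength, toward_one=False)
    cen_r = rows_u * (nrow - 1)
    cen_c = rng_sp.random(n_species) * (ncol - 1)
    target_cells = rng_sp.lognormal(mean=mu, sigma=sig, size=n_species)
    sigma_bump = np.sqrt(target_cells / (2.0 * np.pi))
    sigma_bump = np.clip(sigma_bump, 0.8, max(nrow, ncol) / 2.0)

    cur = np.empty((n_species, nrow, ncol))
    fut = np.empty((n_species, nrow, ncol))
    endemism = np.empty(n_species)
    sig_fut = sigma_bump * config.future_width_multiplier
    for j in range(n_species):
        cur[j], total = _gaussian_bump(nrow, ncol, cen_r[j], cen_c[j],
                                       sigma_bump[j], floor)
        endemism[j] = cur[j].sum() / total if total > 0 else 1.0
        fr = min(cen_r[j] + config.shift_cells, nrow - 1.0)
        fut[j], _ = _gaussian_bump(nrow, ncol, fr, cen_c[j], sig_fut[j], floor)
    suit_cur = SuitabilityStack(cur, list(species_ids))
    suit_fut = SuitabilityStack(fut, list(species_ids))

    # --- protected coverage (clustered, off-gradient, calibrated) ---------
    coverage = np.zeros((nrow, ncol))
    if config.protected_fraction > 0:
        rng_cov = _rng(config.seed, _OFF_COVERAGE)
        # Many small reserves (not a few blocks), so every subregion starts
        # well below the expansion quota, as real protected estates do.
        n_patches = max(6, int(round(config.protected_fraction * n_cells / 40.0)))
        pr = _biased_unit(rng_cov, n_patches, config.protected_placement_bias,
                          toward_one=True) * (nrow - 1)
        pc = rng_cov.random(n_patches) * (ncol - 1)
        scale = max(1.0, min(nrow, ncol) / 100.0)
        radii = rng_cov.uniform(1.5, 4.0, n_patches) * scale
        fld = _patch_field(nrow, ncol, pr, pc, radii)
        q = np.quantile(fld, 1.0 - config.protected_fraction)
        slope = 0.57 / max(fld.max() - q, 1e-9)
        coverage = np.clip(0.43 + (fld - q) * slope, 0.0, 1.0)
    protected_mask = coverage >= 0.43

    # --- human footprint: high near the populated south, low in reserves --
    rng_hfi = _rng(config.seed, _OFF_HFI)
    u_row = (np.arange(nrow, dtype=float) / max(nrow - 1, 1))[:, None]
    hfi = 11.0 * np.exp(-3.2 * u_row) * rng_hfi.lognormal(0.0, 0.45, (nrow, ncol))
    hfi = np.where(protected_mask, np.minimum(hfi, 9.5), hfi)

    # --- excluded land (clustered patches, never on protected cells) ------
    excluded = np.zeros((nrow, ncol), dtype=bool)
    if config.excluded_fraction > 0:
        rng_ex = _rng(config.seed, _OFF_EXCLUDED)
        n_patches = max(3, int(round(config.excluded_fraction * n_cells / 150.0)))
        er = rng_ex.random(n_patches) * (nrow - 1)
        ec = rng_ex.random(n_patches) * (ncol - 1)
        scale = max(1.0, min(nrow, ncol) / 100.0)
        radii = rng_ex.uniform(3.0, 8.0, n_patches) * scale
        fld = _patch_field(nrow, ncol, er, ec, radii)
        excluded = fld >= np.quantile(fld, 1.0 - config.excluded_fraction)
        excluded &= ~protected_mask
    excluded_raster = excluded.astype(np.int8)

    # --- subregions: political = Voronoi; ecological = latitudinal bands --
    rng_sub = _rng(config.seed, _OFF_SUBREGIONS)
    k_pol = config.n_subregions_political
    centers = np.column_stack([rng_sub.random(k_pol) * (nrow - 1),
                               rng_sub.random(k_pol) * (ncol - 1)])
    rows_g, cols_g = np.meshgrid(np.arange(nrow, dtype=float),
                                 np.arange(ncol, dtype=float), indexing="ij")
    d2 = ((rows_g[..., None] - centers[:, 0]) ** 2
          + (cols_g[..., None] - centers[:, 1]) ** 2)
    subregions_political = np.argmin(d2, axis=-1).astype(np.int32)
    k_eco = config.n_subregions_ecological
    subregions_ecological = np.minimum(
        (np.arange(nrow)[:, None] * k_eco) // nrow, k_eco - 1
    ).astype(np.int32) * np.ones((1, ncol), dtype=np.int32)

    # --- species table: range size, endemism, at-risk statuses ------------
    range_size = cur.reshape(n_species, -1).sum(axis=1)
    rng_st = _rng(config.seed, _OFF_STATUS)
    # Rarity-linked risk: rarest species most likely to be listed; the global
    # at-risk set is nested inside the national one (p_global < p_national).
    rarity_pct = pd.Series(range_size).rank(method="first").to_numpy() / n_species
    p_nat = 0.35 * (1.0 - rarity_pct) ** 2
    p_glob = 0.22 * (1.0 - rarity_pct) ** 2
    u = rng_st.random(n_species)
    at_risk_nat = u < p_nat
    at_risk_glob = u < p_glob
    status_national = np.where(
        at_risk_nat,
        rng_st.choice(NATIONAL_STATUSES_AT_RISK, n_species),
        "not_at_risk")
    status_global = np.where(
        at_risk_glob,
        rng_st.choice(GLOBAL_STATUSES_AT_RISK, n_species),
        "least_concern")
    species_table = pd.DataFrame({
        "species_id": species_ids,
        "group": groups,
        "kingdom": [GROUP_KINGDOM[g] for g in groups],
        "centroid_row": cen_r,
        "centroid_col": cen_c,
        "range_size": range_size,
        "endemism_share": np.clip(endemism, 0.0, 1.0),
        "status_national": status_national,
        "status_global": status_global,
    })

    # --- traits (complete; mixed numeric + categorical) -------------------
    rng_tr = _rng(config.seed, _OFF_TRAITS)
    kingdom_codes = pd.Categorical(species_table["kingdom"]).codes
    traits = pd.DataFrame({
        "species_id": species_ids,
        "kingdom": species_table["kingdom"],
        "body_size": rng_tr.lognormal(kingdom_codes * 0.8, 0.9, n_species),
        "fecundity": rng_tr.lognormal(1.0, 0.6, n_species),
        "generation_time": rng_tr.lognormal(kingdom_codes * 0.3, 0.5, n_species),
        "strategy": rng_tr.choice(["resident", "migrant", "dormant"], n_species),
    }).set_index("species_id")

    # --- phylogeny: one rooted tree, kingdom clades -----------------------
    rng_tree = _rng(config.seed, _OFF_TREE)
    clades = []
    for kingdom in ("vertebrate", "plant", "butterfly"):
        ids = [s for s, k in zip(species_ids, species_table["kingdom"]) if k == kingdom]
        if ids:
            clades.append(f"{_random_newick(ids, rng_tree)}:0.5")
    newick = "(" + ",".join(clades) + ");" if len(clades) > 1 else clades[0].rsplit(":", 1)[0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted",
                             preserve_underscores=True)

    return LandscapeBundle(
        grid=grid,
        suitability_current=suit_cur,
        suitability_future=suit_fut,
        coverage_raster=coverage,
        hfi_raster=hfi,
        excluded_raster=excluded_raster,
        subregions_political=subregions_political,
        subregions_ecological=subregions_ecological,
        species_table=species_table,
        traits=traits,
        tree=tree,
        newick=newick,
        config=config,
    )


def generate_occurrences(bundle: LandscapeBundle, n_points: int,
                         bias_strength: Optional[float] = None,
                         seed: Optional[int] = None,
                         error_fraction: float = 0.02) -> pd.DataFrame:
    """Spatially biased occurrence points (x, y, species_id).

    Points are allocated to species proportionally to range size, then
    placed in cells with probability proportional to
    ``suitability * exp(bias_strength * southness)`` where southness runs
    from 1 at row 0 to 0 at the poleward edge. A fraction of points is
    placed uniformly at random ("erroneous" records) to exercise the
    outlier filter.
    """
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if not 0 <= error_fraction <= 1:
        raise ValueError("error_fraction must lie in [0, 1]")
    config = bundle.config
    if bias_strength is None:
        bias_strength = config.sampling_bias_strength if config else 0.0
    if bias_strength < 0:
        raise ValueError("bias_strength must be nonnegative")
    if seed is None:
        seed = (config.seed if config else 0)
    rng = _rng(seed, _OFF_OCCURRENCES)

    grid = bundle.grid
    nrow, ncol = grid.shape
    stack = bundle.suitability_current
    flat = stack.flat()
    southness = 1.0 - np.arange(nrow, dtype=float) / max(nrow - 1, 1)
    bias = np.exp(bias_strength * southness)[:, None] * np.ones((1, ncol))
    bias_flat = bias.ravel()

    range_sizes = flat.sum(axis=1)
    n_err = int(round(error_fraction * n_points))
    n_good = n_points - n_err
    alloc = rng.multinomial(n_good, range_sizes / range_sizes.sum())

    rows_out, cols_out, ids_out = [], [], []
    for j, n_j in enumerate(alloc):
        if n_j == 0:
            continue
        w = flat[j] * bias_flat
        cells = rng.choice(flat.shape[1], size=n_j, p=w / w.sum())
        rows_out.append(cells // ncol)
        cols_out.append(cells % ncol)
        ids_out.extend([stack.species_ids[j]] * n_j)
    if n_err:
        cells = rng.integers(0, grid.n_cells, n_err)
        rows_out.append(cells // ncol)
        cols_out.append(cells % ncol)
        ids_out.extend(rng.choice(stack.species_ids, n_err))

    rows_all = np.concatenate(rows_out) if rows_out else np.empty(0, int)
    cols_all = np.concatenate(cols_out) if cols_out else np.empty(0, int)
    jitter = rng.random((len(ids_out), 2))
    x = grid.x0 + (cols_all + jitter[:, 0]) * grid.cellsize
    y = grid.y0 + (rows_all + jitter[:, 1]) * grid.cellsize
    return pd.DataFrame({"x": x, "y": y, "species_id": ids_out})


def check_bundle(bundle: LandscapeBundle) -> None:
    """Raise if the bundle violates its structural invariants."""
    shape = bundle.grid.shape
    for name in ("coverage_raster", "hfi_raster", "excluded_raster",
                 "subregions_political", "subregions_ecological"):
        if getattr(bundle, name).shape != shape:
            raise ValueError(f"{name} is not on the shared grid")
    if bundle.suitability_current.shape != shape or bundle.suitability_future.shape != shape:
        raise ValueError("suitability stacks are not on the shared grid")
    if not (bundle.suitability_current.flat().sum(axis=1) > 0).all():
        raise ValueError("some species have no positive-suitability cell")
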