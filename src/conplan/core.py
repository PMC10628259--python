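"""Core in-memory containers shared across the pipeline.

All rasters live on a single row/column grid. By convention row 0 is the
equatorward ("south") edge and increasing row index points poleward; the
synthetic landscapes, range-shift logic and sampling-bias model all use this
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# Cell classes for the hierarchical mask.
EXCLUDED = 0
FREE = 1
PROTECTED = 2

CELL_CLASS_NAMES = {EXCLUDED: "excluded", FREE: "free", PROTECTED: "protected"}


@dataclass
class Grid:
    """Rectangular raster grid with half-open cells.

    A point (x, y) falls in column ``floor((x - x0) / cellsize)`` and row
    ``floor((y - y0) / cellsize)``; each cell is ``[x0 + c*d, x0 + (c+1)*d)``
    per axis, so boundary points belong to the higher-index cell.
    """

    nrow: int
    ncol: int
    x0: float = 0.0
    y0: float = 0.0
    cellsize: float = 1.0

    def __post_init__(self) -> None:
        if self.nrow <= 0 or self.ncol <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrow, self.ncol)

    @property
    def n_cells(self) -> int:
        return self.nrow * self.ncol

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices (may be out of range)."""
        col = np.floor((np.asarray(x, float) - self.x0) / self.cellsize).astype(np.int64)
        row = np.floor((np.asarray(y, float) - self.y0) / self.cellsize).astype(np.int64)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.nrow) & (col >= 0) & (col < self.ncol)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as (nrow, ncol) arrays."""
        cols = self.x0 + (np.arange(self.ncol) + 0.5) * self.cellsize
        rows = self.y0 + (np.arange(self.nrow) + 0.5) * self.cellsize
        x, y = np.meshgrid(cols, rows)
        return x, y


@dataclass
class SuitabilityStack:
    """Per-species habitat-suitability rasters, values in [0, 1].

    ``values`` has shape (n_species, nrow, ncol); ``species_ids`` names the
    leading axis.
    """

    values: np.ndarray
    species_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("suitability stack must be 3-D (species, row, col)")
        if len(self.species_ids) != self.values.shape[0]:
            raise ValueError("species_ids length must match leading axis")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("species ids must be unique")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def flat(self) -> np.ndarray:
        """(n_species, n_cells) view of the stack."""
        return self.values.reshape(self.n_species, -1)

    def subset(self, ids: Sequence[str]) -> "SuitabilityStack":
        index = {s: i for i, s in enumerate(self.species_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown species: {missing[:5]}")
        sel = [index[s] for s in ids]
        return SuitabilityStack(self.values[sel], list(ids))


@dataclass
class MaskStack:
    """Hierarchical cell classification plus optional subregion labels.

    ``cell_class`` holds EXCLUDED / FREE / PROTECTED codes; classes are
    exhaustive and mutually exclusive by construction of the integer raster.
    """

    cell_class: np.ndarray
    subregions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cell_class = np.asarray(self.cell_class)
        valid = np.isin(self.cell_class, (EXCLUDED, FREE, PROTECTED))
        if not valid.all():
            raise ValueError("cell_class contains codes outside {excluded, free, protected}")
        if self.subregions is not None:
            self.subregions = np.asarray(self.subregions)
            if self.subregions.shape != self.cell_class.shape:
                raise ValueError("subregion raster shape mismatch")

    @property
    def excluded(self) -> np.ndarray:
        return self.cell_class == EXCLUDED

    @property
    def free(self) -> np.ndarray:
        return self.cell_class == FREE

    @property
    def protected(self) -> np.ndarray:
        return self.cell_class == PROTECTED

    @property
    def available(self) -> np.ndarray:
        """Cells that receive a priority rank (free or protected)."""
        return self.cell_class != EXCLUDED

    @property
    def n_available(self) -> int:
        return int(self.available.sum())


@dataclass
class RankMap:
    """Priority ranks in (0, 1] for available cells; NaN where excluded.

    Rank 1 is the highest priority (the cell the greedy prioritizer would
    remove last); ranks over the N available cells form the permutation
    {1/N, ..., 1} of removal positions, normalized per ranking domain.
    """

    rank: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rank = np.asarray(self.rank, dtype=float)

    @property
    def available(self) -> np.ndarray:
        return np.isfinite(self.rank)
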