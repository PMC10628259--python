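"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from conplan.core import EXCLUDED, FREE, PROTECTED, MaskStack, SuitabilityStack
from conplan.synthetic import SyntheticConfig, generate_landscape

SMALL_GROUPS = {"bird": 5, "mammal": 4, "amphibian_reptile": 4,
                "plant": 14, "butterfly": 5}


def naive_greedy_rank(values: np.ndarray, weights: np.ndarray,
                      cell_class: np.ndarray, rule: str = "caz") -> np.ndarray:
    """Naive prioritizer: full recomputation of every marginal loss at every
    step, free cells before protected, lowest-index tie-break.

    Deliberately independent of the package implementation (dense arrays,
    per-step Q recomputed from scratch). Returns flattened ranks with NaN
    for excluded cells.
    """
    S = values.shape[0]
    flat = values.reshape(S, -1)
    n_cells = flat.shape[1]
    cls = np.asarray(cell_class).ravel()
    remaining = cls != EXCLUDED
    order = []
    for phase in (FREE, PROTECTED):
        while ((cls == phase) & remaining).any():
            Q = flat[:, remaining].sum(axis=1)
            cand = np.flatnonzero((cls == phase) & remaining)
            safe_q = np.where(Q > 0, Q, 1.0)
            terms = (weights / safe_q)[:, None] * flat[:, cand]
            terms[Q <= 0, :] = 0.0
            deltas = terms.max(axis=0) if rule == "caz" else terms.sum(axis=0)
            best = cand[int(np.argmin(deltas))]  # argmin takes the first min
            order.append(best)
            remaining[best] = False
    rank = np.full(n_cells, np.nan)
    n = len(order)
    if n:
        rank[np.array(order)] = np.arange(1, n + 1) / n
    return rank


def random_instance(rng: np.random.Generator, dyadic: bool = True):
    """Random prioritization instance: (values, weights, cell_class).

    Dyadic instances draw values on a 1/64 grid so incremental and
    from-scratch bookkeeping agree bit-for-bit and exact ties occur.
    """
    nrow = int(rng.integers(2, 11))
    ncol = int(rng.integers(2, 11))
    n_species = int(rng.integers(1, 11))
    if dyadic:
        values = rng.integers(0, 65, (n_species, nrow, ncol)) / 64.0
        weights = rng.integers(1, 33, n_species) / 32.0
    else:
        values = rng.random((n_species, nrow, ncol))
        weights = rng.random(n_species) + 0.01
    values[rng.random(values.shape) < 0.3] = 0.0
    cls = rng.choice([EXCLUDED, FREE, FREE, FREE, PROTECTED],
                     size=(nrow, ncol)).astype(np.int8)
    if not (cls != EXCLUDED).any():
        cls[0, 0] = FREE
    return values, weights, cls


@pytest.fixture
def oracle():
    return naive_greedy_rank


@pytest.fixture(scope="session")
def small_bundle():
    """A 40x40 landscape with 32 species, reused by read-only tests."""
    config = SyntheticConfig(grid_rows=40, grid_cols=40,
                             n_species_per_group=dict(SMALL_GROUPS),
                             range_size_lognormal_params=(3.5, 0.8),
                             shift_cells=4, seed=42)
    return generate_landscape(config)


def tiny_stack() -> SuitabilityStack:
    """The 3-cell / 2-species worked fixture p = [[1,0,0],[0,.5,.5]]."""
    values = np.array([[[1.0, 0.0, 0.0]], [[0.0, 0.5, 0.5]]])
    return SuitabilityStack(values, ["a", "b"])


@pytest.fixture
def three_cell_stack():
    return tiny_stack()


@pytest.fixture
def free_mask_1x3():
    return MaskStack(np.full((1, 3), FREE, dtype=np.int8))
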