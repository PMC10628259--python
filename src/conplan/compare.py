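"""Cross-scenario comparison: overlap classes, rank correlations, ordination.

Scenarios are compared on one shared grid: cells are classified by how many
scenario selections contain them (All / Most / Some / No, with "Most"
meaning at least a majority — at least seven of thirteen), rank maps are
correlated pairwise (Pearson over the common ranked domain), and the
scenario-by-cell binary membership matrix is embedded by nonmetric
multidimensional scaling on Bray-Curtis dissimilarities, the community-
ecology convention for a sites-by-species table.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

CLASS_NO, CLASS_SOME, CLASS_MOST, CLASS_ALL = 0, 1, 2, 3
CLASS_NAMES = {CLASS_NO: "No", CLASS_SOME: "Some", CLASS_MOST: "Most",
               CLASS_ALL: "All"}


def _stack_selections(selections: Mapping[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    names = list(selections)
    if len(names) < 2:
        raise ValueError("at least two selections required")
    arrays = [np.asarray(selections[n], bool) for n in names]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("selections are not on one shared grid")
    return names, np.stack([a.ravel() for a in arrays])


def overlap_classes(selections: Mapping[str, np.ndarray],
                    available: Optional[np.ndarray] = None,
                    we_total: Optional[np.ndarray] = None,
                    we_at_risk: Optional[np.ndarray] = None,
                    n_species: Optional[int] = None,
                    n_at_risk: Optional[int] = None,
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify cells by scenario agreement and summarize per class.

    Per cell, k = number of selections containing it; All means k = n,
    Most means ceil((n+1)/2) <= k < n (at least seven of thirteen), Some
    means 1 <= k below the majority, No means k = 0. The summary holds the
    percent of available land per class, plus weighted-endemism capture per
    class when WE rasters are supplied.
    """
    names, mat = _stack_selections(selections)
    n = len(names)
    shape = np.asarray(selections[names[0]]).shape
    counts = mat.sum(axis=0)
    majority = (n + 2) // 2  # ceil((n+1)/2); 7 when n = 13
    cls = np.full(counts.shape, CLASS_NO, dtype=np.int8)
    cls[(counts >= 1) & (counts < majority)] = CLASS_SOME
    cls[(counts >= majority) & (counts < n)] = CLASS_MOST
    cls[counts == n] = CLASS_ALL

    avail = (np.asarray(available, bool).ravel() if available is not None
             else np.ones(counts.shape, bool))
    rows = []
    for code in (CLASS_ALL, CLASS_MOST, CLASS_SOME, CLASS_NO):
        sel = (cls == code) & avail
        row = {"class": CLASS_NAMES[code],
               "percent_land": 100.0 * sel.sum() / avail.sum()}
        if we_total is not None and n_species:
            row["percent_biodiversity"] = float(
                100.0 * np.nansum(np.where(sel, np.asarray(we_total).ravel(), 0.0))
                / n_species)
        if we_at_risk is not None and n_at_risk:
            row["percent_at_risk_biodiversity"] = float(
                100.0 * np.nansum(np.where(sel, np.asarray(we_at_risk).ravel(), 0.0))
                / n_at_risk)
        rows.append(row)
    cls = np.where(avail, cls, CLASS_NO).astype(np.int8)
    return cls.reshape(shape), pd.DataFrame(rows).set_index("class")


def pairwise_correlation(rankmaps: Mapping[str, np.ndarray],
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of rank maps over the common domain.

    Returns (r matrix, p-value matrix); a constant map yields NaN entries.
    """
    names = list(rankmaps)
    if len(names) < 2:
        raise ValueError("at least two rank maps required")
    flats = {n: np.asarray(rankmaps[n], float).ravel() for n in names}
    common = np.ones(next(iter(flats.values())).shape, bool)
    for v in flats.values():
        common &= np.isfinite(v)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            va, vb = flats[a][common], flats[b][common]
            if np.ptp(va) == 0 or np.ptp(vb) == 0:
                warnings.warn(f"constant rank map in pair ({a}, {b}); r undefined")
                rv, pv = np.nan, np.nan
            else:
                res = stats.pearsonr(va, vb)
                rv, pv = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def ordinate_scenarios(selections: Mapping[str, np.ndarray], k: int = 2,
                       seed: int = 0, n_init: int = 8,
                       metric: str = "braycurtis",
                       ) -> tuple[pd.DataFrame, float]:
    """Nonmetric MDS of scenarios from their binary cell memberships.

    Each scenario is a "site" and each cell a "species"; pairwise
    dissimilarity defaults to Bray-Curtis. Returns coordinates (arbitrary
    rotation/reflection) and the final Kruskal stress-1. Identical scenarios
    (zero dissimilarity) are separated by a tiny seeded jitter so the
    embedding is defined.
    """
    from sklearn.manifold import MDS

    names, mat = _stack_selections(selections)
    if len(names) < 4:
        raise ValueError("at least four scenarios required for ordination")
    diss = squareform(pdist(mat.astype(float), metric=metric))
    off = ~np.eye(len(names), dtype=bool)
    if (diss[off] == 0).any():
        warnings.warn("identical scenarios: jittering zero dissimilarities")
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(1e-9, 1e-8, diss.shape)
        jitter = (jitter + jitter.T) / 2
        diss = np.where(off & (diss == 0), jitter, diss)
    mds = MDS(n_components=k, metric=False, dissimilarity="precomputed",
              n_init=n_init, max_iter=500, random_state=seed,
              normalized_stress=True)
    coords = mds.fit_transform(diss)
    frame = pd.DataFrame(coords, index=names,
                         columns=[f"NMDS{i + 1}" for i in range(k)])
    return frame, float(mds.stress_)
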