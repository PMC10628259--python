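# Methods

This note documents the models and procedures `conplan` implements, the
defaults that matter, the design choices made where the design was open,
and what the synthetic landscapes do and do not show about real data.

## Prioritization model

Land is ranked by iterative greedy removal (the core-area family of
marginal-loss rules). State is the per-species remaining total
`Q_j = Σ_{i remaining} c_ij` over the weighted feature layers `c_ij`. Two
rules are provided and named in the output metadata:

- `caz` (default): `δ_i = max_j w_j c_ij / Q_j` — a cell is as valuable as
  it is irreplaceable for its most-dependent species; this balances
  priorities across species and keeps every species' core range to the end.
- `abf`: `δ_i = Σ_j w_j c_ij / Q_j` — additive benefit, favouring
  species-rich cells.

Species with `Q_j = 0` contribute nothing. Ties are broken toward the
lowest flattened cell index, which pins the output exactly; the
implementation caches losses in a lazy min-heap (cached values are lower
bounds because `Q_j` only decreases), and its output is bit-identical to
naive per-step full recomputation — this is property-tested on hundreds of
random instances, including instances drawn on a dyadic value grid so that
exact ties genuinely occur.

The hierarchical mask removes all free cells before any protected cell, so
protected cells always occupy the top ranks. Rank is removal position
divided by the number of ranked cells, normalized per ranking domain (the
whole grid, or each subregion), which makes stitched maps thresholdable at
a common fraction. Top-fraction selection uses a ceiling quota ("protect at
least f"). In per-subregion selection, a subregion already holding more
protected land than the quota keeps all its protected cells — the quota
expands rather than erroring, since hierarchy forbids deselecting protected
land; in whole-domain selection a fraction below the protected share is an
error. Per-subregion weight re-normalization is deliberately not offered:
both marginal-loss rules are invariant to a global rescale of the weight
vector, so it could never change a removal order. What does differ per
subregion is `Q_j`, recomputed within each subregion so every region
prioritizes the species and endemism specific to it.

## Mask construction

Cells are excluded when flagged unavailable or when the human-footprint
index is strictly above 10; otherwise protected when fractional
protected-area coverage is at least 0.43 (inclusive), else free. Both
thresholds are configurable; the defaults reflect the convention that a
coverage threshold is calibrated so the protected cell count matches the
protected land share, and that high-footprint land is not a candidate for
new protection.

## Feature weighting

- **Climate win-win combination** (per species, then rescaled to max 1):
  `c = w_both·min(cur,fut) + w_now·cur + w_fut·fut` with the enforced strict
  ordering `w_both > w_now > w_fut > 0`. Defaults (0.5, 0.35, 0.15). The
  ordering is the substantive contract (overlap cells score highest,
  future-only lowest but positive); the magnitudes are calibration knobs.
  The combination is applied additively to the layers, not multiplicatively
  to the weights — the additive reading keeps the prioritizer's input a
  single raster per species.
- **Kingdom balancing**: scenario weights are rescaled so each kingdom
  (vertebrates, plants, butterflies) receives the same total weight,
  preserving within-kingdom ratios. Facet weights *replace* the uniform
  base weight and are then kingdom-balanced.
- **At-risk subsets**: national scheme keeps special concern / threatened /
  endangered; global scheme keeps vulnerable / endangered / critically
  endangered. An empty subset is an error (the scenario is undefined).
- **Evolutionary distinctiveness**: fair proportion — each branch length
  split equally among descendant tips; scores sum to total tree length
  (machine-precision identity, tested).
- **Functional distinctiveness**: Gower distance on range-normalized
  numeric plus categorical traits → principal-coordinates embedding (first
  two axes) → leave-one-out change in convex-hull area, clipped at zero and
  normalized to sum to 1 per kingdom. The hull area is a deterministic,
  desk-scale-testable stand-in for a kernel-density hypervolume measure;
  interior species get zero contribution by construction. Collinear
  embeddings fall back to the spread of the first axis.
- **Transnational endemism**: the share of a species' total-extent range
  (sum of suitabilities) falling inside the focal region, in [0, 1].

## Evaluation

Range size is the sum of suitability over the non-excluded domain (default:
current-climate suitability; a switch allows evaluating against the
win-win layers instead — current-climate is the default because protection
assessment concerns where species are, while win-win weighting is a
prioritization input). Targets: with `R10`/`R90` the 10th/90th percentiles
of range size (linear interpolation between order statistics, computed over
the full evaluated species pool rather than per taxon — one rule for all
species), `T = 1` below `R10`, `0.10` above `R90`, and linear in `ln R`
between — the only log-linear form consistent with fixed endpoints. A
species is protected when its selected range fraction meets its target;
SPI is the percent protected, reported overall, per group and per at-risk
subset; species with zero in-domain range are flagged and dropped from the
denominator. Weighted endemism sums to the species count over the domain,
so a selection's WE sum reads directly as species-equivalents (and percent)
captured. Trade-offs are `100·n_alt/n_ref − 100`, scale-invariant, with
the nationally coordinated scenario as the default reference; facet
trade-offs are the protected share of summed FD or PD contributions.

## Scenario suite

Thirteen scenarios by default: National; Transnational (endemism weights);
Provinces & Territories (political subregions); Ecozones (ecological
subregions); five single-group scenarios (birds, mammals, amphibians &
reptiles, plants, butterflies); two at-risk scenarios (national, global
scheme); Functional; Phylogenetic. All are selected at 30% of ranked land
and all are evaluated against the full species pool — single-group
scenarios are scored on total biodiversity, which is exactly what makes
their trade-offs informative. Cross-scenario outputs: overlap classes
(Most = at least a majority of scenarios, i.e. at least seven of thirteen,
generalized as `k ≥ ⌈(n+1)/2⌉`), pairwise Pearson correlation of rank maps
(rank values, not binary membership — a binary mode exists), and nonmetric
MDS (Bray-Curtis on binary scenario × cell membership, the community-
ecology convention for a sites-by-species table; zero-dissimilarity pairs
are jittered with a logged seed).

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes:

- **Ranges**: isotropic Gaussian bumps, amplitude 1 at the centroid,
  truncated below 0.02, with bump width set from a lognormal range-size law
  (default `ln N(5.0, 1.0)` cells: median ~150 cells on the default
  100×100 grid, heavy right tail). Simplest construction giving
  controllable range size, [0,1] values and spatial autocorrelation.
- **Richness gradient**: centroid rows drawn with density `∝ exp(−g·u)`
  toward the equatorward edge (row 0); default `g = 3` gives a ~20:1
  south:north density ratio. "Poleward" is the increasing-row direction by
  convention, fixing orientation for shift tests.
- **Climate shift**: future ranges are the current bumps displaced 8 cells
  poleward (clamped to the grid), with an optional width multiplier for
  range contraction (default 1.0, so a zero shift reproduces the current
  stack bit-for-bit).
- **Protected estate**: many small clustered reserves (patch scale ~40
  cells) with a mild poleward placement bias (default 1.0), calibrated by a
  field-quantile construction so the share of cells at coverage ≥ 0.43
  equals the requested protected fraction (default 0.15) essentially
  exactly. Small patches plus mild bias keep every subregion's starting
  share well below the 30% expansion quota, as in real protected estates.
- **Footprint and exclusions**: footprint decays poleward with lognormal
  noise (high where people and species concentrate) and is capped below the
  exclusion threshold inside reserves; a further ~6% of cells is excluded
  in clustered patches placed off the protected estate.
- **Subregions**: political regions are a Voronoi partition of random
  seeds (default 8); ecological regions are equal-height latitudinal bands
  (default 6), deliberately aligned with the gradient.
- **Species pool**: default 300 species dominated by plants
  (vertebrates:plants:butterflies ≈ 1:5:0.3); at-risk status probability
  increases with rarity, and the global at-risk set is nested inside the
  national one. Traits are complete (imputation is out of scope); the
  phylogeny is a random sequential-join tree with kingdom clades.
- **Occurrences**: points allocated to species by range size and placed
  `∝ suitability × exp(bias · southness)`, plus a configurable fraction of
  uniform "erroneous" records to exercise the outlier filter.

One global seed fans out to per-component child generators by fixed
offsets, so identical configurations reproduce bundles bit-for-bit.

What the synthetic world does **not** contain: real geography or climate
covariates, distribution-model fitting or its biases, taxonomic structure
beyond kingdom/group labels, trait realism, or observation-process detail
beyond a single southness bias. Passing tests therefore demonstrate the
correctness and directional behaviour of the planning machinery under the
assumed statistical structure — not that any particular real landscape
would yield the same numbers.

## Problem sizes and numerical choices

The default study conditions are a 100×100 grid with 300 species and 15%
pre-protected land; the acceptance script runs the full 13-scenario suite
at that size, and the heaviest property test replicates the four
coordination scenarios over 20 seeds at the same size. Unit and property
tests use smaller grids (24–60 cells a side) chosen so the whole suite
exercises every code path at desk scale. Ceiling quotas are computed as
`⌈f·N − 10⁻⁹⌉` to guard against binary-float fuzz in products like
`0.3 × N`. Occurrence distances are Euclidean in projected grid units;
species with ≤ k points bypass the outlier filter (the statistic is
undefined for them), and per-group distance thresholds are supplied by
configuration, not hard-coded. Percentile pivots use linear interpolation;
degenerate pivots (`R10 = R90`) assign mid-species the common-species
target with a warning. Rasters are read and written as ESRI ASCII grids —
a plain-text format that carries origin, cell size and nodata — with
multi-band stacks as directories of `.asc` files plus a `bands.csv` band
map.

## Known limitations

- The exact marginal-loss rule of recent core-area implementations is not
  published in detail; `caz` here is the classic core-area rule, pluggable
  and recorded in run metadata, and may order cells differently from other
  software on the same inputs.
- The hull-area functional measure approximates kernel hypervolumes; in
  two dimensions only, interior structure is invisible to it.
- SPI here evaluates one snapshot selection; no uncertainty intervals and
  no population-viability interpretation of targets.
- NMDS stress depends on scenario count and landscape; values are
  comparable across runs of this pipeline, not across studies.
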