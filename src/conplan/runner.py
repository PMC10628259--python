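"""Configuration-driven orchestration of the 13 planning scenarios.

Runs generate -> weight -> prioritize -> select -> evaluate -> compare end
to end. The default scenario set varies what is prioritized (all species,
single taxonomic groups, at-risk subsets under the national or global
assessment, functional or phylogenetic distinctiveness, transnational
endemism) and how protection is coordinated (whole-domain, or independent
per-subregion prioritizations over political or ecological regions). Every
scenario is scored against the full species pool, and trade-offs are
anchored to the nationally coordinated reference scenario.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import compare as compare_mod
from . import evaluate as eval_mod
from . import prioritize as prio_mod
from . import weights as weights_mod
from .core import Grid, MaskStack, RankMap
from .rasters import write_ascii_grid
from .synthetic import (DEFAULT_GROUP_COUNTS, LandscapeBundle, SyntheticConfig,
                        generate_landscape)

GROUP_SCENARIOS = {
    "Birds": ["bird"],
    "Mammals": ["mammal"],
    "Amphibians & Reptiles": ["amphibian_reptile"],
    "Plants": ["plant"],
    "Butterflies": ["butterfly"],
}


@dataclass
class ScenarioSpec:
    name: str
    #: None (all species), ("group", <scenario key>) or ("status", <scheme>).
    species_filter: Optional[tuple[str, str]] = None
    weight_source: str = "uniform"           # uniform | endemism | fd | pd
    coordination: str = "national"           # national | political | ecological
    protect_fraction: float = 0.30

    def validate(self) -> None:
        if self.weight_source not in ("uniform", "endemism", "fd", "pd"):
            raise ValueError(f"unknown weight source {self.weight_source!r}")
        if self.coordination not in ("national", "political", "ecological"):
            raise ValueError(f"unknown coordination {self.coordination!r}")


def default_scenarios(protect_fraction: float = 0.30) -> list[ScenarioSpec]:
    """The standard 13-scenario design."""
    f = protect_fraction
    specs = [
        ScenarioSpec("National", None, "uniform", "national", f),
        ScenarioSpec("Transnational", None, "endemism", "national", f),
        ScenarioSpec("Provinces & Territories", None, "uniform", "political", f),
        ScenarioSpec("Ecozones", None, "uniform", "ecological", f),
    ]
    for name in GROUP_SCENARIOS:
        specs.append(ScenarioSpec(name, ("group", name), "uniform", "national", f))
    specs.append(ScenarioSpec("National Species at-Risk", ("status", "national"),
                              "uniform", "national", f))
    specs.append(ScenarioSpec("Global Species at-Risk", ("status", "global"),
                              "uniform", "national", f))
    specs.append(ScenarioSpec("Functional", None, "fd", "national", f))
    specs.append(ScenarioSpec("Phylogenetic", None, "pd", "national", f))
    return specs


def scaled_group_counts(total: int) -> dict[str, int]:
    """Scale the default species-pool composition to ``total`` species."""
    base_total = sum(DEFAULT_GROUP_COUNTS.values())
    counts = {g: max(1, round(n * total / base_total))
              for g, n in DEFAULT_GROUP_COUNTS.items()}
    # Adjust the largest group so counts sum exactly to total.
    drift = total - sum(counts.values())
    biggest = max(counts, key=counts.get)
    counts[biggest] += drift
    return counts


@dataclass
class SuiteResult:
    bundle: LandscapeBundle
    mask: MaskStack
    rankmaps: dict[str, RankMap]
    selections: dict[str, np.ndarray]
    reports: dict[str, eval_mod.ProtectionReport]
    baseline_report: eval_mod.ProtectionReport
    tradeoffs: pd.DataFrame
    overlap_raster: np.ndarray
    overlap_summary: pd.DataFrame
    correlations: pd.DataFrame
    correlation_pvalues: pd.DataFrame
    ordination: pd.DataFrame
    stress: float
    manifest: dict = field(default_factory=dict)


def _filter_table(spec: ScenarioSpec, table: pd.DataFrame) -> pd.DataFrame:
    if spec.species_filter is None:
        return table
    kind, value = spec.species_filter
    if kind == "group":
        groups = GROUP_SCENARIOS[value]
        sub = table[table["group"].isin(groups)]
        if sub.empty:
            raise ValueError(f"scenario {spec.name!r}: no species in groups {groups}")
        return sub
    if kind == "status":
        base = table.copy()
        base["weight"] = 1.0
        return weights_mod.subset_by_status(base, value)
    raise ValueError(f"unknown filter kind {kind!r}")


def build_scenario_weights(spec: ScenarioSpec, species_table: pd.DataFrame,
                           fd: Optional[pd.Series],
                           pd_scores: Optional[pd.Series]) -> pd.DataFrame:
    sub = _filter_table(spec, species_table)
    return weights_mod.scenario_weights(sub.drop(columns=["weight"], errors="ignore"),
                                        source=spec.weight_source,
                                        fd=fd, pd_scores=pd_scores)


def existing_protection_report(bundle: LandscapeBundle, mask: MaskStack,
                               targets: Optional[pd.Series] = None,
                               ) -> eval_mod.ProtectionReport:
    """Baseline: how well do existing protected cells alone capture species."""
    import warnings

    domain = mask.available.ravel()
    if targets is None:
        ranges = eval_mod.range_size(bundle.suitability_current, domain)
        targets = eval_mod.spi_targets(ranges[ranges > 0])
    selection = mask.protected
    if not selection.any():
        warnings.warn("no protected cells: baseline SPI is 0")
    return eval_mod.assess_protection(bundle.suitability_current, selection,
                                      targets, bundle.species_table, domain)


def run_suite(config: Mapping | str | Path) -> SuiteResult:
    """Run the full scenario suite from a config mapping or YAML path."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    thresholds = dict(config.get("thresholds", {}))
    protected_threshold = float(thresholds.get("protected_threshold", 0.43))
    hfi_threshold = float(thresholds.get("hfi_threshold", 10.0))
    protect_fraction = float(thresholds.get("protect_fraction", 0.30))
    winwin = tuple(config.get("winwin", weights_mod.DEFAULT_WINWIN))
    rule = config.get("rule", "caz")
    reference = config.get("reference", "National")
    output_dir = config.get("output_dir")

    syn_kwargs = dict(config.get("synthetic", {}))
    n_species_total = syn_kwargs.pop("n_species", None)
    if n_species_total is not None and "n_species_per_group" not in syn_kwargs:
        syn_kwargs["n_species_per_group"] = scaled_group_counts(int(n_species_total))
    syn_config = SyntheticConfig(seed=seed, **syn_kwargs)

    t0 = time.time()
    bundle = generate_landscape(syn_config)
    mask = prio_mod.coverage_to_class(
        bundle.coverage_raster, bundle.hfi_raster, bundle.excluded_raster,
        protected_threshold=protected_threshold, hfi_threshold=hfi_threshold)
    feature = weights_mod.winwin_combine(bundle.suitability_current,
                                         bundle.suitability_future, winwin)

    table = bundle.species_table
    fd = weights_mod.functional_distinctiveness(
        bundle.traits.drop(columns=["kingdom"]), bundle.traits["kingdom"])
    ed = weights_mod.fair_proportion_ed(bundle.tree)
    kingdom = table.set_index("species_id")["kingdom"]
    pd_scores = ed.groupby(kingdom).transform(lambda s: s / s.sum())

    domain = mask.available.ravel()
    ranges = eval_mod.range_size(bundle.suitability_current, domain)
    present = ranges[ranges > 0]
    targets = eval_mod.spi_targets(present)
    eval_stack = bundle.suitability_current.subset(list(present.index))
    we_total = eval_mod.weighted_endemism(eval_stack, domain)
    at_risk_ids = [s for s in present.index
                   if table.set_index("species_id").loc[s, "status_national"]
                   in weights_mod.NATIONAL_AT_RISK]
    we_at_risk = (eval_mod.weighted_endemism(
        bundle.suitability_current.subset(at_risk_ids), domain)
        if at_risk_ids else None)

    scenarios = config.get("scenarios")
    if scenarios in (None, "default"):
        specs = default_scenarios(protect_fraction)
    else:
        specs = [ScenarioSpec(**s) for s in scenarios]
    for spec in specs:
        spec.validate()

    subregion_labels = {"political": bundle.subregions_political,
                        "ecological": bundle.subregions_ecological}
    rankmaps: dict[str, RankMap] = {}
    selections: dict[str, np.ndarray] = {}
    reports: dict[str, eval_mod.ProtectionReport] = {}
    for spec in specs:
        try:
            wt = build_scenario_weights(spec, table, fd, pd_scores)
            sub_stack = feature.stack.subset(list(wt["species_id"]))
            w = wt.set_index("species_id")["weight"]
            if spec.coordination == "national":
                rank = prio_mod.greedy_rank(sub_stack, w, mask, rule=rule)
                selection = prio_mod.top_fraction(rank, spec.protect_fraction,
                                                  mask=mask)
            else:
                labels = subregion_labels[spec.coordination]
                rank = prio_mod.subregion_rank(sub_stack, w, mask, labels,
                                               rule=rule)
                selection = prio_mod.top_fraction(rank, spec.protect_fraction,
                                                  mask=mask, subregions=labels)
            report = eval_mod.assess_protection(
                bundle.suitability_current, selection, targets, table, domain)
            report.capture = eval_mod.biodiversity_capture(
                we_total, selection.ravel(), len(present))
        except Exception as exc:
            raise RuntimeError(f"scenario {spec.name!r} failed: {exc}") from exc
        rankmaps[spec.name] = rank
        selections[spec.name] = selection
        reports[spec.name] = report

    baseline = existing_protection_report(bundle, mask, targets)
    baseline.capture = eval_mod.biodiversity_capture(
        we_total, mask.protected.ravel(), len(present))

    if reference not in reports:
        raise ValueError(f"reference scenario {reference!r} not in suite")
    ref_protected = reports[reference].n_protected
    rows = []
    for spec in specs:
        rep = reports[spec.name]
        relative, toff = eval_mod.tradeoff(rep.n_protected, ref_protected)
        fd_pct = eval_mod.facet_tradeoff(rep.per_species["protected"], fd)
        pd_pct = eval_mod.facet_tradeoff(rep.per_species["protected"], pd_scores)
        rows.append({
            "scenario": spec.name, "coordination": spec.coordination,
            "n_protected": rep.n_protected, "spi": rep.spi,
            "capture_percent": rep.capture,
            "relative_protection": relative, "tradeoff": toff,
            "fd_protected_percent": fd_pct, "pd_protected_percent": pd_pct,
        })
    tradeoffs = pd.DataFrame(rows).set_index("scenario")

    overlap_raster, overlap_summary = compare_mod.overlap_classes(
        selections, available=mask.available,
        we_total=we_total, we_at_risk=we_at_risk,
        n_species=len(present), n_at_risk=len(at_risk_ids) or None)
    corr, pvals = compare_mod.pairwise_correlation(
        {n: r.rank for n, r in rankmaps.items()})
    coords, stress = compare_mod.ordinate_scenarios(selections, k=2, seed=seed)

    manifest = {
        "scenarios": [spec.name for spec in specs],
        "n_scenarios": len(specs),
        "seed": seed, "rule": rule,
        "protected_threshold": protected_threshold,
        "hfi_threshold": hfi_threshold,
        "protect_fraction": protect_fraction,
        "winwin_coeffs": list(winwin),
        "reference": reference,
        "grid": list(bundle.grid.shape),
        "n_species": int(len(table)),
        "n_species_evaluated": int(len(present)),
        "tie_break": "lowest_index",
        "runtime_seconds": round(time.time() - t0, 2),
    }

    result = SuiteResult(
        bundle=bundle, mask=mask, rankmaps=rankmaps, selections=selections,
        reports=reports, baseline_report=baseline, tradeoffs=tradeoffs,
        overlap_raster=overlap_raster, overlap_summary=overlap_summary,
        correlations=corr, correlation_pvalues=pvals,
        ordination=coords, stress=stress, manifest=manifest)
    if output_dir:
        write_outputs(result, output_dir)
    return result


def write_outputs(result: SuiteResult, output_dir) -> None:
    """Write rank maps, selections, tables and the manifest to a directory."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = result.bundle.grid
    for name, rank in result.rankmaps.items():
        slug = name.lower().replace(" & ", "_").replace(" ", "_")
        write_ascii_grid(out / f"rank_{slug}.asc", rank.rank, grid)
        write_ascii_grid(out / f"selection_{slug}.asc",
                         result.selections[name].astype(float), grid)
        result.reports[name].to_csv(out / f"report_{slug}.csv")
    write_ascii_grid(out / "overlap_classes.asc",
                     result.overlap_raster.astype(float), grid)
    result.baseline_report.to_csv(out / "report_baseline_existing.csv")
    result.tradeoffs.to_csv(out / "tradeoffs.csv")
    result.overlap_summary.to_csv(out / "overlap_summary.csv")
    result.correlations.to_csv(out / "correlations.csv")
    result.ordination.assign(stress=result.stress).to_csv(out / "ordination.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
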