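"""Country-level gap summaries and end-to-end pipeline orchestration.

The country view asks where the missing species-cell combinations sit:
each country's completeness is the fraction of its required combinations
(sum of expected richness over its cells) documented by records, its share
of the global gap is its missing combinations over the world total, and a
simple OLS of country completeness on log10 wealth probes whether money
alone explains who shares data.

:func:`run_pipeline` wires the whole analysis together from a YAML config:
simulate (or load) a world, build inventories across grains, construct and
standardize the 12 predictors, run the all-subsets + spatial-refit
inference, run the spatial test battery, and write the country report and
bundle of CSV/JSON outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import inference as inf
from . import io as bio
from . import predictors as pred
from . import spatial as sp
from .grid import GridSystem
from .overlay import POOLED, build_inventory, min_grain_map, redundancy_histogram
from .synthetic import World, WorldConfig, generate_world

__all__ = [
    "country_of_analysis_cell",
    "country_completeness",
    "missing_share",
    "wealth_regression",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger(__name__)

ANALYSIS_KEYS = {
    "grain": 1,
    "completeness_threshold": 0.8,
    "daic_window": 10.0,
    "rac_radii": list(inf.DEFAULT_RAC_RADII),
    "kernel_scale": pred.DEFAULT_KERNEL_SCALE,
    "surrounding_radius": None,
    "include_null_in_anova": True,
}


def country_of_analysis_cell(
    country_of_base: np.ndarray, grid: GridSystem, grain: int
) -> np.ndarray:
    """Country of each cell at ``grain``: majority country of its base cells.

    Ties break to the lexicographically smallest country id, so assignment
    is deterministic.
    """
    country_of_base = np.asarray(country_of_base)
    if grain == 1:
        return country_of_base.copy()
    pm = grid.parents(1, grain)
    out = np.empty(grid.n_cells(grain), dtype=country_of_base.dtype)
    for cell in range(grid.n_cells(grain)):
        ctrs, counts = np.unique(country_of_base[pm == cell], return_counts=True)
        out[cell] = min(ctrs[counts == counts.max()])
    return out


def country_completeness(
    inventory: pd.DataFrame,
    country_of_base: np.ndarray,
    grid: GridSystem,
    grain: int = 1,
    taxon: str = POOLED,
) -> pd.DataFrame:
    """Per-country required/documented species-cell combinations and completeness.

    ``required`` sums expected richness over the country's cells at
    ``grain``; ``documented`` sums documented richness. Countries with no
    expected combinations are flagged (completeness NaN) and excluded from
    downstream ratios.
    """
    sub = inventory[(inventory["taxon"] == taxon) & (inventory["grain"] == grain)]
    ctry = country_of_analysis_cell(country_of_base, grid, grain)
    df = sub.assign(country=ctry[sub["cell_id"].to_numpy()])
    agg = df.groupby("country")[["S_exp", "S_doc"]].sum()
    agg.columns = ["required", "documented"]
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["completeness"] = np.where(
            agg["required"] > 0, agg["documented"] / agg["required"], np.nan
        )
    agg["missing"] = agg["required"] - agg["documented"]
    return agg


def missing_share(summary: pd.DataFrame) -> pd.Series:
    """Each country's share of the globally missing species-cell combinations.

    Shares sum to 1; a fully documented world yields all-zero shares (and a
    warning, since the ratio is then undefined).
    """
    missing = summary["missing"].clip(lower=0).astype(float)
    total = missing.sum()
    if total <= 0:
        log.warning("complete world: no missing combinations, shares set to 0")
        return pd.Series(0.0, index=summary.index, name="missing_share")
    return (missing / total).rename("missing_share")


def wealth_regression(
    completeness: pd.Series, wealth: pd.Series
) -> dict[str, float]:
    """OLS of country completeness on log10 per-capita wealth.

    Returns slope, intercept, r2 and the two-sided p of the slope.
    """
    df = pd.DataFrame({"c": completeness, "w": wealth}).dropna()
    if len(df) < 5:
        raise ValueError(f"need >= 5 countries, got {len(df)}")
    lw = np.log10(df["w"].to_numpy(float))
    if np.ptp(lw) == 0:
        raise ValueError("zero-variance wealth covariate")
    res = stats.linregress(lw, df["c"].to_numpy(float))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(len(df)),
    }


# ---------------------------------------------------------------------------
# pipeline


def load_config(path: str | Path) -> dict:
    """Load and schema-validate a pipeline config (unknown keys rejected)."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(doc)


def validate_config(doc: dict) -> dict:
    allowed_top = {"world", "world_dir", "analysis", "output_dir"}
    unknown = set(doc) - allowed_top
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("world", "output_dir"):
        if key not in doc:
            raise ValueError(f"config missing required key: {key!r}")
    world_fields = {f.name for f in dc_fields(WorldConfig)}
    bad = set(doc["world"]) - world_fields
    if bad:
        raise ValueError(f"unknown world config key(s): {sorted(bad)}")
    analysis = dict(ANALYSIS_KEYS)
    bad = set(doc.get("analysis", {})) - set(ANALYSIS_KEYS)
    if bad:
        raise ValueError(f"unknown analysis config key(s): {sorted(bad)}")
    analysis.update(doc.get("analysis", {}))
    out = dict(doc)
    out["analysis"] = analysis
    return out


def _world_from_config(doc: dict, seed: int | None) -> World:
    wc = dict(doc["world"])
    if "extent" in wc:
        wc["extent"] = tuple(wc["extent"])
    if "range_size_distribution" in wc:
        wc["range_size_distribution"] = tuple(wc["range_size_distribution"])
    if seed is not None:
        wc["seed"] = seed
    return generate_world(WorldConfig(**wc))


@dataclass
class PipelineResult:
    world: World
    inventory: pd.DataFrame
    predictor_table: pd.DataFrame
    ranking: inf.SubsetResult
    mam: inf.ModelFit
    importance: pd.DataFrame
    results: dict


def analyze_world(
    world: World,
    analysis: dict | None = None,
) -> PipelineResult:
    """Run overlay, predictors, inference and country summaries on a world."""
    a = dict(ANALYSIS_KEYS)
    a.update(analysis or {})
    grid = world.grid
    grain = a["grain"]

    inventory = build_inventory(world.ranges, world.records, grid)
    pooled = inventory[(inventory["taxon"] == POOLED) & (inventory["grain"] == grain)]
    analyzed = pooled["S_exp"].to_numpy() >= 1
    s_exp = pooled["S_exp"].to_numpy()[analyzed]
    s_doc = pooled["S_doc"].to_numpy()[analyzed]
    n_rec = pooled["N_rec"].to_numpy()[analyzed]
    coords = grid.centroids(grain)[analyzed]

    raw = pred.build_predictor_table(
        world.predictor_inputs(), grid, grain,
        radius=a["surrounding_radius"], kernel_scale=a["kernel_scale"],
    )
    Z = pred.standardize(raw, mask=analyzed)

    ranking = inf.all_subsets(s_doc, s_exp, Z)
    spatial_fits, mam = inf.fit_spatial_candidates(
        s_doc, s_exp, Z, ranking, coords,
        window=a["daic_window"], radii=tuple(a["rac_radii"]),
    )
    importance = inf.importance_table(mam, ranking, a["include_null_in_anova"])
    density = inf.density_bivariate(s_doc, s_exp, n_rec)
    shared = inf.shared_deviance(s_doc, s_exp, Z, mam, n_rec)
    ctry_analysis = country_of_analysis_cell(world.country_of_cell, grid, grain)[analyzed]
    if len(pd.unique(ctry_analysis)) >= 2:
        rac = inf.build_rac(
            next(f for f in ranking.fits if f.predictors == mam.predictors).working_residuals,
            coords, mam.rac_radius,
        )
        delta_d2, lrt_p = inf.country_partial_d2(
            s_doc, s_exp, Z, mam, ctry_analysis, rac
        )
    else:
        delta_d2, lrt_p = float("nan"), float("nan")

    summary = country_completeness(inventory, world.country_of_cell, grid, grain=1)
    summary["missing_share"] = missing_share(summary)
    wealth = wealth_regression(summary["completeness"], world.country_table["gdp_ppp"])

    hist, totals = redundancy_histogram(world.records, world.ranges, grid, grain)
    threshold = a["completeness_threshold"]
    c = pooled["C"].to_numpy()[analyzed]
    results = {
        "n_analyzed_cells": int(analyzed.sum()),
        "grain": grain,
        "mean_completeness": float(np.nanmean(c)),
        "fraction_cells_at_threshold": float(np.mean(c >= threshold)),
        "completeness_threshold": threshold,
        "best_nonspatial_aic": float(ranking.best.aic),
        "n_spatial_candidates": len(spatial_fits),
        "mam_predictors": list(mam.predictors),
        "mam_rac_radius": mam.rac_radius,
        "mam_d2": float(mam.d2),
        "density_d2": float(density.d2),
        "shared_deviance_fraction": float(shared),
        "country_delta_d2": delta_d2,
        "country_lrt_p": lrt_p,
        "wealth_regression": wealth,
        "redundancy_totals": totals,
        "redundancy_histogram": {str(k): v for k, v in hist.items()},
        "n_failed_subsets": len(ranking.failed),
    }
    return PipelineResult(
        world=world,
        inventory=inventory,
        predictor_table=pd.concat(
            [raw.add_suffix("_raw"), Z.reindex(raw.index).add_suffix("_z")], axis=1
        ),
        ranking=ranking,
        mam=mam,
        importance=importance,
        results=results,
    )


def run_pipeline(
    config: str | Path | dict, seed: int | None = None
) -> PipelineResult:
    """Execute the full pipeline from a config file or dict; write the bundle.

    Stages: simulate -> inventory -> predictors -> inference -> spatial
    tests -> country report. Outputs land in the config's ``output_dir``;
    any stage failure raises with the stage named, partial outputs
    retained.
    """
    doc = load_config(config) if not isinstance(config, dict) else validate_config(config)
    outdir = Path(doc["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        if "world_dir" in doc:
            world = bio.read_world(doc["world_dir"])
        else:
            world = _world_from_config(doc, seed)
        bio.write_world(world, outdir / "world")

        stage = "analysis"
        res = analyze_world(world, doc["analysis"])
        grid = world.grid

        stage = "write_outputs"
        res.inventory.to_csv(outdir / "inventory.csv", index=False)
        res.predictor_table.to_csv(outdir / "cell_predictors.csv")
        _write_data_dictionary(outdir / "cell_predictors_dictionary.txt")
        res.ranking.ranking_table().to_csv(outdir / "model_ranking.csv", index=False)
        res.importance.to_csv(outdir / "importance.csv")

        stage = "spatial_tests"
        tests = _test_battery(res.inventory, grid)
        tests.to_csv(outdir / "tests.csv", index=False)

        stage = "country_report"
        summary = country_completeness(res.inventory, world.country_of_cell, grid)
        summary["missing_share"] = missing_share(summary)
        summary.join(world.country_table[["gdp_ppp"]]).to_csv(outdir / "country_summary.csv")

        stage = "export"
        pooled = res.inventory[res.inventory["taxon"] == POOLED]
        for grain in grid.grains:
            g = pooled[pooled["grain"] == grain].sort_values("cell_id")
            bio.write_geojson(
                grid, grain,
                {"C": g["C"].to_numpy(), "S_exp": g["S_exp"].to_numpy(),
                 "N_rec": g["N_rec"].to_numpy()},
                outdir / f"completeness_grain{grain}.geojson",
            )
        mg = min_grain_map(res.inventory, grid, res.results["completeness_threshold"])
        bio.write_geojson(grid, 1, {"min_grain": mg}, outdir / "min_grain.geojson")
        (outdir / "results.json").write_text(json.dumps(res.results, indent=2, default=str))
        _write_summary(outdir / "summary.txt", res.results)
        (outdir / "run.log").write_text(
            f"seed={world.config.seed}\nelapsed_s={time.time() - t0:.1f}\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return res


def _test_battery(inventory: pd.DataFrame, grid: GridSystem) -> pd.DataFrame:
    """Cross-taxon correlations, a region contrast, taxon and grain comparisons."""
    rows = []
    taxa = sorted(t for t in inventory["taxon"].unique() if t != POOLED)
    base = inventory[inventory["grain"] == 1]
    by_taxon = {}
    for t in taxa:
        sub = base[base["taxon"] == t].sort_values("cell_id")
        by_taxon[t] = sub["C"].to_numpy()
    pooled = base[base["taxon"] == POOLED].sort_values("cell_id")
    shared_mask = np.isfinite(pooled["C"].to_numpy())
    for t in taxa:
        shared_mask &= np.isfinite(by_taxon[t])
    coords = grid.centroids(1)[shared_mask]
    if shared_mask.sum() >= 20:
        for a, b in itertools.combinations(taxa, 2):
            r = sp.spearman_dutilleul(by_taxon[a][shared_mask], by_taxon[b][shared_mask], coords)
            rows.append(("cross_taxon_spearman", f"{a} vs {b}", r.statistic, r.n, r.n_eff,
                         r.p_naive, r.p_dut))
        if len(taxa) >= 2:
            vals = {t: by_taxon[t][shared_mask] for t in taxa}
            for r in sp.group_compare(vals, coords):
                rows.append(("taxon_tukey", r.label, r.statistic, r.n, r.n_eff,
                             r.p_naive, r.p_dut))
        south = coords[:, 1] < grid.height / 2
        if south.sum() >= 10 and (~south).sum() >= 10:
            c = pooled["C"].to_numpy()[shared_mask]
            r = sp.region_contrast(c, np.where(south, "south", "north"), coords)
            rows.append(("region_max_t", r.label, r.statistic, r.n, r.n_eff,
                         r.p_naive, r.p_dut))
    for t in taxa + [POOLED]:
        by_grain = {}
        for grain in grid.grains:
            sub = inventory[(inventory["taxon"] == t) & (inventory["grain"] == grain)]
            v = sub["C"].to_numpy()
            v = v[np.isfinite(v)]
            if len(v) >= 5:
                by_grain[grain] = v
        if len(by_grain) >= 2:
            h, p = sp.grain_effect(by_grain)
            rows.append(("grain_kruskal_wallis", t, h, sum(map(len, by_grain.values())),
                         np.nan, p, p))
    return pd.DataFrame(
        rows, columns=["test", "contrast", "statistic", "n", "n_eff", "p", "p_dut"]
    )


def _write_data_dictionary(path: Path) -> None:
    lines = [
        "cell_predictors.csv columns ('<name>_raw' = raw scale, '<name>_z' = standardized):",
        "  endemism_richness   sum of inverse range sizes of species present (per base-cell area)",
        "  topographic_range   max - min elevation among base cells in the cell",
        "  protected_fraction  fraction of base cells inside protected areas [0,1]",
        "  travel_time         mean travel time to the nearest city, hours",
        "  airport_proximity   sum over airports of exp(-distance/scale)",
        "  institution_proximity  record-weighted proximity to contributing publishers",
        "  security            country security score (higher = less secure), area-weighted",
        "  scientific_activities  country H-index x international collaboration share",
        "  gbif_participation  fraction of cell area in data-network member countries [0,1]",
        "  national_funding    research funding of overlapping countries, $/capita",
        "  publisher_funding   funding of contributing publishers' home countries, $/capita",
        "  publisher_size      record-weighted mean log10 publisher record volume",
        "  no_surrounding_records_raw  True where publisher-derived predictors used the",
        "                      global-minimum sentinel (no records within the radius)",
        "Standardization: log10(x+1) for right-skewed columns, then z-score over analyzed cells.",
    ]
    path.write_text("\n".join(lines) + "\n")


def _write_summary(path: Path, results: dict) -> None:
    w = results["wealth_regression"]
    lines = [
        f"analyzed cells (grain {results['grain']}): {results['n_analyzed_cells']}",
        f"mean inventory completeness: {results['mean_completeness']:.3f}",
        f"cells at >= {results['completeness_threshold']:.0%} completeness: "
        f"{results['fraction_cells_at_threshold']:.1%}",
        f"minimum adequate spatial model: {', '.join(results['mam_predictors']) or '(null)'}"
        f" | RAC radius {results['mam_rac_radius']}",
        f"MAM deviance explained D2: {results['mam_d2']:.3f}",
        f"record-density-only d2: {results['density_d2']:.3f}",
        f"shared deviance fraction: {results['shared_deviance_fraction']:.3f}",
        f"country identity extra D2: {results['country_delta_d2']:.4f} "
        f"(LRT p = {results['country_lrt_p']:.2e})",
        f"country completeness ~ log10(GDP): r2 = {w['r2']:.3f}, p = {w['p']:.2e}",
        f"species-cell combinations required: {results['redundancy_totals']['required_combos']}"
        f", documented: {results['redundancy_totals']['documented_combos']}",
    ]
    path.write_text("\n".join(lines) + "\n")
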