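"""Per-cell predictor variables for the driver analysis.

Twelve hypotheses about what limits inventory completeness, in five broad
categories:

* appeal — ``endemism_richness``, ``topographic_range``, ``protected_fraction``
* accessibility — ``travel_time``, ``airport_proximity``, ``institution_proximity``
* security — ``security`` (a Global-Peace-Index-like country score)
* international scientific integration — ``scientific_activities``
  (country H-index x international-collaboration share), ``gbif_participation``
* financial/institutional resources — ``national_funding`` (research funding of
  the countries overlapping the cell), ``publisher_funding`` (funding of the
  countries hosting the publishers that contributed the cell's records),
  ``publisher_size`` (record volume of those publishers, log10).

All distances are planar Euclidean in base-cell widths. The three
publisher-derived predictors weight each publisher by the number of records
it contributed within a radius ``R`` of the cell centroid ("the area
surrounding the cell"); cells with no surrounding records receive the
global minimum of the index so the design matrix stays complete (flagged in
the returned mask for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSystem
from .overlay import SpeciesRange, endemism_richness

__all__ = [
    "PREDICTOR_NAMES",
    "DEFAULT_LOG_COLUMNS",
    "topographic_range",
    "protected_fraction",
    "mean_surface",
    "airport_proximity",
    "publisher_record_weights",
    "institution_proximity",
    "publisher_funding",
    "publisher_size",
    "scientific_activities",
    "country_covariate_to_cells",
    "build_predictor_table",
    "standardize",
]

PREDICTOR_NAMES = [
    "endemism_richness",
    "topographic_range",
    "protected_fraction",
    "travel_time",
    "airport_proximity",
    "institution_proximity",
    "security",
    "scientific_activities",
    "gbif_participation",
    "national_funding",
    "publisher_funding",
    "publisher_size",
]

# Right-skewed predictors log10(x+1)-transformed before z-scoring.
DEFAULT_LOG_COLUMNS = (
    "travel_time",
    "national_funding",
    "publisher_funding",
    "publisher_size",
    "endemism_richness",
    "airport_proximity",
)

DEFAULT_KERNEL_SCALE = 4.0  # e-folding distance of proximity kernels, cell widths


def _agg(base_values: np.ndarray, grid: GridSystem, grain: int, how: str) -> np.ndarray:
    """Aggregate a base-grain surface to ``grain`` by mean/max/min over children."""
    v = np.asarray(base_values, dtype=float)
    if grain == 1:
        return v.copy()
    pm = grid.parents(1, grain)
    n = grid.n_cells(grain)
    if how == "mean":
        s = np.bincount(pm, weights=v, minlength=n)
        c = np.bincount(pm, minlength=n)
        return s / c
    out = np.full(n, -np.inf if how == "max" else np.inf)
    fn = np.maximum if how == "max" else np.minimum
    fn.at(out, pm, v)
    return out


def topographic_range(elevation: np.ndarray, grid: GridSystem, grain: int) -> np.ndarray:
    """Elevational range (max - min) per cell at ``grain``.

    ``elevation`` is either one value per base cell (shape ``(n_base,)``)
    or several digital-elevation-model samples per base cell (shape
    ``(k, n_base)``), in which case within-base-cell relief contributes
    even at the base grain.
    """
    elevation = np.asarray(elevation, dtype=float)
    samples = elevation[None, :] if elevation.ndim == 1 else elevation
    hi = _agg(samples.max(axis=0), grid, grain, "max")
    lo = _agg(samples.min(axis=0), grid, grain, "min")
    return hi - lo


def protected_fraction(mask: np.ndarray, grid: GridSystem, grain: int) -> np.ndarray:
    """Fraction of base cells flagged protected, per cell at ``grain``."""
    return _agg(np.asarray(mask, dtype=float), grid, grain, "mean")


def mean_surface(surface: np.ndarray, grid: GridSystem, grain: int) -> np.ndarray:
    """Mean of a base-grain surface over children (used e.g. for travel time)."""
    return _agg(surface, grid, grain, "mean")


def airport_proximity(
    airports_xy: np.ndarray,
    grid: GridSystem,
    grain: int,
    scale: float = DEFAULT_KERNEL_SCALE,
) -> np.ndarray:
    """Exponential-kernel proximity to airports: sum_a exp(-d(i,a)/scale)."""
    airports_xy = np.atleast_2d(np.asarray(airports_xy, dtype=float))
    if airports_xy.shape[0] == 0:
        raise ValueError("at least one airport required")
    cen = grid.centroids(grain)
    d = np.linalg.norm(cen[:, None, :] - airports_xy[None, :, :], axis=2)
    return np.exp(-d / scale).sum(axis=1)


def publisher_record_weights(
    records: pd.DataFrame,
    publishers: pd.DataFrame,
    grid: GridSystem,
    grain: int,
    radius: float | None = None,
) -> np.ndarray:
    """W[i, p]: records by publisher p within ``radius`` of cell i's centroid.

    ``radius`` defaults to two cell widths at the analysis grain. Records are
    first binned to base cells, so the cost is (cells x base cells), not
    (cells x records).
    """
    if len(publishers) == 0:
        raise ValueError("at least one publisher required")
    if radius is None:
        radius = 2.0 * grid.cell_edge(grain)
    pub_ids = publishers["publisher_id"].tolist()
    pub_index = {p: k for k, p in enumerate(pub_ids)}
    n_base = grid.n_cells(1)
    counts = np.zeros((n_base, len(pub_ids)))
    if len(records):
        cells = grid.cell_of_point(records["x"].to_numpy(float), records["y"].to_numpy(float), 1)
        pcol = records["publisher_id"].map(pub_index).to_numpy()
        ok = (cells >= 0) & pd.notna(pcol)
        np.add.at(counts, (cells[ok], pcol[ok].astype(int)), 1)
    cen = grid.centroids(grain)
    base_cen = grid.centroids(1)
    d = np.linalg.norm(cen[:, None, :] - base_cen[None, :, :], axis=2)
    within = d <= radius
    return within @ counts


def _weighted_publisher_index(
    weights: np.ndarray, per_publisher_value: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Record-weighted mean of a per-publisher value; D6 sentinel where no records."""
    tot = weights.sum(axis=1)
    has = tot > 0
    out = np.empty(len(tot))
    out[has] = (weights[has] * per_publisher_value[None, :]).sum(axis=1) / tot[has]
    if not has.any():
        raise ValueError("no cell has surrounding records; cannot form index")
    out[~has] = out[has].min()
    return out, ~has


def institution_proximity(
    records: pd.DataFrame,
    publishers: pd.DataFrame,
    grid: GridSystem,
    grain: int,
    radius: float | None = None,
    scale: float = DEFAULT_KERNEL_SCALE,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted geographic proximity of a cell to its contributing publishers.

    index_i = sum_p W_p exp(-d(i,p)/scale) / sum_p W_p, where W_p is the
    number of records publisher p contributed within ``radius`` of cell i.
    High where most surrounding records come from nearby publishers.
    Returns ``(index, no_data_mask)``.
    """
    W = publisher_record_weights(records, publishers, grid, grain, radius)
    cen = grid.centroids(grain)
    pub_xy = publishers[["x", "y"]].to_numpy(float)
    d = np.linalg.norm(cen[:, None, :] - pub_xy[None, :, :], axis=2)
    kern = np.exp(-d / scale)
    tot = W.sum(axis=1)
    has = tot > 0
    if not has.any():
        raise ValueError("no cell has surrounding records; cannot form index")
    out = np.empty(len(tot))
    out[has] = (W[has] * kern[has]).sum(axis=1) / tot[has]
    out[~has] = out[has].min()
    return out, ~has


def publisher_funding(
    records: pd.DataFrame,
    publishers: pd.DataFrame,
    country_funding: pd.Series,
    grid: GridSystem,
    grain: int,
    radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Record-weighted mean research funding of contributing publishers' home countries."""
    W = publisher_record_weights(records, publishers, grid, grain, radius)
    fund = publishers["country_id"].map(country_funding)
    if fund.isna().any():
        missing = sorted(publishers.loc[fund.isna(), "country_id"].unique().tolist())
        raise KeyError(f"countries missing from funding table: {missing}")
    return _weighted_publisher_index(W, fund.to_numpy(float))


def publisher_size(
    records: pd.DataFrame,
    publishers: pd.DataFrame,
    grid: GridSystem,
    grain: int,
    radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Record-weighted mean log10 total record volume of contributing publishers."""
    W = publisher_record_weights(records, publishers, grid, grain, radius)
    totals = (
        records["publisher_id"].value_counts().reindex(publishers["publisher_id"]).fillna(0)
    )
    size = np.log10(np.maximum(totals.to_numpy(float), 1.0))
    return _weighted_publisher_index(W, size)


def scientific_activities(h_index: pd.Series, collab_fraction: pd.Series) -> pd.Series:
    """Per-country index: ecology H-index x share of internationally collaborative papers."""
    h = h_index.astype(float)
    f = collab_fraction.astype(float)
    if (h < 0).any():
        raise ValueError("h_index must be >= 0")
    if ((f < 0) | (f > 1)).any():
        raise ValueError("collaboration fraction must lie in [0, 1]")
    return h * f


def country_covariate_to_cells(
    country_of_cell: np.ndarray,
    table: pd.Series,
    grid: GridSystem,
    grain: int,
    mode: str = "area_weighted_mean",
) -> np.ndarray:
    """Map a per-country covariate onto grid cells.

    mode="area_weighted_mean": area-weighted mean of a numeric covariate
    over the countries overlapping the cell. mode="fraction": share of the
    cell's area lying in countries where a boolean covariate holds.
    """
    country_of_cell = np.asarray(country_of_cell)
    present = pd.unique(country_of_cell)
    missing = sorted(set(present) - set(table.index))
    if missing:
        raise KeyError(f"countries missing from covariate table: {missing}")
    vals = table.reindex(country_of_cell).to_numpy(float)
    if mode == "fraction":
        vals = (vals != 0).astype(float)
    elif mode != "area_weighted_mean":
        raise ValueError(f"unknown mode {mode!r}")
    return _agg(vals, grid, grain, "mean")


@dataclass
class PredictorInputs:
    """Raw ingredients for the 12-predictor table.

    ``country_table`` must be indexed by country id with columns
    ``security, h_index, collab_fraction, national_funding, gbif_participant``.
    """

    elevation: np.ndarray
    protected_mask: np.ndarray
    travel_time: np.ndarray
    airports_xy: np.ndarray
    country_of_cell: np.ndarray
    country_table: pd.DataFrame
    ranges: list[SpeciesRange]
    records: pd.DataFrame
    publishers: pd.DataFrame


def build_predictor_table(
    inputs: PredictorInputs,
    grid: GridSystem,
    grain: int,
    radius: float | None = None,
    kernel_scale: float = DEFAULT_KERNEL_SCALE,
) -> pd.DataFrame:
    """Assemble the raw 12-predictor table at ``grain`` (one row per cell).

    Adds a boolean ``no_surrounding_records`` column marking cells whose
    publisher-derived predictors fell back to the global-minimum sentinel.
    """
    ct = inputs.country_table
    sci = scientific_activities(ct["h_index"], ct["collab_fraction"])
    inst, no_data = institution_proximity(
        inputs.records, inputs.publishers, grid, grain, radius, kernel_scale
    )
    pfund, _ = publisher_funding(
        inputs.records, inputs.publishers, ct["national_funding"], grid, grain, radius
    )
    psize, _ = publisher_size(inputs.records, inputs.publishers, grid, grain, radius)
    cc = inputs.country_of_cell
    table = pd.DataFrame(
        {
            "endemism_richness": endemism_richness(inputs.ranges, grid, grain),
            "topographic_range": topographic_range(inputs.elevation, grid, grain),
            "protected_fraction": protected_fraction(inputs.protected_mask, grid, grain),
            "travel_time": mean_surface(inputs.travel_time, grid, grain),
            "airport_proximity": airport_proximity(inputs.airports_xy, grid, grain, kernel_scale),
            "institution_proximity": inst,
            "security": country_covariate_to_cells(cc, ct["security"], grid, grain),
            "scientific_activities": country_covariate_to_cells(cc, sci, grid, grain),
            "gbif_participation": country_covariate_to_cells(
                cc, ct["gbif_participant"], grid, grain, mode="fraction"
            ),
            "national_funding": country_covariate_to_cells(cc, ct["national_funding"], grid, grain),
            "publisher_funding": pfund,
            "publisher_size": psize,
        }
    )
    table.index.name = "cell_id"
    table["no_surrounding_records"] = no_data
    return table


def standardize(
    table: pd.DataFrame,
    mask: np.ndarray | None = None,
    log_columns: tuple[str, ...] = DEFAULT_LOG_COLUMNS,
) -> pd.DataFrame:
    """z-score predictor columns over the analyzed cells.

    Right-skewed columns listed in ``log_columns`` get log10(x+1) first
    (they must be non-negative). ``mask`` selects the analyzed cells
    (those entering the models, e.g. cells with expected species); moments
    are computed over those cells only, and only those rows are returned.
    A zero-variance column raises, naming the column.
    """
    cols = [c for c in table.columns if c in PREDICTOR_NAMES]
    sub = table.loc[mask if mask is not None else slice(None), cols].astype(float).copy()
    for c in cols:
        if c in log_columns:
            if (sub[c] < 0).any():
                raise ValueError(f"column {c!r} has negative values; cannot log-transform")
            sub[c] = np.log10(sub[c] + 1.0)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance predictor column(s): {dead}")
    return (sub - mu) / sd
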