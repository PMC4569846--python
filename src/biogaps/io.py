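"""Reading and writing the pipeline's plain-text formats.

Worlds, inventories and results travel as CSV/JSON; per-cell layers can be
exported as GeoJSON (planar cell squares in world units) for mapping.
Occurrence CSVs with Darwin-Core-style headers are accepted through a
column-mapping config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSystem, build_grid
from .overlay import SpeciesRange
from .synthetic import World, WorldConfig, GroundTruth

__all__ = [
    "write_world",
    "read_world",
    "read_occurrences",
    "write_geojson",
    "DARWIN_CORE_MAPPING",
]

RECORD_COLUMNS = ["record_id", "species_id", "x", "y", "publisher_id"]

#: default Darwin-Core column mapping for user-supplied occurrence CSVs
DARWIN_CORE_MAPPING = {
    "scientificName": "species_id",
    "decimalLongitude": "x",
    "decimalLatitude": "y",
    "institutionCode": "publisher_id",
    "publisher": "publisher_id",
}


def write_world(world: World, outdir: str | Path) -> None:
    """Write a world as ranges/records/publishers/predictors/countries CSVs + truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"species_id": r.species_id, "taxon": r.taxon, "cell_id": c}
        for r in world.ranges
        for c in sorted(r.cells)
    ]
    pd.DataFrame(rows).to_csv(out / "ranges.csv", index=False)
    world.records.to_csv(out / "records.csv", index=False)
    world.publishers.to_csv(out / "publishers.csv", index=False)
    elev = np.atleast_2d(world.elevation)
    surf = {"cell_id": np.arange(world.grid.n_cells(1))}
    for k in range(elev.shape[0]):
        surf[f"elevation_s{k}"] = elev[k]
    surf["travel_time"] = world.travel_time
    surf["protected"] = world.protected_mask.astype(int)
    pd.DataFrame(surf).to_csv(out / "predictors.csv", index=False)
    pd.DataFrame(
        {"cell_id": np.arange(world.grid.n_cells(1)), "country_id": world.country_of_cell}
    ).to_csv(out / "countries.csv", index=False)
    world.country_table.to_csv(out / "country_covariates.csv")
    airports = pd.DataFrame(world.airports_xy, columns=["x", "y"])
    airports.to_csv(out / "airports.csv", index=False)
    cfg = world.config.__dict__.copy()
    cfg["extent"] = list(cfg["extent"])
    cfg["range_size_distribution"] = list(cfg["range_size_distribution"])
    truth = {
        "effect_vector": world.truth.effect_vector,
        "seed": world.truth.seed,
        "config": cfg,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def read_world(indir: str | Path) -> World:
    """Round-trip a world written by :func:`write_world`."""
    ind = Path(indir)
    truth_doc = json.loads((ind / "truth.json").read_text())
    cfg_doc = truth_doc["config"]
    cfg_doc["extent"] = tuple(cfg_doc["extent"])
    cfg_doc["range_size_distribution"] = tuple(cfg_doc["range_size_distribution"])
    config = WorldConfig(**cfg_doc)
    grid = build_grid(*config.extent, 4)
    rngdf = pd.read_csv(ind / "ranges.csv")
    ranges = [
        SpeciesRange(sid, grp["taxon"].iloc[0], frozenset(grp["cell_id"].tolist()))
        for sid, grp in rngdf.groupby("species_id", sort=True)
    ]
    records = pd.read_csv(ind / "records.csv")
    publishers = pd.read_csv(ind / "publishers.csv")
    predictors = pd.read_csv(ind / "predictors.csv").sort_values("cell_id")
    countries = pd.read_csv(ind / "countries.csv").sort_values("cell_id")
    country_table = pd.read_csv(ind / "country_covariates.csv", index_col="country_id")
    airports = pd.read_csv(ind / "airports.csv").to_numpy(float)
    truth = GroundTruth(
        effect_vector=truth_doc["effect_vector"],
        publisher_locations=publishers[["x", "y"]].to_numpy(float),
        log_intensity=np.full(grid.n_cells(1), np.nan),
        occupied=np.zeros(grid.n_cells(1), dtype=bool),
        seed=truth_doc["seed"],
    )
    return World(
        config=config,
        grid=grid,
        ranges=ranges,
        records=records,
        publishers=publishers,
        country_of_cell=countries["country_id"].to_numpy(),
        country_table=country_table,
        elevation=np.vstack(
            [
                predictors[c].to_numpy(float)
                for c in sorted(predictors.columns)
                if c.startswith("elevation_s")
            ]
        ),
        protected_mask=predictors["protected"].to_numpy() > 0,
        travel_time=predictors["travel_time"].to_numpy(float),
        airports_xy=airports,
        truth=truth,
    )


def read_occurrences(
    path: str | Path, column_mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read an occurrence CSV, mapping Darwin-Core-like headers to pipeline names.

    Unknown source columns are kept untouched; after mapping, the frame
    must contain ``species_id, x, y`` (``publisher_id`` optional,
    ``record_id`` generated if absent). A malformed file raises naming the
    missing column.
    """
    df = pd.read_csv(path)
    mapping = dict(DARWIN_CORE_MAPPING)
    if column_mapping:
        mapping.update(column_mapping)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    for col in ("species_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"occurrence file {path}: missing required column {col!r}")
    for i, col in enumerate(("x", "y")):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"occurrence file {path}: non-numeric {col!r} at row {row}")
    df["x"] = pd.to_numeric(df["x"])
    df["y"] = pd.to_numeric(df["y"])
    if "record_id" not in df.columns:
        df["record_id"] = [f"r{i:07d}" for i in range(len(df))]
    if "publisher_id" not in df.columns:
        df["publisher_id"] = "unknown"
    return df[RECORD_COLUMNS + [c for c in df.columns if c not in RECORD_COLUMNS]]


def write_geojson(
    grid: GridSystem,
    grain: int,
    layers: dict[str, np.ndarray],
    path: str | Path,
) -> None:
    """Write per-cell values as a GeoJSON FeatureCollection of cell squares."""
    features = []
    for cell in range(grid.n_cells(grain)):
        props = {"cell_id": cell, "grain": grain}
        for name, vals in layers.items():
            v = vals[cell]
            props[name] = None if (isinstance(v, float) and not np.isfinite(v)) else (
                v.item() if isinstance(v, np.generic) else v
            )
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [grid.cell_polygon(cell, grain)],
                },
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))
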