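"""Synthetic study systems with known ground truth.

Every downstream stage — overlay, predictors, inference, spatial tests —
is exercised on virtual worlds generated here, so the whole pipeline is
testable without external data. A world emulates the ingredients of a
global occurrence-mobilization study at desk scale:

* a flat ``width x height`` grid of unit base cells (the equal-area grid);
* cohesive species ranges with a broad, heavy-tailed range-size
  distribution, grown by a spreading-dye process;
* a partition of the grid into contiguous countries carrying
  socio-economic covariates (research funding, data-sharing participation,
  security, scientific activity, wealth);
* spatially autocorrelated environmental surfaces (elevation, travel
  time, protected areas) and point facilities (airports, data publishers);
* occurrence records whose sampling intensity is log-linear in the
  standardized cell predictors plus an exponential decay with distance to
  the nearest data publisher — the record-generating process whose
  coefficients the inference stage tries to recover.

Per-cell intensity (ground truth):

    log lambda_i = sum_k beta_k z_ik - d_i / s + eps_i

with ``z_ik`` the standardized exogenous predictors, ``d_i`` the distance
to the nearest publisher, ``s`` the distance-decay scale and ``eps_i``
Gaussian noise (optionally spatially autocorrelated). Records fall only in
cells occupied by at least one species; within a cell the species is
uniform over those present and the publisher is chosen with
inverse-distance weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import GridSystem, build_grid
from .overlay import SpeciesRange
from . import predictors as pred

__all__ = [
    "WorldConfig",
    "GroundTruth",
    "World",
    "gen_predictor_field",
    "gen_species_ranges",
    "gen_countries",
    "gen_country_table",
    "gen_publishers",
    "gen_records",
    "generate_world",
    "inject_corruption",
    "EXOGENOUS_PREDICTORS",
]

log = logging.getLogger(__name__)

# Predictors that exist before any record is sampled; only these (plus the
# built-in publisher_distance decay) may carry true effects on sampling
# intensity. The three publisher-record-derived predictors would be circular.
EXOGENOUS_PREDICTORS = (
    "endemism_richness",
    "topographic_range",
    "protected_fraction",
    "travel_time",
    "airport_proximity",
    "security",
    "scientific_activities",
    "gbif_participation",
    "national_funding",
)


@dataclass
class WorldConfig:
    """Study conditions of a virtual world.

    Defaults describe the demo system: a 32x32 base grid (so three
    coarsenings exist), three taxa with more bird than mammal/amphibian
    species, ~50k records, 20 publishers, 8 countries, and true effects on
    sampling intensity dominated by national research funding,
    participation in the data-sharing network, endemism appeal and (via
    the decay term) distance to data publishers.
    """

    extent: tuple[int, int] = (32, 32)
    n_species: dict[str, int] = field(
        default_factory=lambda: {"birds": 120, "mammals": 60, "amphibians": 70}
    )
    #: lognormal over range sizes in base cells: (median_cells, sigma_log)
    range_size_distribution: tuple[float, float] = (30.0, 1.1)
    n_publishers: int = 20
    n_countries: int = 8
    n_airports: int = 12
    n_records: int = 50_000
    #: true log-linear coefficients on standardized exogenous predictors
    effect_vector: dict[str, float] = field(
        default_factory=lambda: {
            "national_funding": 0.7,
            "gbif_participation": 0.7,
            "endemism_richness": 0.4,
            "travel_time": -0.3,
            "protected_fraction": 0.2,
            "security": -0.2,
        }
    )
    #: e-folding length of the publisher-distance decay, in cell widths;
    #: None disables the decay term
    distance_decay_scale: float | None = 8.0
    noise_sd: float = 0.25
    #: autocorrelation range of the intensity noise field (0 = iid)
    noise_autocorr_range: float = 0.0
    #: autocorrelation range of generated environmental surfaces
    predictor_autocorr_range: float = 4.0
    #: publisher placement: fraction of publishers clustered in the
    #: wealthiest countries (emulating Western data-holder concentration)
    publisher_clustering: float = 0.5
    protected_target_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        w, h = self.extent
        if w % 8 or h % 8:
            raise ValueError("extent must be divisible by 8 (three nested coarsenings)")
        for name, v in [
            ("n_publishers", self.n_publishers),
            ("n_countries", self.n_countries),
            ("n_airports", self.n_airports),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        if any(n <= 0 for n in self.n_species.values()):
            raise ValueError("species counts must be > 0")
        if self.distance_decay_scale is not None and self.distance_decay_scale <= 0:
            raise ValueError("distance_decay_scale must be > 0 (or None to disable)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.effect_vector) - set(EXOGENOUS_PREDICTORS) - {"publisher_distance"}
        if unknown:
            raise ValueError(
                f"effect_vector names {sorted(unknown)} are not exogenous predictors; "
                f"allowed: {sorted(EXOGENOUS_PREDICTORS)} + ['publisher_distance']"
            )


@dataclass
class GroundTruth:
    """What the generator knows and the analysis tries to recover."""

    effect_vector: dict[str, float]
    publisher_locations: np.ndarray
    log_intensity: np.ndarray  # per base cell, -inf where unoccupied
    occupied: np.ndarray  # bool per base cell: >=1 species present
    seed: int


@dataclass
class World:
    """A complete generated study system."""

    config: WorldConfig
    grid: GridSystem
    ranges: list[SpeciesRange]
    records: pd.DataFrame
    publishers: pd.DataFrame
    country_of_cell: np.ndarray
    country_table: pd.DataFrame
    elevation: np.ndarray
    protected_mask: np.ndarray
    travel_time: np.ndarray
    airports_xy: np.ndarray
    truth: GroundTruth

    def predictor_inputs(self) -> pred.PredictorInputs:
        return pred.PredictorInputs(
            elevation=self.elevation,
            protected_mask=self.protected_mask,
            travel_time=self.travel_time,
            airports_xy=self.airports_xy,
            country_of_cell=self.country_of_cell,
            country_table=self.country_table,
            ranges=self.ranges,
            records=self.records,
            publishers=self.publishers,
        )


def gen_predictor_field(
    grid: GridSystem, autocorr_range: float, seed: int | np.random.Generator
) -> np.ndarray:
    """A standardized Gaussian random field over base cells.

    iid standard normal noise convolved with an isotropic Gaussian kernel
    of scale ``autocorr_range`` (cell widths), then z-scored: mean 0, sd 1,
    spatial autocorrelation increasing with the range. ``autocorr_range=0``
    returns plain iid noise. Deterministic for a fixed seed.
    """
    if autocorr_range < 0:
        raise ValueError("autocorr_range must be >= 0")
    if grid.width <= 0 or grid.height <= 0:
        raise ValueError("grid extent must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = rng.standard_normal((grid.height, grid.width))
    if autocorr_range > 0:
        z = gaussian_filter(z, sigma=autocorr_range, mode="reflect")
    z = z - z.mean()
    z = z / z.std()
    return z.ravel()  # row-major matches cell_id = iy * width + ix


def _neighbors4(cell: int, w: int, h: int) -> list[int]:
    ix, iy = cell % w, cell // w
    out = []
    if ix > 0:
        out.append(cell - 1)
    if ix < w - 1:
        out.append(cell + 1)
    if iy > 0:
        out.append(cell - w)
    if iy < h - 1:
        out.append(cell + w)
    return out


def _spreading_dye(grid: GridSystem, size: int, rng: np.random.Generator) -> frozenset[int]:
    """Grow a 4-connected cell set of exactly ``size`` cells from a random seed."""
    w, h = grid.width, grid.height
    start = int(rng.integers(w * h))
    chosen = {start}
    frontier = [c for c in _neighbors4(start, w, h)]
    while len(chosen) < size:
        idx = int(rng.integers(len(frontier)))
        cell = frontier.pop(idx)
        if cell in chosen:
            continue
        chosen.add(cell)
        for nb in _neighbors4(cell, w, h):
            if nb not in chosen:
                frontier.append(nb)
    return frozenset(chosen)


def gen_species_ranges(
    grid: GridSystem,
    n_species: int,
    size_dist: tuple[float, float],
    seed: int | np.random.Generator,
    taxon: str = "sp",
) -> list[SpeciesRange]:
    """Contiguous species ranges with lognormal sizes, via spreading dye.

    ``size_dist = (median_cells, sigma_log)``. Draws larger than the grid
    are truncated to the full grid with a warning. Realized sizes equal the
    (clipped) draws exactly and every range is 4-connected.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    median, sigma = size_dist
    n_cells = grid.n_cells(1)
    sizes = np.rint(np.exp(np.log(median) + sigma * rng.standard_normal(n_species))).astype(int)
    sizes = np.maximum(sizes, 1)
    n_over = int((sizes > n_cells).sum())
    if n_over:
        log.warning("%d range-size draws exceed the grid (%d cells); truncated", n_over, n_cells)
        sizes = np.minimum(sizes, n_cells)
    return [
        SpeciesRange(f"{taxon}_{i:04d}", taxon, _spreading_dye(grid, int(s), rng))
        for i, s in enumerate(sizes)
    ]


def gen_countries(grid: GridSystem, n_countries: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous-ish country partition: nearest of n random seed cells."""
    cen = grid.centroids(1)
    seeds = cen[rng.choice(grid.n_cells(1), size=n_countries, replace=False)]
    d = np.linalg.norm(cen[:, None, :] - seeds[None, :, :], axis=2)
    return d.argmin(axis=1)


def gen_country_table(n_countries: int, rng: np.random.Generator) -> pd.DataFrame:
    """Per-country socio-economic covariates, loosely realistic in scale.

    ``security`` follows a Global-Peace-Index convention (higher = less
    peaceful, range ~1-4); funding and GDP are right-skewed (lognormal) and
    positively correlated, as national wealth and research expenditure are.
    """
    wealth = rng.lognormal(mean=np.log(20_000), sigma=0.8, size=n_countries)  # GDP PPP $/cap
    funding = wealth / 100 * rng.lognormal(0, 0.4, n_countries)  # GERD $/cap
    participant = (rng.random(n_countries) < 0.6).astype(int)
    if n_countries >= 2 and len(np.unique(participant)) == 1:
        participant[0] = 1 - participant[0]  # keep the covariate informative
    table = pd.DataFrame(
        {
            "country_id": [f"C{i:02d}" for i in range(n_countries)],
            "security": np.clip(rng.normal(2.2, 0.5, n_countries), 1.0, 4.0),
            "h_index": np.rint(rng.lognormal(np.log(60), 0.7, n_countries)),
            "collab_fraction": rng.beta(2, 2, n_countries),
            "national_funding": funding,
            "gbif_participant": participant,
            "gdp_ppp": wealth,
        }
    ).set_index("country_id")
    return table


def gen_publishers(
    grid: GridSystem,
    n_publishers: int,
    country_of_cell: np.ndarray,
    seed: int | np.random.Generator,
    country_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Place data publishers at random cell centroids with country attribution.

    ``country_weights`` (per country id, need not be normalized) biases
    which country each publisher lands in; default is proportional to
    country area (uniform over cells). Within the chosen country the cell
    is uniform. Each publisher's home country is the country of its cell.
    """
    if n_publishers < 1:
        raise ValueError("n_publishers must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cen = grid.centroids(1)
    countries = pd.unique(country_of_cell)
    if country_weights is None:
        cells = rng.integers(0, grid.n_cells(1), size=n_publishers)
    else:
        w = country_weights.reindex(countries).fillna(0.0).to_numpy(float)
        if w.sum() <= 0:
            raise ValueError("country_weights sum to zero")
        w = w / w.sum()
        cells = np.empty(n_publishers, dtype=int)
        for i in range(n_publishers):
            ctry = countries[rng.choice(len(countries), p=w)]
            pool = np.flatnonzero(country_of_cell == ctry)
            cells[i] = pool[rng.integers(len(pool))]
    return pd.DataFrame(
        {
            "publisher_id": [f"pub_{i:03d}" for i in range(n_publishers)],
            "x": cen[cells, 0],
            "y": cen[cells, 1],
            "country_id": np.asarray(country_of_cell)[cells],
        }
    )


def gen_records(
    ranges: list[SpeciesRange],
    publishers: pd.DataFrame,
    predictor_surfaces: dict[str, np.ndarray],
    config: WorldConfig,
    grid: GridSystem,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample occurrence records from the log-linear intensity model.

    ``predictor_surfaces`` are standardized base-grain columns; every name
    in ``config.effect_vector`` except ``publisher_distance`` must be
    present. Cells with no species get no records (their intensity is
    excluded from the multinomial). Every record's species contains the
    record's cell; record coordinates are uniform within the cell.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_base = grid.n_cells(1)
    cen = grid.centroids(1)

    log_lam = np.zeros(n_base)
    for name, beta in config.effect_vector.items():
        if name == "publisher_distance":
            continue
        if name not in predictor_surfaces:
            raise KeyError(f"effect on {name!r} but no such predictor surface")
        log_lam += beta * np.asarray(predictor_surfaces[name], float)
    pub_xy = publishers[["x", "y"]].to_numpy(float)
    d_pub = np.linalg.norm(cen[:, None, :] - pub_xy[None, :, :], axis=2)
    d_near = d_pub.min(axis=1)
    if config.distance_decay_scale is not None:
        coef = config.effect_vector.get("publisher_distance", 1.0)
        log_lam -= coef * d_near / config.distance_decay_scale
    if config.noise_sd > 0:
        eps = gen_predictor_field(grid, config.noise_autocorr_range, rng) * config.noise_sd
        log_lam += eps

    occupied = np.zeros(n_base, dtype=bool)
    species_in_cell: dict[int, list[str]] = {}
    for r in ranges:
        for c in r.cells:
            occupied[c] = True
            species_in_cell.setdefault(c, []).append(r.species_id)
    for lst in species_in_cell.values():
        lst.sort()

    lam = np.where(occupied, np.exp(log_lam), 0.0)
    truth = GroundTruth(
        effect_vector=dict(config.effect_vector),
        publisher_locations=pub_xy,
        log_intensity=np.where(occupied, log_lam, -np.inf),
        occupied=occupied,
        seed=config.seed,
    )
    empty = pd.DataFrame(
        columns=["record_id", "species_id", "x", "y", "publisher_id"]
    ).astype({"x": float, "y": float})
    if config.n_records == 0:
        return empty, truth
    if lam.sum() <= 0 or not np.isfinite(lam.sum()):
        raise ValueError("degenerate intensity: all-zero or non-finite lambda")

    counts = rng.multinomial(config.n_records, lam / lam.sum())
    inv_d = 1.0 / (d_pub + 0.5)  # inverse-distance publisher weights, finite at d=0
    pub_ids = publishers["publisher_id"].to_numpy()
    rows_species, rows_x, rows_y, rows_pub = [], [], [], []
    w = grid.width
    for cell in np.flatnonzero(counts):
        k = int(counts[cell])
        spp = species_in_cell[cell]
        picks = rng.integers(0, len(spp), size=k)
        pw = inv_d[cell] / inv_d[cell].sum()
        pubs = rng.choice(len(pub_ids), size=k, p=pw)
        x0, y0 = cell % w, cell // w
        rows_x.append(x0 + rng.random(k))
        rows_y.append(y0 + rng.random(k))
        rows_species.extend(spp[i] for i in picks)
        rows_pub.extend(pub_ids[i] for i in pubs)
    records = pd.DataFrame(
        {
            "record_id": [f"r{i:07d}" for i in range(config.n_records)],
            "species_id": rows_species,
            "x": np.concatenate(rows_x),
            "y": np.concatenate(rows_y),
            "publisher_id": rows_pub,
        }
    )
    return records, truth


def generate_world(config: WorldConfig | None = None) -> World:
    """Generate a full study system from a config (deterministic in the seed)."""
    config = config or WorldConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (
        rng_surf,
        rng_country,
        rng_ranges,
        rng_pub,
        rng_rec,
        rng_air,
    ) = [np.random.default_rng(s) for s in ss.spawn(6)]
    grid = build_grid(*config.extent, 4)

    ar = config.predictor_autocorr_range
    # elevation comes from a 2x finer DEM subgrid (4 samples per base cell)
    # so within-cell relief exists even at the base grain
    w, h = config.extent
    subgrid = build_grid(2 * w, 2 * h, 1)
    elev_z_sub = gen_predictor_field(subgrid, 2 * ar, rng_surf)
    sub_ids = np.arange(subgrid.n_cells(1))
    sx, sy = sub_ids % (2 * w), sub_ids // (2 * w)
    base_of_sub = (sy // 2) * w + sx // 2
    sample_slot = (sy % 2) * 2 + sx % 2
    elevation = np.empty((4, grid.n_cells(1)))
    elevation[sample_slot, base_of_sub] = 500.0 + 400.0 * elev_z_sub  # metres
    travel_z = gen_predictor_field(grid, ar, rng_surf)
    prot_z = gen_predictor_field(grid, ar, rng_surf)
    travel_time = 4.0 * np.exp(0.8 * travel_z)  # hours, right-skewed
    thresh = np.quantile(prot_z, 1.0 - config.protected_target_fraction)
    protected_mask = prot_z > thresh

    country_of_cell_idx = gen_countries(grid, config.n_countries, rng_country)
    country_table = gen_country_table(config.n_countries, rng_country)
    ids = country_table.index.to_numpy()
    country_of_cell = ids[country_of_cell_idx]

    airports_xy = np.column_stack(
        [rng_air.random(config.n_airports) * grid.width, rng_air.random(config.n_airports) * grid.height]
    )

    ranges: list[SpeciesRange] = []
    for taxon in sorted(config.n_species):
        ranges.extend(
            gen_species_ranges(
                grid, config.n_species[taxon], config.range_size_distribution, rng_ranges, taxon
            )
        )

    if config.publisher_clustering > 0:
        # wealthier countries attract a disproportionate share of publishers
        w_area = pd.Series(0.0, index=country_table.index)
        for cid in country_of_cell:
            w_area[cid] += 1.0
        w_wealth = country_table["gdp_ppp"] / country_table["gdp_ppp"].sum()
        weights = (1 - config.publisher_clustering) * w_area / w_area.sum() + (
            config.publisher_clustering
        ) * w_wealth
    else:
        weights = None
    publishers = gen_publishers(grid, config.n_publishers, country_of_cell, rng_pub, weights)

    # standardized exogenous surfaces drive sampling intensity exactly as the
    # predictors module will later compute them at the base grain
    sci = pred.scientific_activities(country_table["h_index"], country_table["collab_fraction"])
    raw = pd.DataFrame(
        {
            "endemism_richness": pred.endemism_richness(ranges, grid, 1),
            "topographic_range": pred.topographic_range(elevation, grid, 1),
            "protected_fraction": pred.protected_fraction(protected_mask, grid, 1),
            "travel_time": travel_time,
            "airport_proximity": pred.airport_proximity(airports_xy, grid, 1),
            "security": pred.country_covariate_to_cells(country_of_cell, country_table["security"], grid, 1),
            "scientific_activities": pred.country_covariate_to_cells(country_of_cell, sci, grid, 1),
            "gbif_participation": pred.country_covariate_to_cells(
                country_of_cell, country_table["gbif_participant"], grid, 1, mode="fraction"
            ),
            "national_funding": pred.country_covariate_to_cells(
                country_of_cell, country_table["national_funding"], grid, 1
            ),
        }
    )
    surfaces = {c: pred.standardize(raw[[c]])[c].to_numpy() for c in raw.columns}

    records, truth = gen_records(ranges, publishers, surfaces, config, grid, rng_rec)
    return World(
        config=config,
        grid=grid,
        ranges=ranges,
        records=records,
        publishers=publishers,
        country_of_cell=country_of_cell,
        country_table=country_table,
        elevation=elevation,
        protected_mask=protected_mask,
        travel_time=travel_time,
        airports_xy=airports_xy,
        truth=truth,
    )


def inject_corruption(
    records: pd.DataFrame,
    grid: GridSystem,
    seed: int,
    n_out_of_extent: int = 0,
    n_unknown_species: int = 0,
) -> pd.DataFrame:
    """Append deliberately bad records, to exercise validation paths only."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_out_of_extent):
        rows.append(
            {
                "record_id": f"bad_ext_{i}",
                "species_id": "sp_0000" if len(records) == 0 else records["species_id"].iloc[0],
                "x": grid.width + 1.0 + rng.random(),
                "y": -1.0 - rng.random(),
                "publisher_id": "pub_000",
            }
        )
    for i in range(n_unknown_species):
        rows.append(
            {
                "record_id": f"bad_sp_{i}",
                "species_id": f"ghost_{i}",
                "x": rng.random() * grid.width,
                "y": rng.random() * grid.height,
                "publisher_id": "pub_000",
            }
        )
    return pd.concat([records, pd.DataFrame(rows)], ignore_index=True)
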