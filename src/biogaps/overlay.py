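"""Range/record overlay and inventory completeness on nested grids.

Inventory completeness of a grid cell is the fraction of the species
expected there (from expert range maps, here gridded ranges) that are
documented by at least one validated point record falling in the cell:

    C = S_doc / S_exp,  0 <= C <= 1,

undefined where the expected richness ``S_exp`` is zero. Records of species
not expected in a cell do not enter ``S_doc`` (they are tallied separately
as ``unexpected``), so ``C`` stays a true binomial fraction of expected
richness — the composite response used by the driver models.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSystem

__all__ = [
    "SpeciesRange",
    "expected_richness",
    "endemism_richness",
    "assign_records",
    "build_inventory",
    "completeness",
    "min_grain_for_threshold",
    "min_grain_map",
    "redundancy_histogram",
]

log = logging.getLogger(__name__)

POOLED = "all"


@dataclass(frozen=True)
class SpeciesRange:
    """A species' range as a set of base-grain cell ids."""

    species_id: str
    taxon: str
    cells: frozenset[int]

    def __post_init__(self):
        if not self.cells:
            raise ValueError(f"range of {self.species_id} is empty")

    def cells_at(self, grid: GridSystem, grain: int) -> np.ndarray:
        """Occupied cell ids at ``grain`` (ancestors of the base cells)."""
        base = np.fromiter(self.cells, dtype=int)
        if grain == 1:
            return np.unique(base)
        return np.unique(grid.parents(1, grain)[base])


def _validate_ranges(ranges: list[SpeciesRange], grid: GridSystem) -> None:
    n = grid.n_cells(1)
    for r in ranges:
        cells = np.fromiter(r.cells, dtype=int)
        if cells.min() < 0 or cells.max() >= n:
            raise ValueError(f"range of {r.species_id} has cells outside the grid")


def expected_richness(
    ranges: list[SpeciesRange], grid: GridSystem, grain: int
) -> dict[int, set[str]]:
    """Expected species set per cell at ``grain``.

    The species set of a coarse cell is by construction the union of its
    children's sets (a species occupies a coarse cell iff it occupies at
    least one base cell inside it).
    """
    _validate_ranges(ranges, grid)
    out: dict[int, set[str]] = {}
    for r in ranges:
        for c in r.cells_at(grid, grain):
            out.setdefault(int(c), set()).add(r.species_id)
    return out


def endemism_richness(ranges: list[SpeciesRange], grid: GridSystem, grain: int = 1) -> np.ndarray:
    """Per-cell sum of inverse range sizes (range size in base cells).

    Narrow-ranged species weigh heavily: a single-cell endemic contributes
    1.0 to its cell. Values are computed at the base grain and aggregated to
    coarser grains by the mean over child cells, keeping the index on a
    per-area scale comparable across grains.
    """
    _validate_ranges(ranges, grid)
    base = np.zeros(grid.n_cells(1))
    for r in ranges:
        cells = np.fromiter(r.cells, dtype=int)
        base[cells] += 1.0 / len(r.cells)
    if grain == 1:
        return base
    pm = grid.parents(1, grain)
    sums = np.bincount(pm, weights=base, minlength=grid.n_cells(grain))
    counts = np.bincount(pm, minlength=grid.n_cells(grain))
    return sums / counts


def assign_records(
    records: pd.DataFrame,
    ranges: list[SpeciesRange],
    grid: GridSystem,
    grain: int,
) -> tuple[dict[int, set[str]], np.ndarray, np.ndarray, int]:
    """Overlay point records on the grid at ``grain``.

    Returns ``(documented, n_rec, unexpected, n_invalid)`` where
    ``documented[cell]`` is the set of *expected* species with >= 1 record
    in the cell, ``n_rec`` counts all in-extent records per cell,
    ``unexpected`` counts per cell the records of species not expected
    there (excluded from completeness), and ``n_invalid`` is the number of
    records outside the grid extent (flagged and dropped).
    """
    expected = expected_richness(ranges, grid, grain)
    n_cells = grid.n_cells(grain)
    n_rec = np.zeros(n_cells, dtype=int)
    unexpected = np.zeros(n_cells, dtype=int)
    documented: dict[int, set[str]] = {}
    if len(records) == 0:
        return documented, n_rec, unexpected, 0

    cells = grid.cell_of_point(
        records["x"].to_numpy(float), records["y"].to_numpy(float), grain
    )
    valid = cells >= 0
    n_invalid = int((~valid).sum())
    if n_invalid:
        log.warning("%d records outside grid extent flagged invalid", n_invalid)
    cells = cells[valid]
    species = records["species_id"].to_numpy()[valid]
    np.add.at(n_rec, cells, 1)
    for c, s in zip(cells.tolist(), species.tolist()):
        if s in expected.get(c, ()):
            documented.setdefault(c, set()).add(s)
        else:
            unexpected[c] += 1
    return documented, n_rec, unexpected, n_invalid


def completeness(s_doc: np.ndarray, s_exp: np.ndarray) -> np.ndarray:
    """C = S_doc / S_exp; NaN where S_exp == 0 (no expected species)."""
    s_doc = np.asarray(s_doc, dtype=float)
    s_exp = np.asarray(s_exp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(s_exp > 0, s_doc / s_exp, np.nan)
    return c


def build_inventory(
    ranges: list[SpeciesRange],
    records: pd.DataFrame,
    grid: GridSystem,
    grains: list[int] | None = None,
    per_taxon: bool = True,
) -> pd.DataFrame:
    """Per-(cell, grain, taxon) inventory table.

    Columns: ``cell_id, grain, taxon, S_exp, S_doc, N_rec, unexpected, C``.
    ``taxon`` includes every taxon label in ``ranges`` plus the pooled
    ``"all"`` row set. ``N_rec`` counts all in-extent records of the taxon
    in the cell (documented or not); ``C`` is NaN where ``S_exp`` is zero.
    """
    grains = list(grains) if grains is not None else list(grid.grains)
    taxa = sorted({r.taxon for r in ranges}) if per_taxon else []
    taxon_of = {r.species_id: r.taxon for r in ranges}
    groups: list[tuple[str, list[SpeciesRange], pd.DataFrame]] = [(POOLED, ranges, records)]
    for t in taxa:
        t_ranges = [r for r in ranges if r.taxon == t]
        t_records = records[records["species_id"].map(taxon_of) == t]
        groups.append((t, t_ranges, t_records))

    rows = []
    for taxon, g_ranges, g_records in groups:
        for grain in grains:
            expected = expected_richness(g_ranges, grid, grain)
            documented, n_rec, unexpected, _ = assign_records(g_records, g_ranges, grid, grain)
            for cell in range(grid.n_cells(grain)):
                s_exp = len(expected.get(cell, ()))
                s_doc = len(documented.get(cell, ()))
                rows.append((cell, grain, taxon, s_exp, s_doc, int(n_rec[cell]), int(unexpected[cell])))
    inv = pd.DataFrame(
        rows, columns=["cell_id", "grain", "taxon", "S_exp", "S_doc", "N_rec", "unexpected"]
    )
    inv["C"] = completeness(inv["S_doc"].to_numpy(), inv["S_exp"].to_numpy())
    return inv


def min_grain_for_threshold(
    inventory: pd.DataFrame,
    grid: GridSystem,
    base_cell: int,
    threshold: float = 0.8,
    taxon: str = POOLED,
) -> int | None:
    """Smallest grain at which the ancestor of ``base_cell`` reaches C >= threshold.

    Returns None if the threshold is not reached at the coarsest grain.
    Grains where the ancestor has no expected species are skipped.
    """
    sub = inventory[inventory["taxon"] == taxon]
    for grain in grid.grains:
        anc = int(grid.parents(1, grain)[base_cell])
        row = sub[(sub["grain"] == grain) & (sub["cell_id"] == anc)]
        if len(row) == 0:
            continue
        c = row["C"].iloc[0]
        if np.isfinite(c) and c >= threshold:
            return grain
    return None


def min_grain_map(
    inventory: pd.DataFrame, grid: GridSystem, threshold: float = 0.8, taxon: str = POOLED
) -> np.ndarray:
    """Minimum qualifying grain per base cell (0 where never reached)."""
    sub = inventory[inventory["taxon"] == taxon]
    out = np.zeros(grid.n_cells(1), dtype=int)
    c_by_grain = {}
    for grain in grid.grains:
        g = sub[sub["grain"] == grain].set_index("cell_id")["C"]
        c_by_grain[grain] = g.reindex(range(grid.n_cells(grain))).to_numpy()
    for grain in reversed(list(grid.grains)):  # fine grains overwrite coarse
        pm = grid.parents(1, grain)
        c = c_by_grain[grain][pm]
        hit = np.isfinite(c) & (c >= threshold)
        out[hit] = grain
    return out


def redundancy_histogram(
    records: pd.DataFrame,
    ranges: list[SpeciesRange],
    grid: GridSystem,
    grain: int,
) -> tuple[dict[int, int], dict[str, int]]:
    """Duplication histogram of documented species-cell combinations.

    Returns ``(histogram, totals)``: ``histogram[k]`` is the number of
    (species, cell) combinations documented by exactly ``k`` in-range
    records, and ``totals`` holds ``records_in_range`` (records whose
    species is expected in their cell at this grain), ``documented_combos``
    (unique combinations covered) and ``required_combos``
    (sum over species of range size at this grain — the number of records
    an ideally spread sample would need for 100% completeness).

    Conservation identity: ``sum(k * histogram[k]) == records_in_range``.
    """
    expected = expected_richness(ranges, grid, grain)
    combo_counts: Counter = Counter()
    if len(records):
        cells = grid.cell_of_point(
            records["x"].to_numpy(float), records["y"].to_numpy(float), grain
        )
        species = records["species_id"].to_numpy()
        for c, s in zip(cells.tolist(), species.tolist()):
            if c >= 0 and s in expected.get(c, ()):
                combo_counts[(s, c)] += 1
    hist = Counter(combo_counts.values())
    required = sum(len(r.cells_at(grid, grain)) for r in ranges)
    totals = {
        "records_in_range": sum(combo_counts.values()),
        "documented_combos": len(combo_counts),
        "required_combos": required,
    }
    return dict(sorted(hist.items())), totals
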