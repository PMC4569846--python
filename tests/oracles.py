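"""Independent brute-force oracles used by the test suite.

Everything here is written with naive nested loops and plain set algebra
(or an outside library), deliberately sharing no code with the package.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def cell_of(x: float, y: float, width: int, height: int, factor: int):
    """Half-open point-in-cell lookup; None outside the extent."""
    if not (0 <= x < width and 0 <= y < height):
        return None
    return int(y // factor) * (width // factor) + int(x // factor)


def ancestor(base_cell: int, width: int, factor: int) -> int:
    ix, iy = base_cell % width, base_cell // width
    return (iy // factor) * (width // factor) + (ix // factor)


def naive_inventory(ranges, records, width, height, grain_factor):
    """Per-cell expected/documented sets, record and unexpected counts.

    ``ranges``: {species_id: set(base_cell)}; ``records``: list of
    (species_id, x, y). Returns dict cell -> dict with keys
    s_exp, s_doc (sets) and n_rec, unexpected (ints).
    """
    cells = {}
    ncells = (width // grain_factor) * (height // grain_factor)
    for c in range(ncells):
        cells[c] = {"s_exp": set(), "s_doc": set(), "n_rec": 0, "unexpected": 0}
    for sid, rng_cells in ranges.items():
        for bc in rng_cells:
            cells[ancestor(bc, width, grain_factor)]["s_exp"].add(sid)
    for sid, x, y in records:
        c = cell_of(x, y, width, height, grain_factor)
        if c is None:
            continue
        cells[c]["n_rec"] += 1
        if sid in cells[c]["s_exp"]:
            cells[c]["s_doc"].add(sid)
        else:
            cells[c]["unexpected"] += 1
    return cells


def naive_endemism(ranges, width, height, grain_factor):
    """Per-cell sum of inverse range sizes, mean-aggregated to the grain."""
    base = [0.0] * (width * height)
    for sid, rng_cells in ranges.items():
        for bc in rng_cells:
            base[bc] += 1.0 / len(rng_cells)
    ncells = (width // grain_factor) * (height // grain_factor)
    out = [0.0] * ncells
    counts = [0] * ncells
    for bc, v in enumerate(base):
        a = ancestor(bc, width, grain_factor)
        out[a] += v
        counts[a] += 1
    return [o / c for o, c in zip(out, counts)]


def naive_redundancy(ranges, records, width, height, grain_factor):
    """(histogram, records_in_range, documented, required) by brute force."""
    inv = naive_inventory(ranges, records, width, height, grain_factor)
    combo = Counter()
    for sid, x, y in records:
        c = cell_of(x, y, width, height, grain_factor)
        if c is not None and sid in inv[c]["s_exp"]:
            combo[(sid, c)] += 1
    hist = Counter(combo.values())
    required = 0
    for sid, rng_cells in ranges.items():
        required += len({ancestor(bc, width, grain_factor) for bc in rng_cells})
    return dict(hist), sum(combo.values()), len(combo), required


def naive_country_tally(ranges, records, country_of_base, width, height):
    """Per-country required/documented species-cell combinations (base grain)."""
    inv = naive_inventory(ranges, records, width, height, 1)
    req = Counter()
    doc = Counter()
    for c, d in inv.items():
        ctry = country_of_base[c]
        req[ctry] += len(d["s_exp"])
        doc[ctry] += len(d["s_doc"])
    return dict(req), dict(doc)


def statsmodels_binomial(s_doc, s_exp, X):
    """Independent IRLS reference fit (statsmodels GLM, binomial/logit)."""
    import statsmodels.api as sm

    endog = np.column_stack([s_doc, np.asarray(s_exp) - np.asarray(s_doc)])
    exog = np.column_stack([np.ones(len(s_doc))] + ([np.asarray(X, float)] if X is not None else []))
    if X is not None and np.asarray(X).ndim == 2:
        exog = np.column_stack([np.ones(len(s_doc)), np.asarray(X, float)])
    res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    return np.asarray(res.params), float(res.deviance), float(res.llf)
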