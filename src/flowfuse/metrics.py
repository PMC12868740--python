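"""Evaluation and analysis statistics for migration matrices.

Covers the validation machinery (national rescale, RMSE reduction against a
reference, optionally population-weighted correlations, the demographic
over/undercount estimator sum_i p_i * n_i) and the descriptive statistics
(in-/out-migration rates at any hierarchy level, category-to-category flow
shares with relative rates, conditional upward-mobility curves, and
distance-binned move shares).  "Movers" throughout means off-diagonal mass:
people recorded in the same block group in both years count as stayers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .constraints import UndefinedMetricError
from .geography import LEVEL_WIDTHS, MigrationMatrix
from .synthetic import haversine_miles

DEFAULT_DISTANCE_BINS_MILES = (0.0, 5.0, 50.0, np.inf)


def national_rescale(E: MigrationMatrix, national_population: float) -> MigrationMatrix:
    """Multiply all entries by one scalar so total mass matches the national
    population (removes the overall undercount without touching structure)."""
    total = E.total()
    if total <= 0:
        raise UndefinedMetricError("cannot rescale a matrix with zero total mass")
    scaled = E.matrix * (national_population / total)
    return MigrationMatrix(sparse.csr_array(scaled), E.index, E.year)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_reduction(estimates: np.ndarray, raw: np.ndarray, truth: np.ndarray) -> float:
    """1 - RMSE(estimates, truth) / RMSE(raw, truth)."""
    base = rmse(raw, truth)
    if base == 0:
        raise UndefinedMetricError("raw estimates already match the reference exactly")
    return 1.0 - rmse(estimates, truth) / base


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> float:
    """Pearson correlation, optionally weighted (e.g., by area population)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    sx = np.sqrt(np.sum(w * (x - mx) ** 2))
    sy = np.sqrt(np.sum(w * (y - my) ** 2))
    if sx == 0 or sy == 0:
        raise UndefinedMetricError("zero variance in correlation input")
    return float(cov / (sx * sy))


def migration_rates(E: MigrationMatrix, level: str) -> pd.DataFrame:
    """Per-area in- and out-migration rates at a hierarchy level.

    The in-rate of area a is the mass entering a from outside a divided by
    a's total column mass (its year-t population); the out-rate is the
    symmetric statistic on rows.  Moves within the area at the chosen level
    are not migration at that level.  Zero-population areas get NaN.
    """
    if level not in LEVEL_WIDTHS:
        raise ValueError(f"unknown level {level!r}")
    width = LEVEL_WIDTHS[level]
    coo = sparse.coo_array(E.matrix)
    area = np.array([u[:width] for u in E.index], dtype=object)
    uniq, codes = np.unique(area, return_inverse=True)
    r, c = codes[coo.row], codes[coo.col]
    col_tot = np.bincount(c, weights=coo.data, minlength=len(uniq))
    row_tot = np.bincount(r, weights=coo.data, minlength=len(uniq))
    cross = r != c
    inflow = np.bincount(c[cross], weights=coo.data[cross], minlength=len(uniq))
    outflow = np.bincount(r[cross], weights=coo.data[cross], minlength=len(uniq))
    with np.errstate(invalid="ignore", divide="ignore"):
        in_rate = np.where(col_tot > 0, inflow / col_tot, np.nan)
        out_rate = np.where(row_tot > 0, outflow / row_tot, np.nan)
    return pd.DataFrame(
        {"in_rate": in_rate, "out_rate": out_rate,
         "population_cur": col_tot, "population_prev": row_tot},
        index=pd.Index(uniq, name=level),
    )


def group_count_bias(n: pd.Series, shares: pd.DataFrame,
                     census_group_totals: pd.Series) -> pd.Series:
    """Signed relative over/undercount per demographic group.

    ``n`` holds per-cbg person counts from a matrix (row or column sums);
    ``shares`` per-cbg group proportions p_i; the estimated group count is
    sum_i p_i * n_i, compared against the census total for that group.
    """
    n = n.reindex(shares.index).fillna(0.0)
    est = shares.mul(n, axis=0).sum(axis=0)
    out = {}
    for g in census_group_totals.index:
        total = float(census_group_totals[g])
        if total == 0:
            raise UndefinedMetricError(f"census total for group {g} is zero")
        out[g] = (float(est.get(g, 0.0)) - total) / total
    return pd.Series(out)


def _mover_arrays(E: MigrationMatrix, out_of_county_only: bool = False
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coo = sparse.coo_array(E.matrix)
    keep = coo.row != coo.col
    if out_of_county_only:
        county = np.array([u[:5] for u in E.index], dtype=object)
        keep &= county[coo.row] != county[coo.col]
    return coo.row[keep], coo.col[keep], coo.data[keep]


@dataclass
class CategoryFlowMatrix:
    """Origin-category by destination-category mover shares.

    ``shares`` rows sum to 1 over the destination partition; ``relative``
    divides each row by the overall destination shares of all movers;
    ``destination_shares`` and ``population_shares`` are the two summary
    rows of the display.
    """

    shares: pd.DataFrame
    relative: pd.DataFrame
    destination_shares: pd.Series
    population_shares: pd.Series


def category_flow_matrix(E: MigrationMatrix, labels: pd.Series,
                         out_of_county_only: bool = False) -> CategoryFlowMatrix:
    """Share of movers from each origin category landing in each destination
    category; within-cbg (diagonal) mass is excluded."""
    labels = labels.reindex(E.index).astype(object)
    cats = sorted(labels.dropna().unique())
    cat_pos = {c: k for k, c in enumerate(cats)}
    lab_arr = labels.to_numpy(object)
    rows, cols, data = _mover_arrays(E, out_of_county_only)
    ok = np.array([lab_arr[i] in cat_pos and lab_arr[j] in cat_pos
                   for i, j in zip(rows, cols)])
    if not ok.any():
        raise UndefinedMetricError("no movers with labelled origin and destination")
    rows, cols, data = rows[ok], cols[ok], data[ok]
    oc = np.array([cat_pos[lab_arr[i]] for i in rows])
    dc = np.array([cat_pos[lab_arr[j]] for j in cols])
    k = len(cats)
    flows = np.zeros((k, k))
    np.add.at(flows, (oc, dc), data)

    row_tot = flows.sum(axis=1)
    present = row_tot > 0
    shares = pd.DataFrame(
        flows[present] / row_tot[present, None],
        index=pd.Index(np.array(cats, object)[present], name="origin"),
        columns=pd.Index(cats, name="destination"),
    )
    dest = pd.Series(flows.sum(axis=0) / flows.sum(), index=shares.columns)
    relative = shares.div(dest, axis=1)
    pops = pd.Series(np.asarray(E.matrix.sum(axis=1)).ravel(), index=E.index)
    pop_by_cat = pops.groupby(labels).sum().reindex(cats).fillna(0.0)
    pop_shares = pop_by_cat / pop_by_cat.sum()
    pop_shares.index = shares.columns
    return CategoryFlowMatrix(shares, relative, dest, pop_shares)


def income_deciles(income: pd.Series, weights: pd.Series | None = None) -> pd.Series:
    """Decile (1..10) of each cbg by income, optionally population-weighted."""
    income = income.dropna()
    if weights is None:
        ranks = income.rank(method="first")
        return pd.qcut(ranks, 10, labels=range(1, 11)).astype(int)
    w = weights.reindex(income.index).fillna(0.0)
    order = income.sort_values().index
    cum = w[order].cumsum() / w[order].sum()
    dec = np.minimum((cum * 10).apply(np.ceil).astype(int), 10).clip(lower=1)
    return dec.reindex(income.index)


def upward_mobility_curves(E: MigrationMatrix, income: pd.Series,
                           category: pd.Series,
                           weights: pd.Series | None = None) -> pd.DataFrame:
    """P(destination income > origin income) for movers, by origin income
    decile and origin category; plus destination top/bottom-quartile variants.

    Empty (decile, category) cells come back as NaN.
    """
    income = income.reindex(E.index)
    category = category.reindex(E.index)
    deciles = income_deciles(income, weights).reindex(E.index)
    quart = pd.qcut(income.rank(method="first"), 4, labels=[1, 2, 3, 4]).astype(float)

    rows, cols, data = _mover_arrays(E)
    inc = income.to_numpy(float)
    dec_arr = deciles.to_numpy(float)
    cat_arr = category.to_numpy(object)
    q_arr = quart.to_numpy(float)

    records: dict[tuple[float, object], dict[str, float]] = {}
    for i, j, w in zip(rows, cols, data):
        d, c = dec_arr[i], cat_arr[i]
        if np.isnan(d) or c is None or np.isnan(inc[i]) or np.isnan(inc[j]):
            continue
        cell = records.setdefault((d, c), {"mass": 0.0, "up": 0.0, "top": 0.0, "bottom": 0.0})
        cell["mass"] += w
        if inc[j] > inc[i]:
            cell["up"] += w
        if q_arr[j] == 4:
            cell["top"] += w
        if q_arr[j] == 1:
            cell["bottom"] += w

    out = []
    for (d, c), cell in sorted(records.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        m = cell["mass"]
        out.append({
            "decile": int(d), "category": c,
            "p_higher_income": cell["up"] / m if m else np.nan,
            "p_top_quartile": cell["top"] / m if m else np.nan,
            "p_bottom_quartile": cell["bottom"] / m if m else np.nan,
            "mover_mass": m,
        })
    return pd.DataFrame(out)


def distance_bins(E: MigrationMatrix, centroids: pd.DataFrame,
                  bins: tuple[float, ...] = DEFAULT_DISTANCE_BINS_MILES,
                  category: pd.Series | None = None) -> pd.DataFrame:
    """Share of mover mass per great-circle distance bin ([lo, hi) miles),
    optionally stratified by origin category.  Movers whose origin or
    destination centroid is missing are excluded and counted."""
    centroids = centroids.reindex(E.index)
    rows, cols, data = _mover_arrays(E)
    lat = centroids["lat"].to_numpy(float)
    lon = centroids["lon"].to_numpy(float)
    have = ~(np.isnan(lat[rows]) | np.isnan(lon[rows]) | np.isnan(lat[cols]) | np.isnan(lon[cols]))
    excluded = float(data[~have].sum())
    rows, cols, data = rows[have], cols[have], data[have]
    dist = haversine_miles(lat[rows], lon[rows], lat[cols], lon[cols])
    edges = np.asarray(bins, float)
    which = np.searchsorted(edges, dist, side="right") - 1
    which = np.clip(which, 0, len(edges) - 2)

    def shares_for(mask: np.ndarray) -> list[float]:
        tot = data[mask].sum()
        return [float(data[mask & (which == b)].sum() / tot) if tot else np.nan
                for b in range(len(edges) - 1)]

    labels_cols = [f"[{edges[b]:g}, {edges[b + 1]:g})" for b in range(len(edges) - 1)]
    table = {"all": shares_for(np.ones(len(data), bool))}
    if category is not None:
        cat_arr = category.reindex(E.index).to_numpy(object)
        for c in sorted({x for x in cat_arr[rows] if x is not None}):
            table[str(c)] = shares_for(np.array([cat_arr[i] == c for i in rows]))
    out = pd.DataFrame(table, index=labels_cols).T
    out.attrs["excluded_mass"] = excluded
    return out
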