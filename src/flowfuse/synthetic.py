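"""Synthetic study system: geography, ground-truth flows, messy histories,
biased observation, and census-style constraint tables.

The generator builds a nested state/county/tract/block-group geography on a
coordinate grid, draws ground-truth annual flow matrices from a gravity
model with categorical homophily (a deliberate stand-in with known
structure, not a claim of US realism), realizes those flows as individual
month-resolved address histories with configurable messiness (missing
effective dates, PO boxes, simultaneous addresses, ZIP-only addresses),
subsamples individuals with category-dependent inclusion probabilities to
emulate the demographic bias of consumer-record data, and derives every
constraint table the harmonization consumes -- decennial and rolling
five-year small-area populations, state mover/non-mover counts,
state-to-state flows, county populations, and components of change.

Ground-truth flows are integerized row-by-row (largest-remainder, preserving
row sums exactly), which lets the individual generator realize the truth
*exactly*: with all messiness rates at zero and moves placed on January 1,
pushing the generated individuals back through the history and mapping
modules reproduces the true matrix bit-for-bit.  All randomness flows from a
single integer seed through ``numpy.random.default_rng``.

Defaults are the fixed study conditions: an annual mover share of 12%
(approximately the US rate over 2010-2019), distance-decay exponent 1.5,
homophily boost 3, 5% messiness per channel with 10% ZIP-only addresses,
and group inclusion probabilities of 0.9 / 0.55.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from . import constraints as cons
from . import geography as geo
from . import histories as hist

EARTH_RADIUS_MILES = 3958.8


def haversine_miles(lat1, lon1, lat2, lon2):
    """Great-circle distance in miles; accepts scalars or arrays (degrees)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class SyntheticConfig:
    seed: int = 0
    # geography sizes
    n_states: int = 2
    counties_per_state: int = 2
    tracts_per_county: int = 2
    cbgs_per_tract: int = 2
    # populations
    mean_cbg_population: float = 200.0
    population_sigma: float = 0.4  # lognormal spread of cbg populations
    # gravity model
    distance_decay: float = 1.0
    homophily_boost: float = 3.0
    mobility_rate: float = 0.12  # annual share of movers
    # messiness rates (independent per record)
    p_missing_effective: float = 0.05
    p_po_box: float = 0.05
    p_simultaneous: float = 0.05
    p_zip_only: float = 0.10
    # observation bias: inclusion probability per category group
    inclusion_probabilities: dict[str, float] = field(
        default_factory=lambda: {"majority": 0.9, "minority": 0.55}
    )
    # constraint noise: relative coefficient of variation per survey table
    constraint_noise_cv: float = 0.0
    # components of change: closed population by default (exact feasibility)
    closed_population: bool = True
    component_rate: float = 0.01  # per-capita rate for each component if open
    # years (fixed by the interpolation system)
    first_year: int = 2009
    last_year: int = 2019

    def __post_init__(self) -> None:
        for name in ("p_missing_effective", "p_po_box", "p_simultaneous", "p_zip_only"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not all(0.0 <= p <= 1.0 for p in self.inclusion_probabilities.values()):
            raise ValueError("inclusion probabilities must lie in [0, 1]")
        if min(self.n_states, self.counties_per_state, self.tracts_per_county,
               self.cbgs_per_tract) < 1:
            raise ValueError("geography sizes must be >= 1")
        if self.cbgs_per_tract > 9:
            raise ValueError("at most 9 block groups per tract (single-digit suffix)")


@dataclass
class GroundTruth:
    hierarchy: geo.GeographyHierarchy
    labels: pd.DataFrame  # per cbg: group, income_quartile, urban, median_income
    populations: pd.DataFrame  # years x cbgs, integer populations
    flows: dict[int, geo.MigrationMatrix]  # year t -> truth E^(t)


# ---------------------------------------------------------------------------
# Geography and labels
# ---------------------------------------------------------------------------

def generate_geography(cfg: SyntheticConfig, rng: np.random.Generator | None = None
                       ) -> tuple[geo.GeographyHierarchy, pd.DataFrame]:
    """Nested prefix ids, grid centroids, lognormal-ish populations, and
    spatially correlated category labels."""
    rng = rng or np.random.default_rng(cfg.seed)
    rows = []
    labels = []
    groups = list(cfg.inclusion_probabilities)
    for s in range(cfg.n_states):
        sid = f"{s + 1:02d}"
        for c in range(cfg.counties_per_state):
            cid = sid + f"{c + 1:03d}"
            county_group = groups[rng.integers(len(groups))]
            for t in range(cfg.tracts_per_county):
                tid = cid + f"{t + 1:06d}"
                for b in range(cfg.cbgs_per_tract):
                    bid = tid + f"{b + 1:d}"
                    lat = 30.0 + s * 0.5 + c * 0.15 + t * 0.05 + b * 0.02
                    lon = -100.0 + s * 0.5 + c * 0.15 + t * 0.05 + b * 0.02
                    pop = int(round(rng.lognormal(
                        np.log(cfg.mean_cbg_population), cfg.population_sigma)))
                    pop = max(pop, 20)
                    group = county_group if rng.random() < 0.8 else groups[
                        rng.integers(len(groups))]
                    income = float(rng.lognormal(np.log(50_000.0), 0.3))
                    if group == groups[0]:
                        income *= 1.25  # mild group-income correlation
                    rows.append((bid, "cbg", pop, lat, lon))
                    labels.append((bid, group, income))

    units = pd.DataFrame(rows, columns=["id", "level", "population", "lat", "lon"])
    # aggregate parents (population-weighted centroids)
    for level, width in (("tract", 11), ("county", 5), ("state", 2)):
        grp = units[units["level"] == "cbg"].copy()
        grp["pid"] = grp["id"].str[:width]
        agg = grp.groupby("pid").apply(
            lambda g: pd.Series({
                "population": g["population"].sum(),
                "lat": np.average(g["lat"], weights=g["population"]),
                "lon": np.average(g["lon"], weights=g["population"]),
            }),
            include_groups=False,
        )
        for pid, r in agg.iterrows():
            units.loc[len(units)] = [pid, level, r["population"], r["lat"], r["lon"]]

    hierarchy = geo.GeographyHierarchy(units)
    hierarchy.validate()

    lab = pd.DataFrame(labels, columns=["cbg", "group", "median_income"]).set_index("cbg")
    lab = lab.sort_index()
    quartile = pd.qcut(lab["median_income"].rank(method="first"), 4, labels=[1, 2, 3, 4])
    lab["income_quartile"] = quartile.astype(int)
    pops = hierarchy.populations("cbg")
    lab["urban"] = (pops.reindex(lab.index) >= pops.median()).astype(bool)
    return hierarchy, lab


# ---------------------------------------------------------------------------
# Ground-truth flows
# ---------------------------------------------------------------------------

def _largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers preserving their (integer) sum."""
    floors = np.floor(values).astype(np.int64)
    short = int(total - floors.sum())
    if short > 0:
        order = np.argsort(-(values - floors), kind="stable")
        floors[order[:short]] += 1
    elif short < 0:  # can only occur through float slack
        order = np.argsort(values - floors, kind="stable")
        for k in order:
            if short == 0:
                break
            if floors[k] > 0:
                floors[k] -= 1
                short += 1
    return floors


def generate_true_flows(
    hierarchy: geo.GeographyHierarchy,
    labels: pd.DataFrame,
    populations: pd.Series,
    cfg: SyntheticConfig,
    year: int,
    integerize: bool = True,
) -> geo.MigrationMatrix:
    """Gravity-with-homophily flow matrix whose rows sum to ``populations``.

    Diagonal mass is ``(1 - mobility_rate) * population``; each origin's
    mover mass is allocated across destinations proportionally to
    ``pop_j * dist_ij**(-decay) * boost``, the boost applying when origin and
    destination share a category group.  With ``integerize`` the matrix is
    rounded row-wise by largest remainder so integer row sums are preserved
    exactly.
    """
    cbgs = hierarchy.cbg_ids
    pop = populations.reindex(cbgs).to_numpy(float)
    cent = hierarchy.centroids("cbg").reindex(cbgs)
    lat, lon = cent["lat"].to_numpy(), cent["lon"].to_numpy()
    group = labels["group"].reindex(cbgs).to_numpy(object)
    n = len(cbgs)

    dist = haversine_miles(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(dist, np.inf)  # no self-allocation of mover mass
    with np.errstate(divide="ignore"):
        decay = np.where(np.isfinite(dist), np.maximum(dist, 0.5) ** (-cfg.distance_decay), 0.0)
    boost = np.where(group[:, None] == group[None, :], cfg.homophily_boost, 1.0)
    weight = pop[None, :] * decay * boost
    np.fill_diagonal(weight, 0.0)

    mat = np.zeros((n, n))
    for i in range(n):
        movers = cfg.mobility_rate * pop[i]
        wsum = weight[i].sum()
        if movers > 0 and wsum > 0:
            mat[i] = movers * weight[i] / wsum
        mat[i, i] = pop[i] - mat[i].sum()
    if integerize:
        imat = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            imat[i] = _largest_remainder(mat[i], int(round(pop[i])))
        mat = imat.astype(float)
    sp = sparse.csr_array(sparse.coo_array(mat))
    sp.eliminate_zeros()
    return geo.MigrationMatrix(sp, np.asarray(cbgs, dtype=object), year)


def generate_truth(cfg: SyntheticConfig) -> GroundTruth:
    """Full ground truth: geography, labels, and flows for every year."""
    rng = np.random.default_rng(cfg.seed)
    hierarchy, labels = generate_geography(cfg, rng)
    pops = {cfg.first_year: hierarchy.populations("cbg").astype(int)}
    flows: dict[int, geo.MigrationMatrix] = {}
    for year in range(cfg.first_year + 1, cfg.last_year + 1):
        E = generate_true_flows(hierarchy, labels, pops[year - 1], cfg, year)
        flows[year] = E
        col = np.asarray(E.matrix.sum(axis=0)).ravel()
        pops[year] = pd.Series(col.astype(int), index=E.index)
    populations = pd.DataFrame(pops).T  # years x cbgs
    populations.index.name = "year"
    return GroundTruth(hierarchy, labels, populations, flows)


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------

def street_address(cbg: str, secondary: bool = False) -> str:
    return ("B" if secondary else "A") + cbg


def po_box_address(cbg: str) -> str:
    return "P" + cbg


def zip_address(tract: str) -> str:
    return "Z" + tract


def generate_individuals(truth: GroundTruth, cfg: SyntheticConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Individual address-record table realizing the true flows.

    Persons are routed through the years by slicing each origin's (seeded,
    shuffled) occupant pool according to the integer truth rows, so yearly
    cbg-to-cbg transitions match the truth exactly.  Moves take effect on
    January 1 of the destination year.  Messiness is then injected
    independently per record; a ``origin_cbg`` metadata column records each
    person's initial cbg for the observation-bias step (it is not an input
    to the history pipeline).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    cbgs = list(truth.hierarchy.cbg_ids)
    y0, y1 = cfg.first_year, cfg.last_year

    pop0 = truth.populations.loc[y0]
    trajectories: list[list[tuple[int, str]]] = []
    occupants: dict[str, list[int]] = {}
    pid = 0
    for cbg in cbgs:
        ids = []
        for _ in range(int(pop0[cbg])):
            trajectories.append([(y0, cbg)])
            ids.append(pid)
            pid += 1
        occupants[cbg] = ids

    for year in range(y0 + 1, y1 + 1):
        E = truth.flows[year]
        mat = E.matrix.tocsr()
        new_occ: dict[str, list[int]] = {c: [] for c in cbgs}
        for oi, cbg in enumerate(E.index):
            pool = occupants[cbg]
            rng.shuffle(pool)
            start = mat.indptr[oi]
            end = mat.indptr[oi + 1]
            cursor = 0
            for k in range(start, end):
                dest = E.index[mat.indices[k]]
                count = int(round(mat.data[k]))
                members = pool[cursor: cursor + count]
                cursor += count
                for p in members:
                    if dest != cbg:
                        trajectories[p].append((year, dest))
                    new_occ[dest].append(p)
        occupants = new_occ

    # trajectories -> records with messiness
    rows = []
    listed_start = f"{y0}-01"
    listed_end = f"{y1}-12"
    for p, traj in enumerate(trajectories):
        origin_cbg = traj[0][1]
        person = f"p{p:07d}"
        for year, cbg in traj:
            aid, kind = street_address(cbg), "street"
            if rng.random() < cfg.p_zip_only:
                aid, kind = zip_address(cbg[:11]), "incomplete"
            elif rng.random() < cfg.p_simultaneous:
                # a second simultaneously effective address in the same cbg
                rows.append((person, street_address(cbg, secondary=True), year, 1,
                             "street", listed_start, listed_end, origin_cbg))
            ey: float | int = year
            em: float | int = 1
            if rng.random() < cfg.p_missing_effective:
                ey = em = np.nan
            rows.append((person, aid, ey, em, kind, listed_start, listed_end, origin_cbg))
            if rng.random() < cfg.p_po_box:
                rows.append((person, po_box_address(cbg), year, 6, "po_box",
                             listed_start, listed_end, origin_cbg))
    return pd.DataFrame(
        rows,
        columns=["person_id", "address_id", "effective_year", "effective_month",
                 "kind", "listed_start", "listed_end", "origin_cbg"],
    )


def bias_observation(table: pd.DataFrame, labels: pd.DataFrame, cfg: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Retain each person independently with a category-dependent probability
    keyed on the group of their origin cbg."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    persons = table.drop_duplicates("person_id")[["person_id", "origin_cbg"]]
    group = labels["group"].reindex(persons["origin_cbg"].astype(str)).to_numpy(object)
    probs = np.array([cfg.inclusion_probabilities[g] for g in group])
    keep = rng.random(len(persons)) < probs
    kept_ids = set(persons["person_id"].to_numpy(object)[keep])
    return table[table["person_id"].isin(kept_ids)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mapping inputs (geocode table + ZIP crosswalk)
# ---------------------------------------------------------------------------

def mapping_inputs(truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Geocode table and ZIP crosswalk covering every synthetic address.

    Street addresses (A/B prefixes) geocode one-hot to their cbg; PO-box and
    ZIP-only addresses resolve through the crosswalk, one ZIP per tract with
    residential share 1.
    """
    rows = []
    for cbg in truth.hierarchy.cbg_ids:
        rows.append((street_address(cbg), "street", cbg))
        rows.append((street_address(cbg, secondary=True), "street", cbg))
        rows.append((po_box_address(cbg), "po_box", None))
    tracts = sorted({c[:11] for c in truth.hierarchy.cbg_ids})
    for tract in tracts:
        rows.append((zip_address(tract), "incomplete", None))
    geocoded = pd.DataFrame(rows, columns=["address_id", "kind", "cbg"])
    crosswalk = pd.DataFrame(
        [("2015-06", tract, tract, 1.0) for tract in tracts],
        columns=["snapshot_date", "zip", "tract", "residential_share"],
    )
    return geocoded, crosswalk


def build_synthetic_mapping(truth: GroundTruth) -> geo.MappingMatrix:
    geocoded, crosswalk = mapping_inputs(truth)
    zip_results: dict[str, dict[str, float] | None] = {}
    for row in geocoded.itertuples(index=False):
        if pd.isna(row.cbg):
            zip_code = row.address_id[1:][:11]  # tract doubles as the ZIP
            try:
                zip_results[row.address_id] = geo.zip_fallback_distribution(
                    zip_code, crosswalk, (2015, 6), truth.hierarchy)
            except geo.UnmappableAddressError:
                zip_results[row.address_id] = None
    return geo.build_mapping_matrix(geocoded, zip_results, truth.hierarchy)


# ---------------------------------------------------------------------------
# Constraint tables
# ---------------------------------------------------------------------------

def derive_constraints(truth: GroundTruth, cfg: SyntheticConfig,
                       rng: np.random.Generator | None = None
                       ) -> dict[str, pd.DataFrame]:
    """Census-style constraint tables aggregated from the ground truth.

    Five-year small-area values are the true rolling means implied by the
    interpolation system (windows clipped at 2009); optional multiplicative
    lognormal noise at ``constraint_noise_cv`` is applied to the survey-style
    tables, with margins of error set to 1.645 * cv * value.  County year-t
    populations are rescaled to the year-t-1 national total after noising so
    the IPF feasibility invariant holds by construction.  In the open
    (non-closed) mode, per-state components of change are generated and the
    reported populations shifted by them, so the adjustment operations
    recover truth-consistent constraints.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    years = list(range(cfg.first_year, cfg.last_year + 1))
    if len(years) < len(cons.INTERP_YEARS):
        raise ValueError("need at least the 2009-2019 span of truth years")
    pops = truth.populations  # years x cbgs
    cv = cfg.constraint_noise_cv

    def noisy(v: float) -> float:
        if cv <= 0:
            return float(v)
        return float(v) * rng.lognormal(-0.5 * np.log1p(cv**2), np.sqrt(np.log1p(cv**2)))

    A = cons.interpolation_matrix()
    cbgs = list(pops.columns)
    dec_rows, acs_rows = [], []
    for cbg in cbgs:
        x = pops.loc[list(cons.INTERP_YEARS), cbg].to_numpy(float)
        b = A @ x
        dec_rows.append((cbg, b[0]))
        for k, yend in enumerate(cons.ACS5_WINDOW_END_YEARS, start=1):
            v = noisy(b[k])
            acs_rows.append((cbg, yend, v, cons.MOE_Z * cv * v))
    cbg_decennial = pd.DataFrame(dec_rows, columns=["area_id", "value"])
    cbg_acs5 = pd.DataFrame(acs_rows, columns=["area_id", "year", "value", "moe"])

    state_of = np.array([c[:2] for c in cbgs], dtype=object)
    county_of = np.array([c[:5] for c in cbgs], dtype=object)
    states = sorted(set(state_of))
    counties = sorted(set(county_of))

    # components of change (zero when the population is closed)
    comp_state_rows, comp_county_rows = [], []
    comp: dict[tuple[int, str], dict[str, float]] = {}
    for t in years[1:]:
        for st in states:
            if cfg.closed_population:
                c = dict(births=0.0, deaths=0.0, net_international=0.0, immigrants=0.0)
            else:
                base = float(pops.loc[t, [c_ for c_ in cbgs if c_[:2] == st]].sum())
                births = round(cfg.component_rate * base)
                deaths = round(0.8 * cfg.component_rate * base)
                immigrants = round(0.6 * cfg.component_rate * base)
                emigrants = round(0.3 * cfg.component_rate * base)
                c = dict(births=births, deaths=deaths,
                         net_international=immigrants - emigrants, immigrants=immigrants)
            comp[(t, st)] = c
            comp_state_rows.append((st, t, c["births"], c["deaths"],
                                    c["net_international"], c["immigrants"]))

    sm_rows, fl_rows, cp_rows = [], [], []
    for t in years[1:]:
        E = truth.flows[t].matrix.tocoo()
        idx = truth.flows[t].index
        r_state = np.array([idx[i][:2] for i in E.row], dtype=object)
        c_state = np.array([idx[j][:2] for j in E.col], dtype=object)
        diag = E.row == E.col
        for st in states:
            c = comp[(t, st)]
            emig = max(c["immigrants"] - c["net_international"], 0.0)
            S_true = float(E.data[c_state == st].sum())
            R_true = float(E.data[diag & (c_state == st)].sum())
            # reported values: census populations include the components the
            # adjustment later strips; non-movers exclude deaths/emigrants
            S_rep = noisy(S_true + (c["births"] - c["deaths"]) + c["net_international"])
            R_rep = noisy(max(R_true - c["deaths"] - emig, 0.0))
            sm_rows.append((st, t, S_rep, R_rep))
            for st2 in states:
                v = float(E.data[(r_state == st) & (c_state == st2)].sum())
                if st == st2:
                    v = max(v - c["deaths"] - emig, 0.0)
                fl_rows.append((st, st2, t, noisy(v)))

    # County populations form a chain P(t) = P(t-1) + components(t) at the
    # national level, so after the components adjustment every consecutive
    # pair of years is exactly IPF-feasible, noise or not.
    running_total: float | None = None
    for t in years:
        col_pop = (pd.Series(np.asarray(truth.flows[t].matrix.sum(axis=0)).ravel(),
                             index=truth.flows[t].index)
                   if t > years[0] else pops.loc[t])
        by_county = col_pop.groupby(pd.Index(col_pop.index, dtype=object).str[:5]).sum()
        county_vals = {}
        for cty in counties:
            v = float(by_county.get(cty, 0.0))
            if t > years[0]:
                c = comp[(t, cty[:2])]
                share = v / max(float(by_county[by_county.index.str[:2] == cty[:2]].sum()), 1.0)
                b, d = c["births"] * share, c["deaths"] * share
                ni = c["net_international"] * share
                comp_county_rows.append((cty, t, b, d, ni, c["immigrants"] * share))
                v = v + (b - d) + ni
            county_vals[cty] = noisy(v)
        comp_total = (
            sum(comp[(t, st)]["births"] - comp[(t, st)]["deaths"]
                + comp[(t, st)]["net_international"] for st in states)
            if t > years[0] else 0.0
        )
        if running_total is None:
            target_total = float(by_county.sum())
        else:
            target_total = running_total + comp_total
        scale = target_total / max(sum(county_vals.values()), 1e-12)
        for cty, v in county_vals.items():
            cp_rows.append((cty, t, v * scale))
        running_total = target_total

    tables = {
        "cbg_decennial": cbg_decennial,
        "cbg_acs5": cbg_acs5,
        "state_movers": pd.DataFrame(sm_rows,
                                     columns=["area_id", "year", "population", "nonmovers"]),
        "state_flows": pd.DataFrame(fl_rows, columns=["origin", "dest", "year", "value"]),
        "county_pop": pd.DataFrame(cp_rows, columns=["area_id", "year", "value"]),
        "components_state": pd.DataFrame(
            comp_state_rows,
            columns=["area_id", "year", "births", "deaths", "net_international", "immigrants"]),
        "components_county": pd.DataFrame(
            comp_county_rows,
            columns=["area_id", "year", "births", "deaths", "net_international", "immigrants"]),
    }
    return tables


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class EndToEndResult:
    truth: GroundTruth
    year: int
    observed: geo.MigrationMatrix  # raw collapsed matrix from biased histories
    constraints: cons.ConstraintSet
    harmonized: geo.MigrationMatrix
    reports: list


def observe_flows(truth: GroundTruth, cfg: SyntheticConfig, year: int,
                  with_bias: bool = True) -> geo.MigrationMatrix:
    """Messy observation path: individuals -> (bias) -> histories -> mapping."""
    table = generate_individuals(truth, cfg)
    if with_bias:
        table = bias_observation(table, truth.labels, cfg)
    persons, _ = hist.histories_from_table(
        table.drop(columns=["origin_cbg"]))
    A = hist.aggregate_flows(persons, year)
    G = build_synthetic_mapping(truth)
    return geo.collapse_to_cbg(A, G, year=year)


def run_end_to_end(cfg: SyntheticConfig, year: int = 2015,
                   with_bias: bool = True) -> EndToEndResult:
    """Generate, observe, constrain and harmonize one synthetic replicate."""
    from .harmonize import harmonize_pipeline

    truth = generate_truth(cfg)
    observed = observe_flows(truth, cfg, year, with_bias=with_bias)
    tables = derive_constraints(truth, cfg)
    cset = cons.build_constraint_set(tables, year)
    harmonized, reports = harmonize_pipeline(observed, cset)
    return EndToEndResult(truth, year, observed, cset, harmonized, reports)
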