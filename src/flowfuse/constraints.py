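"""Turn census-style tables into harmonization-ready constraint sets.

Three families of quantities feed the harmonization:

* Yearly small-area (CBG) populations, which no census product publishes
  directly.  They are interpolated from a decennial count plus ten rolling
  five-year survey averages by solving, per CBG, the non-negative least
  squares system ``min ||A x - b||, x >= 0`` where ``A`` is a fixed 11x11
  averaging matrix over the years 2009..2019 and ``b`` stacks the decennial
  2010 value and the 2006-10 .. 2015-19 five-year averages (windows clipped
  to the 2009..2019 range).  ``A`` is nonsingular, so noise-free inputs are
  recovered exactly.

* State-level one-year counts of movers and non-movers and state-to-state
  flows, adjusted so they describe the same universe as the flow matrix:
  deaths and emigrants are added back to the diagonal (they are recorded as
  non-movers), and year-t immigrants -- who had no US residence in year
  t-1 -- are removed from the mover target.

* County populations for years t-1 and t, with the year-t values stripped of
  natural increase (births - deaths) and net international migration so that
  national totals for the two years agree (required for IPF feasibility).

Survey estimates carry 90% margins of error; their coefficient of variation
is (moe / 1.645) / value, and margins aggregate in the L2 norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

#: z-score of the 90% confidence half-width used by survey margins of error.
MOE_Z = 1.645

#: Year span of the interpolation system.
INTERP_YEARS = tuple(range(2009, 2020))
DECENNIAL_YEAR = 2010
ACS5_WINDOW_END_YEARS = tuple(range(2010, 2020))

FEASIBILITY_RTOL = 1e-6


class UndefinedMetricError(ZeroDivisionError):
    """A ratio metric is undefined for this input (zero denominator)."""


class ConfigurationError(KeyError):
    """A required input table is missing."""


@dataclass
class AcsEstimate:
    """A survey estimate with its 90% margin of error."""

    value: float
    moe: float = 0.0


def coefficient_of_variation(est: AcsEstimate) -> float:
    """Standard error (moe / 1.645) over the estimate."""
    if est.value == 0:
        raise UndefinedMetricError("CV undefined for a zero estimate")
    return (est.moe / MOE_Z) / est.value


def aggregate_moe(moes: list[float]) -> float:
    """Aggregate margins of error in the L2 norm (sqrt of sum of squares)."""
    return float(np.sqrt(np.sum(np.square(np.asarray(moes, dtype=float)))))


def interpolation_matrix() -> np.ndarray:
    """The fixed 11x11 averaging matrix over yearly populations 2009..2019.

    Row 0 selects the 2010 decennial year.  Rows 1-4 are the five-year
    windows ending 2010..2013 clipped to the 2009 start (widths 2..5);
    rows 5-10 are the full-width rolling five-year averages ending
    2014..2019.
    """
    A = np.zeros((11, 11))
    A[0, 1] = 1.0
    for k, width in enumerate((2, 3, 4, 5), start=1):
        A[k, :width] = 1.0 / width
    for k, start in enumerate(range(1, 7), start=5):
        A[k, start : start + 5] = 1.0 / 5.0
    return A


_A = interpolation_matrix()


def interpolate_yearly_populations(b: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the non-negative least-squares system for one CBG.

    ``b`` stacks (decennial 2010, ACS five-year windows ending 2010..2019).
    Returns (x, residual) with x the populations for 2009..2019.
    """
    b = np.asarray(b, dtype=float)
    if b.shape != (11,):
        raise ValueError("b must be an 11-vector")
    x, res = nnls(_A, b)
    return x, float(res)


def interpolate_population_table(decennial: pd.Series, acs5: pd.DataFrame) -> pd.DataFrame:
    """Interpolate yearly populations for every CBG.

    ``decennial``: value per CBG id.  ``acs5``: columns (area_id, year,
    value) with year the window-end label (2010..2019).  Returns a frame
    indexed by CBG id with one column per year 2009..2019.
    """
    wide = acs5.pivot_table(index="area_id", columns="year", values="value")
    missing = [y for y in ACS5_WINDOW_END_YEARS if y not in wide.columns]
    if missing:
        raise ConfigurationError(f"acs5 table missing window-end years {missing}")
    out = {}
    for cbg in decennial.index:
        if cbg not in wide.index:
            raise ConfigurationError(f"acs5 table missing CBG {cbg}")
        b = np.concatenate(([decennial.loc[cbg]], wide.loc[cbg, list(ACS5_WINDOW_END_YEARS)]))
        x, _ = interpolate_yearly_populations(b)
        out[cbg] = x
    return pd.DataFrame.from_dict(out, orient="index", columns=list(INTERP_YEARS)).sort_index()


# ---------------------------------------------------------------------------
# Components-of-change bookkeeping
# ---------------------------------------------------------------------------

def adjust_population_for_components(
    pop_t: float, births: float, deaths: float, net_international: float,
    warnings: list[str] | None = None, label: str = "",
) -> float:
    """Strip natural increase and net international migration from a year-t
    population so it describes people already resident in year t-1."""
    adjusted = pop_t - (births - deaths) - net_international
    if adjusted < 0:
        msg = f"adjusted population negative ({adjusted:.3f}) for {label}; floored at 0"
        logger.warning(msg)
        if warnings is not None:
            warnings.append(msg)
        adjusted = 0.0
    return adjusted


def estimate_emigrants(immigrants: float, net_international: float,
                       warnings: list[str] | None = None, label: str = "") -> float:
    """Emigrants = immigrants - net international migration, floored at 0."""
    emig = immigrants - net_international
    if emig < 0:
        msg = f"estimated emigrants negative ({emig:.3f}) for {label}; floored at 0"
        logger.warning(msg)
        if warnings is not None:
            warnings.append(msg)
        emig = 0.0
    return emig


def add_attrition_to_diagonal_targets(
    nonmovers: pd.Series, deaths: pd.Series, emigrants: pd.Series,
    within_state_flows: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series | None]:
    """Add deaths and emigrants back into the non-mover (diagonal) targets.

    People who died or left the country are recorded in the matrix as
    non-movers in their last state of residence, so the census non-mover
    counts R (and the within-state flow targets F_rr, when given) must be
    raised accordingly.  Applied independently per state.
    """
    deaths = deaths.reindex(nonmovers.index, fill_value=0.0)
    emigrants = emigrants.reindex(nonmovers.index, fill_value=0.0)
    r_adj = nonmovers + deaths + emigrants
    f_adj = None
    if within_state_flows is not None:
        f_adj = within_state_flows.copy()
        for state in nonmovers.index:
            key = (state, state)
            if key in f_adj.index:
                f_adj.loc[key] = f_adj.loc[key] + deaths.loc[state] + emigrants.loc[state]
    return r_adj, f_adj


# ---------------------------------------------------------------------------
# Constraint-set assembly
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Everything the harmonization stages need for one matrix year t."""

    year: int
    cbg_pop_prev: pd.Series  # yearly CBG populations at t-1 (row targets)
    state_pop: pd.Series  # S_k^(t)
    state_nonmovers: pd.Series  # R_k^(t), attrition-adjusted
    state_movers: pd.Series  # S - R_adj - immigrants, floored at 0
    state_flows: pd.Series  # MultiIndex (origin, dest), F_rr attrition-adjusted
    county_pop_prev: pd.Series  # P_c^(t-1)
    county_pop_cur: pd.Series  # P_c^(t), components-adjusted
    warnings: list[str] = field(default_factory=list)


REQUIRED_TABLES = ("cbg_decennial", "cbg_acs5", "state_movers", "state_flows", "county_pop")


def build_constraint_set(tables: dict[str, pd.DataFrame], t: int) -> ConstraintSet:
    """Assemble and adjust all constraints for matrix year ``t``.

    ``tables`` keys (all CSV-shaped frames):

    - cbg_decennial: (area_id, value) 2010 decennial CBG populations
    - cbg_acs5: (area_id, year, value[, moe]) five-year windows by end year
    - state_movers: (area_id, year, population, nonmovers)
    - state_flows: (origin, dest, year, value)
    - county_pop: (area_id, year, value)
    - components_state / components_county (optional):
      (area_id, year, births, deaths, net_international, immigrants);
      absent tables mean a closed population (all components zero).
    """
    for name in REQUIRED_TABLES:
        if name not in tables:
            raise ConfigurationError(f"required table {name!r} missing")
    warnings: list[str] = []

    decennial = tables["cbg_decennial"].set_index("area_id")["value"]
    decennial.index = decennial.index.astype(str)
    acs5 = tables["cbg_acs5"].copy()
    acs5["area_id"] = acs5["area_id"].astype(str)
    yearly = interpolate_population_table(decennial, acs5)
    if t - 1 not in yearly.columns:
        raise ConfigurationError(f"year {t - 1} outside the interpolation span")
    cbg_pop_prev = yearly[t - 1]

    sm = tables["state_movers"]
    sm = sm[sm["year"] == t].set_index(sm.loc[sm["year"] == t, "area_id"].astype(str))
    if sm.empty:
        raise ConfigurationError(f"state_movers has no rows for year {t}")
    S = sm["population"].astype(float)
    R = sm["nonmovers"].astype(float)

    fl = tables["state_flows"]
    fl = fl[fl["year"] == t]
    if fl.empty:
        raise ConfigurationError(f"state_flows has no rows for year {t}")
    F = fl.set_index([fl["origin"].astype(str), fl["dest"].astype(str)])["value"].astype(float)
    F.index.names = ["origin", "dest"]

    comp_s = tables.get("components_state")
    if comp_s is not None and not (comp_s := comp_s[comp_s["year"] == t]).empty:
        comp_s = comp_s.set_index(comp_s["area_id"].astype(str))
        births = comp_s["births"].astype(float).reindex(S.index, fill_value=0.0)
        deaths = comp_s["deaths"].astype(float).reindex(S.index, fill_value=0.0)
        net_intl = comp_s["net_international"].astype(float).reindex(S.index, fill_value=0.0)
        immigrants = comp_s["immigrants"].astype(float).reindex(S.index, fill_value=0.0)
    else:
        zeros = pd.Series(0.0, index=S.index)
        births = deaths = net_intl = immigrants = zeros

    emigrants = pd.Series(
        [estimate_emigrants(immigrants.loc[k], net_intl.loc[k], warnings, f"state {k}")
         for k in S.index],
        index=S.index,
    )
    R_adj, F_adj = add_attrition_to_diagonal_targets(R, deaths, emigrants, F)
    # Mover target: people in s at t who had a US residence elsewhere at t-1.
    # Immigrants arrived during year t and are outside the matrix universe.
    raw_movers = S - R_adj - immigrants
    movers = raw_movers.clip(lower=0.0)
    for k in raw_movers.index[raw_movers < 0]:
        warnings.append(f"state {k}: mover target S-R negative; floored at 0")

    cp = tables["county_pop"]
    prev = cp[cp["year"] == t - 1]
    cur = cp[cp["year"] == t]
    if prev.empty or cur.empty:
        raise ConfigurationError(f"county_pop missing year {t - 1} or {t}")
    P_prev = prev.set_index(prev["area_id"].astype(str))["value"].astype(float)
    P_cur = cur.set_index(cur["area_id"].astype(str))["value"].astype(float)

    comp_c = tables.get("components_county")
    if comp_c is not None and not (comp_c := comp_c[comp_c["year"] == t]).empty:
        comp_c = comp_c.set_index(comp_c["area_id"].astype(str))
        P_cur = pd.Series(
            [adjust_population_for_components(
                P_cur.loc[c],
                float(comp_c["births"].get(c, 0.0)),
                float(comp_c["deaths"].get(c, 0.0)),
                float(comp_c["net_international"].get(c, 0.0)),
                warnings, f"county {c}")
             for c in P_cur.index],
            index=P_cur.index,
        )

    tot_prev, tot_cur = float(P_prev.sum()), float(P_cur.sum())
    if tot_prev > 0 and abs(tot_cur - tot_prev) > FEASIBILITY_RTOL * tot_prev:
        warnings.append(
            f"county totals inconsistent after adjustment: sum P(t)={tot_cur:.3f} "
            f"vs sum P(t-1)={tot_prev:.3f}"
        )

    # Destination-total consistency of flows vs populations (checked, not
    # enforced): summing F over origins -- the r = s block holding the
    # non-movers and attrition -- should recover the state column total
    # S + deaths + emigrants.
    F_eff = F_adj if F_adj is not None else F
    inflow_by_dest = F_eff.groupby(level="dest").sum().reindex(S.index, fill_value=0.0)
    expected = S + deaths + emigrants
    rel = np.abs(inflow_by_dest - expected) / expected.clip(lower=1.0)
    for k in expected.index[rel > 0.05]:
        warnings.append(
            f"state {k}: total flow into state deviates from S + attrition by "
            f"{rel.loc[k]:.1%}"
        )

    return ConstraintSet(
        year=t,
        cbg_pop_prev=cbg_pop_prev,
        state_pop=S,
        state_nonmovers=R_adj,
        state_movers=movers,
        state_flows=F_adj if F_adj is not None else F,
        county_pop_prev=P_prev,
        county_pop_cur=P_cur,
        warnings=warnings,
    )
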