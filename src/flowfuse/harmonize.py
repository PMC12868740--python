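"""Sequential rescaling and sparse block IPF of a migration matrix.

A raw origin-destination matrix E over block groups is reconciled with
coarse census constraints by four multiplicative stages, applied in order:

1. each row is scaled so its sum matches the interpolated year-(t-1)
   population of the origin block group;
2. the diagonal entries within each state are scaled to the state's
   non-mover count R, and the off-diagonal entries landing in each state to
   the state's mover count S - R;
3. every (origin state, destination state) block is scaled to the
   state-to-state flow F_rs, the diagonal belonging to the r = s block;
4. blocks of columns and rows grouped by county are alternately scaled to
   the county populations in years t and t-1 (iterative proportional
   fitting), the only stage iterated to convergence -- the earlier, noisier
   targets are matched once and not revisited.

All stages obey the zero-preservation rule: entries are never scaled to
match a zero target, zero entries never become nonzero, and blocks with a
positive target but no support are reported as unmet rather than densified.
Every stage works on the coordinate (COO) representation grouped by id
prefix, so cost per pass is linear in the number of stored entries and no
dense n_cbg**2 structure is ever materialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .constraints import ConstraintSet
from .geography import LEVEL_WIDTHS, MigrationMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAX_ITER = 6000
DEFAULT_STAGE_ORDER = ("rows", "state_nonmovers", "state_movers", "state_flows", "county_ipf")
IPF_FEASIBILITY_RTOL = 1e-6


@dataclass
class ScalingReport:
    stage: str
    factors: dict = field(default_factory=dict)  # target id -> factor applied
    skipped: dict = field(default_factory=dict)  # target id -> reason
    pre_deviation: float = float("nan")  # max relative deviation before
    post_deviation: float = float("nan")  # ... and after, over scaled targets
    extras: dict = field(default_factory=dict)


@dataclass
class IpfState:
    n: int
    l1_delta: float
    max_marginal_deviation: float


def _coo(E: MigrationMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = sparse.coo_array(E.matrix)
    return c.row.copy(), c.col.copy(), c.data.astype(float).copy()


def _rebuild(E: MigrationMatrix, row, col, data) -> MigrationMatrix:
    n = len(E.index)
    mat = sparse.coo_array((data, (row, col)), shape=(n, n)).tocsr()
    mat.eliminate_zeros()
    return MigrationMatrix(sparse.csr_array(mat), E.index, E.year)


def _prefix_codes(index: np.ndarray, level: str) -> tuple[np.ndarray, np.ndarray]:
    """Integer code per cbg for its ancestor at ``level``; also the id list."""
    width = LEVEL_WIDTHS[level]
    prefixes = np.array([u[:width] for u in index], dtype=object)
    uniq, codes = np.unique(prefixes, return_inverse=True)
    return codes, uniq


def _group_factors(
    sums: np.ndarray, uniq: np.ndarray, targets: pd.Series, report: ScalingReport
) -> np.ndarray:
    """Per-group multiplicative factors honoring the zero-preservation rule."""
    factors = np.ones(len(uniq))
    for g, gid in enumerate(uniq):
        target = float(targets.get(gid, np.nan))
        if np.isnan(target):
            report.skipped[gid] = "no target"
        elif target == 0:
            report.skipped[gid] = "zero target (not scaled to zero)"
        elif sums[g] == 0:
            report.skipped[gid] = "zero support for positive target (unmet)"
        else:
            factors[g] = target / sums[g]
            report.factors[gid] = factors[g]
    return factors


def _deviation(sums: np.ndarray, uniq: np.ndarray, targets: pd.Series,
               scaled_only: dict) -> float:
    devs = [
        abs(sums[g] - targets[gid]) / targets[gid]
        for g, gid in enumerate(uniq)
        if gid in scaled_only
    ]
    return max(devs) if devs else 0.0


# ---------------------------------------------------------------------------
# One-shot stages
# ---------------------------------------------------------------------------

def scale_rows_to_populations(E: MigrationMatrix, cbg_pop_prev: pd.Series
                              ) -> tuple[MigrationMatrix, ScalingReport]:
    """Scale each row so its sum matches the origin-year CBG population."""
    report = ScalingReport("rows")
    row, col, data = _coo(E)
    sums = np.bincount(row, weights=data, minlength=len(E.index))
    factors = np.ones(len(E.index))
    for i, cbg in enumerate(E.index):
        target = float(cbg_pop_prev.get(cbg, np.nan))
        if np.isnan(target):
            report.skipped[cbg] = "no target"
        elif target == 0:
            report.skipped[cbg] = "zero target (not scaled to zero)"
        elif sums[i] == 0:
            if target > 0:
                report.skipped[cbg] = "zero support for positive target (unmet)"
        else:
            factors[i] = target / sums[i]
            report.factors[cbg] = factors[i]
    report.pre_deviation = _deviation(sums, E.index, cbg_pop_prev, report.factors)
    data = data * factors[row]
    out = _rebuild(E, row, col, data)
    new_sums = np.bincount(row, weights=data, minlength=len(E.index))
    report.post_deviation = _deviation(new_sums, E.index, cbg_pop_prev, report.factors)
    return out, report


def scale_state_nonmovers(E: MigrationMatrix, R: pd.Series
                          ) -> tuple[MigrationMatrix, ScalingReport]:
    """Scale within-state diagonal mass to the state non-mover counts."""
    report = ScalingReport("state_nonmovers")
    row, col, data = _coo(E)
    codes, uniq = _prefix_codes(E.index, "state")
    diag = row == col
    sums = np.bincount(codes[row[diag]], weights=data[diag], minlength=len(uniq))
    factors = _group_factors(sums, uniq, R, report)
    report.pre_deviation = _deviation(sums, uniq, R, report.factors)
    data[diag] *= factors[codes[row[diag]]]
    out = _rebuild(E, row, col, data)
    new = np.bincount(codes[row[diag]], weights=data[diag], minlength=len(uniq))
    report.post_deviation = _deviation(new, uniq, R, report.factors)
    return out, report


def scale_state_movers(E: MigrationMatrix, S: pd.Series, R: pd.Series,
                       movers: pd.Series | None = None
                       ) -> tuple[MigrationMatrix, ScalingReport]:
    """Scale off-diagonal inflow into each state to its mover count.

    The target is ``movers`` when given (already adjusted upstream),
    otherwise S - R floored at zero (a negative difference triggers the
    skip rule with a warning).
    """
    report = ScalingReport("state_movers")
    if movers is None:
        movers = S - R.reindex(S.index, fill_value=0.0)
        for k in movers.index[movers < 0]:
            logger.warning("state %s: S < R; mover target floored at 0", k)
            movers.loc[k] = 0.0
    row, col, data = _coo(E)
    codes, uniq = _prefix_codes(E.index, "state")
    off = row != col
    sums = np.bincount(codes[col[off]], weights=data[off], minlength=len(uniq))
    factors = _group_factors(sums, uniq, movers, report)
    report.pre_deviation = _deviation(sums, uniq, movers, report.factors)
    data[off] *= factors[codes[col[off]]]
    out = _rebuild(E, row, col, data)
    new = np.bincount(codes[col[off]], weights=data[off], minlength=len(uniq))
    report.post_deviation = _deviation(new, uniq, movers, report.factors)
    return out, report


def scale_state_flows(E: MigrationMatrix, F: pd.Series
                      ) -> tuple[MigrationMatrix, ScalingReport]:
    """Scale every (origin state, destination state) block to the flow F_rs.

    Diagonal entries belong to their (r, r) block.  Blocks whose census flow
    is zero are left untouched.
    """
    report = ScalingReport("state_flows")
    row, col, data = _coo(E)
    codes, uniq = _prefix_codes(E.index, "state")
    ns = len(uniq)
    pair = codes[row] * ns + codes[col]
    sums = np.bincount(pair, weights=data, minlength=ns * ns)
    targets = {(str(o), str(d)): float(v) for (o, d), v in F.items()}
    factors = np.ones(ns * ns)
    pre_devs, scaled_keys = [], []
    for r in range(ns):
        for s in range(ns):
            key = (uniq[r], uniq[s])
            flat = r * ns + s
            if key not in targets:
                report.skipped[key] = "no target"
            elif targets[key] == 0:
                report.skipped[key] = "zero target (not scaled to zero)"
            elif sums[flat] == 0:
                report.skipped[key] = "zero support for positive target (unmet)"
            else:
                factors[flat] = targets[key] / sums[flat]
                report.factors[key] = factors[flat]
                pre_devs.append(abs(sums[flat] - targets[key]) / targets[key])
                scaled_keys.append((flat, targets[key]))
    report.pre_deviation = max(pre_devs) if pre_devs else 0.0
    data *= factors[pair]
    out = _rebuild(E, row, col, data)
    new = np.bincount(pair, weights=data, minlength=ns * ns)
    post = [abs(new[flat] - t) / t for flat, t in scaled_keys]
    report.post_deviation = max(post) if post else 0.0
    return out, report


# ---------------------------------------------------------------------------
# Block IPF to county populations
# ---------------------------------------------------------------------------

def ipf_to_county_populations(
    E: MigrationMatrix,
    P_prev: pd.Series,
    P_cur: pd.Series,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float | None = None,
) -> tuple[MigrationMatrix, list[IpfState]]:
    """Alternately scale county column blocks to P^(t) and row blocks to
    P^(t-1) until the L1 change between successive iterates falls below
    ``tol`` (default 1e-9 of the total mass) or ``max_iter`` iterations.

    Odd iterations scale column blocks, even iterations row blocks.
    Convergence is checked after each even iteration (one full cycle).
    Requires nationally consistent targets: sum P^(t) == sum P^(t-1) within
    1e-6 relative.
    """
    tot_prev, tot_cur = float(P_prev.sum()), float(P_cur.sum())
    if tot_prev <= 0 or abs(tot_cur - tot_prev) > IPF_FEASIBILITY_RTOL * tot_prev:
        raise ValueError(
            f"infeasible county targets: sum P(t)={tot_cur} vs sum P(t-1)={tot_prev}"
        )
    row, col, data = _coo(E)
    codes, uniq = _prefix_codes(E.index, "county")
    nc = len(uniq)
    prev = P_prev.reindex(uniq).to_numpy(float)
    cur = P_cur.reindex(uniq).to_numpy(float)
    if np.isnan(prev).any() or np.isnan(cur).any():
        raise ValueError("county population targets missing for some counties")

    tol = (1e-9 * data.sum()) if tol is None else tol
    row_codes = codes[row]
    col_codes = codes[col]
    history: list[IpfState] = []

    def marginal_dev(d: np.ndarray) -> float:
        col_sums = np.bincount(col_codes, weights=d, minlength=nc)
        row_sums = np.bincount(row_codes, weights=d, minlength=nc)
        devs = []
        for sums, targ in ((col_sums, cur), (row_sums, prev)):
            ok = (targ > 0) & (sums > 0)
            if ok.any():
                devs.append(np.max(np.abs(sums[ok] - targ[ok]) / targ[ok]))
        return max(devs) if devs else 0.0

    cycle_delta = 0.0
    for n in range(1, max_iter + 1):
        old = data
        if n % 2 == 1:  # column blocks to year-t county populations
            sums = np.bincount(col_codes, weights=data, minlength=nc)
            factors = np.where((cur > 0) & (sums > 0), np.divide(
                cur, np.where(sums > 0, sums, 1.0)), 1.0)
            data = data * factors[col_codes]
        else:  # row blocks to year-(t-1) county populations
            sums = np.bincount(row_codes, weights=data, minlength=nc)
            factors = np.where((prev > 0) & (sums > 0), np.divide(
                prev, np.where(sums > 0, sums, 1.0)), 1.0)
            data = data * factors[row_codes]
        l1 = float(np.abs(data - old).sum())
        history.append(IpfState(n, l1, marginal_dev(data)))
        cycle_delta += l1
        if n % 2 == 0:
            if cycle_delta < tol:
                break
            cycle_delta = 0.0

    return _rebuild(E, row, col, data), history


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class HarmonizeConfig:
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    max_iter: int = DEFAULT_MAX_ITER
    tol: float | None = None  # None -> 1e-9 * total mass


def harmonize_pipeline(
    E: MigrationMatrix, constraints: ConstraintSet, config: HarmonizeConfig | None = None
) -> tuple[MigrationMatrix, list[ScalingReport]]:
    """Apply all harmonization stages in the configured order.

    Default order: row populations, state non-movers, state movers, state
    flows, county IPF.  Deterministic; returns the final matrix and one
    report per stage (the IPF report carries the iteration trace in
    ``extras['history']``).
    """
    config = config or HarmonizeConfig()
    reports: list[ScalingReport] = []
    current = E
    for stage in config.stage_order:
        if stage == "rows":
            current, rep = scale_rows_to_populations(current, constraints.cbg_pop_prev)
        elif stage == "state_nonmovers":
            current, rep = scale_state_nonmovers(current, constraints.state_nonmovers)
        elif stage == "state_movers":
            current, rep = scale_state_movers(
                current, constraints.state_pop, constraints.state_nonmovers,
                movers=constraints.state_movers,
            )
        elif stage == "state_flows":
            current, rep = scale_state_flows(current, constraints.state_flows)
        elif stage == "county_ipf":
            current, history = ipf_to_county_populations(
                current, constraints.county_pop_prev, constraints.county_pop_cur,
                max_iter=config.max_iter, tol=config.tol,
            )
            rep = ScalingReport("county_ipf")
            rep.extras["history"] = history
            rep.extras["iterations"] = len(history)
            rep.post_deviation = history[-1].max_marginal_deviation if history else 0.0
            rep.pre_deviation = history[0].max_marginal_deviation if history else 0.0
        else:
            raise ValueError(f"unknown harmonization stage {stage!r}")
        reports.append(rep)
    return current, reports


def dense_ipf(matrix: np.ndarray, row_targets: np.ndarray, col_targets: np.ndarray,
              max_iter: int = DEFAULT_MAX_ITER, tol: float = 1e-12) -> np.ndarray:
    """Textbook dense IPF on a small matrix (used as an independent check)."""
    m = matrix.astype(float).copy()
    for _ in range(max_iter):
        old = m.copy()
        cs = m.sum(axis=0)
        np.divide(col_targets, cs, out=cs, where=cs > 0)
        cs[~(cs > 0)] = 1.0
        m *= cs[None, :]
        rs = m.sum(axis=1)
        np.divide(row_targets, rs, out=rs, where=rs > 0)
        rs[~(rs > 0)] = 1.0
        m *= rs[:, None]
        if np.abs(m - old).sum() < tol:
            break
    return m
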