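"""Four-level geographic hierarchy and address-to-block-group mapping.

US census geography nests block groups (CBGs) inside tracts inside counties
inside states, with containment encoded in the FIPS-style digit prefix of the
unit id (widths 2/5/11/12).  This module models that hierarchy, reconciles
inter-decennial boundary merges, builds the probabilistic mapping matrix G
from addresses to CBGs (one-hot for geocoded addresses, a residential-share /
population-weighted distribution for ZIP-level addresses), and collapses an
address-level flow matrix A to the CBG-level migration matrix

    E = G' (A - diag A) G + diag(G' diag A)

where the first term routes movers and the second keeps stayer mass on the
diagonal regardless of how uncertain the address location is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .histories import AddressFlowMatrix, month_index

logger = logging.getLogger(__name__)

LEVELS = ("state", "county", "tract", "cbg")
LEVEL_WIDTHS = {"state": 2, "county": 5, "tract": 11, "cbg": 12}
PARENT_LEVEL = {"county": "state", "tract": "county", "cbg": "tract"}

# The 2010 US geography universe the method targets: block groups grouped
# into counties and states (50 states plus DC).  An annual origin-destination
# matrix over this universe has n_cbg**2 ordered pairs of cells.
N_CBGS_2010 = 217_740
N_COUNTIES_2010 = 3_142
N_STATES = 51


def ordered_pair_count(n_units: int) -> int:
    """Number of ordered origin-destination pairs over ``n_units`` areas."""
    return n_units * n_units


def granularity_ratio(n_fine: int, n_coarse: int) -> float:
    """How many fine-level cells correspond to one coarse-level cell."""
    return ordered_pair_count(n_fine) / ordered_pair_count(n_coarse)


class GeographyError(ValueError):
    """Structural problem in the geographic hierarchy."""


class UnmappableAddressError(KeyError):
    """An address cannot be assigned to any census unit."""


def parent_id(unit_id: str, level: str) -> str:
    """Prefix-truncate a unit id to its parent level's width."""
    return unit_id[: LEVEL_WIDTHS[level]]


@dataclass
class GeographyHierarchy:
    """Units table (id, level, population, lat, lon[, moe]) plus merge map.

    The merge map is a table (year, old_id, new_id) recording boundary
    changes resolved by keeping only the coarser boundary.
    """

    units: pd.DataFrame
    merge_map: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["year", "old_id", "new_id"])
    )

    def __post_init__(self) -> None:
        self.units = self.units.copy()
        self.units["id"] = self.units["id"].astype(str)
        self.units = self.units.sort_values(["level", "id"]).reset_index(drop=True)

    def validate(self) -> None:
        ids_by_level = {lv: set(self.level(lv)["id"]) for lv in LEVELS}
        for lv in LEVELS:
            width = LEVEL_WIDTHS[lv]
            for uid in ids_by_level[lv]:
                if len(uid) != width or not uid.isdigit():
                    raise GeographyError(f"{lv} id {uid!r} is not {width} digits")
                if lv != "state":
                    par = parent_id(uid, PARENT_LEVEL[lv])
                    if par not in ids_by_level[PARENT_LEVEL[lv]]:
                        raise GeographyError(f"{lv} {uid}: parent {par} missing")
        # populations aggregate upward when both levels carry them
        for child, parent in PARENT_LEVEL.items():
            cdf, pdf = self.level(child), self.level(parent)
            if cdf.empty or pdf.empty:
                continue
            sums = cdf.groupby(cdf["id"].str[: LEVEL_WIDTHS[parent]])["population"].sum()
            joined = pdf.set_index("id")["population"].to_frame("pop").join(sums.rename("child"))
            bad = joined.dropna().query("abs(pop - child) > 1e-6 * (pop + 1)")
            if not bad.empty:
                raise GeographyError(
                    f"populations do not aggregate from {child} to {parent}: {bad.index[0]}"
                )
        for row in self.merge_map.itertuples(index=False):
            if str(row.new_id) not in {u for s in ids_by_level.values() for u in s}:
                raise GeographyError(f"merge target {row.new_id} not a known unit")

    def level(self, level: str) -> pd.DataFrame:
        return self.units[self.units["level"] == level]

    @property
    def cbg_ids(self) -> np.ndarray:
        return self.level("cbg")["id"].to_numpy(dtype=object)

    def populations(self, level: str) -> pd.Series:
        df = self.level(level)
        return pd.Series(df["population"].to_numpy(float), index=df["id"].to_numpy(object))

    def centroids(self, level: str = "cbg") -> pd.DataFrame:
        df = self.level(level)
        return df.set_index("id")[["lat", "lon"]].astype(float)


def apply_merge_map(hierarchy: GeographyHierarchy, year: int) -> GeographyHierarchy:
    """Resolve boundary changes for ``year`` by keeping the coarser unit.

    Retired units are removed and their populations, population-weighted
    centroids and (when present) L2-aggregated margins of error folded into
    the surviving unit.  A merge whose survivor sits at a coarser level must
    be a prefix of the retired id; a same-level merge must share the parent
    prefix -- anything else breaks containment and raises.
    """
    merges = hierarchy.merge_map[hierarchy.merge_map["year"] == year]
    if merges.empty:
        return GeographyHierarchy(hierarchy.units, hierarchy.merge_map)

    units = hierarchy.units.set_index("id", drop=False)
    for row in merges.itertuples(index=False):
        old, new = str(row.old_id), str(row.new_id)
        if old not in units.index:
            raise GeographyError(f"merge source {old} not present")
        if new not in units.index:
            raise GeographyError(f"merge target {new} not present")
        lv_old, lv_new = units.at[old, "level"], units.at[new, "level"]
        w_old, w_new = LEVEL_WIDTHS[lv_old], LEVEL_WIDTHS[lv_new]
        if w_new > w_old:
            raise GeographyError(f"merge {old}->{new} goes to a finer level")
        if w_new < w_old and not old.startswith(new):
            raise GeographyError(f"merge {old}->{new} breaks prefix containment")
        if w_new == w_old and lv_old != "state":
            pw = LEVEL_WIDTHS[PARENT_LEVEL[lv_old]]
            if old[:pw] != new[:pw]:
                raise GeographyError(f"merge {old}->{new} crosses parent boundaries")

        p_old = float(units.at[old, "population"])
        p_new = float(units.at[new, "population"])
        total = p_old + p_new
        for coord in ("lat", "lon"):
            if coord in units.columns and total > 0:
                units.at[new, coord] = (
                    p_old * float(units.at[old, coord]) + p_new * float(units.at[new, coord])
                ) / total
        units.at[new, "population"] = total
        if "moe" in units.columns:
            m_old = float(units.at[old, "moe"]) if pd.notna(units.at[old, "moe"]) else 0.0
            m_new = float(units.at[new, "moe"]) if pd.notna(units.at[new, "moe"]) else 0.0
            units.at[new, "moe"] = float(np.hypot(m_old, m_new))
        units = units.drop(index=old)

    remaining = hierarchy.merge_map[hierarchy.merge_map["year"] != year]
    return GeographyHierarchy(units.reset_index(drop=True), remaining)


# ---------------------------------------------------------------------------
# ZIP fallback and the mapping matrix
# ---------------------------------------------------------------------------

def zip_fallback_distribution(
    zip_code: str,
    crosswalk: pd.DataFrame,
    last_seen_month: tuple[int, int],
    hierarchy: GeographyHierarchy,
) -> dict[str, float]:
    """Distribute an address known only by ZIP code over CBGs.

    Uses the crosswalk snapshot dated nearest to the month the address was
    last seen (earlier snapshot wins ties).  Tract weight is proportional to
    the snapshot's residential share; within a tract, CBG weight is
    proportional to the CBG's share of the tract population (uniform if the
    tract population is zero).  The result sums to 1.

    ``crosswalk`` columns: snapshot_date ('YYYY-MM'), zip, tract,
    residential_share.
    """
    rows = crosswalk[crosswalk["zip"].astype(str) == str(zip_code)]
    if rows.empty:
        raise UnmappableAddressError(f"ZIP {zip_code} absent from all crosswalk snapshots")
    target = month_index(*last_seen_month)
    snap_idx = rows["snapshot_date"].map(lambda s: month_index(int(s[:4]), int(s[5:7])))
    dist_to_target = (snap_idx - target).abs()
    best = snap_idx[dist_to_target == dist_to_target.min()].min()
    rows = rows[snap_idx == best]

    shares = rows.groupby(rows["tract"].astype(str))["residential_share"].sum()
    total_share = shares.sum()
    if total_share <= 0:
        shares = pd.Series(1.0, index=shares.index)
        total_share = shares.sum()
    cbg_pop = hierarchy.populations("cbg")
    out: dict[str, float] = {}
    for tract, share in shares.items():
        members = cbg_pop[cbg_pop.index.str.startswith(tract)]
        if members.empty:
            continue
        tract_pop = members.sum()
        if tract_pop > 0:
            inner = members / tract_pop
        else:
            inner = pd.Series(1.0 / len(members), index=members.index)
        for cbg, w in inner.items():
            out[cbg] = out.get(cbg, 0.0) + (share / total_share) * w
    if not out:
        raise UnmappableAddressError(f"ZIP {zip_code}: no CBGs under its tracts")
    norm = sum(out.values())
    return {c: v / norm for c, v in sorted(out.items())}


@dataclass
class MappingReport:
    """Funnel accounting of how addresses were (or were not) mapped."""

    counts_by_kind: dict[str, int]
    mapped_by_kind: dict[str, int]
    n_unmappable: int
    n_territory: int

    @property
    def match_rates(self) -> dict[str, float]:
        return {
            k: (self.mapped_by_kind.get(k, 0) / n if n else 0.0)
            for k, n in self.counts_by_kind.items()
        }

    @property
    def overall_match_rate(self) -> float:
        total = sum(self.counts_by_kind.values())
        mapped = sum(self.mapped_by_kind.values())
        return mapped / total if total else 0.0


@dataclass
class MappingMatrix:
    """Row-stochastic sparse address-by-CBG matrix (the mapping G)."""

    matrix: sparse.csr_array
    address_index: np.ndarray
    cbg_index: np.ndarray
    report: MappingReport | None = None

    def validate(self) -> None:
        if self.matrix.nnz:
            data = self.matrix.data
            if (data < 0).any() or (data > 1 + 1e-12).any():
                raise ValueError("mapping entries must lie in [0, 1]")
            rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
            if not np.allclose(rowsum, 1.0, atol=1e-9):
                raise ValueError("each retained mapping row must sum to 1")


def build_mapping_matrix(
    geocoded_table: pd.DataFrame,
    zip_fallback_results: dict[str, dict[str, float] | None],
    hierarchy: GeographyHierarchy,
) -> MappingMatrix:
    """Assemble the mapping matrix G from geocode results and ZIP fallbacks.

    ``geocoded_table`` columns: address_id, kind, cbg (NaN when not geocoded
    to a CBG).  ``zip_fallback_results`` maps address ids to a CBG
    distribution, or None for addresses whose ZIP could not be resolved.
    Territory and unmappable addresses are excluded from the matrix and
    tallied in the report.
    """
    cbg_ids = hierarchy.cbg_ids
    cbg_pos = {c: k for k, c in enumerate(cbg_ids)}

    counts: dict[str, int] = {}
    mapped: dict[str, int] = {}
    n_unmappable = 0
    n_territory = 0
    assignments: dict[str, dict[str, float]] = {}

    for row in geocoded_table.itertuples(index=False):
        aid, kind = str(row.address_id), str(row.kind)
        counts[kind] = counts.get(kind, 0) + 1
        if kind == "territory":
            n_territory += 1
            continue
        dist: dict[str, float] | None = None
        if pd.notna(row.cbg):
            dist = {str(row.cbg): 1.0}
        elif aid in zip_fallback_results:
            dist = zip_fallback_results[aid]
        if dist is None:
            n_unmappable += 1
            logger.info("address %s unmappable; dropped", aid)
            continue
        if aid in assignments and assignments[aid] != dist:
            raise ValueError(f"address {aid} has conflicting assignments")
        assignments[aid] = dist
        mapped[kind] = mapped.get(kind, 0) + 1

    address_index = np.array(sorted(assignments), dtype=object)
    rows, cols, data = [], [], []
    for i, aid in enumerate(address_index):
        for cbg, p in assignments[aid].items():
            if cbg not in cbg_pos:
                raise GeographyError(f"address {aid} mapped to unknown CBG {cbg}")
            rows.append(i)
            cols.append(cbg_pos[cbg])
            data.append(p)
    mat = sparse.coo_array(
        (np.array(data, float), (np.array(rows, int), np.array(cols, int))),
        shape=(len(address_index), len(cbg_ids)),
    ).tocsr()
    report = MappingReport(counts, mapped, n_unmappable, n_territory)
    out = MappingMatrix(mat, address_index, np.asarray(cbg_ids, dtype=object), report)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Migration matrices and the address-level collapse
# ---------------------------------------------------------------------------

@dataclass
class MigrationMatrix:
    """Sparse non-negative square matrix of expected person flows over CBGs.

    Entry (i, j) is the expected number of people residing in CBG i in year
    t-1 and CBG j in year t; the diagonal holds non-movers (including deaths
    and emigrants by convention).
    """

    matrix: sparse.csr_array
    index: np.ndarray  # cbg ids, sorted; rows == columns
    year: int

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=object)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("migration matrix must be square")
        if self.matrix.shape[0] != len(self.index):
            raise ValueError("index length must match matrix dimension")

    def total(self) -> float:
        return float(self.matrix.sum())

    def copy(self) -> "MigrationMatrix":
        return MigrationMatrix(self.matrix.copy(), self.index.copy(), self.year)


def collapse_to_cbg(A: AddressFlowMatrix, G: MappingMatrix, year: int | None = None) -> MigrationMatrix:
    """Collapse an address-level flow matrix to CBG level through G.

    Computes ``G' (A - diag A) G + diag(G' diag A)``: mover mass is spread
    over the origin-row/destination-row product of CBG probabilities, while
    stayer mass is distributed along the diagonal only, so an uncertainly
    located stayer never manufactures an apparent move between CBGs.
    Addresses absent from G's rows are dropped (their mass is excluded).
    """
    if A.matrix.shape[0] != A.matrix.shape[1]:
        raise ValueError("address flow matrix must be square")
    a_pos = {a: k for k, a in enumerate(A.index)}
    keep = [a for a in G.address_index if a in a_pos]
    g_pos = {a: k for k, a in enumerate(G.address_index)}
    rows_a = np.array([a_pos[a] for a in keep], dtype=int)
    rows_g = np.array([g_pos[a] for a in keep], dtype=int)
    if len(keep) == 0:
        n = len(G.cbg_index)
        return MigrationMatrix(sparse.csr_array((n, n)), G.cbg_index, year or A.year)

    Asub = A.matrix[rows_a][:, rows_a].tocsr()
    if Asub.nnz and Asub.data.min() < 0:
        raise ValueError("address flow matrix must be non-negative")
    Gsub = G.matrix[rows_g].tocsr()

    diag = Asub.diagonal()
    movers = Asub - sparse.diags_array(diag, format="csr")
    E = (Gsub.T @ movers @ Gsub).tocsr()
    stay = Gsub.T @ diag  # vector over cbgs
    E = E + sparse.diags_array(np.asarray(stay).ravel(), format="csr")
    E.eliminate_zeros()
    return MigrationMatrix(sparse.csr_array(E), G.cbg_index, year if year is not None else A.year)


# ---------------------------------------------------------------------------
# MatrixMarket + index-file exchange format
# ---------------------------------------------------------------------------

def write_matrix(matrix: sparse.sparray, index: np.ndarray, mtx_path: str | Path,
                 index_path: str | Path | None = None) -> None:
    """Write a sparse matrix as MatrixMarket plus a one-column id index file."""
    mtx_path = Path(mtx_path)
    mmwrite(mtx_path, sparse.coo_matrix(matrix))
    if index_path is None:
        index_path = mtx_path.with_suffix(".index.txt")
    Path(index_path).write_text("\n".join(str(i) for i in index) + "\n")


def read_matrix(mtx_path: str | Path, index_path: str | Path | None = None
                ) -> tuple[sparse.csr_array, np.ndarray]:
    mtx_path = Path(mtx_path)
    if index_path is None:
        index_path = mtx_path.with_suffix(".index.txt")
    mat = sparse.csr_array(sparse.coo_array(mmread(mtx_path)))
    index = np.array(Path(index_path).read_text().split(), dtype=object)
    if mat.shape[0] != len(index) and mat.shape[1] != len(index):
        raise ValueError("index file length does not match matrix dimensions")
    return mat, index


def hierarchy_from_tables(units_path: str | Path, merge_path: str | Path | None = None
                          ) -> GeographyHierarchy:
    """Load a hierarchy from a units CSV (id, level, population, lat, lon)."""
    units = pd.read_csv(units_path, dtype={"id": str})
    merge = (
        pd.read_csv(merge_path, dtype={"old_id": str, "new_id": str})
        if merge_path is not None
        else pd.DataFrame(columns=["year", "old_id", "new_id"])
    )
    h = GeographyHierarchy(units, merge)
    h.validate()
    return h
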