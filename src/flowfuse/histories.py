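"""Clean individual address histories and simulate survey responses.

Raw longitudinal address data lists, for each person, the addresses at which
they were observed, the month each address first became effective, and a
listed start/end date for the person as a whole.  These dates are mutually
inconsistent in messy data, so we first *reconcile* them into an interval of
activity, then build a monthly probability distribution over addresses for
every month of that interval, and finally simulate the one-year-ago residence
question of a rolling annual survey ("Where did this person live 1 year
ago?") to obtain, for each year, a distribution over (origin address,
destination address) pairs per person.  Summing those distributions over the
population yields the annual address-to-address flow matrix A^(t).

Months are represented internally as integer indices ``year*12 + month - 1``
so that interval arithmetic is plain integer arithmetic.  The module is fully
deterministic: no randomness enters at any point.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

# Address kinds mirroring the funnel used when classifying raw records.
ADDRESS_KINDS = ("street", "po_box", "rural_route", "incomplete", "territory")

# PO boxes are dropped when a non-PO-box record is effective within a year:
# at month resolution this is an inclusive |delta| <= 12 months.
PO_BOX_WINDOW_MONTHS = 12

# Activity intervals pad the reconciled span by one year on both sides so
# edge years are not discarded and terminal addresses persist (which also
# encodes deaths/emigrants as diagonal non-movers downstream).
ACTIVITY_PAD_MONTHS = 12


def month_index(year: int, month: int) -> int:
    """Map a (year, month) pair to a monotone integer month index."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return year * 12 + (month - 1)


def index_to_ym(idx: int) -> tuple[int, int]:
    return idx // 12, idx % 12 + 1


def parse_ym(text: str) -> tuple[int, int]:
    """Parse a 'YYYY-MM' string."""
    y, m = text.split("-")
    return int(y), int(m)


class HistoryError(ValueError):
    """A person's records cannot be processed (e.g., no usable dates)."""


@dataclass
class AddressRecord:
    address_id: str
    effective: tuple[int, int] | None  # (year, month) or None when missing
    kind: str = "street"

    def __post_init__(self) -> None:
        if self.kind not in ADDRESS_KINDS:
            raise ValueError(f"unknown address kind: {self.kind!r}")

    @property
    def effective_index(self) -> int | None:
        return None if self.effective is None else month_index(*self.effective)


@dataclass
class IndividualHistory:
    """One person's records plus everything derived from them.

    ``monthly_residence`` is stored as piecewise-constant segments
    ``(start_month, end_month_exclusive, {address_id: probability})`` covering
    the activity interval with no gaps; each distribution sums to 1.
    """

    person_id: str
    records: list[AddressRecord]
    listed_start: tuple[int, int] | None = None
    listed_end: tuple[int, int] | None = None
    # derived
    reconciled_start: int | None = None  # month indices
    reconciled_end: int | None = None
    activity_start: int | None = None
    activity_end: int | None = None  # inclusive
    segments: list[tuple[int, int, dict[str, float]]] = field(default_factory=list)

    def residence(self, month: int) -> dict[str, float] | None:
        """Distribution over addresses for one month, or None outside activity."""
        for lo, hi, dist in self.segments:
            if lo <= month < hi:
                return dist
        return None


@dataclass
class AddressFlowMatrix:
    """Square sparse matrix of expected survey responses between addresses."""

    matrix: sparse.csr_array
    index: np.ndarray  # address ids, sorted, rows == columns
    year: int

    def total(self) -> float:
        return float(self.matrix.sum())


# ---------------------------------------------------------------------------
# Interval reconciliation and record cleaning
# ---------------------------------------------------------------------------

def reconcile_interval(person: IndividualHistory) -> tuple[int, int, tuple[int, int]]:
    """Resolve listed vs effective dates into a reconciled span.

    The reconciled start is the minimum of the first effective date and the
    listed start date; the reconciled end the maximum of the last effective
    date and the listed end date.  The activity interval pads both ends by
    twelve months.  Results are written back onto ``person`` and returned as
    ``(reconciled_start, reconciled_end, (activity_start, activity_end))`` in
    month indices (activity end inclusive).
    """
    effective = [r.effective_index for r in person.records if r.effective is not None]
    candidates_start = list(effective)
    candidates_end = list(effective)
    if person.listed_start is not None:
        candidates_start.append(month_index(*person.listed_start))
    if person.listed_end is not None:
        candidates_end.append(month_index(*person.listed_end))
    if not candidates_start or not candidates_end:
        raise HistoryError(f"person {person.person_id}: no dates at all")
    rs = min(candidates_start)
    re_ = max(candidates_end)
    person.reconciled_start = rs
    person.reconciled_end = re_
    person.activity_start = rs - ACTIVITY_PAD_MONTHS
    person.activity_end = re_ + ACTIVITY_PAD_MONTHS
    return rs, re_, (person.activity_start, person.activity_end)


def clean_records(person: IndividualHistory) -> list[AddressRecord]:
    """Apply the record-level filtering rules.

    Territory addresses are discarded.  Records lacking an effective date are
    discarded unless they are the person's only address, in which case the
    reconciled start date becomes their effective date.  PO-box records are
    discarded whenever some non-PO-box record's effective date lies within
    twelve months.  The surviving list is written to ``person.records`` and
    returned; an empty survivor set raises :class:`HistoryError`.
    """
    if person.reconciled_start is None:
        raise HistoryError("reconcile_interval must run before clean_records")

    records = [r for r in person.records if r.kind != "territory"]

    if len(records) == 1 and records[0].effective is None:
        only = records[0]
        only.effective = index_to_ym(person.reconciled_start)
        records = [only]
    else:
        records = [r for r in records if r.effective is not None]

    dated_non_po = [r.effective_index for r in records if r.kind != "po_box"]
    kept: list[AddressRecord] = []
    for r in records:
        if r.kind == "po_box" and any(
            abs(r.effective_index - e) <= PO_BOX_WINDOW_MONTHS for e in dated_non_po
        ):
            continue
        kept.append(r)

    if not kept:
        raise HistoryError(f"person {person.person_id}: all records dropped")
    person.records = kept
    return kept


def monthly_residence(person: IndividualHistory) -> list[tuple[int, int, dict[str, float]]]:
    """Forward-fill cleaned records into monthly residence distributions.

    Each address spans from its effective date to the next distinct effective
    date.  Records sharing an effective date split probability uniformly and
    the split persists until the next effective date.  Months of the activity
    interval before the first effective date take the first distribution,
    months after the last take the last.  Segments are clipped to the
    activity interval and written back onto ``person``.
    """
    if person.activity_start is None:
        raise HistoryError("reconcile_interval must run before monthly_residence")
    dated = sorted(person.records, key=lambda r: r.effective_index)
    if not dated:
        raise HistoryError(f"person {person.person_id}: no dated records")

    # group records by effective month
    groups: list[tuple[int, list[str]]] = []
    for r in dated:
        e = r.effective_index
        if groups and groups[-1][0] == e:
            groups[-1][1].append(r.address_id)
        else:
            groups.append((e, [r.address_id]))

    a0, a1 = person.activity_start, person.activity_end
    bounds = [a0] + [e for e, _ in groups[1:]] + [a1 + 1]
    segments: list[tuple[int, int, dict[str, float]]] = []
    for (lo, hi), (_, addrs) in zip(zip(bounds[:-1], bounds[1:]), groups):
        lo = max(lo, a0)
        hi = min(hi, a1 + 1)
        if lo >= hi:
            continue
        p = 1.0 / len(addrs)
        dist = {a: p for a in sorted(set(addrs))}
        if len(dist) < len(addrs):  # duplicated address id at same date
            dist = {a: 1.0 / len(dist) for a in dist}
        segments.append((lo, hi, dist))
    person.segments = segments
    return segments


def process_person(person: IndividualHistory) -> IndividualHistory:
    """Run reconcile, clean and monthly-residence steps in order."""
    reconcile_interval(person)
    clean_records(person)
    monthly_residence(person)
    return person


# ---------------------------------------------------------------------------
# Survey-response simulation
# ---------------------------------------------------------------------------

def _days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1]


def simulate_acs_year(person: IndividualHistory, t: int) -> list[tuple[str, str, float]]:
    """Simulate the one-year-ago residence question for survey year ``t``.

    For each month m of year t falling inside the activity interval (and
    whose counterpart month of year t-1 is also covered), the response pairs
    the month-m distribution of year t-1 (origin) with that of year t
    (destination).  Identical distributions denote permanence and contribute
    diagonal triples (a, a, p_a); otherwise the outer product of the two
    distributions is emitted.  Months are weighted by their day count in year
    t over the total day count of the contributing months, so the output sums
    to 1 for any person covering at least one month.
    """
    if not person.segments:
        raise HistoryError("monthly_residence must run before simulate_acs_year")
    months = []
    for m in range(1, 13):
        cur = month_index(t, m)
        prev = cur - 12
        if person.activity_start <= prev and cur <= person.activity_end:
            months.append(m)
    if not months:
        return []
    weights = np.array([_days_in_month(t, m) for m in months], dtype=float)
    weights /= weights.sum()

    acc: dict[tuple[str, str], float] = {}
    for m, w in zip(months, weights):
        cur = person.residence(month_index(t, m))
        prev = person.residence(month_index(t, m) - 12)
        if prev == cur:  # permanence: no move reported
            for a, p in prev.items():
                key = (a, a)
                acc[key] = acc.get(key, 0.0) + w * p
        else:
            for a, pa in prev.items():
                for b, pb in cur.items():
                    key = (a, b)
                    acc[key] = acc.get(key, 0.0) + w * pa * pb
    return [(i, j, p) for (i, j), p in sorted(acc.items())]


def aggregate_flows(persons: list[IndividualHistory], t: int) -> AddressFlowMatrix:
    """Sum per-person survey responses into the year-``t`` flow matrix A^(t)."""
    acc: dict[tuple[str, str], float] = {}
    for person in persons:
        for i, j, p in simulate_acs_year(person, t):
            acc[(i, j)] = acc.get((i, j), 0.0) + p
    ids = sorted({a for pair in acc for a in pair})
    index = np.array(ids, dtype=object)
    pos = {a: k for k, a in enumerate(ids)}
    n = len(ids)
    if acc:
        rows = np.fromiter((pos[i] for i, _ in acc), dtype=np.int64, count=len(acc))
        cols = np.fromiter((pos[j] for _, j in acc), dtype=np.int64, count=len(acc))
        data = np.fromiter(acc.values(), dtype=float, count=len(acc))
        mat = sparse.coo_array((data, (rows, cols)), shape=(n, n)).tocsr()
    else:
        mat = sparse.csr_array((0, 0))
    return AddressFlowMatrix(matrix=mat, index=index, year=t)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def histories_from_table(df: pd.DataFrame) -> tuple[list[IndividualHistory], list[str]]:
    """Build processed histories from a records table.

    Expected columns: person_id, address_id, effective_year, effective_month
    (nullable), kind, listed_start, listed_end ('YYYY-MM' strings, nullable).
    Returns the successfully processed histories and a list of logged
    rejection reasons for persons that could not be processed.
    """
    persons: list[IndividualHistory] = []
    rejected: list[str] = []
    for pid, grp in df.groupby("person_id", sort=True):
        records = []
        for row in grp.itertuples(index=False):
            ey, em = row.effective_year, row.effective_month
            eff = None
            if pd.notna(ey) and pd.notna(em):
                eff = (int(ey), int(em))
            records.append(AddressRecord(str(row.address_id), eff, str(row.kind)))
        first = grp.iloc[0]
        ls = parse_ym(first["listed_start"]) if pd.notna(first["listed_start"]) else None
        le = parse_ym(first["listed_end"]) if pd.notna(first["listed_end"]) else None
        person = IndividualHistory(str(pid), records, ls, le)
        try:
            process_person(person)
        except HistoryError as exc:
            rejected.append(str(exc))
            logger.info("dropping person %s: %s", pid, exc)
            continue
        persons.append(person)
    return persons, rejected
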