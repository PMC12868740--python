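import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from flowfuse.geography import GeographyHierarchy, MigrationMatrix


def make_hierarchy(cbgs, merge_map=None):
    """Build a validated hierarchy from (cbg_id, population, lat, lon) rows,
    synthesizing all parent levels by prefix aggregation."""
    df = pd.DataFrame(cbgs, columns=["id", "population", "lat", "lon"])
    df["level"] = "cbg"
    frames = [df]
    for level, width in (("tract", 11), ("county", 5), ("state", 2)):
        g = df.copy()
        g["pid"] = g["id"].str[:width]
        agg = g.groupby("pid").apply(
            lambda x: pd.Series({
                "population": x["population"].sum(),
                "lat": np.average(x["lat"], weights=np.maximum(x["population"], 1)),
                "lon": np.average(x["lon"], weights=np.maximum(x["population"], 1)),
            }),
            include_groups=False,
        ).reset_index(names="id")
        agg["level"] = level
        frames.append(agg)
    units = pd.concat(frames, ignore_index=True)[["id", "level", "population", "lat", "lon"]]
    mm = merge_map if merge_map is not None else pd.DataFrame(
        columns=["year", "old_id", "new_id"])
    h = GeographyHierarchy(units, mm)
    h.validate()
    return h


def matrix_from_dense(dense, index, year=2015):
    mat = sparse.csr_array(sparse.coo_array(np.asarray(dense, dtype=float)))
    mat.eliminate_zeros()
    return MigrationMatrix(mat, np.asarray(index, dtype=object), year)


@pytest.fixture
def two_state_hierarchy():
    """Two states x one county x one tract x two cbgs each (4 cbgs)."""
    return make_hierarchy([
        ("010010000011", 600, 30.0, -100.0),
        ("010010000012", 400, 30.1, -100.1),
        ("020010000011", 500, 31.0, -99.0),
        ("020010000012", 500, 31.1, -99.1),
    ])


@pytest.fixture
def four_county_hierarchy():
    """Two states x two counties x one tract x two cbgs (8 cbgs)."""
    rows = []
    for s in (1, 2):
        for c in (1, 2):
            for b in (1, 2):
                cid = f"{s:02d}{c:03d}{1:06d}{b:d}"
                rows.append((cid, 100 * s + 10 * c + b,
                             30 + s * 0.5 + c * 0.1 + b * 0.02,
                             -100 + s * 0.5 + c * 0.1 + b * 0.02))
    return make_hierarchy(rows)
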