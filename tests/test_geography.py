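"""Hierarchy handling, ZIP fallback mapping, and the flow collapse."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from conftest import make_hierarchy, matrix_from_dense
from flowfuse.geography import (
    GeographyError,
    MappingMatrix,
    UnmappableAddressError,
    apply_merge_map,
    build_mapping_matrix,
    collapse_to_cbg,
    granularity_ratio,
    ordered_pair_count,
    read_matrix,
    write_matrix,
    zip_fallback_distribution,
)
from flowfuse.histories import AddressFlowMatrix


def flow_matrix(dense, index, year=2015):
    mat = sparse.csr_array(sparse.coo_array(np.asarray(dense, float)))
    return AddressFlowMatrix(mat, np.asarray(index, dtype=object), year)


def mapping(dense, addresses, cbgs):
    mat = sparse.csr_array(sparse.coo_array(np.asarray(dense, float)))
    return MappingMatrix(mat, np.asarray(addresses, dtype=object),
                         np.asarray(cbgs, dtype=object))


class TestMergeMap:
    def base(self, merge_map):
        return make_hierarchy(
            [
                ("010010000011", 300, 30.0, -100.0),
                ("010010000021", 200, 30.2, -100.2),
            ],
            merge_map=merge_map,
        )

    def test_populations_add(self):
        mm = pd.DataFrame([(2012, "01001000002", "01001000001")],
                          columns=["year", "old_id", "new_id"])
        h = self.base(mm)
        merged = apply_merge_map(h, 2012)
        tracts = merged.level("tract")
        assert tracts["id"].tolist() == ["01001000001"]
        assert tracts["population"].iloc[0] == 500
        # population-weighted centroid
        assert tracts["lat"].iloc[0] == pytest.approx((300 * 30.0 + 200 * 30.2) / 500)

    def test_empty_merge_map_is_identity(self):
        h = self.base(None)
        merged = apply_merge_map(h, 2012)
        pd.testing.assert_frame_equal(
            merged.units.reset_index(drop=True), h.units.reset_index(drop=True))

    def test_missing_target_errors(self):
        mm = pd.DataFrame([(2012, "01001000002", "01001000009")],
                          columns=["year", "old_id", "new_id"])
        with pytest.raises(GeographyError):
            apply_merge_map(self.base(mm), 2012)

    def test_cross_parent_merge_errors(self):
        h = make_hierarchy(
            [("010010000011", 300, 30.0, -100.0), ("020010000011", 200, 31.0, -99.0)],
            merge_map=pd.DataFrame([(2012, "01001000001", "02001000001")],
                                   columns=["year", "old_id", "new_id"]),
        )
        with pytest.raises(GeographyError):
            apply_merge_map(h, 2012)

    def test_moe_aggregates_in_l2(self):
        mm = pd.DataFrame([(2012, "01001000002", "01001000001")],
                          columns=["year", "old_id", "new_id"])
        h = self.base(mm)
        h.units["moe"] = 0.0
        h.units.loc[h.units["id"] == "01001000001", "moe"] = 3.0
        h.units.loc[h.units["id"] == "01001000002", "moe"] = 4.0
        merged = apply_merge_map(h, 2012)
        row = merged.units[merged.units["id"] == "01001000001"]
        assert row["moe"].iloc[0] == pytest.approx(5.0)


class TestZipFallback:
    def test_population_shares_within_single_tract(self, two_state_hierarchy):
        cw = pd.DataFrame([("2015-06", "99901", "01001000001", 1.0)],
                          columns=["snapshot_date", "zip", "tract", "residential_share"])
        dist = zip_fallback_distribution("99901", cw, (2015, 6), two_state_hierarchy)
        assert dist == pytest.approx({"010010000011": 0.6, "010010000012": 0.4})

    def test_residential_shares_across_tracts(self, two_state_hierarchy):
        cw = pd.DataFrame(
            [("2015-06", "99902", "01001000001", 0.7),
             ("2015-06", "99902", "02001000001", 0.3)],
            columns=["snapshot_date", "zip", "tract", "residential_share"])
        dist = zip_fallback_distribution("99902", cw, (2015, 6), two_state_hierarchy)
        assert sum(dist.values()) == pytest.approx(1.0)
        tract1 = sum(v for k, v in dist.items() if k.startswith("01001000001"))
        assert tract1 == pytest.approx(0.7)

    def test_nearest_snapshot_selected(self, two_state_hierarchy):
        cw = pd.DataFrame(
            [("2014-12", "99903", "01001000001", 1.0),
             ("2012-12", "99903", "02001000001", 1.0)],
            columns=["snapshot_date", "zip", "tract", "residential_share"])
        # last seen 2015-06: 6 months vs 30 months
        dist = zip_fallback_distribution("99903", cw, (2015, 6), two_state_hierarchy)
        assert all(k.startswith("01001000001") for k in dist)

    def test_unknown_zip_raises(self, two_state_hierarchy):
        cw = pd.DataFrame(columns=["snapshot_date", "zip", "tract", "residential_share"])
        with pytest.raises(UnmappableAddressError):
            zip_fallback_distribution("00000", cw, (2015, 6), two_state_hierarchy)


class TestBuildMappingMatrix:
    def test_one_hot_and_fallback_rows(self, two_state_hierarchy):
        table = pd.DataFrame(
            [("a1", "street", "010010000011"),
             ("a2", "street", "010010000012"),
             ("a3", "street", "020010000011"),
             ("z1", "incomplete", None)],
            columns=["address_id", "kind", "cbg"])
        zres = {"z1": {"010010000011": 0.6, "010010000012": 0.4}}
        G = build_mapping_matrix(table, zres, two_state_hierarchy)
        assert G.matrix.shape == (4, 4)
        rowsums = np.asarray(G.matrix.sum(axis=1)).ravel()
        assert rowsums == pytest.approx(np.ones(4))
        dense = G.matrix.toarray()
        one_hot_rows = (dense == 1.0).sum(axis=1)
        assert sorted(one_hot_rows) == [0, 1, 1, 1]

    def test_all_unmappable_gives_empty_matrix(self, two_state_hierarchy):
        table = pd.DataFrame([("z1", "incomplete", None)],
                             columns=["address_id", "kind", "cbg"])
        G = build_mapping_matrix(table, {"z1": None}, two_state_hierarchy)
        assert G.matrix.shape[0] == 0
        assert G.report.overall_match_rate == 0.0

    def test_report_mirrors_funnel_categories(self, two_state_hierarchy):
        table = pd.DataFrame(
            [("a1", "street", "010010000011"),
             ("p1", "po_box", None),
             ("r1", "rural_route", None),
             ("i1", "incomplete", None),
             ("t1", "territory", None)],
            columns=["address_id", "kind", "cbg"])
        zres = {"p1": {"010010000011": 1.0}, "r1": None, "i1": {"010010000012": 1.0}}
        G = build_mapping_matrix(table, zres, two_state_hierarchy)
        rep = G.report
        assert set(rep.counts_by_kind) == {"street", "po_box", "rural_route",
                                           "incomplete", "territory"}
        assert rep.n_territory == 1
        assert rep.n_unmappable == 1
        assert rep.match_rates["street"] == 1.0
        assert rep.match_rates["rural_route"] == 0.0

    def test_conflicting_duplicate_errors(self, two_state_hierarchy):
        table = pd.DataFrame(
            [("a1", "street", "010010000011"), ("a1", "street", "010010000012")],
            columns=["address_id", "kind", "cbg"])
        with pytest.raises(ValueError, match="conflicting"):
            build_mapping_matrix(table, {}, two_state_hierarchy)


class TestCollapse:
    CBGS = ["c1", "c2"]

    def test_identity_mapping_preserves_matrix(self):
        A = flow_matrix([[5, 2], [1, 3]], ["a1", "a2"])
        G = mapping(np.eye(2), ["a1", "a2"], self.CBGS)
        E = collapse_to_cbg(A, G)
        assert E.matrix.toarray() == pytest.approx(np.array([[5.0, 2], [1, 3]]))

    def test_uncertain_stayer_stays_on_diagonal(self):
        A = flow_matrix([[1.0]], ["a1"])
        G = mapping([[0.6, 0.4]], ["a1"], self.CBGS)
        E = collapse_to_cbg(A, G)
        assert E.matrix.toarray() == pytest.approx(np.array([[0.6, 0.0], [0.0, 0.4]]))

    def test_uncertain_mover_outer_product(self):
        A = flow_matrix([[0, 1], [0, 0]], ["a1", "a2"])
        G = mapping([[0.5, 0.5], [0.5, 0.5]], ["a1", "a2"], self.CBGS)
        E = collapse_to_cbg(A, G)
        assert E.matrix.toarray() == pytest.approx(np.full((2, 2), 0.25))

    def test_unmapped_addresses_dropped_mass_conserved_on_rest(self):
        A = flow_matrix([[1, 0, 0], [0, 2, 0], [0, 0, 4]], ["a1", "a2", "a3"])
        G = mapping(np.eye(2), ["a1", "a2"], self.CBGS)  # a3 not mapped
        E = collapse_to_cbg(A, G)
        assert E.total() == pytest.approx(3.0)

    def test_brute_force_oracle_on_random_instances(self):
        """G'(A - diag A)G + diag(G' diag A) via an explicit triple loop."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            na, nc = 6, 4
            A = rng.random((na, na)) * (rng.random((na, na)) < 0.5)
            G = rng.random((na, nc)) * (rng.random((na, nc)) < 0.7)
            G[G.sum(axis=1) == 0, 0] = 1.0
            G /= G.sum(axis=1, keepdims=True)
            expected = np.zeros((nc, nc))
            for i in range(na):
                for j in range(na):
                    for a in range(nc):
                        if i == j:
                            expected[a, a] += G[i, a] * A[i, i]
                        else:
                            for b in range(nc):
                                expected[a, b] += G[i, a] * A[i, j] * G[j, b]
            addrs = [f"a{k}" for k in range(na)]
            cbgs = [f"c{k}" for k in range(nc)]
            E = collapse_to_cbg(flow_matrix(A, addrs), mapping(G, addrs, cbgs))
            assert E.matrix.toarray() == pytest.approx(expected, abs=1e-10)
            assert E.total() == pytest.approx(A.sum(), rel=1e-8)


def test_matrix_round_trip(tmp_path):
    mat = sparse.csr_array(sparse.coo_array(np.array([[1.5, 0.0], [0.0, 2.0]])))
    write_matrix(mat, np.array(["c1", "c2"], dtype=object), tmp_path / "m.mtx")
    back, index = read_matrix(tmp_path / "m.mtx")
    assert index.tolist() == ["c1", "c2"]
    assert back.toarray() == pytest.approx(mat.toarray())


def test_pair_universe_arithmetic():
    assert ordered_pair_count(3) == 9
    assert granularity_ratio(6, 2) == 9.0
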