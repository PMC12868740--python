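"""Sequential scalings and sparse block IPF."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from conftest import matrix_from_dense
from flowfuse.harmonize import (
    HarmonizeConfig,
    dense_ipf,
    harmonize_pipeline,
    ipf_to_county_populations,
    scale_rows_to_populations,
    scale_state_flows,
    scale_state_movers,
    scale_state_nonmovers,
)

CBGS4 = ["010010000011", "010010000012", "020010000011", "020010000012"]


def county_sums(E, axis):
    coo = sparse.coo_array(E.matrix)
    county = np.array([u[:5] for u in E.index], dtype=object)
    uniq, codes = np.unique(county, return_inverse=True)
    which = codes[coo.col] if axis == "col" else codes[coo.row]
    return pd.Series(np.bincount(which, weights=coo.data, minlength=len(uniq)), index=uniq)


class TestRowScaling:
    def test_row_doubled(self):
        E = matrix_from_dense([[30, 20, 0, 0]] + [[0] * 4] * 3, CBGS4)
        pops = pd.Series({CBGS4[0]: 100.0})
        out, rep = scale_rows_to_populations(E, pops)
        assert out.matrix.toarray()[0] == pytest.approx([60, 40, 0, 0])
        assert rep.factors[CBGS4[0]] == pytest.approx(2.0)

    def test_matching_target_identity(self):
        E = matrix_from_dense(np.diag([10.0, 20, 30, 40]), CBGS4)
        pops = pd.Series([10.0, 20, 30, 40], index=CBGS4)
        out, rep = scale_rows_to_populations(E, pops)
        assert (out.matrix != E.matrix).nnz == 0
        assert rep.post_deviation < 1e-12

    def test_zero_target_row_untouched(self):
        E = matrix_from_dense(np.diag([10.0, 20, 30, 40]), CBGS4)
        pops = pd.Series([0.0, 20, 30, 40], index=CBGS4)
        out, rep = scale_rows_to_populations(E, pops)
        assert out.matrix.toarray()[0, 0] == 10.0  # never scaled to zero
        assert CBGS4[0] in rep.skipped


class TestStateDiagonalScaling:
    def test_diagonal_doubled(self):
        E = matrix_from_dense(np.diag([30.0, 20, 0, 0]), CBGS4)
        out, _ = scale_state_nonmovers(E, pd.Series({"01": 100.0}))
        assert out.matrix.diagonal()[:2] == pytest.approx([60, 40])

    def test_two_states_scaled_independently(self):
        E = matrix_from_dense(np.diag([30.0, 20, 10, 40]), CBGS4)
        R = pd.Series({"01": 100.0, "02": 25.0})
        out, rep = scale_state_nonmovers(E, R)
        d = out.matrix.diagonal()
        assert d[0] + d[1] == pytest.approx(100.0)
        assert d[2] + d[3] == pytest.approx(25.0)
        assert rep.factors["01"] == pytest.approx(2.0)
        assert rep.factors["02"] == pytest.approx(0.5)
        # off-diagonal untouched (none present)
        assert rep.post_deviation < 1e-12


class TestStateMoverScaling:
    def test_inflow_tripled(self):
        dense = np.zeros((4, 4))
        dense[0, 2] = 6.0  # into state 02
        dense[1, 3] = 4.0
        dense[2, 2] = 50.0  # diagonal not touched
        E = matrix_from_dense(dense, CBGS4)
        S = pd.Series({"01": 0.0, "02": 80.0})
        R = pd.Series({"01": 0.0, "02": 50.0})
        out, rep = scale_state_movers(E, S, R)
        arr = out.matrix.toarray()
        assert arr[0, 2] == pytest.approx(18.0)
        assert arr[1, 3] == pytest.approx(12.0)
        assert arr[2, 2] == pytest.approx(50.0)
        assert rep.factors["02"] == pytest.approx(3.0)

    def test_negative_target_floored_and_skipped(self):
        dense = np.zeros((4, 4))
        dense[0, 2] = 6.0
        E = matrix_from_dense(dense, CBGS4)
        out, rep = scale_state_movers(E, pd.Series({"02": 40.0}), pd.Series({"02": 50.0}))
        assert out.matrix.toarray()[0, 2] == pytest.approx(6.0)
        assert "02" in rep.skipped

    def test_positive_target_without_support_reported(self):
        E = matrix_from_dense(np.diag([1.0, 1, 1, 1]), CBGS4)
        _, rep = scale_state_movers(E, pd.Series({"02": 80.0}), pd.Series({"02": 50.0}))
        assert rep.skipped["02"].startswith("zero support")


class TestStateFlowScaling:
    def test_block_doubled_and_diagonal_joint(self):
        dense = np.array([
            [5.0, 2, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 3, 1],
            [2, 0, 1, 3],
        ])
        E = matrix_from_dense(dense, CBGS4)
        F = pd.Series({("01", "01"): 18.0, ("01", "02"): 4.0,
                       ("02", "01"): 3.0, ("02", "02"): 8.0})
        F.index = pd.MultiIndex.from_tuples(F.index, names=["origin", "dest"])
        out, rep = scale_state_flows(E, F)
        arr = out.matrix.toarray()
        # (01,01) block (incl. diagonal) sums 9 -> 18: factor 2
        assert arr[:2, :2].sum() == pytest.approx(18.0)
        assert arr[0, 0] == pytest.approx(10.0)
        assert arr[:2, 2:].sum() == pytest.approx(4.0)
        assert arr[2:, :2].sum() == pytest.approx(3.0)
        assert arr[2:, 2:].sum() == pytest.approx(8.0)
        assert rep.post_deviation < 1e-12

    def test_zero_flow_block_untouched(self):
        dense = np.zeros((4, 4))
        dense[0, 2] = 5.0
        E = matrix_from_dense(dense, CBGS4)
        F = pd.Series({("01", "02"): 0.0})
        F.index = pd.MultiIndex.from_tuples(F.index, names=["origin", "dest"])
        out, rep = scale_state_flows(E, F)
        assert out.matrix.toarray()[0, 2] == pytest.approx(5.0)
        assert rep.skipped[("01", "02")].startswith("zero target")


class TestIpf:
    def test_already_satisfied_converges_in_two_iterations(self):
        E = matrix_from_dense(np.diag([10.0, 20, 30, 40]), CBGS4)
        P_prev = pd.Series({"01001": 30.0, "02001": 70.0})
        out, history = ipf_to_county_populations(E, P_prev, P_prev)
        assert len(history) == 2
        assert all(h.l1_delta < 1e-12 for h in history)
        assert (out.matrix != E.matrix).nnz == 0

    def test_infeasible_totals_error_before_iterating(self):
        E = matrix_from_dense(np.diag([10.0, 20, 30, 40]), CBGS4)
        with pytest.raises(ValueError, match="infeasible"):
            ipf_to_county_populations(
                E, pd.Series({"01001": 30.0, "02001": 70.0}),
                pd.Series({"01001": 60.0, "02001": 70.0}))

    def test_zeros_stay_zero(self):
        rng = np.random.default_rng(0)
        dense = rng.random((4, 4)) * (rng.random((4, 4)) < 0.6)
        dense[0, 0] = 1.0  # ensure support in each county block
        dense[2, 2] = 1.0
        E = matrix_from_dense(dense, CBGS4)
        P_prev = county_sums(E, "row") * 1.0
        P_cur = county_sums(E, "col")
        P_cur = P_cur * (P_prev.sum() / P_cur.sum())
        out, _ = ipf_to_county_populations(E, P_prev, P_cur, tol=1e-12)
        before = set(zip(*sparse.coo_array(E.matrix).coords))
        after = set(zip(*sparse.coo_array(out.matrix).coords))
        assert after <= before

    def test_marginals_met_on_feasible_toy(self):
        rng = np.random.default_rng(1)
        dense = rng.random((4, 4)) + 0.1  # full support
        E = matrix_from_dense(dense, CBGS4)
        ref = rng.random((4, 4)) + 0.1
        Eref = matrix_from_dense(ref, CBGS4)
        P_prev = county_sums(Eref, "row")
        P_cur = county_sums(Eref, "col")
        P_cur *= P_prev.sum() / P_cur.sum()
        out, history = ipf_to_county_populations(E, P_prev, P_cur, tol=1e-10)
        got_cur = county_sums(out, "col")
        got_prev = county_sums(out, "row")
        assert got_cur.to_numpy() == pytest.approx(P_cur.to_numpy(), rel=1e-6)
        assert got_prev.to_numpy() == pytest.approx(P_prev.to_numpy(), rel=1e-6)
        assert history[-1].max_marginal_deviation < 1e-6

    def test_block_ipf_matches_dense_ipf_on_county_aggregate(self):
        rng = np.random.default_rng(2)
        dense = rng.random((4, 4)) + 0.05
        E = matrix_from_dense(dense, CBGS4)
        P_prev = pd.Series({"01001": 40.0, "02001": 60.0})
        P_cur = pd.Series({"01001": 55.0, "02001": 45.0})
        out, _ = ipf_to_county_populations(E, P_prev, P_cur, tol=1e-14)
        agg0 = np.array([[dense[:2, :2].sum(), dense[:2, 2:].sum()],
                         [dense[2:, :2].sum(), dense[2:, 2:].sum()]])
        oracle = dense_ipf(agg0, np.array([40.0, 60.0]), np.array([55.0, 45.0]),
                           tol=1e-14)
        arr = out.matrix.toarray()
        agg = np.array([[arr[:2, :2].sum(), arr[:2, 2:].sum()],
                        [arr[2:, :2].sum(), arr[2:, 2:].sum()]])
        assert agg == pytest.approx(oracle, abs=1e-8)


def truth_constraints(seed=11):
    from flowfuse.constraints import build_constraint_set
    from flowfuse.synthetic import SyntheticConfig, derive_constraints, generate_truth

    cfg = SyntheticConfig(seed=seed)
    truth = generate_truth(cfg)
    cset = build_constraint_set(derive_constraints(truth, cfg), 2015)
    return truth, cset


class TestPipeline:
    def test_truth_is_fixed_point(self):
        truth, cset = truth_constraints()
        E = truth.flows[2015]
        out, reports = harmonize_pipeline(E, cset)
        diff = abs(out.matrix - E.matrix)
        assert (diff.max() if diff.nnz else 0.0) < 1e-6
        for rep in reports:
            assert rep.post_deviation < 1e-6

    def test_scale_invariance(self):
        truth, cset = truth_constraints()
        E = truth.flows[2015]
        E_scaled = matrix_from_dense(E.matrix.toarray() * 7.3, E.index)
        out1, _ = harmonize_pipeline(E, cset)
        out2, _ = harmonize_pipeline(E_scaled, cset)
        diff = abs(out1.matrix - out2.matrix)
        assert (diff.max() if diff.nnz else 0.0) < 1e-8

    def test_support_never_grows_and_nonnegative(self):
        truth, cset = truth_constraints()
        rng = np.random.default_rng(3)
        dense = truth.flows[2015].matrix.toarray()
        dense *= rng.uniform(0.3, 1.8, size=dense.shape)
        E = matrix_from_dense(dense, truth.flows[2015].index)
        out, _ = harmonize_pipeline(E, cset)
        before = set(zip(*sparse.coo_array(E.matrix).coords))
        after = set(zip(*sparse.coo_array(out.matrix).coords))
        assert after <= before
        assert out.matrix.nnz == 0 or out.matrix.data.min() >= 0

    def test_stage_order_changes_result(self):
        truth, cset = truth_constraints()
        rng = np.random.default_rng(4)
        dense = truth.flows[2015].matrix.toarray()
        dense *= rng.uniform(0.3, 1.8, size=dense.shape)
        E = matrix_from_dense(dense, truth.flows[2015].index)
        out1, _ = harmonize_pipeline(E, cset)
        reordered = HarmonizeConfig(stage_order=(
            "state_flows", "state_movers", "state_nonmovers", "rows", "county_ipf"))
        out2, _ = harmonize_pipeline(E, cset, reordered)
        diff = abs(out1.matrix - out2.matrix)
        assert (diff.max() if diff.nnz else 0.0) > 1e-8
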