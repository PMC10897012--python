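"""Edge inference: hypergeometric tail, BH step-up, MI, pair tests, estimator."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.metrics import mutual_info_score

from comorbinet import (
    ComorbidityNetworkInference,
    bh_adjust,
    build_incidence,
    build_network,
    hypergeom_pvalue,
    mutual_information,
    pairwise_tests,
)
from comorbinet.records import PatientRecord


def exact_upper_tail(N, n_a, n_b, k):
    """Exhaustive hypergeometric pmf enumeration with exact rationals."""
    total = Fraction(0)
    for j in range(k, min(n_a, n_b) + 1):
        total += Fraction(comb(n_a, j) * comb(N - n_a, n_b - j), comb(N, n_b))
    return total


def rec(case_id, codes):
    return PatientRecord(case_id, 10, "man", "low", frozenset(codes))


class TestHypergeomPvalue:
    def test_k_zero_is_one(self):
        assert hypergeom_pvalue(100, 10, 10, 0) == 1.0

    def test_small_exhaustive_case(self):
        assert hypergeom_pvalue(4, 2, 2, 2) == pytest.approx(1 / 6, abs=1e-12)

    def test_two_term_tail(self):
        expected = float(exact_upper_tail(20, 5, 4, 3))
        assert hypergeom_pvalue(20, 5, 4, 3) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_marginals(self):
        assert hypergeom_pvalue(50, 12, 7, 4) == pytest.approx(
            hypergeom_pvalue(50, 7, 12, 4), abs=1e-15
        )

    def test_matches_enumeration_oracle_small_populations(self):
        for N in range(1, 13):
            for n_a in range(N + 1):
                for n_b in range(n_a, N + 1):
                    lo = max(0, n_a + n_b - N)
                    for k in range(lo, min(n_a, n_b) + 1):
                        expected = float(exact_upper_tail(N, n_a, n_b, k))
                        assert hypergeom_pvalue(N, n_a, n_b, k) == pytest.approx(
                            expected, abs=1e-12
                        ), (N, n_a, n_b, k)

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_nonincreasing_in_k(self, data):
        N = data.draw(st.integers(2, 200))
        n_a = data.draw(st.integers(1, N))
        n_b = data.draw(st.integers(1, N))
        lo = max(0, n_a + n_b - N)
        hi = min(n_a, n_b)
        ps = [hypergeom_pvalue(N, n_a, n_b, k) for k in range(lo, hi + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_infeasible_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 4, 4, 5)
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 12, 4, 2)


class TestBHAdjust:
    def test_all_ones_reject_nothing(self):
        _, reject = bh_adjust([1.0] * 5)
        assert not reject.any()

    def test_single_pvalue(self):
        q, reject = bh_adjust([0.01])
        assert q[0] == pytest.approx(0.01) and reject[0]

    def test_manual_stepup_example(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.9]
        q, reject = bh_adjust(p, alpha=0.05)
        # step-up: largest i with p(i) <= i*alpha/m is i=4
        assert list(reject) == [True, True, True, True, False]
        assert q == pytest.approx([0.005, 0.025, 0.02 * 5 / 3, 0.05, 0.9])

    def test_q_monotone_and_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, size=50)
        q, _ = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_empty_input(self):
        q, reject = bh_adjust([])
        assert len(q) == 0 and len(reject) == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestMutualInformation:
    def test_identical_indicators_give_ln2(self):
        assert mutual_information(7, 0, 0, 7) == pytest.approx(np.log(2), abs=1e-12)

    def test_constant_indicator_gives_zero(self):
        assert mutual_information(5, 0, 5, 0) == 0.0

    def test_hand_evaluated_four_term_sum(self):
        assert mutual_information(3, 1, 1, 5) == pytest.approx(0.1777408838, abs=1e-9)

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n11, n10, n01, n00 = rng.integers(0, 30, size=4)
            if n11 + n10 + n01 + n00 == 0:
                continue
            x = [1] * (n11 + n10) + [0] * (n01 + n00)
            y = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
            assert mutual_information(n11, n10, n01, n00) == pytest.approx(
                mutual_info_score(x, y), abs=1e-12
            )

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_and_nonnegative(self, n11, n10, n01, n00):
        mi = mutual_information(n11, n10, n01, n00)
        assert mi >= 0.0
        assert mi == pytest.approx(mutual_information(n11, n01, n10, n00), abs=1e-12)

    def test_zero_exactly_at_empirical_independence(self):
        # joint factorizes: p11 = 0.25 = 0.5 * 0.5
        assert mutual_information(1, 1, 1, 1) == 0.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            mutual_information(0, 0, 0, 0)


class TestPairwiseTests:
    def test_never_cooccurring_pairs_not_tested(self):
        inc = build_incidence([rec("c1", {"A00"}), rec("c2", {"B00"})])
        assert pairwise_tests(inc) == []

    def test_fully_overlapping_pair_has_smallest_p(self):
        records = [
            rec("c1", {"A00", "B00"}),
            rec("c2", {"A00", "B00"}),
            rec("c3", {"A00", "B00", "C00"}),
            rec("c4", {"C00", "D00"}),
            rec("c5", {"D00"}),
        ]
        tests = pairwise_tests(build_incidence(records))
        best = min(tests, key=lambda t: t.p_value)
        assert best.pair == ("A00", "B00")
        # output is sorted by (q, p, pair)
        assert tests[0].pair == ("A00", "B00")

    def test_one_qvalue_per_tested_pair(self):
        rng = np.random.default_rng(3)
        records = [
            rec(f"c{i}", {f"A{j:02d}" for j in rng.choice(8, size=3, replace=False)})
            for i in range(40)
        ]
        tests = pairwise_tests(build_incidence(records))
        assert len({t.pair for t in tests}) == len(tests)
        assert all(t.q_value >= t.p_value - 1e-15 for t in tests)
        assert all(t.k >= 1 for t in tests)

    def test_counts_are_feasible(self):
        rng = np.random.default_rng(4)
        records = [
            rec(f"c{i}", {f"A{j:02d}" for j in rng.choice(6, size=2, replace=False)})
            for i in range(30)
        ]
        for t in pairwise_tests(build_incidence(records)):
            assert max(0, t.n_a + t.n_b - t.N) <= t.k <= min(t.n_a, t.n_b)
            assert 0 < t.p_value <= 1


class TestBuildNetwork:
    def test_no_significant_pair_gives_zero_nodes(self):
        inc = build_incidence([rec("c1", {"A00", "B00"}), rec("c2", {"A00"})])
        net = build_network(inc, alpha=1e-9)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_empty_incidence_gives_valid_empty_network(self):
        net = build_network(build_incidence([]))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_every_edge_significant_and_no_isolated_nodes(self):
        rng = np.random.default_rng(5)
        base = rng.random(60) < 0.5
        records = []
        for i in range(60):
            codes = {"A00"} if base[i] else set()
            if base[i] or rng.random() < 0.1:
                codes.add("B00")
            codes.add(f"C{int(rng.integers(3)):02d}")
            records.append(rec(f"c{i}", codes))
        net = build_network(build_incidence(records), alpha=0.1)
        for a, b, data in net.graph.edges(data=True):
            assert data["q_value"] <= net.alpha
            assert data["mi"] >= 0
        for node in net.graph.nodes:
            assert net.graph.degree(node) >= 1


class TestEstimator:
    def test_fit_matches_functional_path(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(
            rng.random((50, 5)) < 0.3, columns=[f"A{i:02d}" for i in range(5)]
        )
        X = X[X.any(axis=1)].reset_index(drop=True)  # same cases on both paths
        records = [
            rec(f"c{i}", {c for c in X.columns if X.loc[i, c]}) for i in range(len(X))
        ]
        est = ComorbidityNetworkInference(alpha=0.2).fit(X)
        tests = pairwise_tests(build_incidence(records), alpha=0.2)
        # same test universe and identical p-values pair by pair
        by_pair = {t.pair: t for t in tests}
        assert set(map(tuple, est.tests_[["code_a", "code_b"]].values)) == set(by_pair)
        for row in est.tests_.itertuples(index=False):
            t = by_pair[(row.code_a, row.code_b)]
            assert row.p_value == pytest.approx(t.p_value, rel=1e-12)
            assert row.mi == pytest.approx(t.mi, rel=1e-12)

    def test_sklearn_protocol(self):
        est = ComorbidityNetworkInference(alpha=0.1)
        assert est.get_params() == {"alpha": 0.1}
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        X = np.array([[1, 1], [1, 1], [0, 0], [1, 0]])
        cloned.fit(X)
        assert cloned.n_features_in_ == 2
        assert cloned.tests_.shape[0] == 1

    def test_rejects_non_binary_input(self):
        with pytest.raises(ValueError, match="binary"):
            ComorbidityNetworkInference().fit(np.array([[0.5, 2.0], [1.0, 0.0]]))
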