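"""Bayesian-network scoring, hill-climbing search and model averaging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sleepnets as sn
from sleepnets.dag import (
    ArcRecord,
    ArcTable,
    DAGStructure,
    _local_bic,
    hill_climb,
)


def _all_three_node_dags(labels=("A", "B", "C")):
    pairs = [(a, b) for a in labels for b in labels if a != b]
    dags = []
    for r in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            try:
                dags.append(DAGStructure(labels, frozenset(combo)))
            except ValueError:
                pass
    return dags


def _independent(n, p, seed, labels=None):
    rng = np.random.default_rng(seed)
    vals = (rng.random((n, p)) < 0.5).astype(int)
    return sn.BinaryDataset(vals, labels or tuple("ABCDEFG"[:p]))


class TestDAGStructure:
    def test_rejects_cycle(self):
        with pytest.raises(ValueError, match="cycle"):
            DAGStructure(("a", "b"), {("a", "b"), ("b", "a")})

    def test_rejects_self_arc(self):
        with pytest.raises(ValueError, match="self"):
            DAGStructure(("a", "b"), {("a", "a")})

    def test_topological_order_respects_arcs(self):
        dag = DAGStructure(("a", "b", "c"), {("c", "b"), ("b", "a")})
        order = dag.topological_order()
        assert order.index("c") < order.index("b") < order.index("a")


class TestScores:
    def test_loglik_closed_form_single_node(self):
        # one balanced binary node, empty graph: 4 * ln(1/2)
        d = sn.BinaryDataset(np.array([[0], [0], [1], [1]]), ("a",))
        dag = DAGStructure(("a",), frozenset())
        assert sn.bn_loglik(dag, d) == pytest.approx(-2.77259, abs=1e-5)

    def test_bic_closed_form_single_node(self):
        d = sn.BinaryDataset(np.array([[0], [0], [1], [1]]), ("a",))
        dag = DAGStructure(("a",), frozenset())
        assert sn.bn_bic(dag, d) == pytest.approx(-3.46574, abs=1e-5)

    def test_deterministic_child_contributes_zero_loglik(self):
        vals = np.array([[0, 0], [1, 1], [0, 0], [1, 1], [1, 1]])
        d = sn.BinaryDataset(vals, ("A", "B"))
        with_arc = DAGStructure(("A", "B"), {("A", "B")})
        empty = DAGStructure(("A", "B"), frozenset())
        # B's contribution = loglik(with arc) - loglik of A alone
        a_only = sn.bn_loglik(DAGStructure(("A",), frozenset()),
                              sn.BinaryDataset(vals[:, :1], ("A",)))
        assert sn.bn_loglik(with_arc, d) == pytest.approx(a_only, abs=1e-12)
        assert sn.bn_loglik(with_arc, d) > sn.bn_loglik(empty, d)

    def test_parameter_count_two_parents(self):
        # BIC penalty difference between 2-parent and no-parent child
        # is (ln n / 2) * (4 - 1)
        d = _independent(64, 3, 0)
        full = DAGStructure(d.labels, {("A", "C"), ("B", "C")})
        empty = DAGStructure(d.labels, frozenset())
        pen_diff = (sn.bn_loglik(full, d) - sn.bn_bic(full, d)) \
            - (sn.bn_loglik(empty, d) - sn.bn_bic(empty, d))
        assert pen_diff == pytest.approx(np.log(64) / 2 * 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_empty_beats_spurious_arc_on_independent_nodes(self, seed):
        d = _independent(5000, 2, 100 + seed)
        empty = DAGStructure(("A", "B"), frozenset())
        arc = DAGStructure(("A", "B"), {("A", "B")})
        assert sn.bn_bic(empty, d) > sn.bn_bic(arc, d)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_adding_an_arc_never_decreases_loglik(self, seed):
        rng = np.random.default_rng(seed)
        d = sn.BinaryDataset((rng.random((50, 3)) < rng.uniform(0.2, 0.8, 3))
                             .astype(int), ("A", "B", "C"))
        base = DAGStructure(d.labels, {("A", "B")})
        larger = DAGStructure(d.labels, {("A", "B"), ("C", "B")})
        assert sn.bn_loglik(larger, d) >= sn.bn_loglik(base, d) - 1e-9


class TestHillClimb:
    def test_independent_columns_give_empty_graph(self):
        d = _independent(5000, 4, 1)
        dag, score, _, converged = hill_climb(d)
        assert dag.arcs == frozenset()
        assert converged
        # exhaustive confirmation: no single arc has positive gain
        for u in d.labels:
            for v in d.labels:
                if u != v:
                    one = DAGStructure(d.labels, {(u, v)})
                    assert sn.bn_bic(one, d) <= score

    def test_chain_recovered_without_shortcut(self, chain_spec):
        d = sn.sample_bayes_net(chain_spec, 5000, seed=8)
        dag, score, _, _ = hill_climb(d)
        skeleton = {frozenset(arc) for arc in dag.arcs}
        assert skeleton == {frozenset(("A", "B")), frozenset(("B", "C"))}
        # global optimum over all 25 three-node DAGs
        best = max(sn.bn_bic(g, d) for g in _all_three_node_dags())
        assert score == pytest.approx(best, abs=1e-9)

    def test_score_trace_strictly_increasing(self, chain_spec):
        d = sn.sample_bayes_net(chain_spec, 2000, seed=9)
        _, _, trace, _ = hill_climb(d)
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_final_score_equals_full_rescoring(self, chain_spec):
        """Decomposable incremental scoring agrees with bn_bic on the
        returned structure."""
        for seed in range(5):
            d = sn.sample_bayes_net(chain_spec, 500, seed=30 + seed)
            dag, score, _, _ = hill_climb(d)
            assert score == pytest.approx(sn.bn_bic(dag, d), abs=1e-9)

    def test_deterministic_given_data(self, chain_spec):
        d = sn.sample_bayes_net(chain_spec, 500, seed=10)
        a = hill_climb(d)
        b = hill_climb(d)
        assert a[0].arcs == b[0].arcs and a[1] == b[1]


class TestBootstrapDags:
    def test_single_planted_arc_high_strength(self):
        spec = sn.BayesNetSpec(("A", "B"), ((), (0,)), ([0.5], [0.1, 0.9]))
        d = sn.sample_bayes_net(spec, 1000, seed=11)
        table = sn.bootstrap_dags(d, m=200, seed=12)
        assert table.strength("A", "B") > 0.9

    def test_independent_columns_low_strengths(self):
        d = _independent(1000, 3, 13)
        table = sn.bootstrap_dags(d, m=200, seed=14)
        assert np.all(table.strengths() < 0.5)

    def test_direction_probabilities_complementary(self, chain_spec):
        d = sn.sample_bayes_net(chain_spec, 400, seed=15)
        table = sn.bootstrap_dags(d, m=50, seed=16)
        for a, b in table.pairs():
            if table.strength(a, b) > 0:
                assert table.direction_prob(a, b) \
                    + table.direction_prob(b, a) == pytest.approx(1.0)

    def test_same_seed_identical(self, chain_spec):
        d = sn.sample_bayes_net(chain_spec, 400, seed=17)
        t1 = sn.bootstrap_dags(d, m=30, seed=18)
        t2 = sn.bootstrap_dags(d, m=30, seed=18)
        assert t1.to_dataframe().equals(t2.to_dataframe())

    def test_degenerate_replicates_redrawn_and_counted(self):
        # one rare column: resamples often miss the single 1
        vals = np.zeros((40, 2), dtype=int)
        vals[0, 0] = 1
        vals[:20, 1] = 1
        d = sn.BinaryDataset(vals, ("rare", "even"))
        table = sn.bootstrap_dags(d, m=20, seed=19)
        assert table.redraws > 0


class TestSignificanceThreshold:
    def test_perfectly_separated(self):
        t = sn.significance_threshold([1, 1, 0, 0, 0])
        assert 0 < t < 1
        kept = [s for s in (1, 1, 0, 0, 0) if s > t]
        assert kept == [1, 1]

    def test_brute_force_oracle_agreement(self):
        strengths = np.array([0.95, 0.90, 0.15, 0.10, 0.05])

        def l1(pi):  # exact L1 distance between ECDF and two-point CDF
            xs = np.linspace(0, 1, 100_001)
            ecdf = np.searchsorted(np.sort(strengths), xs, side="right") / 5
            return np.trapezoid(np.abs(ecdf - pi), xs)

        best_pi = min((c / 5 for c in range(6)), key=l1)
        t = sn.significance_threshold(strengths)
        kept = sorted(s for s in strengths if s > t)
        assert kept == [0.90, 0.95]
        assert best_pi == pytest.approx(3 / 5)

    def test_all_equal_flagged_all_significant(self):
        t = sn.significance_threshold([0.4, 0.4, 0.4])
        assert t < 0.4
        assert all(s > t for s in (0.4, 0.4, 0.4))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sn.significance_threshold([])


def _manual_table(labels, entries, m=100):
    """entries: {(a, b): (strength, direction_prob_a_to_b)}"""
    either, directed = {}, {}
    for (a, b), (s, dp) in entries.items():
        key = tuple(sorted((a, b)))
        either[key] = int(round(s * m))
        directed[(a, b)] = int(round(s * m * dp))
        directed[(b, a)] = either[key] - directed[(a, b)]
    return ArcTable(labels, m, either, directed)


class TestAveragedNetwork:
    def test_single_planted_arc_retained_and_oriented(self):
        spec = sn.BayesNetSpec(("A", "B"), ((), (0,)), ([0.5], [0.05, 0.95]))
        d = sn.sample_bayes_net(spec, 1000, seed=21)
        table = sn.bootstrap_dags(d, m=100, seed=22)
        avg = sn.averaged_network(table, d)
        assert len(avg.arcs) == 1
        arc = avg.arcs[0]
        assert {arc.parent, arc.child} == {"A", "B"}
        assert arc.direction_prob >= 0.5

    def test_display_rule_boundary(self):
        labels = ("A", "B", "C", "D")
        table = _manual_table(labels, {
            ("A", "B"): (0.9, 0.51),
            ("C", "D"): (0.9, 0.50),
        })
        rng = np.random.default_rng(0)
        d = sn.BinaryDataset((rng.random((100, 4)) < 0.5).astype(int),
                             labels)
        avg = sn.averaged_network(table, d, threshold=0.5)
        by_pair = {frozenset((a.parent, a.child)): a for a in avg.arcs}
        at_51 = by_pair[frozenset(("A", "B"))]
        at_50 = by_pair[frozenset(("C", "D"))]
        assert at_51.displayed and not at_51.bidirectional
        assert at_50.bidirectional and not at_50.displayed

    def test_result_is_acyclic_after_cycle_resolution(self):
        labels = ("A", "B", "C")
        # majority orientations form the cycle A->B->C->A
        table = _manual_table(labels, {
            ("A", "B"): (1.0, 0.9),
            ("B", "C"): (1.0, 0.9),
            ("C", "A"): (1.0, 0.55),
        })
        rng = np.random.default_rng(1)
        d = sn.BinaryDataset((rng.random((100, 3)) < 0.5).astype(int),
                             labels)
        avg = sn.averaged_network(table, d, threshold=0.5)
        assert avg.structure().topological_order() is not None
        # the arc closest to 0.5 was the one reversed
        assert ("C", "A") in avg.cycle_reversals

    def test_every_retained_arc_above_threshold(self, chain_spec):
        d = sn.sample_bayes_net(chain_spec, 800, seed=23)
        table = sn.bootstrap_dags(d, m=100, seed=24)
        avg = sn.averaged_network(table, d)
        for arc in avg.arcs:
            assert arc.strength > avg.threshold


class TestArcBicStrength:
    def test_spurious_arc_value_is_pure_penalty_relief(self):
        # child independent of its one parent: removing the arc changes
        # the score by about +(ln n / 2) * 2^(1-1) ... with |parents|=1
        n = 20_000
        d = _independent(n, 2, 25)
        dag = DAGStructure(("A", "B"), {("A", "B")})
        val = sn.arc_bic_strength(dag, d)[("A", "B")]
        # the likelihood loss from deleting a null arc is O(1) (half a
        # chi-square(1)), the penalty relief grows as (ln n)/2
        assert val == pytest.approx(np.log(n) / 2, abs=2.0)
        assert val > 0

    def test_deterministic_dependence_large_negative(self):
        rng = np.random.default_rng(26)
        a = (rng.random(1000) < 0.5).astype(int)
        d = sn.BinaryDataset(np.column_stack([a, a]), ("A", "B"))
        dag = DAGStructure(("A", "B"), {("A", "B")})
        val = sn.arc_bic_strength(dag, d)[("A", "B")]
        assert val < -500

    def test_matches_global_bic_difference(self, chain_spec):
        d = sn.sample_bayes_net(chain_spec, 500, seed=27)
        dag = DAGStructure(("A", "B", "C"), {("A", "B"), ("B", "C")})
        vals = sn.arc_bic_strength(dag, d)
        for (a, b), v in vals.items():
            without = DAGStructure(dag.labels,
                                   dag.arcs - {(a, b)})
            expect = sn.bn_bic(without, d) - sn.bn_bic(dag, d)
            assert v == pytest.approx(expect, abs=1e-9)


class TestModelSurface:
    def test_fit_and_summary(self, chain_spec):
        d = sn.sample_bayes_net(chain_spec, 800, seed=28)
        res = sn.BayesNetModel(d).fit()
        assert res.converged
        assert "BIC" in res.summary()
        assert res.dag.topological_order() is not None

    def test_averaged_pipeline_exports(self, tmp_path, chain_spec):
        d = sn.sample_bayes_net(chain_spec, 500, seed=29)
        avg = sn.BayesNetModel(d).fit().averaged(m=40, seed=30)
        avg.to_dot(tmp_path / "g.dot")
        avg.to_graphml(tmp_path / "g.graphml")
        assert "digraph" in (tmp_path / "g.dot").read_text()
        assert (tmp_path / "g.graphml").exists()
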