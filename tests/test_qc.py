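"""Locus QC classification, ANOVA/eta^2, patristic distances, regression."""

import math

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from slims.fixtures import _random_tree
from slims.qc import (AnovaResult, BaitDistanceCalculator,
                      DegenerateRegressionError, UnscorableSampleError,
                      anova_by_family, classify_locus, distance_regression,
                      summarize_sample)


@pytest.mark.parametrize("cov,length,high_copy,expected", [
    (6.0, 350, False, True),     # both thresholds met exactly
    (5.99, 10000, False, False),  # coverage just under
    (100.0, 349, False, False),   # length just under
    (6.0, 350, True, None),       # high-copy: not scored
    (0.0, 0, False, False),
])
def test_classify_locus_boundaries(cov, length, high_copy, expected):
    assert classify_locus(cov, length, high_copy) is expected


def _records(n_success, n_fail, n_high=0):
    recs = [(10.0, 500, False)] * n_success
    recs += [(1.0, 100, False)] * n_fail
    recs += [(200.0, 1000, True)] * n_high
    return recs


def test_failure_flag_is_strict():
    ok = summarize_sample("s", _records(5, 95))
    assert ok.fraction == 0.05 and not ok.failed
    bad = summarize_sample("s", _records(4, 96))
    assert bad.fraction == 0.04 and bad.failed


def test_high_copy_excluded_from_both_sides():
    s = summarize_sample("s", _records(10, 10, n_high=14))
    assert s.n_loci_scored == 20 and s.n_success == 10


def test_all_high_copy_is_unscorable():
    with pytest.raises(UnscorableSampleError):
        summarize_sample("s", _records(0, 0, n_high=5))


def test_anova_degenerate_groups():
    res, _ = anova_by_family([0, 0, 1, 1], ["A", "A", "B", "B"], min_n=1)
    assert res.eta_squared == 1.0 and math.isinf(res.F)
    res, _ = anova_by_family([3.0] * 10, ["A"] * 5 + ["B"] * 5, min_n=1)
    assert res.eta_squared == 0.0 and res.F == 0.0
    with pytest.raises(ValueError):
        anova_by_family([1, 2], ["A", "A"])


def test_eta_squared_decomposition():
    rng = np.random.default_rng(4)
    y = rng.normal(size=200)
    g = rng.choice(list("ABCDE"), size=200)
    res, _ = anova_by_family(y, g, min_n=10)
    ss_total = res.ss_between + res.ss_within
    assert res.eta_squared == pytest.approx(
        1 - res.ss_within / ss_total, abs=1e-12)


def test_anova_matches_reference_implementation():
    """F, p and eta^2 agree with scipy/statsmodels to 1e-8 on random
    tables."""
    rng = np.random.default_rng(5)
    for trial in range(25):
        k = int(rng.integers(2, 6))
        sizes = rng.integers(5, 40, size=k)
        groups = [rng.normal(rng.normal(0, 1), 1, size=n) for n in sizes]
        y = np.concatenate(groups)
        g = np.concatenate([[f"G{i}"] * n for i, n in enumerate(sizes)])
        res, _ = anova_by_family(y, g, min_n=5)
        f_ref, p_ref = stats.f_oneway(*groups)
        assert res.F == pytest.approx(f_ref, abs=1e-8, rel=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-8)
        # eta^2 from an explicit OLS fit of the group-means model
        X = pd.get_dummies(pd.Series(g), drop_first=True, dtype=float)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        eta_ref = fit.ess / (fit.ess + fit.ssr)
        assert res.eta_squared == pytest.approx(eta_ref, abs=1e-8)


def test_bait_tip_distance_zero_and_two_tip_path():
    calc = BaitDistanceCalculator("(A_a:1,B_b:2);", ["B b"])
    assert calc.distance("B b") == 0.0
    assert calc.distance("A a") == pytest.approx(3.0)
    assert calc.distance("C c") is None  # unmapped


def test_unmapped_counted_not_fatal():
    calc = BaitDistanceCalculator("(A_a:1,(B_b:2,C_c:1):1);", ["A a"])
    dists, n_unmapped = calc.distances(["A a", "B b", "Z z"])
    assert n_unmapped == 1
    assert dists["B b"] == pytest.approx(4.0)


def _tips(n, rng):
    return [f"Tip{i:02d} sp{i:02d}" for i in range(n)]


def test_nearest_bait_matches_graph_oracle():
    """Distances equal a brute-force shortest-path oracle over the tree's
    edge graph, exactly, on random 50-tip trees."""
    rng = np.random.default_rng(6)
    for trial in range(5):
        labels = _tips(50, rng)
        newick = _random_tree(labels, rng)
        baits = [labels[int(i)] for i in rng.choice(50, size=4,
                                                    replace=False)]
        calc = BaitDistanceCalculator(newick, baits)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        G = nx.Graph()
        leaf_of = {}
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None:
                G.add_edge(id(edge.tail_node), id(edge.head_node),
                           weight=float(edge.length or 0))
        for leaf in tree.leaf_node_iter():
            leaf_of[leaf.taxon.label.replace("_", " ")] = id(leaf)
        for lab in labels:
            expected = min(
                nx.dijkstra_path_length(G, leaf_of[lab], leaf_of[b])
                for b in baits)
            assert calc.distance(lab) == pytest.approx(expected, abs=1e-12)


def test_patristic_triangle_inequality():
    rng = np.random.default_rng(7)
    labels = _tips(20, rng)
    newick = _random_tree(labels, rng)

    def d(x, y):
        return BaitDistanceCalculator(newick, [y]).distance(x)

    for _ in range(15):
        a, b, c = (labels[int(i)] for i in rng.choice(20, 3, replace=False))
        assert d(a, b) <= d(a, c) + d(c, b) + 1e-9


def test_regression_collinear_and_null():
    x = np.arange(10, dtype=float)
    res = distance_regression(x, 3 * x + 2)
    assert res.adjusted_r_squared == pytest.approx(1.0)
    assert res.slope == pytest.approx(3.0)
    rng = np.random.default_rng(8)
    xs = rng.normal(size=3000)
    ys = rng.permutation(rng.normal(size=3000))
    res = distance_regression(xs, ys)
    assert abs(res.adjusted_r_squared) < 0.01
    assert res.adjusted_r_squared <= res.r_squared


def test_regression_matches_statsmodels():
    rng = np.random.default_rng(9)
    for trial in range(25):
        n = int(rng.integers(5, 60))
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        res = distance_regression(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slope == pytest.approx(fit.params[1], abs=1e-8)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-8)
        assert res.adjusted_r_squared == pytest.approx(
            fit.rsquared_adj, abs=1e-8)


def test_regression_degenerate_inputs():
    with pytest.raises(DegenerateRegressionError):
        distance_regression([1.0, 1.0, 1.0], [1, 2, 3])
    with pytest.raises(ValueError):
        distance_regression([1.0, 2.0], [1, 2])
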