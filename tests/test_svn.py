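import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from medlifenet.simulate import generate_null
from medlifenet.instrument import IndicatorMatrix
from medlifenet.svn import (
    ContingencyTable2x2,
    bonferroni_adjust,
    build_svn,
    fisher_exact_2x2,
    pair_table,
)


def fisher_p_exact_rational(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: two-sided Fisher p by exact rational enumeration
    of the hypergeometric distribution at the observed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(
            math.comb(r1, k) * math.comb(n - r1, c1 - k), math.comb(n, c1)
        )

    p_obs = pmf(a)
    total = sum((p for k in range(lo, hi + 1) if (p := pmf(k)) <= p_obs), Fraction(0))
    return float(total)


class TestFisherExact:
    def test_symmetric_table(self):
        p, or_ = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert p == pytest.approx(1.0)
        assert or_ == pytest.approx(1.0)

    def test_perfect_diagonal(self):
        # only the two extreme tables are as unlikely as the observed one
        p, or_ = fisher_exact_2x2(ContingencyTable2x2(10, 0, 0, 10))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
        assert math.isinf(or_)

    def test_zero_margin_uninformative(self):
        p, or_ = fisher_exact_2x2(ContingencyTable2x2(0, 0, 7, 3))
        assert p == 1.0
        assert math.isnan(or_)

    def test_matches_rational_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 61))
            cells = rng.multinomial(n, rng.dirichlet(np.ones(4)))
            a, b, c, d = (int(x) for x in cells)
            p, _ = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(fisher_p_exact_rational(a, b, c, d), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            cells = rng.integers(0, 30, size=4)
            a, b, c, d = (int(x) for x in cells)
            if (a + b + c + d) == 0:
                continue
            p, _ = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(
                st.fisher_exact([[a, b], [c, d]]).pvalue, rel=1e-9
            )

    @settings(max_examples=100, deadline=None)
    @given(st_h.tuples(*[st_h.integers(1, 25)] * 4))
    def test_symmetry_invariances(self, cells):
        a, b, c, d = cells
        p0, or0 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        # swap the two variables: transpose the table
        p1, or1 = fisher_exact_2x2(ContingencyTable2x2(a, c, b, d))
        # relabel 0/1 in both variables simultaneously
        p2, or2 = fisher_exact_2x2(ContingencyTable2x2(d, c, b, a))
        assert p1 == pytest.approx(p0, rel=1e-10)
        assert p2 == pytest.approx(p0, rel=1e-10)
        assert abs(math.log(or1)) == pytest.approx(abs(math.log(or0)), rel=1e-10)
        assert abs(math.log(or2)) == pytest.approx(abs(math.log(or0)), rel=1e-10)


class TestBonferroni:
    def test_definition_and_cap(self):
        assert bonferroni_adjust([0.01, 0.2], m=10) == [0.1, 1.0]

    def test_single_test_unchanged(self):
        assert bonferroni_adjust([0.37], m=1) == [0.37]

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="outside"):
            bonferroni_adjust([1.2], m=3)
        with pytest.raises(ValueError, match="at least"):
            bonferroni_adjust([0.1, 0.2], m=1)


class TestBuildSVN:
    def test_duplicated_column_gives_positive_edge(self):
        rng = np.random.default_rng(4)
        x = (rng.random(200) < 0.5).astype(np.int8)
        noise = (rng.random((200, 4)) < 0.5).astype(np.int8)
        V = np.column_stack([x, x, noise])
        X = IndicatorMatrix(
            tuple(f"r{i}" for i in range(200)),
            ("x", "x_copy", "n1", "n2", "n3", "n4"),
            V,
        )
        net = build_svn(X)
        found = {frozenset((e.node_u, e.node_v)): e for e in net.edges}
        edge = found[frozenset(("x", "x_copy"))]
        assert edge.sign == "positive" and math.isinf(edge.log_or)
        assert net.m == 15

    def test_complementary_column_gives_negative_edge(self):
        rng = np.random.default_rng(5)
        x = (rng.random(200) < 0.5).astype(np.int8)
        V = np.column_stack([x, 1 - x, (rng.random(200) < 0.5).astype(np.int8)])
        X = IndicatorMatrix(
            tuple(f"r{i}" for i in range(200)), ("x", "not_x", "n"), V
        )
        net = build_svn(X)
        found = {frozenset((e.node_u, e.node_v)): e for e in net.edges}
        edge = found[frozenset(("x", "not_x"))]
        assert edge.sign == "negative" and edge.log_or == -math.inf

    def test_degenerate_columns_excluded_from_m(self):
        rng = np.random.default_rng(6)
        V = (rng.random((50, 3)) < 0.5).astype(np.int8)
        V = np.column_stack([V, np.ones(50, dtype=np.int8)])
        X = IndicatorMatrix(
            tuple(f"r{i}" for i in range(50)), ("a", "b", "c", "const"), V
        )
        net = build_svn(X)
        assert net.excluded_nodes == ("const",)
        assert net.m == 3
        assert "const" not in net.nodes

    def test_too_few_usable_columns_rejected(self):
        V = np.column_stack(
            [np.ones(10, dtype=np.int8), np.zeros(10, dtype=np.int8),
             np.array([0, 1] * 5, dtype=np.int8)]
        )
        X = IndicatorMatrix(tuple(f"r{i}" for i in range(10)), ("a", "b", "c"), V)
        with pytest.raises(ValueError, match="non-degenerate"):
            build_svn(X)

    def test_retained_edges_respect_alpha(self):
        X = generate_null(300, [0.5] * 6, seed=9)
        net = build_svn(X, alpha=0.05)
        assert all(e.p_adjusted < 0.05 for e in net.edges)
        assert all(e.p_adjusted == pytest.approx(min(1.0, net.m * e.p_raw)) for e in net.edges)

    def test_null_cohorts_rarely_produce_edges(self):
        # small-scale family-wise check; the full 500-replicate version runs
        # in the acceptance suite
        rng = np.random.default_rng(10)
        hits = 0
        for rep in range(50):
            p = rng.uniform(0.2, 0.8, 16)
            X = generate_null(300, p, seed=1000 + rep)
            hits += bool(build_svn(X).edges)
        assert hits / 50 <= 0.05 + 0.05  # generous guard at this replicate count

    def test_pair_table_counts(self):
        x = np.array([1, 1, 0, 0, 1])
        y = np.array([1, 0, 1, 0, 1])
        t = pair_table(x, y)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 1)


def test_edge_table_round_trip(tmp_path):
    X = generate_null(120, [0.5] * 4, seed=2)
    V = np.column_stack([X.values, X.values[:, 0]])  # force one edge
    X2 = IndicatorMatrix(X.respondent_ids, X.indicator_ids + ("dup",), V)
    net = build_svn(X2)
    path = tmp_path / "edges.tsv"
    net.to_tsv(path)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert list(df.columns)[:4] == ["node_u", "node_v", "p_raw", "p_adjusted"]
    assert len(df) == len(net.edges) >= 1
    g = net.to_networkx()
    assert g.number_of_nodes() == 5 and g.number_of_edges() == len(net.edges)
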