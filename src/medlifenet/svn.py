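"""Statistically validated network of binary indicators.

Every unordered pair of non-degenerate indicator columns is tested for
association with Fisher's exact test (two-sided, the usual
probability-mass rule: sum hypergeometric probabilities of all tables, at
the observed margins, no more likely than the observed one). Raw p-values
receive a Bonferroni correction over the number of pairs tested, and only
edges with adjusted p < alpha are retained. Each retained edge is signed by
its sample odds ratio: positive for OR > 1 (co-occurrence), negative for
OR < 1 (dissociation).

The exact test is computed by direct enumeration of the hypergeometric
support using log-factorials, which keeps an all-pairs scan over hundreds
of cohorts fast without sacrificing exactness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .instrument import IndicatorMatrix

__all__ = [
    "ContingencyTable2x2",
    "EdgeRecord",
    "ValidatedNetwork",
    "fisher_exact_2x2",
    "bonferroni_adjust",
    "build_svn",
    "pair_table",
]

# relative tolerance for "no more likely than observed" — absorbs float
# noise between mathematically tied hypergeometric probabilities
_TIE_REL_TOL = 1 + 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a=both 1, b=first only, c=second only, d=neither)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        """Sample odds ratio ad/bc; inf or 0 for single zero cells, nan if
        a whole margin is zero (non-estimable)."""
        r1, r2 = self.a + self.b, self.c + self.d
        c1, c2 = self.a + self.c, self.b + self.d
        if 0 in (r1, r2, c1, c2):
            return math.nan
        ad, bc = self.a * self.d, self.b * self.c
        if bc == 0:
            return math.inf
        return ad / bc


@dataclass(frozen=True)
class EdgeRecord:
    node_u: str
    node_v: str
    p_raw: float
    p_adjusted: float
    odds_ratio: float
    log_or: float                 # +-inf allowed for single-zero-cell tables
    sign: str                     # "positive" / "negative"
    structural_exclusive: bool = False   # same-item tripartite pair


@dataclass(frozen=True)
class ValidatedNetwork:
    nodes: tuple[str, ...]
    edges: tuple[EdgeRecord, ...]
    alpha: float
    m: int                        # number of pairwise tests performed
    excluded_nodes: tuple[str, ...] = field(default_factory=tuple)  # degenerate columns

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node_u": e.node_u,
                    "node_v": e.node_v,
                    "p_raw": e.p_raw,
                    "p_adjusted": e.p_adjusted,
                    "log_or": e.log_or,
                    "sign": e.sign,
                    "structural_exclusive": e.structural_exclusive,
                }
                for e in self.edges
            ],
            columns=[
                "node_u",
                "node_v",
                "p_raw",
                "p_adjusted",
                "log_or",
                "sign",
                "structural_exclusive",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(alpha=self.alpha, m=self.m)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.node_u, e.node_v, sign=e.sign, p_adjusted=e.p_adjusted)
        return g

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def to_sif(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            linked = set()
            for e in self.edges:
                fh.write(f"{e.node_u}\t{e.sign}\t{e.node_v}\n")
                linked.update((e.node_u, e.node_v))
            for node in self.nodes:
                if node not in linked:
                    fh.write(f"{node}\n")

    def positive_subgraph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (e.node_u, e.node_v) for e in self.edges if e.sign == "positive"
        )
        return g


def _hypergeom_logpmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """log P(A = k) for the 2x2 table with total n, row-1 margin r1,
    column-1 margin c1 (A the top-left cell)."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(n - r1 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(n - r1 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(p_two_sided, odds_ratio)``. With any zero margin the table
    carries no information: p = 1 and the OR is non-estimable (nan).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n < 1:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0, table.odds_ratio()
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = np.exp(_hypergeom_logpmf(ks, n, r1, c1))
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * _TIE_REL_TOL].sum())
    return min(p, 1.0), table.odds_ratio()


def bonferroni_adjust(p_values, m: int) -> list[float]:
    """Bonferroni family-wise correction: min(1, m*p), order preserved."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


def pair_table(x: np.ndarray, y: np.ndarray) -> ContingencyTable2x2:
    """2x2 co-occurrence table for two 0/1 vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    a = int((x & y).sum())
    b = int((x & (1 - y)).sum())
    c = int(((1 - x) & y).sum())
    d = int(((1 - x) & (1 - y)).sum())
    return ContingencyTable2x2(a, b, c, d)


def _signed_log_or(or_value: float) -> tuple[float, str]:
    if math.isinf(or_value):
        return math.inf, "positive"
    if or_value == 0.0:
        return -math.inf, "negative"
    log_or = math.log(or_value)
    return log_or, "positive" if or_value > 1 else "negative"


def build_svn(
    X: IndicatorMatrix,
    alpha: float = 0.05,
    structural_pairs: set[frozenset[str]] | None = None,
) -> ValidatedNetwork:
    """All-pairs Fisher screen with Bonferroni control.

    Constant (degenerate) columns carry no 2x2 information and are excluded
    from testing; they are reported in ``excluded_nodes``. ``m`` counts the
    pairs actually tested. Pairs of structurally exclusive indicators (the
    one-hot triple of a tripartite item) are tested like any other pair but
    annotated so downstream consumers can filter their guaranteed negative
    association.
    """
    V = np.asarray(X.values, dtype=np.int64)
    n = V.shape[0]
    col_sums = V.sum(axis=0)
    usable = [(j, X.indicator_ids[j]) for j in range(V.shape[1]) if 0 < col_sums[j] < n]
    excluded = tuple(
        X.indicator_ids[j] for j in range(V.shape[1]) if not (0 < col_sums[j] < n)
    )
    if len(usable) < 2:
        raise ValueError(
            f"need at least 2 non-degenerate indicator columns, found {len(usable)} "
            f"(excluded: {list(excluded)})"
        )
    structural_pairs = structural_pairs or set()

    # all pairwise a-counts at once; margins from the column sums
    cols = [j for j, _ in usable]
    names = [name for _, name in usable]
    sub = V[:, cols]
    A = sub.T @ sub
    sums = sub.sum(axis=0)

    results = []
    k = len(cols)
    for i in range(k):
        for j in range(i + 1, k):
            a = int(A[i, j])
            t = ContingencyTable2x2(
                a, int(sums[i]) - a, int(sums[j]) - a, n - int(sums[i]) - int(sums[j]) + a
            )
            p, or_value = fisher_exact_2x2(t)
            results.append((names[i], names[j], p, or_value))

    m = len(results)
    edges = []
    for u, v, p, or_value in results:
        p_adj = min(1.0, m * p)
        if p_adj < alpha:
            log_or, sign = _signed_log_or(or_value)
            edges.append(
                EdgeRecord(
                    node_u=u,
                    node_v=v,
                    p_raw=p,
                    p_adjusted=p_adj,
                    odds_ratio=or_value,
                    log_or=log_or,
                    sign=sign,
                    structural_exclusive=frozenset((u, v)) in structural_pairs,
                )
            )
    return ValidatedNetwork(
        nodes=tuple(names), edges=tuple(edges), alpha=alpha, m=m, excluded_nodes=excluded
    )
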