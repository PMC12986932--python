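"""Respondent clustering on binary profiles: Jaccard distance + UPGMA.

Respondents are compared over all emitted indicators with the Jaccard
distance (one minus shared over combined 1-positions) and grouped by
average-linkage hierarchical clustering. The tree is cut to a user-chosen
number of communities, or to the k in 2..12 maximising the mean silhouette.
Communities are then profiled with the enrichment module, each community
against the rest of the cohort, with Bonferroni correction over communities
x indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .enrichment import EnrichmentResult, enrich
from .instrument import IndicatorMatrix

__all__ = [
    "ClusterAssignment",
    "jaccard_distance",
    "jaccard_matrix",
    "hierarchical_cluster",
    "select_k_silhouette",
    "profile_clusters",
]


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, int]        # respondent_id -> community label (1..k)
    k: int
    linkage_height: float         # merge height just above the cut

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.labels.items()), columns=["respondent_id", "community"]
        ).to_csv(path, sep="\t", index=False)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for rid, lab in self.labels.items():
            out.setdefault(lab, []).append(rid)
        return out


def jaccard_distance(u, v) -> float:
    """1 - |intersection| / |union| of the 1-positions of two 0/1 vectors.

    Two all-zero vectors have no support to compare; their distance is 0 by
    convention (with a warning).
    """
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError("vectors differ in length")
    union = np.logical_or(u, v).sum()
    if union == 0:
        warnings.warn("both vectors all-zero; Jaccard distance defined as 0")
        return 0.0
    return 1.0 - np.logical_and(u, v).sum() / union

def jaccard_matrix(X: IndicatorMatrix) -> np.ndarray:
    """Condensed pairwise Jaccard distance over respondents."""
    return pdist(np.asarray(X.values, dtype=bool), metric="jaccard")


def hierarchical_cluster(
    D: np.ndarray, k: int, method: str = "average"
) -> tuple[np.ndarray, float]:
    """Cut an agglomerative tree on distance matrix ``D`` into ``k`` groups.

    ``D`` may be square-symmetric or condensed. Returns 1-based labels
    (relabelled contiguously in respondent order) and the merge height just
    above the cut. Ties break deterministically on the lowest-index pair, as
    in scipy's linkage.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim == 2:
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        dc = squareform(D, checks=False)
    else:
        dc = D
    if (dc < 0).any():
        raise ValueError("negative distances are not admissible")
    n = int(round((1 + np.sqrt(1 + 8 * dc.size)) / 2))
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    Z = linkage(dc, method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # scipy may return fewer than k clusters only if distances tie exactly at
    # the cut; relabel contiguously by first appearance
    mapping: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[i] = mapping[lab]
    n_found = len(mapping)
    # height of the last merge performed to reach n_found clusters
    height = float(Z[n - n_found - 1, 2]) if n_found < n else 0.0
    return labels, height


def select_k_silhouette(
    D: np.ndarray, k_range: range = range(2, 13), method: str = "average"
) -> int:
    """Pick k maximising the mean silhouette on the precomputed distances."""
    D = np.asarray(D, dtype=float)
    square = squareform(D, checks=False) if D.ndim == 1 else D
    n = square.shape[0]
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= n:
            break
        labels, _ = hierarchical_cluster(square, k, method=method)
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(square, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no valid k in range")
    return best_k


def cluster_respondents(
    X: IndicatorMatrix, k: int | None = None, method: str = "average"
) -> ClusterAssignment:
    """Jaccard + UPGMA clustering of the cohort; k auto-selected if omitted."""
    dc = jaccard_matrix(X)
    if k is None:
        k = select_k_silhouette(dc, method=method)
    labels, height = hierarchical_cluster(dc, k, method=method)
    return ClusterAssignment(
        labels=dict(zip(X.respondent_ids, (int(x) for x in labels))),
        k=int(len(set(labels))),
        linkage_height=height,
    )


def profile_clusters(
    assignment: ClusterAssignment, X: IndicatorMatrix, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Enrich every community against the rest of the cohort.

    The Bonferroni family is communities x indicators. Singleton communities
    are skipped with a warning (a single respondent cannot support an exact
    test of practical power).
    """
    rid_to_row = {rid: i for i, rid in enumerate(X.respondent_ids)}
    members = assignment.members()
    profiled = {lab: mem for lab, mem in members.items() if len(mem) >= 2}
    skipped = sorted(set(members) - set(profiled))
    if skipped:
        warnings.warn(f"skipping singleton communities: {skipped}")
    m = len(profiled) * len(X.indicator_ids)
    results: list[EnrichmentResult] = []
    all_rows = np.arange(X.n)
    for lab in sorted(profiled):
        rows = np.array([rid_to_row[r] for r in profiled[lab]])
        rest = np.setdiff1d(all_rows, rows)
        results.extend(
            enrich(rows, rest, X, group_label=f"community_{lab}", alpha=alpha, m=m)
        )
    return results
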