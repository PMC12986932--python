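"""Group enrichment of binary indicators: exact tests with log-OR intervals.

For a target group of respondents versus a contrast group (the opposite
adherence extreme, or the rest of the cohort), each indicator's 2x2 table
(group membership x indicator value) is tested with Fisher's exact test and
Bonferroni-corrected over the indicators tested. The reported effect is the
sample log odds ratio with a Woolf (logit) confidence interval; when any
cell is zero the interval is computed on the Haldane–Anscombe corrected
table (0.5 added to every cell), and when the uncorrected OR itself is 0 or
infinite the unbounded side of the interval is omitted — an OR of 0 (no
events in the target group) reports only its upper confidence bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .instrument import IndicatorMatrix
from .svn import ContingencyTable2x2, fisher_exact_2x2

__all__ = ["EnrichmentResult", "log_or_ci", "enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    indicator_id: str
    group_label: str
    counts: ContingencyTable2x2   # a=group&1, b=group&0, c=contrast&1, d=contrast&0
    log_or: float                 # +-inf flagged, nan if non-estimable
    ci_low: float | None
    ci_high: float | None
    p_raw: float
    p_adjusted: float
    direction: str                # "over" / "under"
    significant: bool


def log_or_ci(
    table: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, float | None, float | None]:
    """Sample log odds ratio with a Woolf logit confidence interval.

    Returns ``(log_or, ci_low, ci_high)``. Zero cells trigger the
    Haldane–Anscombe correction for the interval; if the uncorrected OR is 0
    the lower bound is omitted (None), if infinite the upper bound is.
    """
    if table.n < 1:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    or_raw = table.odds_ratio()
    z = norm.ppf(0.5 + level / 2.0)
    if min(a, b, c, d) > 0:
        log_or = math.log(or_raw)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        return log_or, log_or - z * se, log_or + z * se
    # zero-cell handling: interval from the corrected table
    ac, bc_, cc, dc = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or_corr = math.log((ac * dc) / (bc_ * cc))
    se = math.sqrt(1 / ac + 1 / bc_ + 1 / cc + 1 / dc)
    low, high = log_or_corr - z * se, log_or_corr + z * se
    if math.isnan(or_raw):
        return math.nan, low, high
    if or_raw == 0.0:
        return -math.inf, None, high
    if math.isinf(or_raw):
        return math.inf, low, None
    return math.log(or_raw), low, high


def enrich(
    target_idx: Sequence[int],
    contrast_idx: Sequence[int],
    X: IndicatorMatrix,
    group_label: str = "target",
    alpha: float = 0.05,
    m: int | None = None,
) -> list[EnrichmentResult]:
    """Per-indicator enrichment of a target group against a contrast group.

    ``target_idx`` / ``contrast_idx`` are disjoint row indices into ``X``.
    Bonferroni correction defaults to the number of indicators tested here;
    pass ``m`` to correct over a wider family (e.g. clusters x indicators).
    """
    target_idx = np.asarray(target_idx, dtype=int)
    contrast_idx = np.asarray(contrast_idx, dtype=int)
    if target_idx.size == 0 or contrast_idx.size == 0:
        raise ValueError("target and contrast groups must be non-empty")
    if np.intersect1d(target_idx, contrast_idx).size > 0:
        raise ValueError("target and contrast groups overlap")

    G = np.asarray(X.values, dtype=np.int64)[target_idx]
    C = np.asarray(X.values, dtype=np.int64)[contrast_idx]
    n_tests = m if m is not None else len(X.indicator_ids)
    if n_tests < len(X.indicator_ids):
        raise ValueError("m must cover all indicators tested")

    results = []
    for j, ind in enumerate(X.indicator_ids):
        a = int(G[:, j].sum())
        b = G.shape[0] - a
        c = int(C[:, j].sum())
        d = C.shape[0] - c
        t = ContingencyTable2x2(a, b, c, d)
        p, or_value = fisher_exact_2x2(t)
        p_adj = min(1.0, n_tests * p)
        log_or, low, high = log_or_ci(t)
        direction = "over" if (or_value > 1 or math.isinf(or_value)) else "under"
        results.append(
            EnrichmentResult(
                indicator_id=ind,
                group_label=group_label,
                counts=t,
                log_or=log_or,
                ci_low=low,
                ci_high=high,
                p_raw=p,
                p_adjusted=p_adj,
                direction=direction,
                significant=p_adj < alpha,
            )
        )
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Forest-plot table of enrichment results."""
    return pd.DataFrame(
        [
            {
                "indicator": r.indicator_id,
                "group": r.group_label,
                "log_or": r.log_or,
                "ci_low": np.nan if r.ci_low is None else r.ci_low,
                "ci_high": np.nan if r.ci_high is None else r.ci_high,
                "p_raw": r.p_raw,
                "p_adj": r.p_adjusted,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def write_forest_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    enrichment_frame(results).to_csv(path, sep="\t", index=False)
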