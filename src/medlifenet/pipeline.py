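"""End-to-end pipeline: raw cohort CSV to scores, network, modules,
enrichments, clusters and regression, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import cluster_respondents, profile_clusters
from .communities import detect_communities
from .covariates import design_from_records, ols_fit, smoking_contrast
from .enrichment import enrich, write_forest_tsv
from .instrument import (
    InstrumentDefinition,
    default_instrument,
    encode_cohort,
    group_percentages,
    load_instrument,
    read_cohort_csv,
    score_matrix,
    stratify_quartiles,
)
from .svn import build_svn

logger = logging.getLogger("medlifenet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort_path: str
    out_dir: str
    instrument_path: str | None = None    # None -> bundled default instrument
    alpha: float = 0.05
    contrast: str = "other_extreme"       # or "rest"
    k: int | None = None                  # None -> silhouette-selected
    seed: int = 0
    delimiter: str = ","


def _structural_pairs(instrument: InstrumentDefinition) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    for it in instrument.tripartite_items:
        ids = it.indicator_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.add(frozenset((ids[i], ids[j])))
    return pairs


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle to ``out_dir``.

    Outputs: scores + group labels TSV, SVN edge TSV / GraphML / SIF, module
    partition TSV, extreme-group and per-cluster enrichment forest tables,
    regression summary, and a JSON manifest (versions, seed, alpha, number
    of tests, node/edge/module counts, input hash) that pins the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    instrument = (
        load_instrument(config.instrument_path)
        if config.instrument_path
        else default_instrument()
    )
    logger.info("stage=encode instrument=%s", instrument.version)
    records = read_cohort_csv(config.cohort_path, sep=config.delimiter)
    X = encode_cohort(instrument, records)
    X.to_tsv(out / "indicators.tsv")

    logger.info("stage=score n=%d", X.n)
    scores = score_matrix(instrument, X)
    groups = stratify_quartiles(scores)
    counts = {g: groups.count(g) for g in ("low", "intermediate", "high")}
    pd.DataFrame(
        {"respondent_id": X.respondent_ids, "score": scores, "group": groups}
    ).to_csv(out / "scores.tsv", sep="\t", index=False)

    logger.info("stage=svn alpha=%g", config.alpha)
    net = build_svn(X, alpha=config.alpha, structural_pairs=_structural_pairs(instrument))
    net.to_tsv(out / "edges.tsv")
    net.to_graphml(out / "network.graphml")
    net.to_sif(out / "network.sif")

    logger.info("stage=modules")
    partition = detect_communities(net, seed=config.seed)
    partition.to_tsv(out / "modules.tsv")
    with open(out / "modules.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "n_modules": partition.n_modules,
                "codelength_bits": partition.codelength,
                "modules": {str(k): v for k, v in partition.modules().items()},
            },
            fh,
            indent=2,
        )

    logger.info("stage=enrich contrast=%s", config.contrast)
    low_idx = [i for i, g in enumerate(groups) if g == "low"]
    high_idx = [i for i, g in enumerate(groups) if g == "high"]
    rest_of_high = [i for i in range(X.n) if i not in set(high_idx)]
    rest_of_low = [i for i in range(X.n) if i not in set(low_idx)]
    if config.contrast == "other_extreme":
        low_res = enrich(low_idx, high_idx, X, group_label="low", alpha=config.alpha)
        high_res = enrich(high_idx, low_idx, X, group_label="high", alpha=config.alpha)
    else:
        low_res = enrich(low_idx, rest_of_low, X, group_label="low", alpha=config.alpha)
        high_res = enrich(high_idx, rest_of_high, X, group_label="high", alpha=config.alpha)
    write_forest_tsv(low_res + high_res, out / "enrichment_extremes.tsv")

    logger.info("stage=cluster k=%s", config.k)
    assignment = cluster_respondents(X, k=config.k)
    assignment.to_tsv(out / "clusters.tsv")
    cluster_res = profile_clusters(assignment, X, alpha=config.alpha)
    write_forest_tsv(cluster_res, out / "enrichment_clusters.tsv")

    logger.info("stage=regress")
    design = design_from_records(records)
    reg = ols_fit(scores, design)
    reg.to_frame().rename_axis("term").to_csv(out / "regression.tsv", sep="\t")
    contrast = smoking_contrast(scores, design["smoking"].to_numpy())

    manifest = {
        "medlifenet_version": __version__,
        "instrument_version": instrument.version,
        "cohort_sha256": _sha256(config.cohort_path),
        "seed": config.seed,
        "alpha": config.alpha,
        "contrast": config.contrast,
        "n_respondents": X.n,
        "n_nodes": len(net.nodes),
        "n_excluded_degenerate": len(net.excluded_nodes),
        "m_tests": net.m,
        "n_edges": len(net.edges),
        "n_positive_edges": sum(e.sign == "positive" for e in net.edges),
        "n_negative_edges": sum(e.sign == "negative" for e in net.edges),
        "n_modules": partition.n_modules,
        "n_clusters": assignment.k,
        "group_counts": counts,
        "group_percent": group_percentages(counts),
        "score_mean": float(np.mean(scores)),
        "score_sd": float(np.std(scores, ddof=1)),
        "smoking_contrast": contrast,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", out)
    return manifest
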