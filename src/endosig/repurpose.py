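"""Proximity-based drug prioritization against CI-enriched clusters.

Every drug is scored against every CI-enriched cluster by network proximity
between its target genes and the cluster genes: d is the symmetrized mean
closest distance (mean of target->cluster and cluster->target; a
drug-to-cluster-only direction is available), similarity s = 1/(1+d).
Significance comes from an empirical null of 200 random (targets, cluster)
pairs matched in size and degree distribution, with the +1-corrected
empirical p-value (the small null would otherwise produce zero p-values and
break -log10 ranking downstream).  Within each disease, similarities are
min-max normalized, p-values BH-corrected, each drug keeps its lowest-FDR
cluster as the disease-level record, and pairs with FDR < 0.01 are the
predicted treatments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._stats import bh_adjust
from .cienrich import degree_matched_sample
from .cluster import Cluster
from .netio import DegreeIndex, DrugTargetMap, GeneNetwork
from .signature import closest_distance

logger = logging.getLogger(__name__)

__all__ = ["DrugPrediction", "drug_cluster_score", "normalize_and_call", "score_drugs_for_disease"]


@dataclass
class DrugPrediction:
    """One drug x cluster (or drug x disease, after assignment) record."""

    drug: str
    owner: str
    cluster_id: int
    similarity: float
    p: float
    similarity_normalized: float = field(default=float("nan"))
    fdr: float = field(default=float("nan"))
    is_predicted: bool = False


def _proximity(net: GeneNetwork, targets: Iterable[str], cluster_genes: Iterable[str], direction: str) -> float:
    if direction == "sym":
        return 0.5 * (
            closest_distance(net, targets, cluster_genes)
            + closest_distance(net, cluster_genes, targets)
        )
    if direction == "drug_to_disease":
        return closest_distance(net, targets, cluster_genes)
    raise ValueError(f"unknown direction {direction!r}")


def drug_cluster_score(
    net: GeneNetwork,
    drug: str,
    targets: Iterable[str],
    cluster: Cluster,
    index: DegreeIndex,
    n_null: int = 200,
    seed: int = 0,
    direction: str = "sym",
    min_candidates: int = 10,
) -> DrugPrediction | None:
    """Similarity and empirical p for one drug against one cluster.

    The null re-draws both the target set and the cluster gene set as
    degree-matched random sets of the same sizes, ``n_null`` times;
    p = (#{null s >= s} + 1)/(n_null + 1).  Drugs with no target on the
    network are skipped with a notice (returns None).
    """
    on_net = sorted(set(targets) & set(net.graph.nodes))
    if not on_net:
        logger.info("drug %s has no target on the network; skipped", drug)
        return None
    cluster_genes = sorted(cluster.genes.genes & frozenset(net.graph.nodes))
    if not cluster_genes:
        raise ValueError(f"cluster {cluster.key} has no genes on the network")
    s_obs = 1.0 / (1.0 + _proximity(net, on_net, cluster_genes, direction))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_null):
        rand_t = degree_matched_sample(on_net, index, rng, min_candidates)
        rand_c = degree_matched_sample(cluster_genes, index, rng, min_candidates)
        s_null = 1.0 / (1.0 + _proximity(net, rand_t, rand_c, direction))
        if s_null >= s_obs:
            exceed += 1
    p = (exceed + 1) / (n_null + 1)
    return DrugPrediction(drug, cluster.owner, cluster.cluster_id, s_obs, p)


def normalize_and_call(
    preds: Sequence[DrugPrediction],
    fdr_threshold: float = 0.01,
) -> list[DrugPrediction]:
    """Disease-level treatment calls from one disease's drug x cluster records.

    Min-max normalizes similarity within the disease (a single record, or all
    records tied, normalizes to 1.0), BH-corrects p-values within the
    disease, keeps each drug's lowest-FDR cluster (ties broken by higher
    normalized similarity, then cluster id), and flags FDR < threshold as
    predicted treatments.
    """
    preds = list(preds)
    if not preds:
        raise ValueError("no predictions for this disease")
    owners = {p.owner for p in preds}
    if len(owners) != 1:
        raise ValueError(f"normalize_and_call expects one disease, got {sorted(owners)}")
    sims = np.array([p.similarity for p in preds])
    lo, hi = sims.min(), sims.max()
    for pred, s in zip(preds, sims):
        pred.similarity_normalized = 1.0 if hi == lo else float((s - lo) / (hi - lo))
    for pred, fdr in zip(preds, bh_adjust([p.p for p in preds])):
        pred.fdr = float(fdr)
    best: dict[str, DrugPrediction] = {}
    for pred in preds:
        cur = best.get(pred.drug)
        if cur is None or (pred.fdr, -pred.similarity_normalized, pred.cluster_id) < (
            cur.fdr,
            -cur.similarity_normalized,
            cur.cluster_id,
        ):
            best[pred.drug] = pred
    out = []
    for drug in sorted(best):
        rec = best[drug]
        rec.is_predicted = bool(rec.fdr < fdr_threshold)
        out.append(rec)
    return out


def score_drugs_for_disease(
    net: GeneNetwork,
    drugs: DrugTargetMap,
    enriched_clusters: Sequence[Cluster],
    index: DegreeIndex,
    n_null: int = 200,
    seed: int = 0,
    fdr_threshold: float = 0.01,
    direction: str = "sym",
) -> list[DrugPrediction]:
    """Convenience: score every drug against every CI-enriched cluster of one
    disease and reduce to disease-level calls."""
    if not enriched_clusters:
        raise ValueError("no CI-enriched clusters for this disease")
    rng = np.random.default_rng(seed)
    pair_seeds = rng.integers(0, 2**31 - 1, size=len(drugs.targets) * len(enriched_clusters))
    preds: list[DrugPrediction] = []
    i = 0
    for drug in sorted(drugs.targets):
        for clu in enriched_clusters:
            pred = drug_cluster_score(
                net, drug, drugs.targets[drug], clu, index,
                n_null=n_null, seed=int(pair_seeds[i]), direction=direction,
            )
            i += 1
            if pred is not None:
                preds.append(pred)
    return normalize_and_call(preds, fdr_threshold)
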