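"""Cross-disease comparison and grouping of CI-enriched clusters.

Cluster-cluster proximity is the mean closest-gene shortest-path distance,
d(A,B) = mean over a in A of min over b in B of sp(a, b), converted to a
similarity s = 1/(1+d).  Because the two directions differ, each direction
gets its own empirical p-value against degree-matched random set pairs, the
two one-sided p-values are combined with Stouffer's method, and similarities
are averaged.  Significant pairs (BH across pairs) form a cluster-level
graph that is Leiden-partitioned into signature groups; each group is then
characterized by over-representation of its group-unique genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np

from ._stats import bh_adjust, stouffer_combine
from .cienrich import degree_matched_sample
from .cluster import AnnotationEnrichment, Cluster, annotate_cluster_sets
from .netio import DegreeIndex, GeneNetwork, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityRecord",
    "SignatureGroup",
    "closest_distance",
    "cluster_similarity",
    "group_signatures",
    "characterize_groups",
]


@dataclass
class SimilarityRecord:
    """Directional proximities and the combined evidence for one cluster pair."""

    cluster_a: Cluster
    cluster_b: Cluster
    d_ab: float
    d_ba: float
    s_ab: float
    s_ba: float
    p_ab: float
    p_ba: float
    p_combined: float
    s_mean: float
    fdr: float = field(default=float("nan"))


@dataclass
class SignatureGroup:
    """A group of similar CI-enriched clusters across diseases."""

    group_id: int
    members: list[Cluster]
    union_genes: GeneSet
    unique_genes: GeneSet


def _restrict(net: GeneNetwork, genes) -> list[str]:
    pool = genes.genes if isinstance(genes, GeneSet) else set(genes)
    present = sorted(pool & set(net.graph.nodes))
    if not present:
        raise ValueError("gene set has no members on the network")
    return present


def closest_distance(
    net: GeneNetwork,
    a,
    b,
    unreachable_penalty: float | None = None,
) -> float:
    """Mean over genes of A of the unweighted distance to the closest gene of B.

    Unreachable (cross-component) contributions enter with a finite penalty
    D+1, where D is the largest finite shortest-path distance in the network;
    dropping them would silently bias the mean downward.
    """
    genes_a = _restrict(net, a)
    genes_b = _restrict(net, b)
    dist = net.distance_matrix()
    idx = net.node_index
    sub = dist[np.ix_([idx[g] for g in genes_a], [idx[g] for g in genes_b])]
    mins = sub.min(axis=1)
    if np.isinf(mins).any():
        if unreachable_penalty is None:
            unreachable_penalty = net.max_finite_distance() + 1.0
        mins = np.where(np.isinf(mins), unreachable_penalty, mins)
    return float(mins.mean())


def _similarity(d: float) -> float:
    return 1.0 / (1.0 + d)


def cluster_similarity(
    net: GeneNetwork,
    cluster_a: Cluster,
    cluster_b: Cluster,
    index: DegreeIndex,
    n_null: int = 1000,
    seed: int = 0,
    min_candidates: int = 10,
) -> SimilarityRecord:
    """Directional similarities with degree-matched empirical p-values.

    The null draws ``n_null`` random set pairs preserving the size and degree
    multiset of each cluster; per direction p = (#{null s >= s} + 1)/(n_null
    + 1), then Stouffer-combined.
    """
    if n_null < 20:
        raise ValueError("n_null < 20 gives too coarse a null")
    genes_a = _restrict(net, cluster_a.genes)
    genes_b = _restrict(net, cluster_b.genes)
    d_ab = closest_distance(net, genes_a, genes_b)
    d_ba = closest_distance(net, genes_b, genes_a)
    s_ab, s_ba = _similarity(d_ab), _similarity(d_ba)

    rng = np.random.default_rng(seed)
    exceed_ab = exceed_ba = 0
    for _ in range(n_null):
        rand_a = degree_matched_sample(genes_a, index, rng, min_candidates)
        rand_b = degree_matched_sample(genes_b, index, rng, min_candidates)
        if _similarity(closest_distance(net, rand_a, rand_b)) >= s_ab:
            exceed_ab += 1
        if _similarity(closest_distance(net, rand_b, rand_a)) >= s_ba:
            exceed_ba += 1
    p_ab = (exceed_ab + 1) / (n_null + 1)
    p_ba = (exceed_ba + 1) / (n_null + 1)
    return SimilarityRecord(
        cluster_a,
        cluster_b,
        d_ab,
        d_ba,
        s_ab,
        s_ba,
        p_ab,
        p_ba,
        stouffer_combine(p_ab, p_ba),
        (s_ab + s_ba) / 2.0,
    )


def group_signatures(
    records: Sequence[SimilarityRecord],
    alpha: float = 0.05,
    seed: int = 0,
    leiden_iterations: int = 100,
) -> list[SignatureGroup]:
    """Group clusters whose pairwise similarity is significant.

    BH-adjusts the combined p-values across all pairs, builds a cluster-level
    graph with an s_mean-weighted edge for every pair with FDR < ``alpha``,
    and Leiden-partitions it.  With no significant pair every cluster becomes
    its own singleton group.  Group ids are ordered by decreasing size.
    """
    if not records:
        raise ValueError("no similarity records")
    clusters: dict[tuple[str, int], Cluster] = {}
    for rec in records:
        clusters[rec.cluster_a.key] = rec.cluster_a
        clusters[rec.cluster_b.key] = rec.cluster_b
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to group")
    fdrs = bh_adjust([r.p_combined for r in records])
    for rec, fdr in zip(records, fdrs):
        rec.fdr = float(fdr)
    keys = sorted(clusters)
    key_index = {k: i for i, k in enumerate(keys)}
    edges, weights = [], []
    for rec in records:
        if rec.fdr < alpha:
            edges.append((key_index[rec.cluster_a.key], key_index[rec.cluster_b.key]))
            weights.append(rec.s_mean)
    if not edges:
        logger.info("no significant cluster pair; every cluster is a singleton group")
    g = ig.Graph(n=len(keys), edges=edges, directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.ModularityVertexPartition,
        weights=weights or None,
        n_iterations=leiden_iterations,
        seed=seed,
    )
    members_of: dict[int, list[Cluster]] = {}
    for vertex, community in enumerate(part.membership):
        members_of.setdefault(community, []).append(clusters[keys[vertex]])
    ordered = sorted(members_of.values(), key=lambda ms: (-len(ms), ms[0].key))
    unions = [frozenset().union(*(m.genes.genes for m in ms)) for ms in ordered]
    groups = []
    for gid, (ms, union) in enumerate(zip(ordered, unions)):
        others = frozenset().union(*(u for j, u in enumerate(unions) if j != gid)) if len(unions) > 1 else frozenset()
        groups.append(
            SignatureGroup(
                gid,
                ms,
                GeneSet(f"group{gid}|union", genes=union),
                GeneSet(f"group{gid}|unique", genes=union - others),
            )
        )
    return groups


def characterize_groups(
    groups: Sequence[SignatureGroup],
    annotations: Sequence[GeneSet],
    background: int,
    network_genes=None,
    min_set_size: int = 5,
    max_set_size: int = 100,
) -> list[AnnotationEnrichment]:
    """Over-representation of annotation sets among each group's unique genes,
    BH-corrected across annotations within each group.  Groups with an empty
    unique set are skipped with a notice."""
    out: list[AnnotationEnrichment] = []
    for group in groups:
        if len(group.unique_genes) == 0:
            logger.info("group %d has no unique genes; skipped", group.group_id)
            continue
        pseudo = Cluster(f"group{group.group_id}", group.group_id, group.unique_genes)
        results = annotate_cluster_sets(
            pseudo, annotations, background, network_genes, min_set_size, max_set_size
        )
        for res in results:
            res.cluster_key = f"group{group.group_id}"
        out.extend(results)
    return out
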