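"""Partition disease-/trait-specific subnetworks and annotate the clusters.

Communities are found with the Leiden algorithm optimising plain modularity
(``ModularityVertexPartition``), run for a fixed number of iterations with an
explicit seed so partitions are reproducible.  Cluster annotation against
arbitrary gene-set collections uses a one-sided hypergeometric
over-representation test with Benjamini-Hochberg correction across the
annotation sets of each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import leidenalg

from ._stats import bh_adjust, hypergeom_sf
from .netio import GeneNetwork, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "AnnotationEnrichment",
    "partition_leiden",
    "filter_clusters",
    "annotate_cluster",
    "annotate_cluster_sets",
]


@dataclass
class Cluster:
    """One partition element of an owner's subnetwork."""

    owner: str
    cluster_id: int
    genes: GeneSet

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def key(self) -> tuple[str, int]:
        return (self.owner, self.cluster_id)


@dataclass
class AnnotationEnrichment:
    """Over-representation of one annotation set in one cluster (or group)."""

    cluster_key: tuple[str, int] | str
    annotation_id: str
    overlap: int
    fold_enrichment: float
    p: float
    fdr: float = field(default=float("nan"))


def partition_leiden(
    subnet: GeneNetwork,
    iterations: int = 100,
    seed: int = 0,
    use_weights: bool = True,
) -> list[Cluster]:
    """Leiden modularity partition of a subnetwork.

    Isolated nodes become singleton clusters.  Cluster ids are assigned
    deterministically: decreasing size, ties broken by smallest member gene.
    ``use_weights`` controls whether stored edge weights enter the modularity
    objective (degrees and shortest paths elsewhere never use them).
    """
    if subnet.n_nodes == 0:
        return []
    g = subnet.to_igraph()
    weights = "weight" if (use_weights and subnet.is_weighted) else None
    part = leidenalg.find_partition(
        g,
        leidenalg.ModularityVertexPartition,
        weights=weights,
        n_iterations=iterations,
        seed=seed,
    )
    names = g.vs["name"]
    members: dict[int, set] = {}
    for vertex, community in enumerate(part.membership):
        members.setdefault(community, set()).add(names[vertex])
    ordered = sorted(members.values(), key=lambda s: (-len(s), min(s)))
    return [
        Cluster(subnet.name, i, GeneSet(f"{subnet.name}|c{i}", genes=frozenset(s)))
        for i, s in enumerate(ordered)
    ]


def filter_clusters(clusters: Sequence[Cluster], min_size: int = 5) -> list[Cluster]:
    """Keep clusters with at least ``min_size`` genes, preserving order."""
    return [c for c in clusters if c.size >= min_size]


def annotate_cluster(
    cluster: Cluster,
    annotation: GeneSet,
    background: int,
    network_genes: Iterable[str] | None = None,
) -> AnnotationEnrichment | None:
    """One-sided hypergeometric over-representation of one annotation set.

    ``background`` is the number of genes in the clustering network; the
    annotation is restricted to ``network_genes`` when provided.  Annotations
    with no gene on the network are skipped (returns None with a notice).
    """
    if background <= 0:
        raise ValueError("background must be positive")
    ann_genes = annotation.genes
    if network_genes is not None:
        ann_genes = ann_genes & frozenset(network_genes)
    n_ann = len(ann_genes)
    if n_ann == 0:
        logger.info("annotation %s has no genes on the network; skipped", annotation.id)
        return None
    if background < cluster.size or background < n_ann:
        raise ValueError("background smaller than cluster or annotation")
    overlap = len(cluster.genes.genes & ann_genes)
    p = hypergeom_sf(overlap, background, n_ann, cluster.size)
    fold = (overlap / cluster.size) / (n_ann / background)
    return AnnotationEnrichment(cluster.key, annotation.id, overlap, fold, p)


def annotate_cluster_sets(
    cluster: Cluster,
    annotations: Sequence[GeneSet],
    background: int,
    network_genes: Iterable[str] | None = None,
    min_set_size: int = 5,
    max_set_size: int = 100,
) -> list[AnnotationEnrichment]:
    """Annotate one cluster against a collection, with BH across annotations.

    Annotation sets outside the [min_set_size, max_set_size] bounds (counted
    on the network when ``network_genes`` is given) are excluded before
    testing, so the correction family only contains testable sets.
    """
    results = []
    for ann in annotations:
        genes = ann.genes
        if network_genes is not None:
            genes = genes & frozenset(network_genes)
        if not (min_set_size <= len(genes) <= max_set_size):
            continue
        res = annotate_cluster(cluster, ann, background, network_genes)
        if res is not None:
            results.append(res)
    if results:
        for res, fdr in zip(results, bh_adjust([r.p for r in results])):
            res.fdr = float(fdr)
    return results
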