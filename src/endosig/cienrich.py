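"""Chronic-inflammation enrichment of clusters against a degree-matched null.

This is the pipeline's core statistic.  For each owner (disease or trait),
random gene lists matching the degree distribution of the owner's final gene
list are repeatedly clustered; the enrichment score of every random cluster
with >= 5 genes forms the empirical null.  The observed score of a real
cluster,

    E = log2( (|CG ∩ CI| / |CG|) / (|CI| / background) ),

is compared against that pooled null to obtain a permutation p-value

    p = #(null scores >= E) / (n + 1),

where n is the number of random clusters pooled over all random lists.  Note
the numerator carries no pseudo-count, so p can be exactly 0; pass
``pseudo_count=True`` for the conventional (1 + #exceedances)/(n + 1)
variant.  p-values are BH-corrected within an owner, and clusters with
FDR < 0.05 and E > 0 are called CI-enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._stats import bh_adjust, fisher_one_sided
from .cluster import Cluster
from .netio import DegreeIndex, GeneNetwork, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsemble",
    "EnrichmentResult",
    "ContrastResult",
    "degree_matched_sample",
    "build_null_ensemble",
    "enrichment_score",
    "permutation_pvalue",
    "randomized_permutation_pvalue",
    "call_ci_clusters",
    "unannotated_ci_probability_contrast",
]

NEG_INF = float("-inf")


@dataclass
class NullEnsemble:
    """Pooled enrichment scores of all qualifying random-trait clusters."""

    owner: str
    n_lists: int
    null_cluster_scores: np.ndarray
    n_random_clusters: int

    @property
    def is_empty(self) -> bool:
        return self.n_random_clusters == 0


@dataclass
class EnrichmentResult:
    """CI-enrichment of one cluster: E, permutation p, FDR, and the call."""

    cluster: Cluster
    E: float
    p: float
    fdr: float = field(default=float("nan"))
    is_ci_enriched: bool = False
    n_null_clusters: int = 0


@dataclass
class ContrastResult:
    """CI-probability contrast of unannotated genes across cluster calls."""

    mean_enriched: float
    mean_non_enriched: float
    p_ranksum: float
    p_fisher: float
    n_enriched_genes: int
    n_non_enriched_genes: int


def degree_matched_sample(
    genes: Iterable[str],
    index: DegreeIndex,
    rng: np.random.Generator,
    min_candidates: int = 10,
) -> set[str]:
    """Replace every gene by a random gene of equal (or near-equal) degree.

    Each gene is replaced independently by a uniform draw from the genes at
    its degree; when fewer than ``min_candidates`` genes share that degree,
    the candidate pool is widened symmetrically over neighbouring occupied
    degrees.  The output has the same size as the input (duplicates are
    resolved by redrawing, widening the pool if necessary).
    """
    chosen: set[str] = set()
    for gene in sorted(set(genes)):
        degree = index.degree_of[gene]
        k = max(1, min_candidates)
        pool = index.candidate_pool(degree, k)
        attempts = 0
        while True:
            cand = pool[int(rng.integers(len(pool)))]
            if cand not in chosen:
                chosen.add(cand)
                break
            attempts += 1
            if attempts >= 4 * len(pool):
                if len(pool) >= len(index.degree_of):
                    raise RuntimeError("cannot draw enough distinct genes")
                k *= 2
                pool = index.candidate_pool(degree, k)
                attempts = 0
    return chosen


def enrichment_score(
    cluster_genes: Iterable[str] | GeneSet,
    ci: Iterable[str] | GeneSet,
    background: int,
) -> float:
    """E = log2 of the cluster's CI fraction over the background CI fraction.

    Zero overlap yields -inf (the cluster contains no CI gene at all).
    ``ci`` must already be restricted to the clustering network whose size
    is ``background``.
    """
    cg = set(cluster_genes.genes if isinstance(cluster_genes, GeneSet) else cluster_genes)
    ci_set = set(ci.genes if isinstance(ci, GeneSet) else ci)
    if background <= 0:
        raise ValueError("background must be positive")
    if not ci_set:
        raise ValueError("CI gene set is empty on the network")
    if not cg:
        raise ValueError("cluster is empty")
    if len(ci_set) > background:
        raise ValueError("CI set larger than background")
    overlap = len(cg & ci_set)
    if overlap == 0:
        return NEG_INF
    return float(np.log2((overlap / len(cg)) / (len(ci_set) / background)))


def permutation_pvalue(
    E_obs: float,
    null_scores: Sequence[float] | np.ndarray,
    pseudo_count: bool = False,
) -> float:
    """Empirical permutation p-value against pooled null cluster scores.

    Verbatim convention: p = #(null >= E_obs) / (n + 1), which can return 0
    when nothing in the null reaches the observed score.  With
    ``pseudo_count=True`` the numerator gains the conventional +1.  An
    observed score of -inf counts every null score as an exceedance.
    """
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("null_scores must be nonempty")
    exceed = int(np.count_nonzero(null >= E_obs))
    if pseudo_count:
        exceed += 1
    return exceed / (null.size + 1)


def randomized_permutation_pvalue(
    E_obs: float,
    null_scores: Sequence[float] | np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Tie-randomized permutation p-value, exactly uniform under the null.

    The pooled enrichment scores are heavily tied (many random clusters share
    the same overlap counts, and zero-overlap clusters all score -inf), so
    the plain empirical p-value is discrete and conservative.  For
    calibration diagnostics this variant breaks ties uniformly:
    p = (#{null > E} + U * (#{null == E} + 1)) / (n + 1), U ~ Uniform(0,1).
    """
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("null_scores must be nonempty")
    greater = int(np.count_nonzero(null > E_obs))
    ties = int(np.count_nonzero(null == E_obs))
    return (greater + float(rng.uniform()) * (ties + 1)) / (null.size + 1)


def build_null_ensemble(
    disease_genes: Iterable[str] | GeneSet,
    net: GeneNetwork,
    index: DegreeIndex,
    ci: Iterable[str] | GeneSet,
    n_lists: int = 5000,
    min_size: int = 5,
    seed: int = 0,
    leiden_iterations: int = 100,
    min_candidates: int = 10,
    use_weights: bool = True,
) -> NullEnsemble:
    """Cluster ``n_lists`` degree-matched random lists and pool their scores.

    Each random list is induced on the network, Leiden-partitioned exactly
    like a real owner, filtered to clusters of >= ``min_size`` genes, and the
    enrichment score of every surviving cluster (including zero-overlap
    clusters, which score -inf) is accumulated into one pooled null.
    """
    if n_lists <= 0:
        raise ValueError("n_lists must be positive (cannot form a null)")
    genes = set(disease_genes.genes if isinstance(disease_genes, GeneSet) else disease_genes)
    genes &= set(net.graph.nodes)
    if not genes:
        raise ValueError("no disease genes on the network")
    ci_set = set(ci.genes if isinstance(ci, GeneSet) else ci) & set(net.graph.nodes)
    if not ci_set:
        raise ValueError("CI gene set is empty on the network")
    background = net.n_nodes
    ci_frac = len(ci_set) / background

    g = net.to_igraph()
    node_index = net.node_index
    weights_attr = "weight" if (use_weights and net.is_weighted) else None

    rng = np.random.default_rng(seed)
    leiden_seeds = rng.integers(0, 2**31 - 1, size=n_lists)

    import leidenalg

    scores: list[np.ndarray] = []
    n_clusters = 0
    for i in range(n_lists):
        sample = degree_matched_sample(genes, index, rng, min_candidates=min_candidates)
        idx = [node_index[x] for x in sample]
        sub = g.induced_subgraph(idx)
        part = leidenalg.find_partition(
            sub,
            leidenalg.ModularityVertexPartition,
            weights=weights_attr if weights_attr and sub.ecount() else None,
            n_iterations=leiden_iterations,
            seed=int(leiden_seeds[i]),
        )
        membership = np.asarray(part.membership)
        sizes = np.bincount(membership)
        # vertex order of the subgraph differs from `idx`; map via names
        sub_ci = np.fromiter((v in ci_set for v in sub.vs["name"]), dtype=bool, count=sub.vcount())
        overlaps = np.bincount(membership, weights=sub_ci.astype(float)).astype(int)
        keep = sizes >= min_size
        if not keep.any():
            continue
        sz = sizes[keep].astype(float)
        ov = overlaps[keep].astype(float)
        with np.errstate(divide="ignore"):
            e = np.where(ov > 0, np.log2((ov / sz) / ci_frac), NEG_INF)
        scores.append(e)
        n_clusters += int(keep.sum())

    pooled = np.concatenate(scores) if scores else np.empty(0)
    if n_clusters == 0:
        logger.warning(
            "owner %s: no random list produced a cluster with >=%d genes; "
            "owner must be excluded from the enrichment analysis",
            getattr(disease_genes, "id", "?"),
            min_size,
        )
    return NullEnsemble(getattr(disease_genes, "id", "?"), n_lists, pooled, n_clusters)


def call_ci_clusters(
    results: Sequence[EnrichmentResult],
    alpha: float = 0.05,
    pseudo_count: bool = False,  # noqa: ARG001 - recorded by callers, not used here
) -> list[EnrichmentResult]:
    """BH-correct permutation p-values within one owner and set the calls.

    A cluster is CI-enriched iff FDR < ``alpha`` and E > 0; the E > 0
    condition guards against calling depleted or untouched clusters whose
    p-value happens to be small in a degenerate null.
    """
    results = list(results)
    if not results:
        return []
    owners = {r.cluster.owner for r in results}
    if len(owners) != 1:
        raise ValueError(f"call_ci_clusters expects one owner, got {sorted(owners)}")
    fdrs = bh_adjust([r.p for r in results])
    for res, fdr in zip(results, fdrs):
        res.fdr = float(fdr)
        res.is_ci_enriched = bool(res.fdr < alpha and res.E > 0)
    return results


def unannotated_ci_probability_contrast(
    results: Sequence[EnrichmentResult],
    ci: Iterable[str] | GeneSet,
    ci_scores: Mapping[str, float],
) -> ContrastResult:
    """Contrast CI-model probabilities of unannotated genes across calls.

    Restricting to cluster genes absent from the CI gene set, compares the
    CI-association probabilities (from the CI expansion model) of genes in
    CI-enriched clusters against those in non-enriched clusters.  Reports a
    one-sided rank-sum p (enriched greater) and, as a cruder companion, a
    one-sided Fisher's exact p on the 2x2 of (above/below the pooled median
    probability) x (enriched/non-enriched cluster).
    """
    ci_set = set(ci.genes if isinstance(ci, GeneSet) else ci)
    enriched: list[float] = []
    non_enriched: list[float] = []
    for res in results:
        bucket = enriched if res.is_ci_enriched else non_enriched
        for gene in res.cluster.genes.genes:
            if gene not in ci_set and gene in ci_scores:
                bucket.append(float(ci_scores[gene]))
    if not enriched:
        raise ValueError("no unannotated genes in CI-enriched clusters")
    if not non_enriched:
        raise ValueError("no unannotated genes in non-enriched clusters")
    a = np.asarray(enriched)
    b = np.asarray(non_enriched)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        p_rank = 1.0  # degenerate: identical constant scores carry no signal
    else:
        p_rank = float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
    median = float(np.median(np.concatenate([a, b])))
    table = [
        [int(np.sum(a > median)), int(np.sum(a <= median))],
        [int(np.sum(b > median)), int(np.sum(b <= median))],
    ]
    p_fisher = fisher_one_sided(table)
    return ContrastResult(float(a.mean()), float(b.mean()), p_rank, p_fisher, a.size, b.size)
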