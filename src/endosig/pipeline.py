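"""End-to-end orchestration: seeds -> expansion -> clusters -> CI calls.

These helpers wire the stage modules together the way a full study runs
them, one owner (disease or trait) at a time:

1. negative selection against the annotation universe;
2. cross-validated qualification of the seed set (>= 15 network genes,
   median log2(auPRC/prior) >= 1) -- owners failing the gate are excluded;
3. network-feature expansion at probability >= 0.80;
4. induced subnetwork, Leiden partition, >= 5-gene cluster filter;
5. degree-matched null ensemble, enrichment scores, permutation p-values,
   BH within owner, CI calls (FDR < 0.05 and E > 0).

An owner can drop out at several points (no negatives, failed gate, no
sizable cluster, empty null); the reason is recorded rather than raised so a
scenario-wide sweep always completes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cienrich import (
    EnrichmentResult,
    NullEnsemble,
    build_null_ensemble,
    call_ci_clusters,
    enrichment_score,
    permutation_pvalue,
)
from .cluster import Cluster, filter_clusters, partition_leiden
from .expand import (
    CVReport,
    ExpansionModel,
    cross_validate,
    expand_gene_set,
    qualify_gene_set,
    select_negatives,
    train_expansion_model,
)
from .netio import DegreeIndex, GeneNetwork, GeneSet, build_degree_index, induced_subgraph
from .synthdata import Scenario

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "OwnerAnalysis", "ScenarioAnalysis", "expand_ci_genes", "analyze_owner", "run_scenario_analysis"]


@dataclass
class PipelineParams:
    """Tunable parameters of the owner-level pipeline (defaults = study)."""

    reg: float = 1.0
    cv_folds: int = 3
    expansion_threshold: float = 0.80
    min_qualifying_genes: int = 15
    min_median_score: float = 1.0
    min_cluster_size: int = 5
    leiden_iterations: int = 100
    n_null_lists: int = 5000
    ci_fdr_alpha: float = 0.05
    pseudo_count: bool = False
    min_degree_candidates: int = 10
    use_weights: bool = True
    apply_gate: bool = True


@dataclass
class OwnerAnalysis:
    """Everything the pipeline derived for one disease or trait."""

    owner: str
    seeds: GeneSet
    cv: CVReport | None = None
    qualified: bool = False
    excluded_reason: str | None = None
    model: ExpansionModel | None = None
    genes: GeneSet | None = None
    probabilities: dict[str, float] = field(default_factory=dict)
    clusters: list[Cluster] = field(default_factory=list)
    null: NullEnsemble | None = None
    results: list[EnrichmentResult] = field(default_factory=list)

    @property
    def enriched_clusters(self) -> list[Cluster]:
        return [r.cluster for r in self.results if r.is_ci_enriched]

    @property
    def has_ci_call(self) -> bool:
        return any(r.is_ci_enriched for r in self.results)

    @property
    def fraction_predicted(self) -> float:
        """Fraction of the final gene list contributed by the model."""
        if self.genes is None or len(self.genes) == 0:
            return 0.0
        return 1.0 - len(self.seeds.genes & self.genes.genes) / len(self.genes)


@dataclass
class ScenarioAnalysis:
    """Scenario-wide results, keyed by owner name."""

    ci_expanded: GeneSet
    ci_model: ExpansionModel | None
    ci_probabilities: dict[str, float]
    owners: dict[str, OwnerAnalysis]

    def called_owners(self) -> list[str]:
        return sorted(o for o, a in self.owners.items() if a.has_ci_call)


def expand_ci_genes(
    net: GeneNetwork,
    ci_seeds: GeneSet,
    annotations: dict[str, GeneSet],
    params: PipelineParams,
    seed: int = 0,
) -> tuple[GeneSet, ExpansionModel | None, dict[str, float]]:
    """Expand the CI gene list itself with the same machinery.

    Negatives come from annotation sets that do not significantly overlap the
    CI seeds.  If negative selection or training is impossible the seeds are
    used as-is (the pipeline can run with an unexpanded CI list).
    """
    try:
        negatives = select_negatives(ci_seeds, annotations, net)
        model = train_expansion_model(net, ci_seeds, negatives, reg=params.reg, seed=seed)
        expanded, probs = expand_gene_set(model, net, ci_seeds, params.expansion_threshold)
        return expanded, model, probs
    except ValueError as exc:
        logger.warning("CI expansion unavailable (%s); using seed CI genes", exc)
        return ci_seeds, None, {}


def analyze_owner(
    net: GeneNetwork,
    index: DegreeIndex,
    seeds: GeneSet,
    annotations: dict[str, GeneSet],
    ci: GeneSet,
    params: PipelineParams,
    seed: int = 0,
) -> OwnerAnalysis:
    """Run the per-owner pipeline; never raises for data-driven exclusions."""
    analysis = OwnerAnalysis(owner=seeds.id, seeds=seeds)
    own_annotations = {k: v for k, v in annotations.items() if k != seeds.id}
    try:
        negatives = select_negatives(seeds, own_annotations, net)
    except ValueError as exc:
        analysis.excluded_reason = f"no_negatives: {exc}"
        return analysis
    try:
        analysis.cv = cross_validate(
            net, seeds, negatives, k=params.cv_folds, reg=params.reg, seed=seed
        )
    except ValueError as exc:
        analysis.excluded_reason = f"cv_failed: {exc}"
        return analysis
    analysis.qualified = qualify_gene_set(
        seeds, analysis.cv, params.min_qualifying_genes, params.min_median_score
    )
    if params.apply_gate and not analysis.qualified:
        analysis.excluded_reason = "failed_qualification"
        return analysis
    analysis.model = train_expansion_model(net, seeds, negatives, reg=params.reg, seed=seed)
    analysis.genes, analysis.probabilities = expand_gene_set(
        analysis.model, net, seeds, params.expansion_threshold
    )
    subnet = induced_subgraph(net, analysis.genes, name=seeds.id)
    clusters = partition_leiden(
        subnet, iterations=params.leiden_iterations, seed=seed, use_weights=params.use_weights
    )
    analysis.clusters = filter_clusters(clusters, params.min_cluster_size)
    if not analysis.clusters:
        analysis.excluded_reason = "no_cluster_of_min_size"
        return analysis
    analysis.null = build_null_ensemble(
        analysis.genes,
        net,
        index,
        ci,
        n_lists=params.n_null_lists,
        min_size=params.min_cluster_size,
        seed=seed,
        leiden_iterations=params.leiden_iterations,
        min_candidates=params.min_degree_candidates,
        use_weights=params.use_weights,
    )
    if analysis.null.is_empty:
        analysis.excluded_reason = "no_null_clusters"
        return analysis
    background = net.n_nodes
    ci_on_net = ci.genes & frozenset(net.graph.nodes)
    results = []
    for clu in analysis.clusters:
        e = enrichment_score(clu.genes, ci_on_net, background)
        p = permutation_pvalue(e, analysis.null.null_cluster_scores, params.pseudo_count)
        results.append(
            EnrichmentResult(clu, e, p, n_null_clusters=analysis.null.n_random_clusters)
        )
    analysis.results = call_ci_clusters(results, params.ci_fdr_alpha)
    return analysis


def run_scenario_analysis(
    scenario: Scenario,
    params: PipelineParams | None = None,
    seed: int = 0,
    include_diseases: bool = True,
    include_traits: bool = True,
) -> ScenarioAnalysis:
    """Full CI-signature analysis of one synthetic scenario.

    Owner-level seeds are drawn from one RNG stream in sorted owner order,
    so the analysis of each owner is reproducible independently of which
    owners are included.
    """
    params = params or PipelineParams()
    net = scenario.network
    index = build_degree_index(net)
    rng = np.random.default_rng(seed)
    ci_seed = int(rng.integers(2**31 - 1))
    ci_expanded, ci_model, ci_probs = expand_ci_genes(
        net, scenario.ci_genes, scenario.all_disease_annotations, params, ci_seed
    )
    owners: dict[str, OwnerAnalysis] = {}
    pool: dict[str, GeneSet] = {}
    if include_diseases:
        pool.update(scenario.disease_seeds)
    if include_traits:
        pool.update(scenario.trait_seeds)
    owner_seeds = {name: int(s) for name, s in zip(sorted(pool), rng.integers(2**31 - 1, size=len(pool)))}
    for name in sorted(pool):
        owners[name] = analyze_owner(
            net,
            index,
            pool[name],
            scenario.all_disease_annotations,
            ci_expanded,
            params,
            seed=owner_seeds[name],
        )
    return ScenarioAnalysis(ci_expanded, ci_model, ci_probs, owners)
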