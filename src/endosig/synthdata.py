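"""Synthetic scenarios with planted chronic-inflammation structure.

The generator emulates the statistical regimes the analysis assumes, so that
every downstream stage can be exercised and scored without any database
downloads:

* the interactome is a planted-partition (stochastic block model) graph --
  genes fall into equal-size blocks, with dense within-block and sparse
  between-block wiring;
* a CI gene set concentrated in designated "CI blocks";
* "disease-like" seed sets drawing a fixed fraction of their genes from the
  CI blocks (modular, like autoimmune-disease annotations);
* "trait-like" seed sets drawn degree-matched at random (realistic hubness,
  no block coherence, like GWAS genes of non-disease traits);
* an annotation universe of additional disease-like sets concentrated in
  non-CI blocks (the negative-selection pool);
* drugs whose targets sit inside the CI blocks or at degree-matched random
  positions, with an indications table marking CI-targeting drugs as trial
  positives for every CI-planted disease (ground truth for evaluation).

Everything is driven by a single RNG stream seeded from ``rng_seed`` and
consumed in a fixed order (interactome, CI genes, disease seeds, trait seeds,
annotation sets, drugs), so a scenario regenerates byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .cienrich import degree_matched_sample
from .netio import (
    DegreeIndex,
    DrugTargetMap,
    GeneNetwork,
    GeneSet,
    IndicationTable,
    build_degree_index,
    write_drug_targets,
    write_gmt,
    write_indications,
    write_network,
)

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "default_scenario_config",
    "generate_interactome",
    "generate_disease_seeds",
    "generate_trait_seeds",
    "generate_drugs",
    "generate_scenario",
    "write_scenario",
]

CI_DRUG_CLASS = "antiinflammatory"
OTHER_DRUG_CLASS = "unrelated"


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario."""

    n_genes: int = 2000
    n_blocks: int = 20
    p_within: float = 0.15
    p_between: float = 0.004
    ci_blocks: tuple[int, ...] = (0, 1)
    n_ci_genes: int = 80
    # (name, n_seed_genes, fraction_from_ci_blocks, fraction_from_other_blocks)
    disease_specs: list[tuple[str, int, float, float]] = field(default_factory=list)
    # (name, n_seed_genes)
    trait_specs: list[tuple[str, int]] = field(default_factory=list)
    # (drug_id, n_targets, placement in {"ci_module", "random"})
    drug_specs: list[tuple[str, int, str]] = field(default_factory=list)
    # annotation universe of non-inflammatory disease-like sets (negatives pool)
    n_extra_annotations: int = 15
    extra_annotation_size: int = 60
    extra_annotation_concentration: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        # degenerate regimes (p_between = 0, or = p_within) are allowed for testing
        if not (0 <= self.p_between <= self.p_within <= 1) or self.p_within == 0:
            raise ValueError("need 0 <= p_between <= p_within <= 1 with p_within > 0")
        if any(b < 0 or b >= self.n_blocks for b in self.ci_blocks):
            raise ValueError("ci_blocks must lie in [0, n_blocks)")
        if self.n_genes <= 0 or self.n_blocks <= 0 or self.n_ci_genes <= 0:
            raise ValueError("all counts must be positive")
        for name, n, f_ci, f_other in self.disease_specs:
            if n <= 0:
                raise ValueError(f"disease {name}: n_seed_genes must be positive")
            if not (0 <= f_ci <= 1 and 0 <= f_other <= 1):
                raise ValueError(f"disease {name}: fractions must lie in [0,1]")
            if abs(f_ci + f_other - 1.0) > 1e-9:
                raise ValueError(f"disease {name}: fractions must sum to 1")
        for name, n in self.trait_specs:
            if n < 0:
                raise ValueError(f"trait {name}: negative seed count")
        for drug, n, placement in self.drug_specs:
            if n <= 0:
                raise ValueError(f"drug {drug}: n_targets must be positive")
            if placement not in ("ci_module", "random"):
                raise ValueError(f"drug {drug}: unknown placement {placement!r}")


def default_scenario_config(rng_seed: int = 0) -> ScenarioConfig:
    """The default study scenario: 2,000 genes in 20 blocks (2 CI-planted),
    80 CI genes, 10 autoimmune-like diseases (60 seeds, 60% from CI blocks),
    10 diffuse trait-like sets (60 seeds), 10 CI-module drugs and 20
    random-target drugs with 5 targets each."""
    return ScenarioConfig(
        disease_specs=[(f"disease_{i:02d}", 60, 0.6, 0.4) for i in range(10)],
        trait_specs=[(f"trait_{i:02d}", 60) for i in range(10)],
        drug_specs=(
            [(f"cidrug_{i:02d}", 5, "ci_module") for i in range(10)]
            + [(f"rdrug_{i:02d}", 5, "random") for i in range(20)]
        ),
        rng_seed=rng_seed,
    )


@dataclass
class Scenario:
    """A fully materialized synthetic study, with ground truth for scoring."""

    config: ScenarioConfig
    network: GeneNetwork
    block_of: dict[str, int]
    disease_seeds: dict[str, GeneSet]
    trait_seeds: dict[str, GeneSet]
    ci_genes: GeneSet
    all_disease_annotations: dict[str, GeneSet]
    drugs: DrugTargetMap
    indications: IndicationTable
    truth: dict


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _block_assignment(cfg: ScenarioConfig) -> list[np.ndarray]:
    """Contiguous, (near-)equal-size block membership over gene indices."""
    return np.array_split(np.arange(cfg.n_genes), cfg.n_blocks)


def generate_interactome(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> tuple[GeneNetwork, dict[str, int]]:
    """Sample the planted-partition interactome.

    Each within-block gene pair is an edge with probability ``p_within``,
    each between-block pair with ``p_between``.  Refuses configurations with
    an expected mean degree below 1 (downstream stages assume a giant
    component).  Returns the network and the gene -> block map.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    names = _gene_names(cfg.n_genes)
    blocks = _block_assignment(cfg)
    mean_size = cfg.n_genes / cfg.n_blocks
    expected_degree = cfg.p_within * (mean_size - 1) + cfg.p_between * (cfg.n_genes - mean_size)
    if expected_degree < 1:
        raise ValueError(
            f"expected mean degree {expected_degree:.3f} < 1; increase edge probabilities"
        )

    graph = nx.Graph()
    graph.add_nodes_from(names)
    triu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for bi in range(cfg.n_blocks):
        for bj in range(bi, cfg.n_blocks):
            gi, gj = blocks[bi], blocks[bj]
            if bi == bj:
                s = len(gi)
                n_pairs = s * (s - 1) // 2
                prob = cfg.p_within
            else:
                n_pairs = len(gi) * len(gj)
                prob = cfg.p_between
            if n_pairs == 0:
                continue
            m = int(rng.binomial(n_pairs, prob))
            if m == 0:
                continue
            flat = rng.choice(n_pairs, size=m, replace=False)
            if bi == bj:
                if len(gi) not in triu_cache:
                    triu_cache[len(gi)] = np.triu_indices(len(gi), k=1)
                rows, cols = triu_cache[len(gi)]
                edges = ((gi[rows[k]], gi[cols[k]]) for k in flat)
            else:
                edges = ((gi[k // len(gj)], gj[k % len(gj)]) for k in flat)
            graph.add_edges_from((names[a], names[b]) for a, b in edges)

    block_of = {}
    for b, members in enumerate(blocks):
        for i in members:
            block_of[names[i]] = b
    return GeneNetwork(graph, name="synthetic_interactome"), block_of


def _sample_ci_genes(cfg: ScenarioConfig, block_of: dict[str, int], rng: np.random.Generator) -> GeneSet:
    """CI genes split evenly across the CI blocks."""
    per_block = np.full(len(cfg.ci_blocks), cfg.n_ci_genes // len(cfg.ci_blocks))
    per_block[: cfg.n_ci_genes % len(cfg.ci_blocks)] += 1
    chosen: list[str] = []
    for b, k in zip(cfg.ci_blocks, per_block):
        members = sorted(g for g, blk in block_of.items() if blk == b)
        if k > len(members):
            raise ValueError(f"block {b} has only {len(members)} genes, need {k} CI genes")
        chosen.extend(rng.choice(members, size=int(k), replace=False))
    return GeneSet("ci_genes", "planted chronic-inflammation genes", frozenset(chosen))


def generate_disease_seeds(
    block_of: dict[str, int],
    cfg: ScenarioConfig,
    spec: tuple[str, int, float, float],
    rng: np.random.Generator,
) -> GeneSet:
    """Stratified seed draw: an exact fraction from CI blocks, rest outside."""
    name, n, f_ci, _ = spec
    n_ci = int(round(f_ci * n))
    ci_pool = sorted(g for g, b in block_of.items() if b in cfg.ci_blocks)
    other_pool = sorted(g for g, b in block_of.items() if b not in cfg.ci_blocks)
    if n_ci > len(ci_pool):
        raise ValueError(f"disease {name}: requested {n_ci} CI-block seeds, only {len(ci_pool)} available")
    if n - n_ci > len(other_pool):
        raise ValueError(f"disease {name}: requested {n - n_ci} non-CI seeds, only {len(other_pool)} available")
    seeds = list(rng.choice(ci_pool, size=n_ci, replace=False))
    seeds += list(rng.choice(other_pool, size=n - n_ci, replace=False))
    return GeneSet(name, "disease-like seed genes", frozenset(seeds))


def generate_trait_seeds(
    net: GeneNetwork,
    index: DegreeIndex,
    spec: tuple[str, int],
    rng: np.random.Generator,
) -> GeneSet:
    """Diffuse seed set: a uniform reference draw, degree-preservingly shuffled.

    The result has a realistic degree profile but no block coherence."""
    name, n = spec
    if n == 0:
        return GeneSet(name, "trait-like seed genes", frozenset())
    reference = rng.choice(sorted(net.graph.nodes), size=n, replace=False)
    shuffled = degree_matched_sample(reference, index, rng, min_candidates=1)
    return GeneSet(name, "trait-like seed genes", frozenset(shuffled))


def _extra_annotations(
    cfg: ScenarioConfig, block_of: dict[str, int], rng: np.random.Generator
) -> dict[str, GeneSet]:
    """Non-inflammatory disease-like annotation sets (negatives pool).

    Each set concentrates in one random non-CI block with the remainder
    scattered over the other non-CI blocks, mimicking disease annotations
    with their own (non-inflammatory) modules."""
    non_ci_blocks = [b for b in range(cfg.n_blocks) if b not in cfg.ci_blocks]
    out: dict[str, GeneSet] = {}
    for j in range(cfg.n_extra_annotations):
        home = int(rng.choice(non_ci_blocks))
        home_pool = sorted(g for g, b in block_of.items() if b == home)
        scatter_pool = sorted(
            g for g, b in block_of.items() if b not in cfg.ci_blocks and b != home
        )
        n_home = int(round(cfg.extra_annotation_concentration * cfg.extra_annotation_size))
        n_home = min(n_home, len(home_pool))
        n_rest = cfg.extra_annotation_size - n_home
        genes = list(rng.choice(home_pool, size=n_home, replace=False))
        genes += list(rng.choice(scatter_pool, size=n_rest, replace=False))
        name = f"annotation_{j:02d}"
        out[name] = GeneSet(name, "non-inflammatory disease-like annotation", frozenset(genes))
    return out


def generate_drugs(
    net: GeneNetwork,
    index: DegreeIndex,
    cfg: ScenarioConfig,
    block_of: dict[str, int],
    ci_planted_diseases: list[str],
    rng: np.random.Generator,
) -> tuple[DrugTargetMap, IndicationTable]:
    """Drug-target placement plus the ground-truth indications table.

    ``ci_module`` drugs draw their targets from the CI-planted blocks and are
    marked as trial positives for every CI-planted disease; ``random`` drugs
    draw degree-matched random targets anywhere."""
    ci_pool = sorted(g for g, b in block_of.items() if b in cfg.ci_blocks)
    all_nodes = sorted(net.graph.nodes)
    targets: dict[str, frozenset] = {}
    class_of: dict[str, frozenset] = {}
    records: list[tuple[str, str, str]] = []
    for drug, n, placement in cfg.drug_specs:
        if placement == "ci_module":
            chosen = rng.choice(ci_pool, size=n, replace=False)
            class_of[drug] = frozenset({CI_DRUG_CLASS})
            records.extend((drug, disease, "trial") for disease in ci_planted_diseases)
        else:
            reference = rng.choice(all_nodes, size=n, replace=False)
            chosen = sorted(degree_matched_sample(reference, index, rng, min_candidates=1))
            class_of[drug] = frozenset({OTHER_DRUG_CLASS})
        targets[drug] = frozenset(str(g) for g in chosen)
    return DrugTargetMap(targets, class_of), IndicationTable(records)


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Materialize a full scenario from a config; deterministic per seed."""
    rng = np.random.default_rng(cfg.rng_seed)
    net, block_of = generate_interactome(cfg, rng)
    index = build_degree_index(net)
    ci_genes = _sample_ci_genes(cfg, block_of, rng)
    disease_seeds = {
        spec[0]: generate_disease_seeds(block_of, cfg, spec, rng) for spec in cfg.disease_specs
    }
    trait_seeds = {
        spec[0]: generate_trait_seeds(net, index, spec, rng) for spec in cfg.trait_specs
    }
    annotations = dict(disease_seeds)
    annotations.update(_extra_annotations(cfg, block_of, rng))
    ci_planted = [name for name, _, f_ci, _ in cfg.disease_specs if f_ci > 0]
    drugs, indications = generate_drugs(net, index, cfg, block_of, ci_planted, rng)
    truth = {
        "ci_blocks": list(cfg.ci_blocks),
        "ci_planted_diseases": ci_planted,
        "drug_placement": {drug: placement for drug, _, placement in cfg.drug_specs},
        "block_of": block_of,
    }
    return Scenario(
        config=cfg,
        network=net,
        block_of=block_of,
        disease_seeds=disease_seeds,
        trait_seeds=trait_seeds,
        ci_genes=ci_genes,
        all_disease_annotations=annotations,
        drugs=drugs,
        indications=indications,
        truth=truth,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Write a scenario as flat files (TSV/GMT/JSON); fully deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(scenario.network, outdir / "network.tsv")
    write_gmt(
        [scenario.disease_seeds[k] for k in sorted(scenario.disease_seeds)],
        outdir / "disease_seeds.gmt",
    )
    write_gmt(
        [scenario.trait_seeds[k] for k in sorted(scenario.trait_seeds)],
        outdir / "trait_seeds.gmt",
    )
    write_gmt([scenario.ci_genes], outdir / "ci_genes.gmt")
    write_gmt(
        [scenario.all_disease_annotations[k] for k in sorted(scenario.all_disease_annotations)],
        outdir / "annotations.gmt",
    )
    write_drug_targets(scenario.drugs, outdir / "drug_targets.tsv")
    write_gmt(
        [
            GeneSet(cls, "drug class", frozenset(d for d, cs in scenario.drugs.class_of.items() if cls in cs))
            for cls in sorted({c for cs in scenario.drugs.class_of.values() for c in cs})
        ],
        outdir / "drug_classes.gmt",
    )
    write_indications(scenario.indications, outdir / "indications.tsv")
    (outdir / "truth.json").write_text(json.dumps(scenario.truth, indent=1, sort_keys=True))
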