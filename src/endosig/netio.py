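"""Network and gene-set containers plus readers/writers for the flat formats.

The interactome is an undirected gene-gene network stored as a
:class:`networkx.Graph`; gene identifiers are opaque strings (no species or
ID-system assumption -- mapping identifiers is the caller's job).  Edge
weights, when present, are kept for modularity-based clustering but are
ignored for degrees and shortest paths.

Formats: 2-3 column TSV edge lists ('#'-prefixed comments skipped), GMT for
gene sets, simple headered TSVs for drug targets and drug-disease indications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneNetwork",
    "DegreeIndex",
    "DrugTargetMap",
    "IndicationTable",
    "NetworkParseError",
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "read_drug_targets",
    "write_drug_targets",
    "read_indications",
    "write_indications",
    "build_degree_index",
    "induced_subgraph",
]


class NetworkParseError(ValueError):
    """Raised for malformed edge-list / GMT / table lines; names the line."""


@dataclass
class GeneSet:
    """A named, duplicate-free collection of gene identifiers."""

    id: str
    description: str = ""
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def restricted_to(self, universe: Iterable[str]) -> "GeneSet":
        """The same set restricted to ``universe`` (e.g. network nodes)."""
        return GeneSet(self.id, self.description, self.genes & frozenset(universe))


class GeneNetwork:
    """Undirected gene interaction network; the background universe.

    Wraps :class:`networkx.Graph` and caches an :mod:`igraph` twin (used for
    Leiden partitions) and an all-pairs unweighted shortest-path matrix (used
    for proximity scores).  Node order in cached structures is the sorted
    gene list, which makes every derived computation order-independent.
    """

    def __init__(self, graph: nx.Graph, name: str = "network"):
        self.graph = graph
        self.name = name
        self._node_order: list[str] | None = None
        self._node_index: dict[str, int] | None = None
        self._igraph: ig.Graph | None = None
        self._dist: np.ndarray | None = None

    # -- basic views ------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def is_weighted(self) -> bool:
        return any("weight" in d for _, _, d in self.graph.edges(data=True))

    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    @property
    def node_order(self) -> list[str]:
        if self._node_order is None:
            self._node_order = sorted(self.graph.nodes)
            self._node_index = {g: i for i, g in enumerate(self._node_order)}
        return self._node_order

    @property
    def node_index(self) -> dict[str, int]:
        self.node_order
        return self._node_index  # type: ignore[return-value]

    # -- cached igraph / distances ----------------------------------------
    def to_igraph(self) -> ig.Graph:
        if self._igraph is None:
            order = self.node_order
            idx = self.node_index
            edges = [(idx[a], idx[b]) for a, b in self.graph.edges]
            g = ig.Graph(n=len(order), edges=edges, directed=False)
            g.vs["name"] = order
            if self.is_weighted:
                g.es["weight"] = [
                    float(self.graph[a][b].get("weight", 1.0)) for a, b in self.graph.edges
                ]
            self._igraph = g
        return self._igraph

    def distance_matrix(self) -> np.ndarray:
        """Unweighted all-pairs shortest-path matrix (inf if unreachable)."""
        if self._dist is None:
            g = self.to_igraph()
            self._dist = np.array(g.distances(), dtype=float)
        return self._dist

    def max_finite_distance(self) -> float:
        """Largest finite shortest-path distance (network 'diameter')."""
        d = self.distance_matrix()
        finite = d[np.isfinite(d)]
        return float(finite.max()) if finite.size else 0.0

    def adjacency(self, weighted: bool = True) -> tuple[np.ndarray, list[str]]:
        """Dense adjacency matrix in canonical node order."""
        order = self.node_order
        w = "weight" if (weighted and self.is_weighted) else None
        mat = nx.to_numpy_array(self.graph, nodelist=order, weight=w)
        return mat, order


@dataclass
class DegreeIndex:
    """Degree lookup tables backing every degree-matched null model.

    ``degree_of`` and ``genes_at`` are mutually consistent and cover exactly
    the network's nodes; degrees are computed on the unweighted topology.
    """

    degree_of: dict[str, int]
    genes_at: dict[int, list[str]]
    sorted_degrees: list[int]
    _pool_cache: dict[tuple[int, int], list[str]] = field(default_factory=dict, repr=False)

    def candidate_pool(self, degree: int, min_candidates: int) -> list[str]:
        """Genes at ``degree``, widened symmetrically over neighbouring
        occupied degrees until at least ``min_candidates`` genes are found."""
        key = (degree, min_candidates)
        cached = self._pool_cache.get(key)
        if cached is not None:
            return cached
        degs = self.sorted_degrees
        pool = list(self.genes_at.get(degree, []))
        if len(pool) < min_candidates:
            import bisect

            lo = bisect.bisect_left(degs, degree) - 1
            hi = bisect.bisect_right(degs, degree)
            if hi < len(degs) and degs[hi] == degree:  # pragma: no cover - defensive
                hi += 1
            while len(pool) < min_candidates and (lo >= 0 or hi < len(degs)):
                d_lo = degree - degs[lo] if lo >= 0 else None
                d_hi = degs[hi] - degree if hi < len(degs) else None
                if d_hi is None or (d_lo is not None and d_lo <= d_hi):
                    pool.extend(self.genes_at[degs[lo]])
                    lo -= 1
                else:
                    pool.extend(self.genes_at[degs[hi]])
                    hi += 1
        pool.sort()
        self._pool_cache[key] = pool
        return pool


@dataclass
class DrugTargetMap:
    """drug id -> target genes, with optional flat class labels per drug."""

    targets: dict[str, frozenset]
    class_of: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, genes in self.targets.items():
            if not genes:
                raise ValueError(f"drug {drug!r} has no target genes")
            self.targets[drug] = frozenset(genes)
        self.class_of = {d: frozenset(c) for d, c in self.class_of.items()}


@dataclass
class IndicationTable:
    """Known drug-disease indication records used only for evaluation."""

    records: list[tuple[str, str, str]]

    VALID_STATUS = ("approved", "off_label", "trial")

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for rec in self.records:
            if rec not in seen:
                seen.add(rec)
                deduped.append(tuple(rec))
        self.records = deduped

    def positives_for(self, disease: str, statuses: Sequence[str] | None = None) -> set[str]:
        statuses = set(statuses) if statuses is not None else None
        return {
            drug
            for drug, dis, status in self.records
            if dis == disease and (statuses is None or status in statuses)
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_network(path: str | Path, weighted: bool | None = None, name: str | None = None) -> GeneNetwork:
    """Read a 2-3 column TSV edge list into a :class:`GeneNetwork`.

    Lines starting with '#' are skipped; a first line whose third field is
    non-numeric is treated as a header.  Duplicate edges are collapsed
    keeping the maximum weight; self-loops are dropped with a warning.
    """
    path = Path(path)
    graph = nx.Graph()
    first_data_line = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(fields)}"
                )
            if first_data_line and len(fields) == 3:
                try:
                    float(fields[2])
                except ValueError:
                    first_data_line = False
                    continue  # header line
            first_data_line = False
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise NetworkParseError(f"{path}:{lineno}: empty gene identifier")
            weight = None
            if len(fields) == 3 and weighted is not False:
                try:
                    weight = float(fields[2])
                except ValueError as exc:
                    raise NetworkParseError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from exc
                if weight <= 0:
                    raise NetworkParseError(f"{path}:{lineno}: non-positive weight {weight}")
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                continue
            if graph.has_edge(a, b):
                old = graph[a][b].get("weight")
                if weight is not None and (old is None or weight > old):
                    graph[a][b]["weight"] = weight
            else:
                if weight is None:
                    graph.add_edge(a, b)
                else:
                    graph.add_edge(a, b, weight=weight)
    return GeneNetwork(graph, name=name or path.stem)


def write_network(net: GeneNetwork, path: str | Path) -> None:
    """Write the edge list as TSV (sorted; weight column only if weighted)."""
    path = Path(path)
    weighted = net.is_weighted
    lines = []
    for a, b, data in net.graph.edges(data=True):
        a, b = sorted((a, b))
        if weighted:
            lines.append(f"{a}\t{b}\t{data.get('weight', 1.0):.12g}")
        else:
            lines.append(f"{a}\t{b}")
    # isolated nodes are recorded as a comment block so round-trips keep edges only
    path.write_text("\n".join(sorted(lines)) + ("\n" if lines else ""))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line (id, description, genes...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: GMT line needs >=3 fields (id, description, genes)"
                )
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets.append(GeneSet(fields[0], fields[1], genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.id, s.description or "na", *sorted(s.genes)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_drug_targets(path: str | Path) -> DrugTargetMap:
    """Read a (drug_id, gene) TSV; a header line is detected by field names."""
    path = Path(path)
    targets: dict[str, set] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise NetworkParseError(f"{path}:{lineno}: expected 2 fields (drug, gene)")
            if lineno == 1 and fields[0].lower() in ("drug", "drug_id"):
                continue
            targets.setdefault(fields[0], set()).add(fields[1])
    return DrugTargetMap({d: frozenset(g) for d, g in targets.items()})


def write_drug_targets(drugs: DrugTargetMap, path: str | Path) -> None:
    lines = ["drug_id\tgene"]
    for drug in sorted(drugs.targets):
        for gene in sorted(drugs.targets[drug]):
            lines.append(f"{drug}\t{gene}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_indications(path: str | Path) -> IndicationTable:
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 3 fields (drug, disease, status)"
                )
            if lineno == 1 and fields[0].lower() in ("drug", "drug_id"):
                continue
            records.append((fields[0], fields[1], fields[2]))
    return IndicationTable(records)


def write_indications(table: IndicationTable, path: str | Path) -> None:
    lines = ["drug_id\tdisease_id\tstatus"]
    for drug, disease, status in sorted(table.records):
        lines.append(f"{drug}\t{disease}\t{status}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------


def build_degree_index(net: GeneNetwork) -> DegreeIndex:
    """Degree lookup on the unweighted topology (weights never count)."""
    degree_of = {g: int(d) for g, d in net.graph.degree()}
    genes_at: dict[int, list[str]] = {}
    for gene in sorted(degree_of):
        genes_at.setdefault(degree_of[gene], []).append(gene)
    return DegreeIndex(degree_of, genes_at, sorted(genes_at))


def induced_subgraph(net: GeneNetwork, genes: GeneSet | Iterable[str], name: str | None = None) -> GeneNetwork:
    """Subnetwork on ``genes`` and the edges directly connecting them.

    Genes absent from the network are dropped (tally logged); genes present
    but unconnected are retained as isolated nodes -- small clusters are
    filtered later anyway.
    """
    wanted = set(genes.genes if isinstance(genes, GeneSet) else genes)
    present = wanted & set(net.graph.nodes)
    dropped = len(wanted) - len(present)
    if dropped:
        logger.info("induced_subgraph(%s): %d gene(s) absent from network", net.name, dropped)
    sub = nx.Graph()
    sub.add_nodes_from(present)
    for a, b, data in net.graph.subgraph(present).edges(data=True):
        sub.add_edge(a, b, **data)
    return GeneNetwork(sub, name=name or f"{net.name}|induced")
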