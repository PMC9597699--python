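"""Guilt-by-association expansion of seed gene sets on a network.

A gene's feature vector is its (weighted) adjacency row in the interactome;
an L2-regularized logistic regression trained on seed genes (positives)
against genes annotated to unrelated diseases (negatives) scores every
network gene's association with the seed set.  Genes scoring at or above a
probability threshold (default 0.80) join the seeds to form the expanded
set.  A seed set only qualifies for downstream analysis if it has at least
15 genes on the network and a median 3-fold cross-validated
log2(auPRC/prior) of at least 1 -- i.e. the model retrieves held-out seeds
at least twice as well as chance.

Feature columns are standardized (mean 0, variance 1 over the training
genes) before fitting so the ridge penalty is scale-free; the regularization
strength ``reg`` maps to scikit-learn's ``C = 1/reg``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._stats import average_precision, fisher_one_sided
from .netio import GeneNetwork, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ExpansionModel",
    "CVReport",
    "dedup_gene_sets",
    "select_negatives",
    "train_expansion_model",
    "cross_validate",
    "qualify_gene_set",
    "expand_gene_set",
]


@dataclass
class ExpansionModel:
    """A fitted network-feature logistic regression.

    ``feature_genes`` is the ordered feature axis (one coefficient per
    network gene); standardization parameters are stored so the model can
    score any gene of the same network later.
    """

    feature_genes: list[str]
    coefficients: np.ndarray
    intercept: float
    regularization_strength: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def predict(self, net: GeneNetwork, genes: Sequence[str] | None = None) -> dict[str, float]:
        """Predicted association probability for ``genes`` (default: all)."""
        if net.node_order != self.feature_genes:
            raise ValueError("network does not match the model's feature axis")
        mat, order = net.adjacency()
        if genes is None:
            genes = order
        idx = [net.node_index[g] for g in genes]
        x = (mat[idx] - self.scaler_mean) / self.scaler_scale
        z = x @ self.coefficients + self.intercept
        probs = 1.0 / (1.0 + np.exp(-z))
        return {g: float(p) for g, p in zip(genes, probs)}


@dataclass
class CVReport:
    """Per-fold log2(auPRC/prior) scores of a seed-recovery cross-validation."""

    fold_scores: list[float]
    median_score: float
    n_positives: int


def dedup_gene_sets(sets: Sequence[GeneSet], threshold: float = 0.6) -> list[GeneSet]:
    """Collapse near-duplicate gene sets, one representative per overlap group.

    Two sets are linked when |A∩B| / min(|A|,|B|) >= ``threshold``; connected
    components of that graph are collapsed to their largest member (ties
    broken by lexicographically smallest id).  Output preserves the input
    order of the representatives.
    """
    if not sets:
        raise ValueError("need at least one gene set")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    for s in sets:
        if len(s) == 0:
            raise ValueError(f"gene set {s.id!r} is empty; overlap undefined")
    g = nx.Graph()
    g.add_nodes_from(range(len(sets)))
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i].genes, sets[j].genes
            if len(a & b) / min(len(a), len(b)) >= threshold:
                g.add_edge(i, j)
    representatives = []
    for component in nx.connected_components(g):
        rep = min(component, key=lambda k: (-len(sets[k]), sets[k].id))
        representatives.append(rep)
    return [sets[k] for k in sorted(representatives)]


def select_negatives(
    seeds: GeneSet,
    all_annotations: Mapping[str, GeneSet],
    universe: GeneNetwork,
    alpha: float = 0.05,
) -> GeneSet:
    """Negative training genes for one seed set.

    Start from the union of every annotation set, remove the seeds, then
    remove all genes of any annotation set that significantly overlaps the
    seeds (one-sided Fisher's exact p < ``alpha``, universe = network
    nodes).  Everything is restricted to network nodes first.
    """
    if len(seeds) == 0:
        raise ValueError("seed set is empty")
    if not all_annotations:
        raise ValueError("annotation collection is empty")
    nodes = set(universe.graph.nodes)
    seed_genes = seeds.genes & frozenset(nodes)
    n_universe = len(nodes)
    negatives = set()
    for ann in all_annotations.values():
        negatives |= ann.genes & nodes
    negatives -= seed_genes
    for name, ann in all_annotations.items():
        ann_genes = ann.genes & frozenset(nodes)
        if not ann_genes:
            continue
        overlap = len(ann_genes & seed_genes)
        table = [
            [overlap, len(seed_genes) - overlap],
            [len(ann_genes) - overlap, n_universe - len(seed_genes) - len(ann_genes) + overlap],
        ]
        if fisher_one_sided(table) < alpha:
            logger.debug("excluding annotation %s from negatives (overlaps seeds)", name)
            negatives -= ann_genes
    if not negatives:
        raise ValueError(
            "no negatives remain after removing seed-overlapping annotation sets; "
            "supply more annotation sets"
        )
    return GeneSet(f"{seeds.id}|negatives", "negative training genes", frozenset(negatives))


def _training_matrix(
    net: GeneNetwork, positives: GeneSet, negatives: GeneSet
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    pos = sorted(positives.genes & frozenset(net.graph.nodes))
    neg = sorted(negatives.genes & frozenset(net.graph.nodes))
    if set(pos) & set(neg):
        raise ValueError("positives and negatives overlap")
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 genes in each class on the network")
    mat, _ = net.adjacency()
    idx = [net.node_index[g] for g in pos + neg]
    x = mat[idx]
    y = np.array([1] * len(pos) + [0] * len(neg))
    return x, y, pos + neg


def _fit(x: np.ndarray, y: np.ndarray, reg: float, seed: int) -> tuple[LogisticRegression, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    # default penalty is the L2 ridge; C is the inverse regularization strength
    clf = LogisticRegression(C=1.0 / reg, solver="lbfgs", max_iter=2000, random_state=seed)
    clf.fit(xs, y)
    return clf, mean, scale


def train_expansion_model(
    net: GeneNetwork,
    positives: GeneSet,
    negatives: GeneSet,
    reg: float = 1.0,
    seed: int = 0,
) -> ExpansionModel:
    """Fit the expansion model on adjacency-row features.

    Deterministic given the data and seed; feature columns are standardized
    over the training genes.
    """
    if reg <= 0:
        raise ValueError("regularization strength must be positive")
    x, y, train_genes = _training_matrix(net, positives, negatives)
    clf, mean, scale = _fit(x, y, reg, seed)
    return ExpansionModel(
        feature_genes=net.node_order,
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        regularization_strength=reg,
        scaler_mean=mean,
        scaler_scale=scale,
        training_meta={
            "n_positives": int(y.sum()),
            "n_negatives": int((1 - y).sum()),
            "seed": seed,
            "training_genes": train_genes,
        },
    )


def cross_validate(
    net: GeneNetwork,
    positives: GeneSet,
    negatives: GeneSet,
    k: int = 3,
    reg: float = 1.0,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold seed-recovery performance, scored per fold as
    log2(auPRC/prior).

    auPRC is step-wise average precision over the held-out genes ranked by
    predicted probability (ties broken by gene id for determinism); prior is
    the held-out positive fraction, so 0 means chance-level retrieval.
    Genes are processed in canonical sorted order, making fold assignment
    independent of input ordering.
    """
    x, y, genes = _training_matrix(net, positives, negatives)
    n_pos = int(y.sum())
    if n_pos < k or int((1 - y).sum()) < k:
        raise ValueError(f"need at least k={k} genes per class for {k}-fold CV")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_scores = []
    for train_idx, test_idx in splitter.split(x, y):
        clf, mean, scale = _fit(x[train_idx], y[train_idx], reg, seed)
        scores = clf.predict_proba((x[test_idx] - mean) / scale)[:, 1]
        order = sorted(
            range(len(test_idx)), key=lambda i: (-scores[i], genes[test_idx[i]])
        )
        labels = [int(y[test_idx[i]]) for i in order]
        prior = sum(labels) / len(labels)
        auprc = average_precision(labels)
        fold_scores.append(float(np.log2(auprc / prior)))
    return CVReport(fold_scores, float(median(fold_scores)), n_pos)


def qualify_gene_set(
    seeds: GeneSet,
    cv: CVReport,
    min_genes: int = 15,
    min_median: float = 1.0,
) -> bool:
    """Inclusion gate: enough seed genes on the network (counted by the CV's
    positives) and median log2(auPRC/prior) at least ``min_median``."""
    return cv.n_positives >= min_genes and cv.median_score >= min_median


def expand_gene_set(
    model: ExpansionModel,
    net: GeneNetwork,
    seeds: GeneSet,
    threshold: float = 0.80,
) -> tuple[GeneSet, dict[str, float]]:
    """Expanded set: seeds plus every gene predicted at or above ``threshold``.

    Seeds are always retained regardless of their own scores.  Returns the
    expanded set and the full gene -> probability table.
    """
    probs = model.predict(net)
    predicted = {g for g, p in probs.items() if p >= threshold}
    expanded = GeneSet(
        seeds.id,
        f"{seeds.description} (expanded at p>={threshold})",
        seeds.genes | frozenset(predicted),
    )
    return expanded, probs
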