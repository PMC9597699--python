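"""Evaluation of drug predictions against known indications.

Three complementary views: ranked-retrieval quality (log2(auPRC/prior) of
the -log10(FDR) drug ranking against known positives), enrichment of
previously indicated drugs among the predicted treatments (one-tailed
Fisher's exact test), and preranked set enrichment of drug classes along the
ranking (weighted Kolmogorov-Smirnov running sum with a permutation p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._stats import average_precision, bh_adjust, fisher_one_sided
from .repurpose import DrugPrediction

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationRecord",
    "ClassEnrichment",
    "rank_predictions",
    "ranked_retrieval",
    "indication_enrichment",
    "indication_enrichment_by_disease",
    "drug_class_gsea",
]


@dataclass
class EvaluationRecord:
    """Ranked-retrieval quality of one disease's drug ranking."""

    disease: str
    positives_source: str
    auprc: float
    prior: float
    log2_auprc_over_prior: float
    n_positives: int


@dataclass
class ClassEnrichment:
    """Preranked enrichment of one drug class for one disease."""

    disease: str
    class_label: str
    es: float
    p: float
    adjusted_p: float = field(default=float("nan"))
    n_members: int = 0


def rank_predictions(preds: Sequence[DrugPrediction]) -> list[DrugPrediction]:
    """Deterministic ranking by -log10(FDR): descending, ties broken by
    normalized similarity (descending) then drug id."""
    return sorted(preds, key=lambda p: (p.fdr, -p.similarity_normalized, p.drug))


def ranked_retrieval(
    preds: Sequence[DrugPrediction],
    positives: Iterable[str],
    disease: str | None = None,
    positives_source: str = "indicated",
    min_positives: int = 1,
) -> EvaluationRecord | None:
    """log2(auPRC/prior) of the drug ranking against known positives.

    Returns None (with a notice) when fewer than ``min_positives`` positives
    or no negative appears among the ranked drugs; the indicated-drug
    analysis conventionally requires at least five known treatments.
    """
    preds = rank_predictions(preds)
    if not preds:
        raise ValueError("no predictions to evaluate")
    pos = set(positives)
    labels = [1 if p.drug in pos else 0 for p in preds]
    n_pos = sum(labels)
    disease = disease or preds[0].owner
    if n_pos < min_positives or n_pos == 0:
        logger.info("disease %s: only %d positives among ranked drugs; skipped", disease, n_pos)
        return None
    if n_pos == len(labels):
        logger.info("disease %s: no negative among ranked drugs; skipped", disease)
        return None
    auprc = average_precision(labels)
    prior = n_pos / len(labels)
    return EvaluationRecord(
        disease, positives_source, auprc, prior, float(np.log2(auprc / prior)), n_pos
    )


def indication_enrichment(
    all_drugs: int,
    indicated_to_disease: int,
    predicted: int,
    predicted_and_indicated: int,
) -> float:
    """One-tailed Fisher's exact p for over-representation of previously
    indicated drugs among this disease's predicted treatments.

    The universe is the total number of unique drugs indicated to any
    disease; BH across diseases is the caller's job.
    """
    if predicted_and_indicated > min(indicated_to_disease, predicted):
        raise ValueError("overlap exceeds a margin of the contingency table")
    if predicted > all_drugs or indicated_to_disease > all_drugs:
        raise ValueError("margins exceed the drug universe")
    a = predicted_and_indicated
    table = [
        [a, predicted - a],
        [indicated_to_disease - a, all_drugs - indicated_to_disease - predicted + a],
    ]
    if min(min(row) for row in table) < 0:
        raise ValueError("inconsistent contingency table")
    return fisher_one_sided(table)


def indication_enrichment_by_disease(
    tables: dict[str, tuple[int, int, int, int]],
) -> dict[str, tuple[float, float]]:
    """Fisher p per disease plus BH across diseases.

    ``tables`` maps disease id -> (all_drugs, indicated_to_disease,
    predicted, predicted_and_indicated); returns disease -> (p, fdr).
    """
    diseases = sorted(tables)
    pvals = [indication_enrichment(*tables[d]) for d in diseases]
    fdrs = bh_adjust(pvals)
    return {d: (p, float(f)) for d, p, f in zip(diseases, pvals, fdrs)}


def _running_es(is_member: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximal deviation of the weighted KS running sum (exponent 1)."""
    n = is_member.size
    n_member = int(is_member.sum())
    member_weight = weights[is_member].sum()
    if member_weight == 0:
        # all member scores are 0: fall back to equal hit increments
        hit = is_member / n_member
    else:
        hit = np.where(is_member, weights / member_weight, 0.0)
    miss = np.where(is_member, 0.0, 1.0 / (n - n_member))
    running = np.cumsum(hit - miss)
    peak = np.argmax(np.abs(running))
    return float(running[peak])


def drug_class_gsea(
    ranked_drugs: Sequence[tuple[str, float]],
    class_members: Iterable[str],
    n_perm: int = 10000,
    seed: int = 0,
    disease: str = "",
    class_label: str = "",
) -> ClassEnrichment | None:
    """Preranked set enrichment of one drug class along a scored ranking.

    ``ranked_drugs`` is the (drug, score) list already ordered from best to
    worst (scores are the ranking weights, e.g. -log10(FDR)).  The enrichment
    score is the signed maximal deviation of the weighted running sum;
    significance comes from ``n_perm`` random placements of the member
    positions (one-sided on the observed ES's sign).  Classes with fewer
    than 2 members in the ranking, or spanning the entire ranking, are
    degenerate and skipped with a notice (returns None).
    """
    drugs = [d for d, _ in ranked_drugs]
    scores = np.array([s for _, s in ranked_drugs], dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    members = set(class_members) & set(drugs)
    if len(members) < 2:
        logger.info("class %s: <2 members among ranked drugs; skipped", class_label)
        return None
    if len(members) == len(drugs):
        logger.info("class %s covers every ranked drug; ES degenerate, skipped", class_label)
        return None
    is_member = np.array([d in members for d in drugs])
    weights = np.abs(scores)
    es_obs = _running_es(is_member, weights)
    rng = np.random.default_rng(seed)
    n = len(drugs)
    m = len(members)
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=m, replace=False)] = True
        es_perm = _running_es(perm, weights)
        if es_obs >= 0:
            exceed += es_perm >= es_obs
        else:
            exceed += es_perm <= es_obs
    p = (exceed + 1) / (n_perm + 1)
    return ClassEnrichment(disease, class_label, es_obs, p, n_members=m)


def adjust_class_enrichments(results: Sequence[ClassEnrichment]) -> list[ClassEnrichment]:
    """BH across the drug classes tested within one disease."""
    results = list(results)
    if results:
        for res, fdr in zip(results, bh_adjust([r.p for r in results])):
            res.adjusted_p = float(fdr)
    return results
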