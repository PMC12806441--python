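"""Metrics, negative sampling and leakage-controlled validation splits.

Covers the evaluation protocol around the scorers: threshold-free ranking
metrics (ROC-AUC as the Mann–Whitney ordering probability, PR-AUC by the
average-precision convention), confusion-matrix metrics at a hard-call
threshold, negative construction by re-pairing TCRs with peptides they are
not known to bind (the "shuffle" scheme), the seen/unseen-peptide
partition of a validation set against its training set, and a
CDR3β-similarity filter that removes validation pairs too close to the
training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .core_data import BindingDataset, BindingPair
from .rank_search import edit_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsReport:
    roc_auc: float
    pr_auc: float
    precision: float
    recall: float
    f1: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full classification report for binary labels and probabilities.

    ROC-AUC equals the probability that a random positive outscores a
    random negative, with 0.5 credit for ties; PR-AUC is average
    precision. Hard calls use ``score >= threshold``. Both classes must be
    present — AUCs on a single class are undefined and raise rather than
    silently returning 0.5.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError(f"labels and scores lengths differ: {y.shape} vs {s.shape}")
    if len(np.unique(y)) < 2:
        raise ValueError("AUCs are undefined on a single-class label vector")
    roc = float(roc_auc_score(y, s))
    pr = float(average_precision_score(y, s))
    pred = (s >= threshold).astype(int)
    yi = y.astype(int)
    tp = int(np.sum((pred == 1) & (yi == 1)))
    fp = int(np.sum((pred == 1) & (yi == 0)))
    tn = int(np.sum((pred == 0) & (yi == 0)))
    fn = int(np.sum((pred == 0) & (yi == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    accuracy = (tp + tn) / len(y)
    return MetricsReport(roc, pr, precision, recall, f1, accuracy,
                         tp, fp, tn, fn, threshold)


def negative_sample(positives: BindingDataset, tcr_pool: list[str],
                    ratio: float = 1.0, seed: int = 0) -> BindingDataset:
    """Build negatives by re-pairing pool TCRs with each peptide.

    For each peptide with ``p`` positive pairs, ``round(ratio * p)`` TCRs
    are drawn uniformly without replacement from the pool, excluding every
    TCR positively paired with that peptide anywhere in ``positives``; the
    drawn pairs are labeled 0. The combined positive+negative dataset is
    shuffled deterministically by the seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if any(p.label != 1 for p in positives):
        raise ValueError("positives dataset must contain only label-1 pairs")
    rng = np.random.default_rng(seed)
    by_peptide: dict[str, list[BindingPair]] = {}
    for p in positives:
        by_peptide.setdefault(p.peptide, []).append(p)
    positive_tcrs = {pep: {q.cdr3b for q in ps} for pep, ps in by_peptide.items()}

    negatives: list[BindingPair] = []
    for pep in by_peptide:  # insertion order: deterministic
        n_neg = int(round(ratio * len(by_peptide[pep])))
        eligible = [t for t in tcr_pool if t not in positive_tcrs[pep]]
        if len(eligible) < n_neg:
            raise ValueError(
                f"TCR pool exhausted for peptide {pep}: need {n_neg}, "
                f"have {len(eligible)} eligible")
        sel = rng.choice(len(eligible), size=n_neg, replace=False)
        negatives.extend(BindingPair(eligible[i], pep, 0) for i in sel)

    combined = list(positives) + negatives
    order = rng.permutation(len(combined))
    logger.info("negative sampling: %d positives, %d negatives", len(positives), len(negatives))
    return BindingDataset([combined[i] for i in order],
                          provenance=positives.provenance or "negative-sampled")


def split_seen_unseen(validation: BindingDataset,
                      training: BindingDataset) -> tuple[BindingDataset, BindingDataset]:
    """Partition validation positives by peptide overlap with training.

    A positive validation pair whose peptide occurs in any training pair
    goes to the shared-peptide set; the rest form the unique-peptide
    (unseen) set. Generalization to the unseen side is the hard problem —
    the model has never observed those epitopes.
    """
    train_peptides = training.peptides()
    positives = [p for p in validation if p.label is None or p.label == 1]
    shared = [p for p in positives if p.peptide in train_peptides]
    unique = [p for p in positives if p.peptide not in train_peptides]
    logger.info("seen/unseen split: %d shared pairs (%d peptides), %d unique pairs (%d peptides)",
                len(shared), len({p.peptide for p in shared}),
                len(unique), len({p.peptide for p in unique}))
    return (BindingDataset(shared, "shared-peptide"),
            BindingDataset(unique, "unique-peptide"))


def sequence_similarity(a: str, b: str) -> float:
    """Normalized similarity: 1 − edit_distance / max(len(a), len(b))."""
    return 1.0 - edit_distance(a, b) / max(len(a), len(b))


def similarity_filter(validation: BindingDataset, training: BindingDataset,
                      max_similarity: float, side: str = "cdr3b") -> BindingDataset:
    """Drop validation pairs too similar to any training sequence.

    A validation pair is removed when its CDR3β (or peptide, with
    ``side="peptide"``) has normalized similarity strictly greater than
    ``max_similarity`` to *any* training sequence on the same side. Used
    to verify that performance is not an artifact of near-duplicate
    sequences leaking from training into validation.
    """
    if not 0.0 < max_similarity <= 1.0:
        raise ValueError("max_similarity must be in (0, 1]")
    if side not in ("cdr3b", "peptide"):
        raise ValueError("side must be 'cdr3b' or 'peptide'")
    train_seqs = sorted({getattr(p, side) for p in training})
    kept = []
    for pair in validation:
        q = getattr(pair, side)
        if all(sequence_similarity(q, t) <= max_similarity for t in train_seqs):
            kept.append(pair)
    logger.info("similarity filter (%s <= %.2f): kept %d / %d validation pairs",
                side, max_similarity, len(kept), len(validation))
    return BindingDataset(kept, validation.provenance)
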