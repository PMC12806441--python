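"""Percentile binding rank, repertoire scanning and neighbor search.

The binding rank places a query pair's score within the score distribution
of a background TCR repertoire (reference protocol: 1000 randomly drawn
CD4 TCRs) scored against the *same* peptide. Smaller rank means stronger
binding: rank ≤ 0.05 is called strong, ≤ 0.1 weak, otherwise non-binding.
Ties receive half weight, which makes the rank the complement of a
Mann–Whitney placement and keeps it exactly antitone in the query score.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .core_data import BackgroundRepertoire, BindingDataset, BindingPair

STRONG_RANK = 0.05
WEAK_RANK = 0.1
#: Default reactivity cutoff for repertoire scanning; chosen in the
#: reference application to control the number of called reactive cells.
REACTIVITY_THRESHOLD = 0.54


@dataclass(frozen=True)
class RankResult:
    score: float
    rank: float
    category: str
    background_size: int


def _categorize(rank: float, strong: float, weak: float) -> str:
    if rank <= strong:
        return "strong"
    if rank <= weak:
        return "weak"
    return "non"


def compute_rank(query: BindingPair, scorer, background: BackgroundRepertoire,
                 seed: int = 0, subsample_to: int | None = None,
                 strong: float = STRONG_RANK, weak: float = WEAK_RANK) -> RankResult:
    """Percentile rank of a query pair against a background repertoire.

    Every background TCR is paired with the query's peptide and scored by
    the same scorer; the rank is the fraction of background scores
    exceeding the query score, ties counted half::

        rank = (#{b : s_b > s} + 0.5 * #{b : s_b == s}) / N

    ``subsample_to`` draws a random subset of the repertoire (seeded) when
    a smaller background is wanted; otherwise the full repertoire is used
    and the result is deterministic.
    """
    tcrs = background.tcrs
    if subsample_to is not None and subsample_to < len(tcrs):
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(tcrs), size=subsample_to, replace=False)
        tcrs = [tcrs[i] for i in sel]
    n = len(tcrs)
    bg_pairs = BindingDataset([BindingPair(t, query.peptide) for t in tcrs])
    bg_scores = np.asarray(scorer.predict(bg_pairs))
    s = float(np.asarray(scorer.predict(BindingDataset([query])))[0])
    rank = float((np.sum(bg_scores > s) + 0.5 * np.sum(bg_scores == s)) / n)
    return RankResult(score=s, rank=rank, category=_categorize(rank, strong, weak),
                      background_size=n)


def scan_repertoire(tcrs: list[str], peptides: list[str], scorer,
                    score_threshold: float = REACTIVITY_THRESHOLD) -> list[tuple[str, str, float]]:
    """Score every TCR × peptide combination and keep the reactive ones.

    Returns ``(tcr, peptide, score)`` records with score ≥ threshold,
    sorted by descending score with ties in input (TCR-major) order.
    """
    if not tcrs or not peptides:
        raise ValueError("tcrs and peptides must be nonempty")
    combos = [(t, p) for t in tcrs for p in peptides]
    ds = BindingDataset([BindingPair(t, p) for t, p in combos])
    scores = np.asarray(scorer.predict(ds))
    keep = np.nonzero(scores >= score_threshold)[0]
    order = keep[np.argsort(-scores[keep], kind="stable")]
    return [(combos[i][0], combos[i][1], float(scores[i])) for i in order]


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost insert/delete/substitute)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def search_neighbors(query: BindingPair, database: BindingDataset,
                     max_dist_cdr3: int, max_dist_peptide: int) -> list[dict]:
    """Database pairs within the edit-distance bounds of the query.

    A match must satisfy both bounds (CDR3β and peptide sides); matches
    are sorted by summed distance, ties in database order. Mirrors a
    search page that finds curated records near a query pair.
    """
    if max_dist_cdr3 < 0 or max_dist_peptide < 0:
        raise ValueError("distance bounds must be nonnegative")
    if len(database) == 0:
        raise ValueError("database is empty")
    matches = []
    for i, rec in enumerate(database):
        dc = edit_distance(query.cdr3b, rec.cdr3b)
        if dc > max_dist_cdr3:
            continue
        dp = edit_distance(query.peptide, rec.peptide)
        if dp > max_dist_peptide:
            continue
        matches.append({"index": i, "pair": rec, "dist_cdr3": dc, "dist_peptide": dp,
                        "dist_total": dc + dp})
    matches.sort(key=lambda m: (m["dist_total"], m["index"]))
    return matches
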