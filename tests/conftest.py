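"""Shared fixtures and independent oracles for the test suite.

The oracles here (Wagner–Fischer edit distance, Mann–Whitney AUC
counting, brute-force neighbor search) are deliberately written from
first principles and never call into the package paths they check.
"""

import numpy as np
import pytest

from tcrbind import AMINO_ACIDS, BindingDataset, BindingPair, EncodingScheme


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def wagner_fischer(a: str, b: str) -> int:
    """Textbook dynamic-programming Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[len(b)]


def mann_whitney_auc(labels, scores) -> float:
    """Brute-force pairwise ordering probability with 0.5 tie credit."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_neighbors(query, database, max_dc, max_dp):
    """Filter-and-sort reference for neighbor search."""
    out = []
    for i, rec in enumerate(database):
        dc = wagner_fischer(query.cdr3b, rec.cdr3b)
        dp = wagner_fischer(query.peptide, rec.peptide)
        if dc <= max_dc and dp <= max_dp:
            out.append((dc + dp, i, rec, dc, dp))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def random_seq(rng, lo, hi) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


# ---------------------------------------------------------------------------
# Stub scorers (score tables, no training involved)
# ---------------------------------------------------------------------------

class StubScorer:
    """Deterministic scorer backed by a lookup table on CDR3β (or pair)."""

    trained = True

    def __init__(self, table: dict, default: float = 0.5,
                 scheme: EncodingScheme | None = None):
        self.table = table
        self.default = default
        self.scheme = scheme or EncodingScheme()

    def predict(self, pairs, **kwargs):
        out = []
        for p in pairs:
            if (p.cdr3b, p.peptide) in self.table:
                out.append(self.table[(p.cdr3b, p.peptide)])
            else:
                out.append(self.table.get(p.cdr3b, self.default))
        return np.asarray(out, dtype=float)


@pytest.fixture
def stub_scorer_factory():
    return StubScorer


# ---------------------------------------------------------------------------
# Small shared data
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_scheme():
    return EncodingScheme(max_len_cdr3=18, max_len_peptide=17)


@pytest.fixture
def labeled_pairs():
    return BindingDataset([
        BindingPair("CASSLGQETQYF", "ACDEFGHIK", 1),
        BindingPair("CASSIRSSYEQYF", "KLMNPQRST", 0),
        BindingPair("CAWSVGVGQPQHF", "ACDEFGHIK", 1),
        BindingPair("CASSPGTGGYEQYF", "VWYACDEFG", 0),
    ], provenance="fixture")
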