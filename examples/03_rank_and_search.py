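"""Percentile binding rank and edit-distance neighbor search.

Trains a quick scorer, then (a) ranks one query pair against a
1000-TCR random background — rank <= 0.05 is called a strong binder,
<= 0.1 weak — and (b) finds curated pairs within a small edit distance
of a query, mirroring a database search page.
"""

import numpy as np

from tcrbind import (
    AMINO_ACIDS, BackgroundRepertoire, ScorerConfig, TrainingConfig,
    build_scorer, compute_rank, make_learnability_benchmark,
    search_neighbors, train,
)
from tcrbind.experiments import BENCH_SCHEME

task, train_set, heldout = make_learnability_benchmark(seed=11)
scorer = build_scorer(ScorerConfig(family="convolutional"), BENCH_SCHEME, seed=1)
train(scorer, train_set, heldout, TrainingConfig(seed=2))

rng = np.random.default_rng(3)
background = BackgroundRepertoire(
    ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=int(n)))
     for n in rng.integers(12, 19, size=1000)])

binder = next(p for p in heldout if p.label == 1)
res = compute_rank(binder, scorer, background)
print(f"query {binder.cdr3b} x {binder.peptide}")
print(f"  score {res.score:.3f}, rank {res.rank:.3f} vs {res.background_size} "
      f"background TCRs -> {res.category} binder")

# search: perturb a known training pair by one residue, then look it up
known = train_set[0]
query = type(known)(known.cdr3b[:-1] + ("A" if known.cdr3b[-1] != "A" else "C"),
                    known.peptide)
matches = search_neighbors(query, train_set, max_dist_cdr3=3, max_dist_peptide=3)
print(f"\n{len(matches)} training pair(s) within edit distance (3, 3) of the "
      "perturbed query; closest:")
for m in matches[:3]:
    print(f"  {m['pair'].cdr3b} x {m['pair'].peptide} "
          f"(CDR3 dist {m['dist_cdr3']}, peptide dist {m['dist_peptide']})")
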