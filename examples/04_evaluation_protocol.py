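"""The evaluation protocol: negative sampling, unseen peptides,
similarity filtering.

Builds a positive-only synthetic dataset, balances it by re-pairing TCRs
with peptides they are not known to bind (the shuffle scheme), splits a
validation set into seen/unseen peptides, and filters validation pairs
whose CDR3β is near-identical to a training CDR3β.
"""

import numpy as np

from tcrbind import (
    BindingDataset, negative_sample, sample_pairs, similarity_filter,
    split_seen_unseen,
)
from tcrbind.synthetic import SyntheticTaskSpec, make_task

task = make_task(SyntheticTaskSpec(n_motif_pairs=4, seed=9))
train_set = sample_pairs(task, 150, 150, seed=10)
fresh = sample_pairs(task, 40, 40, seed=11)
# validation mixes novel pairs with some whose peptides occur in training,
# as real independent validation sets do
reused = [p for p in train_set.positives()][:20]
valid_set = BindingDataset(fresh.pairs + reused, provenance="validation")

positives = train_set.positives()
pool = sorted({p.cdr3b for p in train_set} | {p.cdr3b for p in valid_set})
balanced = negative_sample(positives, pool, ratio=1.0, seed=12)
print(f"negative sampling: {len(positives)} positives -> balanced set of "
      f"{len(balanced)} ({len(balanced.negatives())} shuffled negatives)")

shared, unique = split_seen_unseen(valid_set, train_set)
print(f"seen/unseen split: {len(shared)} validation positives use peptides "
      f"seen in training, {len(unique)} use novel peptides")

for t in (0.9, 0.7, 0.5):
    kept = similarity_filter(valid_set, train_set, max_similarity=t)
    print(f"similarity filter at {t:.1f}: kept {len(kept)}/{len(valid_set)} "
          "validation pairs (lower caps remove near-duplicate CDR3βs)")
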