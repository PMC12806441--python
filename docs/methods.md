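# Methods

## Problem and scope

The package predicts whether a TCR binds a peptide from two amino-acid
strings: the CDR3β loop of the TCR β-chain and the epitope sequence.
This representation deliberately omits MHC allele, TCRα and V/J gene
context — curated binding data rarely carry all of them, and the CDR3β
loop dominates peptide contact. The central scientific device is
transfer learning: CD8-restricted (MHC-I, ~9-mer epitope) binding data
are roughly nine times more abundant than CD4-restricted (MHC-II,
~15-mer) data, so a model pretrained on the abundant regime initializes
one for the scarce regime.

## Scorer architectures

Both families share a contract: pair in, probability out, deterministic
at prediction time, batch-size independent.

* **Recurrent**: residue indices (pad 0, residues 1–20 in alphabetical
  order ACDEFGHIKLMNPQRSTVWY) pass through a learned embedding
  (dimension 10) into one LSTM per sequence (hidden size 32, forget-gate
  bias initialized to 1). Padded timesteps carry state forward, so the
  final state is the state at the last true residue. The two final
  states are concatenated.
* **Convolutional**: one-hot matrices pass through per-sequence 1-D
  convolutions with window sizes 2, 3, 4 (32 channels each) and ReLU;
  global max pooling is restricted to windows that lie fully inside the
  true sequence, so padding can never win the max.
* **Head**: fully connected ReLU layers of widths 64 and 16 with dropout
  0.1 after each, ending in a single sigmoid unit.

The networks, their backward passes and the Adam optimizer are written
directly in numpy (float64). Every gradient is pinned by
finite-difference tests, which is the correctness anchor for all
training-level results. Default training: Adam at 1e-3, batch 64, up to
100 epochs, early stopping on validation ROC-AUC with patience 10 and
best-epoch restoration. All randomness flows through seeded
`numpy.random.Generator` instances, making data generation, training,
transfer and ensembling bit-reproducible.

The recurrent hidden size of 32 (rather than a larger one) is a
deliberate economy: on motif-governed tasks the larger recurrence adds
cost but no measurable accuracy, and a float64 CPU LSTM is the single
most expensive component in the pipeline.

## Transfer and ensembling

`transfer_parameters` copies every parameter of a trained source scorer
into a target scorer of identical architecture. By default the head is
kept and nothing is frozen — the published description of the approach
speaks only of initializing the target parameter set, not of freezing —
but both a head reinitialization and per-layer-group freezing
(`cdr3_encoder`, `peptide_encoder`, `head`) are available, and frozen
groups are verified bitwise-unchanged by fine-tuning.

Two combiners merge trained members that share one encoding scheme:

* **avg** — the unweighted arithmetic mean of member probabilities (the
  reference final-model combiner);
* **sub** — a weighted mean with simplex weights fitted by exhaustive
  grid search (step 0.01) maximizing ROC-AUC on a labeled calibration
  set, ties resolved toward uniform weights. The original sub-ensemble
  construction is not specified in the available text; this grid-fitted
  weighting is this package's own determinate definition and is not
  claimed to be canonical.

## Binding rank

For query score `s` against background scores `s_b` (background TCRs
paired with the query's peptide), `rank = (#{s_b > s} + ½#{s_b = s})/N`.
The half-weight tie rule makes the rank the complement of a
Mann–Whitney placement: it is exactly antitone in the query score and
takes values `k/N` when scores are distinct. Thresholds are inclusive:
rank ≤ 0.05 → strong, ≤ 0.1 → weak, else non; the reference background
size is 1000 TCRs. Repertoire scanning uses a default reactivity cutoff
of 0.54, the value used in the reference application to keep the called
reactive-cell count manageable; it is a plain parameter.

## Evaluation protocol

* ROC-AUC is the Mann–Whitney ordering probability with 0.5 tie credit
  (computed via scikit-learn, cross-checked in tests against an
  independent pairwise-counting oracle to 1e-12); PR-AUC uses the
  average-precision convention, which is exactly reproducible, unlike
  interpolated trapezoids. Single-class inputs raise rather than
  returning a misleading 0.5.
* Negative sampling ("shuffle" scheme): for each peptide with `p`
  positives, `round(ratio·p)` TCRs are drawn without replacement from a
  pool, excluding TCRs positively paired with that peptide; default
  ratio 1.0 balances the classes.
* Seen/unseen split: validation positives are partitioned by whether
  their peptide occurs anywhere in training. Generalization to the
  unseen side is the hard problem in this field.
* Similarity filter: a validation pair is dropped when its CDR3β has
  normalized similarity `1 − d/max(len)` strictly above the cap to any
  training CDR3β (peptide-side filtering is available). The filter is
  provably monotone in the cap. Similarity is defined on the CDR3β side
  by default because that is where near-duplicates inflate performance.
* Edit distances are unit-cost Levenshtein via edlib; the test suite
  keeps an independent Wagner–Fischer implementation as the oracle.

## Synthetic tasks: what they emulate and what they do not

A task holds `n` distinct (TCR 3-mer, peptide 3-mer) motif pairs; a pair
binds iff some TCR motif is a substring of the CDR3β and its partner a
substring of the peptide. Positives implant a motif pair at random
offsets in uniform-random background sequences; negatives are
rejection-sampled non-binders; labels then flip with the configured
noise probability. The substring rule was chosen over positional weight
matrices because exhaustive string search is a perfect, model-free
oracle for every generated label.

Reference conditions:

* **Learnability benchmark** — one motif pair, noiseless, peptides 8–10
  residues, CDR3β 12–18; 2000 training / 500 held-out pairs. A logistic
  regression on joint k-mer co-occurrence features certifies the task
  (ROC-AUC ≥ 0.95), so a scorer family failing it indicates a bug, not
  an impossible task.
* **Scarcity benchmark** — source: 20 motif pairs, 9-mer regime, 5%
  label noise, 4500 + 500 pairs; target: derived with 70% shared motif
  vocabulary, 15-mer regime, 450 + 100 pairs plus a 1000-pair test set
  disjoint from training. Source/target volume is 5000 : 550 ≈ 9 : 1,
  the abundance ratio that motivates the transfer design.

The generator reproduces the *structural* features that matter for the
mechanisms under test — shared determinants across tasks, length-regime
shift, class balance, label noise, data scarcity — and none of the
biological texture of real repertoires: V/J-biased CDR3 composition,
epitope source distributions, MHC restriction, clonal structure.
Passing results therefore demonstrate that the machinery (transfer,
ensembling, rank, filtering) behaves as designed, not that any
particular accuracy will be attained on real CD4 data.

## Study sizes and numerical choices

The transfer-lift study runs 10 paired seeds of the scarcity benchmark
with the convolutional family — the family in which transfer produces
the clearest, most reproducible enhancement — using source training
capped at 40 epochs (patience 8) and target training at 60 (patience
12); a one-sided sign test over per-seed wins summarizes the paired
comparison. Ensemble behavior is measured on separate 10-seed
replicates (5-motif task, 5% noise, 800/200/400 pairs) training both
families and averaging them. These sizes are the package's reference
conditions; all are plain arguments.

Other numerical conventions: encoding schemes are fixed per model and
serialized into checkpoints; over-length sequences are errors, never
truncated; CV stratification uses scikit-learn's stratified K-fold with
the training seed, and AUC ties between folds resolve to the lower fold
index; duplicate CSV rows are dropped keeping the first, while the same
pair labeled both 0 and 1 is a hard error.

## Known limitations

* No claim of numerical identity with any published model: the original
  layer sizes, optimizer settings and encodings are not public, so the
  defaults here are declared substitutes.
* Only CDR3β and peptide enter the model; paired-chain and MHC effects
  are invisible.
* The sub-ensemble combiner is this package's own construction (see
  above).
* Uniform-random synthetic sequences make the tasks easier than real
  repertoires, where background k-mer statistics are highly biased; the
  learnability thresholds are calibrated to the synthetic setting only.
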