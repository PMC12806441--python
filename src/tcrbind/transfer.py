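"""CD8→CD4 parameter transfer and ensemble combination.

The abundant-source / scarce-target workflow: a scorer trained on the
data-rich source task (CD8-like, ~9-mer epitopes) initializes a scorer for
the data-poor target task (CD4-like, ~15-mer epitopes) by copying its
parameters, optionally reinitializing the head and freezing encoder
layers, then fine-tuning on the target data. Two combiners merge the
fine-tuned members into one probability per pair:

* ``avg`` — unweighted arithmetic mean of member probabilities (the
  final-model combiner);
* ``sub`` — a calibration-weighted mean whose simplex weights are fitted
  by grid search to maximize ROC-AUC on a held-out calibration set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._nn import LAYER_GROUPS
from .core_data import BindingDataset
from .scorers import TrainedScorer, TrainingConfig, build_scorer, train


@dataclass
class TransferConfig:
    """How source parameters seed the target model before fine-tuning."""

    reinit_head: bool = False
    frozen_layers: list[str] = field(default_factory=list)
    fine_tune: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self):
        unknown = [l for l in self.frozen_layers if l not in LAYER_GROUPS]
        if unknown:
            raise ValueError(f"unknown frozen layer name(s): {unknown}; "
                             f"choose from {list(LAYER_GROUPS)}")


def transfer_parameters(source: TrainedScorer, tconf: TransferConfig,
                        head_seed: int | None = None) -> TrainedScorer:
    """Initialize a target-task scorer from a trained source scorer.

    All parameters are copied; with ``reinit_head`` the head is redrawn
    from ``head_seed`` (default: source seed + 1). Frozen layer groups are
    recorded on the returned scorer and left untouched by fine-tuning.
    The target architecture is the source architecture — transfer across
    differing configs is an error, not a silent reshape.
    """
    if not source.trained:
        raise ValueError("source scorer must be trained before transfer")
    target = source.copy()
    target.trained = False
    target.history = []
    if tconf.reinit_head:
        seed = (source.seed + 1) if head_seed is None else head_seed
        fresh = build_scorer(source.config, source.scheme, seed=seed)
        for k in list(target.params):
            if k.startswith("head."):
                target.params[k] = fresh.params[k]
        target.provenance["head_seed"] = seed
    target.frozen_layers = tuple(tconf.frozen_layers)
    target.provenance["transferred_from"] = {
        "seed": source.seed,
        "reinit_head": tconf.reinit_head,
        "frozen_layers": list(tconf.frozen_layers),
        "source_training": source.provenance.get("training", {}),
    }
    return target


def check_same_architecture(a: TrainedScorer, b: TrainedScorer) -> None:
    if a.config != b.config or a.scheme != b.scheme:
        raise ValueError("architecture mismatch: configs/schemes differ")
    for k in a.params:
        if a.params[k].shape != b.params[k].shape:
            raise ValueError(f"architecture mismatch at parameter {k}")


def fine_tune(initialized: TrainedScorer, target_train: BindingDataset,
              target_valid: BindingDataset, tconf: TransferConfig) -> TrainedScorer:
    """Fine-tune a transferred (or scratch, for controls) scorer.

    Identical contract to :func:`tcrbind.scorers.train`; layer groups in
    ``initialized.frozen_layers`` are bitwise unchanged afterwards.
    """
    return train(initialized, target_train, target_valid, tconf.fine_tune)


class EnsembleScorer:
    """Combine ≥2 trained scorers sharing one encoding scheme."""

    def __init__(self, members: list[TrainedScorer], mode: str = "avg",
                 sub_weights: np.ndarray | None = None):
        if len(members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if mode not in ("avg", "sub"):
            raise ValueError(f"unknown ensemble mode: {mode!r}")
        scheme = members[0].scheme
        for m in members[1:]:
            if m.scheme != scheme:
                raise ValueError("ensemble members must share one encoding scheme")
        if mode == "sub":
            if sub_weights is None:
                raise ValueError("sub mode requires sub_weights")
            w = np.asarray(sub_weights, dtype=float)
            if w.shape != (len(members),) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("sub_weights must be nonnegative and sum to 1, one per member")
            self.sub_weights = w
        else:
            self.sub_weights = None
        self.members = members
        self.mode = mode
        self.scheme = scheme
        self.trained = all(m.trained for m in members)

    def member_scores(self, pairs) -> np.ndarray:
        return np.stack([m.predict(pairs) for m in self.members])  # (k, n)

    def predict(self, pairs) -> np.ndarray:
        """One probability per pair: plain or weighted mean of members."""
        if not self.trained:
            raise RuntimeError("all ensemble members must be trained")
        scores = self.member_scores(pairs)
        if self.mode == "avg":
            return scores.mean(axis=0)
        return self.sub_weights @ scores

    def save(self, path) -> None:
        import json
        arrays, metas = {}, []
        for j, m in enumerate(self.members):
            for k, v in m.params.items():
                arrays[f"m{j}:param:{k}"] = v
            from dataclasses import asdict
            metas.append({"config": asdict(m.config), "scheme": m.scheme.to_dict(),
                          "seed": m.seed, "trained": m.trained,
                          "frozen_layers": list(m.frozen_layers),
                          "provenance": m.provenance})
        meta = {"format": "tcrbind-ens-1", "mode": self.mode,
                "sub_weights": None if self.sub_weights is None else self.sub_weights.tolist(),
                "members": metas}
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                     **arrays)

    @classmethod
    def load(cls, path) -> "EnsembleScorer":
        import json
        from .encoding import EncodingScheme
        from .scorers import ScorerConfig
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            if meta.get("format") != "tcrbind-ens-1":
                raise ValueError("unsupported ensemble checkpoint format")
            members = []
            for j, mm in enumerate(meta["members"]):
                prefix = f"m{j}:param:"
                params = {k[len(prefix):]: npz[k].copy() for k in npz.files
                          if k.startswith(prefix)}
                sc = TrainedScorer(ScorerConfig(**mm["config"]),
                                   EncodingScheme.from_dict(mm["scheme"]), params, mm["seed"])
                sc.trained = mm["trained"]
                sc.frozen_layers = tuple(mm["frozen_layers"])
                sc.provenance = mm["provenance"]
                members.append(sc)
        w = meta["sub_weights"]
        return cls(members, meta["mode"], None if w is None else np.asarray(w))


def ensemble_predict(ens: EnsembleScorer, pairs) -> np.ndarray:
    return ens.predict(pairs)


def fit_sub_ensemble_weights(members: list[TrainedScorer], calib: BindingDataset,
                             step: float = 0.01) -> np.ndarray:
    """Grid-search simplex weights maximizing calibration ROC-AUC.

    The grid walks the weight simplex at the given step; ties prefer the
    weight vector closest to uniform, so identical members yield uniform
    weights. Deterministic.
    """
    from sklearn.metrics import roc_auc_score

    if len(calib) == 0:
        raise ValueError("calibration set is empty")
    y = np.asarray(calib.labels, dtype=float)
    if any(l is None for l in calib.labels) or len(np.unique(y)) < 2:
        raise ValueError("calibration set must be labeled with both classes present")
    scores = np.stack([m.predict(calib) for m in members])  # (k, n)

    k = len(members)
    n_steps = int(round(1.0 / step))
    uniform = np.full(k, 1.0 / k)
    best_auc, best_w, best_dist = -np.inf, None, np.inf
    for combo in itertools.combinations_with_replacement(range(k), n_steps):
        w = np.bincount(np.asarray(combo), minlength=k) / n_steps
        auc = roc_auc_score(y, w @ scores)
        dist = float(np.sum((w - uniform) ** 2))
        if auc > best_auc + 1e-12 or (abs(auc - best_auc) <= 1e-12 and dist < best_dist):
            best_auc, best_w, best_dist = auc, w, dist
    return best_w
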