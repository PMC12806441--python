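"""Parameter transfer, freezing, and the two ensemble combiners."""

import numpy as np
import pytest

from tcrbind import (
    BindingDataset,
    BindingPair,
    EncodingScheme,
    EnsembleScorer,
    ScorerConfig,
    TrainingConfig,
    TransferConfig,
    build_scorer,
    fine_tune,
    fit_sub_ensemble_weights,
    train,
    transfer_parameters,
)
from tcrbind.transfer import check_same_architecture
from tcrbind.synthetic import SyntheticTaskSpec, make_task, sample_pairs

from conftest import StubScorer

TINY = dict(embed_dim=4, hidden_dim=6, conv_channels=4, head_layers=[8], dropout=0.1)
SCHEME = EncodingScheme(max_len_cdr3=18, max_len_peptide=17)


@pytest.fixture(scope="module")
def source_and_data():
    spec = SyntheticTaskSpec(n_motif_pairs=2, peptide_len=(8, 10), cdr3_len=(12, 18), seed=21)
    task = make_task(spec)
    train_set = sample_pairs(task, 60, 60, seed=22)
    valid_set = sample_pairs(task, 20, 20, seed=23)
    source = build_scorer(ScorerConfig(family="convolutional", **TINY), SCHEME, seed=24)
    train(source, train_set, valid_set,
          TrainingConfig(epochs=3, batch_size=16, seed=25, early_stop_patience=5))
    return source, train_set, valid_set


class TestTransferParameters:
    def test_plain_transfer_is_bitwise_copy(self, source_and_data):
        source, *_ = source_and_data
        target = transfer_parameters(source, TransferConfig())
        for k in source.params:
            assert (target.params[k] == source.params[k]).all(), k
        assert not target.trained  # needs fine-tuning before prediction

    def test_reinit_head_keeps_encoders_replaces_head(self, source_and_data):
        source, *_ = source_and_data
        target = transfer_parameters(source, TransferConfig(reinit_head=True))
        for k in source.params:
            if k.startswith("head."):
                if source.params[k].any():  # biases start at zero either way
                    assert not (target.params[k] == source.params[k]).all(), k
            else:
                assert (target.params[k] == source.params[k]).all(), k

    def test_untrained_source_rejected(self):
        src = build_scorer(ScorerConfig(family="convolutional", **TINY), SCHEME, seed=1)
        with pytest.raises(ValueError, match="trained"):
            transfer_parameters(src, TransferConfig())

    def test_architecture_mismatch_detected(self, source_and_data):
        source, *_ = source_and_data
        other = build_scorer(ScorerConfig(family="convolutional",
                                          **{**TINY, "conv_channels": 8}), SCHEME, seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            check_same_architecture(source, other)

    def test_unknown_frozen_layer_name_rejected(self):
        with pytest.raises(ValueError, match="unknown frozen layer"):
            TransferConfig(frozen_layers=["encoder_x"])

    def test_provenance_recorded(self, source_and_data):
        source, *_ = source_and_data
        target = transfer_parameters(source, TransferConfig(frozen_layers=["cdr3_encoder"]))
        assert target.provenance["transferred_from"]["frozen_layers"] == ["cdr3_encoder"]


class TestFineTune:
    def test_frozen_layers_bitwise_unchanged(self, source_and_data):
        source, train_set, valid_set = source_and_data
        tconf = TransferConfig(
            frozen_layers=["cdr3_encoder", "peptide_encoder"],
            fine_tune=TrainingConfig(epochs=3, batch_size=16, seed=31, early_stop_patience=5))
        target = transfer_parameters(source, tconf)
        before = {k: v.copy() for k, v in target.params.items()}
        fine_tune(target, train_set, valid_set, tconf)
        for k, v in target.params.items():
            if k.startswith(("cdr3_encoder.", "peptide_encoder.")):
                assert (v == before[k]).all(), f"frozen {k} changed"
        assert any(not (target.params[k] == before[k]).all()
                   for k in target.params if k.startswith("head."))

    def test_empty_target_train_rejected(self, source_and_data):
        source, _, valid_set = source_and_data
        tconf = TransferConfig()
        target = transfer_parameters(source, tconf)
        with pytest.raises(ValueError, match="empty"):
            fine_tune(target, BindingDataset([]), valid_set, tconf)


def _stub_members(scores_a, scores_b, pairs):
    table_a = {(p.cdr3b, p.peptide): s for p, s in zip(pairs, scores_a)}
    table_b = {(p.cdr3b, p.peptide): s for p, s in zip(pairs, scores_b)}
    scheme = EncodingScheme()
    return StubScorer(table_a, scheme=scheme), StubScorer(table_b, scheme=scheme)


PAIRS = BindingDataset([
    BindingPair("CASSLGQETQYF", "ACDEFGHIK", 1),
    BindingPair("CASSIRSSYEQYF", "KLMNPQRST", 0),
])


class TestEnsemble:
    def test_avg_is_arithmetic_mean(self):
        a, b = _stub_members([0.6, 0.2], [0.8, 0.4], PAIRS)
        ens = EnsembleScorer([a, b], mode="avg")
        assert np.allclose(ens.predict(PAIRS), [0.7, 0.3])

    def test_agreeing_members_are_identity(self):
        a, b = _stub_members([0.42, 0.9], [0.42, 0.9], PAIRS)
        for mode, w in (("avg", None), ("sub", np.array([0.3, 0.7]))):
            ens = EnsembleScorer([a, b], mode=mode, sub_weights=w)
            assert np.allclose(ens.predict(PAIRS), [0.42, 0.9])

    def test_sub_mode_with_degenerate_weights(self):
        a, b = _stub_members([0.3, 0.3], [0.9, 0.9], PAIRS)
        ens = EnsembleScorer([a, b], mode="sub", sub_weights=np.array([1.0, 0.0]))
        assert np.allclose(ens.predict(PAIRS), [0.3, 0.3])

    def test_avg_bounded_by_member_extremes(self):
        rng = np.random.default_rng(0)
        sa, sb = rng.random(2), rng.random(2)
        a, b = _stub_members(sa, sb, PAIRS)
        out = EnsembleScorer([a, b], mode="avg").predict(PAIRS)
        assert (out >= np.minimum(sa, sb) - 1e-12).all()
        assert (out <= np.maximum(sa, sb) + 1e-12).all()

    def test_sub_mode_requires_weights(self):
        a, b = _stub_members([0.5, 0.5], [0.5, 0.5], PAIRS)
        with pytest.raises(ValueError, match="sub_weights"):
            EnsembleScorer([a, b], mode="sub")

    def test_scheme_mismatch_rejected(self):
        a = StubScorer({}, scheme=EncodingScheme())
        b = StubScorer({}, scheme=EncodingScheme(max_len_cdr3=12))
        with pytest.raises(ValueError, match="scheme"):
            EnsembleScorer([a, b], mode="avg")

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError, match="2 members"):
            EnsembleScorer([StubScorer({})], mode="avg")


class TestSubEnsembleWeights:
    def _calib(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        pairs, labels = [], []
        for i in range(n):
            label = i % 2
            pairs.append(BindingPair(f"CASS{'ACDEFGHIKLMNPQRSTVWY'[i % 20]}GQETQYF",
                                     f"ACDEFGH{'ACDEFGHIKLMNPQRSTVWY'[i % 20]}", label))
            labels.append(label)
        return BindingDataset(pairs), np.array(labels), rng

    def test_perfect_member_dominates_random_member(self):
        calib, y, rng = self._calib()
        # perfect member separates with tiny margins; any admixture of the
        # random member breaks the ordering, so AUC is uniquely maximized
        # at weight 1 on the perfect member
        perfect = 0.5 + (2 * y - 1) * (1e-4 * (1 + np.arange(len(y))))
        random_scores = rng.random(len(y))
        a = StubScorer({(p.cdr3b, p.peptide): s for p, s in zip(calib, perfect)})
        b = StubScorer({(p.cdr3b, p.peptide): s for p, s in zip(calib, random_scores)})
        w = fit_sub_ensemble_weights([a, b], calib)
        assert w[0] >= 0.99 and abs(w.sum() - 1.0) < 1e-9

    def test_identical_members_get_uniform_weights(self):
        calib, y, rng = self._calib(seed=1)
        scores = rng.random(len(y))
        table = {(p.cdr3b, p.peptide): s for p, s in zip(calib, scores)}
        w = fit_sub_ensemble_weights([StubScorer(table), StubScorer(table)], calib)
        assert np.allclose(w, [0.5, 0.5])

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_sub_ensemble_weights([StubScorer({}), StubScorer({})], BindingDataset([]))

    def test_single_class_calibration_rejected(self):
        calib = BindingDataset([BindingPair("CASSLGQETQYF", "ACDEFGHIK", 1)] * 3)
        with pytest.raises(ValueError, match="both classes"):
            fit_sub_ensemble_weights([StubScorer({}), StubScorer({})], calib)
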