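import numpy as np
import pytest

from contourclf.corpus import Document
from contourclf.models import (
    AttentionEncoderConfig,
    BiLSTMConfig,
    ContourDataset,
    FusionConfig,
    TokenDataset,
    TrainConfig,
    fusion_loss,
    silver_label,
    train_bilstm,
    train_encoder,
    train_fusion,
)
from contourclf.models.autodiff import Tensor
from contourclf.models.nets import BiLSTMClassifier


class TestFusionLoss:
    def test_lambda_one_reduces_to_primary(self):
        assert fusion_loss(1.0, 0.5, 1.0) == 1.0

    def test_lambda_zero_reduces_to_secondary(self):
        assert fusion_loss(1.0, 0.5, 0.0) == 0.5

    def test_linear_form(self):
        assert fusion_loss(1.0, 0.5, 0.7) == pytest.approx(0.85)

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_lambda_out_of_range(self, lam):
        with pytest.raises(ValueError):
            fusion_loss(1.0, 0.5, lam)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fusion_loss(float("nan"), 0.5, 0.5)

    def test_gradient_wrt_lambda_is_loss_difference(self):
        # d/dlam [lam*a + (1-lam)*b] = a - b, checked by central difference
        a, b, lam = 1.3, 0.4, 0.6
        eps = 1e-6
        fd = (fusion_loss(a, b, lam + eps) - fusion_loss(a, b, lam - eps)) / (2 * eps)
        assert abs(fd - (a - b)) / abs(a - b) < 1e-5


class TestBiLSTM:
    def test_parameter_count_closed_form(self):
        net = BiLSTMClassifier(input_width=7, hidden_dim=5, n_layers=3, seed=0)
        H = 5
        expected = 0
        d_in = 7
        for _ in range(3):
            expected += 2 * (4 * H * (d_in + H) + 4 * H)
            d_in = 2 * H
        assert net.lstm_parameter_count() == expected

    def test_default_dims_parameter_count(self):
        net = BiLSTMClassifier(input_width=498, hidden_dim=512, n_layers=3, seed=0)
        H = 512
        expected = 0
        d_in = 498
        for _ in range(3):
            expected += 2 * (4 * H * (d_in + H) + 4 * H)
            d_in = 2 * H
        assert net.lstm_parameter_count() == expected

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BiLSTMConfig(input_width=10, n_layers=0)

    def test_width_mismatch_is_validation_error(self, planted_contour_data):
        inputs, labels = planted_contour_data
        ds = ContourDataset(inputs[:20], labels[:20])
        cfg = BiLSTMConfig(input_width=99, hidden_dim=4, n_layers=1)
        with pytest.raises(ValueError, match="width"):
            train_bilstm(ds, ds, cfg, TrainConfig(epochs=1))

    def test_empty_split_is_validation_error(self, planted_contour_data):
        inputs, labels = planted_contour_data
        ds = ContourDataset(inputs[:20], labels[:20])
        empty = ContourDataset([], np.array([], dtype=int))
        cfg = BiLSTMConfig(input_width=40, hidden_dim=4, n_layers=1)
        with pytest.raises(ValueError, match="empty"):
            train_bilstm(ds, empty, cfg, TrainConfig(epochs=1))

    def test_zero_window_docs_dropped_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            ds = ContourDataset(
                [np.ones((2, 3)), np.zeros((0, 3)), np.ones((1, 3))],
                np.array([0, 1, 1]))
        assert len(ds) == 2
        assert any("zero windows" in r.message for r in caplog.records)

    def test_planted_signal_recovery(self, planted_contour_data):
        inputs, labels = planted_contour_data
        train = ContourDataset(inputs[:180], labels[:180])
        val = ContourDataset(inputs[180:], labels[180:])
        cfg = BiLSTMConfig(input_width=40, hidden_dim=16, n_layers=1, seed=0)
        model = train_bilstm(train, val, cfg,
                             TrainConfig(learning_rate=1e-2, epochs=4, seed=0))
        assert max(h["val_accuracy"] for h in model.history) >= 0.95

    def test_deterministic_prediction(self, planted_contour_data):
        inputs, labels = planted_contour_data
        ds = ContourDataset(inputs[:40], labels[:40])
        cfg = BiLSTMConfig(input_width=40, hidden_dim=8, n_layers=1, seed=1)
        model = train_bilstm(ds, ds, cfg, TrainConfig(epochs=1, seed=1))
        p1 = model.predict_proba(ds.inputs[:5])
        p2 = model.predict_proba(ds.inputs[:5])
        np.testing.assert_array_equal(p1, p2)
        assert np.all((p1 > 0) & (p1 < 1))

    def test_seeded_rerun_reproduces_metrics(self, planted_contour_data):
        inputs, labels = planted_contour_data
        train = ContourDataset(inputs[:100], labels[:100])
        val = ContourDataset(inputs[100:140], labels[100:140])
        cfg = BiLSTMConfig(input_width=40, hidden_dim=8, n_layers=1, seed=5)
        runs = [train_bilstm(train, val, cfg, TrainConfig(epochs=2, seed=5)).history
                for _ in range(2)]
        assert runs[0] == runs[1]


def _token_data(n, seed, signal_word="sorrow"):
    rng = np.random.default_rng(seed)
    filler = ["calm", "walk", "tree", "house", "river", "cloud"]
    token_lists, labels = [], []
    for i in range(n):
        y = i % 2
        toks = [filler[rng.integers(len(filler))] for _ in range(10)]
        if y:
            toks[rng.integers(10)] = signal_word
        token_lists.append(toks)
        labels.append(y)
    return TokenDataset(token_lists, np.array(labels))


class TestEncoder:
    def test_truncation_to_max_tokens(self):
        train = _token_data(24, 0)
        cfg = AttentionEncoderConfig(model_dim=8, n_heads=2, n_layers=1, max_tokens=4)
        model = train_encoder(train, train, cfg, TrainConfig(epochs=1, learning_rate=1e-2))
        long_doc = ["word"] * 1000
        p = model.predict_proba([long_doc])
        assert p.shape == (1,)
        ids = model.net.prepare_ids([model.vocab.encode(long_doc)])
        assert ids.shape[1] == 5  # CLS + max_tokens

    def test_deterministic_forward(self):
        train = _token_data(24, 1)
        cfg = AttentionEncoderConfig(model_dim=8, n_heads=2, n_layers=1, max_tokens=16)
        model = train_encoder(train, train, cfg, TrainConfig(epochs=1))
        toks = train.token_lists[:4]
        np.testing.assert_array_equal(model.predict_proba(toks),
                                      model.predict_proba(toks))

    def test_keyword_planted_recovery(self):
        train = _token_data(160, 2)
        val = _token_data(60, 3)
        cfg = AttentionEncoderConfig(model_dim=32, n_heads=2, n_layers=1,
                                     max_tokens=16, seed=0)
        model = train_encoder(train, val, cfg,
                              TrainConfig(learning_rate=1e-2, epochs=8, seed=0))
        assert max(h["val_accuracy"] for h in model.history) >= 0.9

    def test_invalid_head_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            AttentionEncoderConfig(model_dim=10, n_heads=4)


@pytest.fixture(scope="module")
def aux_model():
    from contourclf.models import train_aux_encoder
    train = _token_data(80, 4)
    # emotion 0 mirrors the condition, the rest are constant zero
    emo = np.zeros((len(train), 6), dtype=int)
    emo[:, 0] = train.labels
    train.emotion = emo
    cfg = AttentionEncoderConfig(model_dim=32, n_heads=2, n_layers=1,
                                 max_tokens=16, seed=0)
    return train_aux_encoder(train, train, "emotion", cfg,
                             TrainConfig(learning_rate=1e-2, epochs=8, seed=0)), train


class TestSilverLabels:

    def test_shape_contract(self, aux_model):
        model, train = aux_model
        docs = [Document(doc_id=f"d{i}", text=" ".join(toks), label=0)
                for i, toks in enumerate(train.token_lists[:7])]
        silver_label(model, docs, "emotion")
        mat = np.array([d.emotion for d in docs])
        assert mat.shape == (7, 6)
        assert set(mat.ravel()) <= {0, 1}

    def test_memorized_exemplar_gets_training_label(self, aux_model):
        model, train = aux_model
        probs = model.predict_task_proba(train.token_lists, "emotion")
        # the most confidently separated training exemplar must round-trip
        conf = np.abs(probs[:, 0] - 0.5)
        i = int(np.argmax(conf))
        doc = Document(doc_id="x", text=" ".join(train.token_lists[i]), label=0)
        silver_label(model, [doc], "emotion")
        assert doc.emotion[0] == train.emotion[i, 0]

    def test_tie_breaks_to_one(self):
        # threshold is >=, so probability exactly 0.5 labels 1
        assert (np.array([0.5]) >= 0.5).astype(int)[0] == 1

    def test_task_mismatch_is_validation_error(self, aux_model):
        model, _ = aux_model
        docs = [Document(doc_id="d", text="calm tree", label=0)]
        with pytest.raises(ValueError, match="personality"):
            silver_label(model, docs, "personality")

    def test_gold_labels_untouched(self, aux_model):
        model, _ = aux_model
        doc = Document(doc_id="d", text="calm tree house", label=1)
        silver_label(model, [doc], "emotion")
        assert doc.label == 1


class TestFusion:
    def _fusion_data(self, n, seed):
        ds = _token_data(n, seed)
        rng = np.random.default_rng(seed + 100)
        emo = np.zeros((n, 6), dtype=int)
        emo[:, 0] = np.where(rng.random(n) < 0.8, ds.labels, 1 - ds.labels)
        ds.emotion = emo
        pers = np.zeros((n, 4), dtype=int)
        pers[:, 0] = ds.labels
        ds.personality = pers
        return ds

    def test_lambda_one_matches_single_task_curve(self):
        train = self._fusion_data(48, 5)
        val = self._fusion_data(24, 6)
        cfg = AttentionEncoderConfig(model_dim=16, n_heads=2, n_layers=1,
                                     max_tokens=16, seed=3)
        tcfg = TrainConfig(learning_rate=1e-2, epochs=2, seed=3)
        single = train_encoder(train, val, cfg, tcfg)
        fused = train_fusion(train, val, FusionConfig(lambda_mhc=1.0,
                                                      secondary_tasks=("emotion",)),
                             cfg, tcfg)
        for h_single, h_fused in zip(single.history, fused.history):
            assert h_single["val_accuracy"] == pytest.approx(h_fused["val_accuracy"])
            assert h_single["train_loss"] == pytest.approx(h_fused["train_loss"], rel=1e-9)

    def test_loss_decomposition_sums_to_total(self):
        train = self._fusion_data(32, 7)
        cfg = AttentionEncoderConfig(model_dim=16, n_heads=2, n_layers=1,
                                     max_tokens=16, seed=0)
        model = train_fusion(
            train, train,
            FusionConfig(lambda_mhc=0.6, secondary_tasks=("emotion", "personality")),
            cfg, TrainConfig(epochs=1, seed=0))
        comp = model.loss_components(
            train.token_lists[:8], train.labels[:8], lambda_mhc=0.6,
            emotion=train.emotion[:8], personality=train.personality[:8])
        expected = 0.6 * comp["primary"] + 0.4 * comp["secondary"]
        assert comp["total"] == pytest.approx(expected, abs=1e-6)

    def test_missing_silver_labels_is_error(self):
        train = _token_data(16, 8)  # no emotion labels attached
        cfg = AttentionEncoderConfig(model_dim=8, n_heads=2, n_layers=1, max_tokens=16)
        with pytest.raises(ValueError, match="silver"):
            train_fusion(train, train, FusionConfig(secondary_tasks=("emotion",)),
                         cfg, TrainConfig(epochs=1))

    def test_fusion_config_requires_secondary_task(self):
        with pytest.raises(ValueError):
            FusionConfig(secondary_tasks=())

    def test_correlated_auxiliary_does_not_hurt_primary(self):
        # auxiliary label correlates r=0.6 with the condition; fusion
        # accuracy must stay within 0.02 of the single-task encoder
        from contourclf.corpus import split_docs
        from contourclf.models import token_dataset_from_docs
        from contourclf.synthetic import (
            GeneratorConfig, generate_auxiliary, generate_corpus, generate_lexicons)

        diffs = []
        for seed in range(1, 6):
            cfg = GeneratorConfig(
                n_docs=1000, p_case=0.6, p_control=0.1,
                r_emotion=(0.6, 0, 0, 0, 0, 0), sentence_mean=4, seed=seed)
            lexicons = generate_lexicons(cfg)
            docs = generate_auxiliary(cfg, generate_corpus(cfg, lexicons))
            by = split_docs(docs)
            train = token_dataset_from_docs(by["train"])
            val = token_dataset_from_docs(by["val"])
            enc_cfg = AttentionEncoderConfig(model_dim=16, n_heads=2, n_layers=1,
                                             max_tokens=48, seed=seed)
            tcfg = TrainConfig(learning_rate=1e-2, epochs=8, seed=seed)
            single = train_encoder(train, val, enc_cfg, tcfg)
            fused = train_fusion(
                train, val,
                FusionConfig(lambda_mhc=0.5, secondary_tasks=("emotion",)),
                enc_cfg, tcfg)
            s = max(h["val_accuracy"] for h in single.history)
            f = max(h["val_accuracy"] for h in fused.history)
            diffs.append(f - s)
        assert all(d >= -0.02 for d in diffs)
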