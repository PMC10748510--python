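import numpy as np
import pytest

from contourclf.explain import (
    AttributionRecord,
    GroupImportanceTable,
    agrad_attribution,
    category_coverage,
    label_correlations,
    lime_explain,
    lime_feature_weights,
    sp_lime_group_importance,
    top_k_unigrams,
)
from contourclf.features.lexicon import Lexicon
from contourclf.models import TrainedEncoderModel
from contourclf.models.autodiff import Tensor, binary_cross_entropy
from contourclf.models.nets import AttentionEncoder, Vocabulary


class BagOfWordsOracle:
    """Deterministic linear scorer in bag-of-unigrams space."""

    def __init__(self, weights: dict[str, float]):
        self.weights = weights

    def predict_proba(self, token_lists):
        out = []
        for toks in token_lists:
            s = sum(self.weights.get(t, 0.0) for t in {t.lower() for t in toks})
            out.append(1.0 / (1.0 + np.exp(-s)))
        return np.asarray(out)


class TestLime:
    def test_planted_weight_ranked_first_with_positive_sign(self):
        oracle = BagOfWordsOracle({"sad": 2.0})
        tokens = "i feel sad about many different things today".split()
        recs = lime_explain(oracle, tokens, n_samples=500, seed=0)
        top = max(recs, key=lambda r: r.importance)
        assert top.token == "sad"
        assert top.importance > 0

    def test_constant_model_gives_near_zero_weights(self):
        class Constant:
            def predict_proba(self, token_lists):
                return np.full(len(token_lists), 0.7)
        recs = lime_explain(Constant(), "alpha beta gamma delta".split(),
                            n_samples=200, seed=1)
        assert all(abs(r.importance) < 1e-3 for r in recs)

    def test_same_seed_identical_records(self):
        oracle = BagOfWordsOracle({"sad": 1.0, "joy": -1.0})
        tokens = "sad joy other words here".split()
        a = lime_explain(oracle, tokens, n_samples=100, seed=3)
        b = lime_explain(oracle, tokens, n_samples=100, seed=3)
        assert a == b

    def test_one_record_per_distinct_unigram(self):
        oracle = BagOfWordsOracle({})
        recs = lime_explain(oracle, "a b a b c".split(), n_samples=50, seed=0)
        assert sorted(r.token for r in recs) == ["a", "b", "c"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            lime_explain(BagOfWordsOracle({}), ["a", "b"], n_samples=5)

    def test_sign_recovery_rate_on_linear_oracle(self):
        # >= 95% of seeded runs recover the sign of every nonzero weight
        oracle = BagOfWordsOracle({"grim": 1.5, "glad": -1.5})
        tokens = "grim glad filler words appear here often".split()
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            recs = {r.token: r.importance
                    for r in lime_explain(oracle, tokens, n_samples=300, seed=seed)}
            if recs["grim"] > 0 and recs["glad"] < 0:
                hits += 1
        assert hits / n_runs >= 0.95


class LinearContourModel:
    """predict_proba = sigmoid(sum of selected feature columns)."""

    def __init__(self, weights: np.ndarray):
        self.weights = weights

    def predict_proba(self, inputs):
        return np.asarray([
            1.0 / (1.0 + np.exp(-float(x.mean(axis=0) @ self.weights)))
            for x in inputs
        ])


class TestSpLime:
    def test_single_group_is_hundred_percent(self):
        model = LinearContourModel(np.ones(6))
        inputs = [np.random.default_rng(i).normal(size=(4, 6)) for i in range(4)]
        col = sp_lime_group_importance(model, inputs, {"all": list(range(6))},
                                       seed=0, n_samples=60)
        assert col["all"] == pytest.approx(100.0)

    def test_columns_sum_to_hundred(self):
        model = LinearContourModel(np.arange(8) / 4.0)
        inputs = [np.random.default_rng(i).normal(size=(3, 8)) for i in range(5)]
        grouping = {"a": [0, 1, 2], "b": [3, 4, 5], "c": [6, 7]}
        col = sp_lime_group_importance(model, inputs, grouping, seed=0, n_samples=60)
        assert sum(col.values()) == pytest.approx(100.0, abs=1e-9)

    def test_planted_group_dominates(self):
        # model reads only features 0-2 -> that group must exceed 50% and rank 1
        w = np.zeros(12)
        w[:3] = 2.0
        model = LinearContourModel(w)
        rng = np.random.default_rng(0)
        inputs = [rng.normal(size=(4, 12)) for _ in range(6)]
        grouping = {"planted": [0, 1, 2], "noise1": [3, 4, 5, 6, 7],
                    "noise2": [8, 9, 10, 11]}
        wins = 0
        for seed in range(5):
            col = sp_lime_group_importance(model, inputs, grouping,
                                           seed=seed, n_samples=100)
            if max(col, key=col.get) == "planted" and col["planted"] > 50:
                wins += 1
        assert wins >= 4

    def test_non_partition_grouping_rejected(self):
        model = LinearContourModel(np.ones(4))
        inputs = [np.zeros((2, 4))]
        with pytest.raises(ValueError, match="partition"):
            sp_lime_group_importance(model, inputs, {"a": [0, 1], "b": [1, 2, 3]})

    def test_feature_weights_require_enough_samples(self):
        model = LinearContourModel(np.ones(3))
        with pytest.raises(ValueError):
            lime_feature_weights(model, np.zeros((2, 3)), n_samples=4)


class TestGroupImportanceTable:
    def test_column_sum_invariant_enforced(self):
        with pytest.raises(ValueError, match="sums to"):
            GroupImportanceTable(groups=["a", "b"],
                                 columns={"c1": {"a": 60.0, "b": 30.0}})

    def test_ranks_are_a_permutation(self):
        table = GroupImportanceTable(
            groups=["a", "b", "c"],
            columns={"c1": {"a": 20.0, "b": 50.0, "c": 30.0}})
        ranks = table.ranks("c1")
        assert sorted(ranks.values()) == [1, 2, 3]
        assert ranks["b"] == 1


@pytest.fixture(scope="module")
def toy_encoder():
    enc = AttentionEncoder(vocab_size=30, model_dim=8, n_heads=2, n_layers=2,
                           max_tokens=16, seed=9)
    vocab = Vocabulary(["alpha", "beta", "gamma", "delta", "epsilon"])
    return TrainedEncoderModel(enc, vocab, history=[])


class TestAgrad:
    def test_direct_substitution(self):
        # A = -(dL/da) * a with dL/da = 0.2, a = 0.5
        assert -(0.2 * 0.5) == pytest.approx(-0.1)

    def test_zero_attention_gives_zero_importance(self, toy_encoder):
        recs = agrad_attribution(toy_encoder, ["alpha", "beta"], target_label=1)
        # multiplicative form: positions can never dominate without weight
        net = toy_encoder.net
        ids = net.prepare_ids([toy_encoder.vocab.encode(["alpha", "beta"])])
        _, alphas = net.forward(ids)
        alpha = alphas[-1].data[0].sum(axis=0)[0]
        for rec in recs:
            if alpha[rec.position + 1] == 0:
                assert rec.importance == 0.0

    def test_matches_finite_difference_oracle(self, toy_encoder):
        net = toy_encoder.net
        tokens = ["alpha", "beta", "gamma", "delta"]
        recs = agrad_attribution(toy_encoder, tokens, target_label=1)
        ids = net.prepare_ids([toy_encoder.vocab.encode(tokens)])
        B, T = ids.shape
        _, alphas = net.forward(ids)
        alpha_last = alphas[-1].data[0]

        def loss_with(deltas):
            probs, _ = net.forward(ids, attn_deltas=[Tensor(d) for d in deltas])
            return float(binary_cross_entropy(probs["primary"],
                                              np.array([[1.0]])).data)

        eps = 1e-5
        for rec in recs:
            i = rec.position + 1
            a_fd = 0.0
            for h in range(net.n_heads):
                deltas = [np.zeros((B, net.n_heads, T, T)) for _ in net.layers]
                deltas[-1][0, h, 0, i] = eps
                lp = loss_with(deltas)
                deltas[-1][0, h, 0, i] = -eps
                lm = loss_with(deltas)
                a_fd += -(lp - lm) / (2 * eps) * alpha_last[h, 0, i]
            assert rec.importance == pytest.approx(a_fd, rel=1e-4, abs=1e-12)

    def test_requires_attention_model(self):
        with pytest.raises(TypeError, match="attention"):
            agrad_attribution(object(), ["a"], target_label=0)


def _rec(doc, token, pos, imp):
    return AttributionRecord(doc_id=doc, token=token, position=pos,
                             importance=imp, method="LIME")


class TestTopK:
    def test_selection_contract(self):
        recs = [_rec("d", f"w{i}", i, float(i)) for i in range(25)]
        top = top_k_unigrams(recs, k=10)["d"]
        assert len(top) == 10
        imps = [r.importance for r in top]
        assert imps == sorted(imps, reverse=True)

    def test_short_document_rule(self):
        recs = [_rec("d", f"w{i}", i, float(i)) for i in range(4)]
        assert len(top_k_unigrams(recs, k=10)["d"]) == 4

    def test_total_count_ten_per_document(self):
        recs = [_rec(f"d{j}", f"w{i}", i, float(i))
                for j in range(30) for i in range(15)]
        top = top_k_unigrams(recs, k=10)
        assert sum(len(v) for v in top.values()) == 300

    def test_tie_broken_by_earlier_position(self):
        recs = [_rec("d", "b", 5, 1.0), _rec("d", "a", 2, 1.0)]
        assert top_k_unigrams(recs, k=1)["d"][0].token == "a"

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            top_k_unigrams([], k=0)


class TestCategoryCoverage:
    def _lexicon(self):
        lex = Lexicon(slot="LIWC")
        for w in ("think", "know", "cause"):
            lex.add(w, "cogproc")
        lex.add("friend", "social")
        return lex

    def test_ratio(self):
        lex = self._lexicon()
        recs = [_rec("d", w, i, 1.0) for i, w in enumerate(
            ["think", "know", "cause", "friend"] + ["other"] * 16)]
        top = top_k_unigrams(recs, k=20)
        rows = category_coverage(top, lex, ["cogproc"])
        assert rows[0].percentage == pytest.approx(15.0)

    def test_unmatched_category_zero(self):
        rows = category_coverage(
            top_k_unigrams([_rec("d", "zzz", 0, 1.0)], k=5),
            self._lexicon(), ["social"])
        assert rows[0].percentage == 0.0

    def test_all_words_in_category_is_hundred(self):
        recs = [_rec("d", "think", 0, 2.0), _rec("d", "know", 1, 1.0)]
        rows = category_coverage(top_k_unigrams(recs, k=5),
                                 self._lexicon(), ["cogproc"])
        assert rows[0].percentage == 100.0

    def test_empty_selection_warns_and_reports_zero(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            rows = category_coverage({}, self._lexicon(), ["cogproc"])
        assert rows[0].percentage == 0.0
        assert any("empty" in r.message for r in caplog.records)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            category_coverage({}, self._lexicon(), ["nope"])


class TestLabelCorrelations:
    def test_identical_vectors(self):
        r, flagged = label_correlations([1, 0, 1, 0], [1, 0, 1, 0])["label_0"]
        assert r == pytest.approx(1.0)
        assert not flagged

    def test_orthogonal_case(self):
        r, _ = label_correlations([1, 1, 0, 0], [1, 0, 1, 0])["label_0"]
        assert r == pytest.approx(0.0)

    def test_constant_vector_flagged_zero(self):
        r, flagged = label_correlations([1, 0, 1, 0], [1, 1, 1, 1])["label_0"]
        assert (r, flagged) == (0.0, True)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            label_correlations([1, 0], [1, 0, 1])

    def test_planted_correlation_recovered(self):
        from contourclf.synthetic import GeneratorConfig, generate_auxiliary
        from contourclf.corpus import Document
        estimates = []
        for seed in range(5):
            cfg = GeneratorConfig(n_docs=2000, r_emotion=(0.6, 0, 0, 0, 0, 0),
                                  seed=seed)
            rng = np.random.default_rng(seed)
            docs = [Document(doc_id=str(i), text="x.", label=int(rng.random() < 0.5))
                    for i in range(2000)]
            generate_auxiliary(cfg, docs)
            silver = np.array([d.emotion for d in docs])
            gold = np.array([d.label for d in docs])
            r, _ = label_correlations(gold, silver[:, 0:1])["label_0"]
            estimates.append(r)
        assert all(abs(r - 0.6) <= 0.06 for r in estimates)
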