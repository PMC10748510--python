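import numpy as np
import pytest

from contourclf.corpus import Document, read_corpus, write_corpus
from contourclf.features.lexicon import LEXICON_SLOTS
from contourclf.features.registry import LBF_SLOT_LAYOUT
from contourclf.synthetic import (
    GeneratorConfig,
    generate_auxiliary,
    generate_corpus,
    generate_lexicons,
    generate_vocabulary,
    write_fixture_suite,
    write_lexicon_files,
)


class TestConfigValidation:
    def test_small_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="200"):
            GeneratorConfig(vocab_size=100)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(p_case=1.5)

    def test_bad_correlation_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(r_emotion=(2.0, 0, 0, 0, 0, 0))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(planted_group="nope")


class TestLexiconGeneration:
    def test_seven_slots_emitted(self, lexicons):
        assert set(lexicons) == set(LEXICON_SLOTS)

    def test_every_registry_category_nonempty(self, lexicons):
        for slot, (kind, targets, _stats) in LBF_SLOT_LAYOUT.items():
            if kind == "categorical":
                for cat in targets:
                    assert lexicons[slot].words_in_category(cat)
            else:
                assert lexicons[slot].norm_names() == set(targets)

    def test_categories_disjoint_within_slot(self, lexicons):
        for slot, lex in lexicons.items():
            for word, cats in lex.categorical.items():
                if " " not in word:  # the demo bigram may overlap
                    assert len(cats) == 1

    def test_byte_identical_under_seed(self, gen_cfg, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_lexicon_files(generate_lexicons(gen_cfg), d1)
        write_lexicon_files(generate_lexicons(gen_cfg), d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()


class TestCorpusGeneration:
    def test_deterministic_under_seed(self, gen_cfg, lexicons):
        a = generate_corpus(gen_cfg, lexicons)
        b = generate_corpus(gen_cfg, lexicons)
        assert [(d.doc_id, d.text, d.label, d.split) for d in a] == \
               [(d.doc_id, d.text, d.label, d.split) for d in b]

    def test_round_trip_through_reader(self, gen_cfg, lexicons, tmp_path):
        docs = generate_auxiliary(gen_cfg, generate_corpus(gen_cfg, lexicons))
        path = tmp_path / "corpus.jsonl"
        write_corpus(docs, path)
        again = read_corpus(path)
        assert [(d.doc_id, d.text, d.label, d.split, d.emotion, d.personality)
                for d in docs] == \
               [(d.doc_id, d.text, d.label, d.split, d.emotion, d.personality)
                for d in again]

    def test_class_balance_within_binomial_error(self):
        cfg = GeneratorConfig(n_docs=1000, seed=3)
        docs = generate_corpus(cfg)
        rate = np.mean([d.label for d in docs])
        assert abs(rate - 0.5) < 3 * 0.5 / np.sqrt(1000)

    def test_planted_emission_rates(self):
        # per-sentence emission probabilities recovered within +-0.03
        cfg = GeneratorConfig(n_docs=1000, p_case=0.3, p_control=0.05, seed=5)
        lexicons = generate_lexicons(cfg)
        planted = lexicons[cfg.planted_slot].words_in_category(cfg.planted_category)
        planted = {w for w in planted if " " not in w}
        rates = {0: [], 1: []}
        for doc in generate_corpus(cfg, lexicons):
            for sent in doc.text.lower().split("."):
                words = sent.split()
                if words:
                    rates[doc.label].append(bool(planted & set(words)))
        assert abs(np.mean(rates[1]) - 0.3) <= 0.03
        assert abs(np.mean(rates[0]) - 0.05) <= 0.03

    def test_null_config_classes_indistinguishable(self):
        # d=0 and equal emission rates: mean sentence length must not
        # separate the classes (two-sample t at alpha=0.01)
        from scipy import stats
        cfg = GeneratorConfig(n_docs=400, effect_size=0.0, p_case=0.1,
                              p_control=0.1, seed=6)
        docs = generate_corpus(cfg)
        by_class = {0: [], 1: []}
        for doc in docs:
            lengths = [len(s.split()) for s in doc.text.split(".") if s.strip()]
            by_class[doc.label].append(np.mean(lengths))
        _, p = stats.ttest_ind(by_class[0], by_class[1])
        assert p > 0.01

    def test_effect_size_shifts_sentence_length(self):
        cfg = GeneratorConfig(n_docs=400, effect_size=1.5, seed=7)
        docs = generate_corpus(cfg)
        means = {0: [], 1: []}
        for doc in docs:
            lengths = [len(s.split()) for s in doc.text.split(".") if s.strip()]
            means[doc.label].append(np.mean(lengths))
        assert np.mean(means[1]) - np.mean(means[0]) > 2.0


class TestVocabulary:
    def test_syllable_structure(self, gen_cfg):
        from contourclf.annotation import count_syllables
        vocab = generate_vocabulary(gen_cfg)
        for n_syll, words in vocab.items():
            hits = sum(count_syllables(w) == n_syll for w in words)
            assert hits / len(words) > 0.85  # silent-e edge cases allowed

    def test_total_size(self, gen_cfg):
        vocab = generate_vocabulary(gen_cfg)
        assert sum(len(v) for v in vocab.values()) == gen_cfg.vocab_size


class TestAuxiliary:
    def _docs(self, n, seed):
        rng = np.random.default_rng(seed)
        return [Document(doc_id=str(i), text="x.", label=int(rng.random() < 0.5))
                for i in range(n)]

    def test_zero_target_near_zero(self):
        cfg = GeneratorConfig(n_docs=2000, seed=8)
        docs = generate_auxiliary(cfg, self._docs(2000, 8))
        gold = np.array([d.label for d in docs])
        emo = np.array([d.emotion for d in docs], dtype=float)
        for j in range(6):
            assert abs(np.corrcoef(gold, emo[:, j])[0, 1]) < 0.05

    def test_target_point_six_recovered(self):
        cfg = GeneratorConfig(n_docs=2000, r_emotion=(0.6, 0, 0, 0, 0, 0), seed=9)
        docs = generate_auxiliary(cfg, self._docs(2000, 9))
        gold = np.array([d.label for d in docs])
        emo = np.array([d.emotion for d in docs], dtype=float)
        r = np.corrcoef(gold, emo[:, 0])[0, 1]
        assert 0.54 <= r <= 0.66

    def test_perfect_correlation_identity_when_balanced(self):
        docs = [Document(doc_id=str(i), text="x.", label=i % 2) for i in range(100)]
        cfg = GeneratorConfig(n_docs=100, r_emotion=(1.0, 0, 0, 0, 0, 0), seed=11)
        generate_auxiliary(cfg, docs)
        assert all(d.emotion[0] == d.label for d in docs)

    def test_infeasible_correlation_names_range(self):
        docs = [Document(doc_id=str(i), text="x.", label=int(i < 90))
                for i in range(100)]
        cfg = GeneratorConfig(n_docs=100, r_emotion=(0.99, 0, 0, 0, 0, 0), seed=12)
        with pytest.raises(ValueError, match="feasible range"):
            generate_auxiliary(cfg, docs)


def test_fixture_suite_is_deterministic(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_fixture_suite(d1, seed=0)
    write_fixture_suite(d2, seed=0)
    assert (d1 / "corpus.jsonl").read_bytes() == (d2 / "corpus.jsonl").read_bytes()
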