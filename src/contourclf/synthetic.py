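"""Deterministic synthetic corpora, lexicons and auxiliary labels.

Everything the pipeline consumes can be generated here with planted,
analytically known structure: binary condition labels, a per-class shift
of one GLF group's distribution (standardized effect size ``d``), planted
lexicon-word emission rates (``p_case`` vs ``p_control``) and auxiliary
emotion/personality labels with configurable Pearson correlation to the
condition label (2x2 contingency construction with a specified phi
coefficient).

Text is realized from a closed synthetic vocabulary with controlled word
lengths and syllable counts, so feature-level ground truth is computable
by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Document
from .features.lexicon import LEXICON_SLOTS, Lexicon, write_lexicon
from .features.registry import GLF_GROUPS, LBF_SLOT_LAYOUT

_ONSETS = "b d f g k l m n p r s t v z".split()
_VOWELS = "a e i o u".split()
_CODAS = ["", "n", "s", "r", "l", "t"]


@dataclass
class GeneratorConfig:
    n_docs: int = 200
    class_balance: float = 0.5
    sentence_mean: float = 8.0          # Poisson mean (floored at 1)
    planted_group: str = "morphosyntactic"
    effect_size: float = 0.0            # standardized mean shift for cases
    p_case: float = 0.0                 # planted-word emission rate, cases
    p_control: float = 0.0              # planted-word emission rate, controls
    planted_slot: str = "ANEW-Emo"
    planted_category: str = "sadness"
    r_emotion: tuple = (0.0,) * 6
    r_personality: tuple = (0.0,) * 4
    vocab_size: int = 600
    split_fractions: tuple = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        for p in (self.p_case, self.p_control):
            if not 0.0 <= p <= 1.0:
                raise ValueError("emission rates must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.planted_group not in GLF_GROUPS:
            raise ValueError(f"planted_group must be one of {GLF_GROUPS}")
        if len(self.r_emotion) != 6 or len(self.r_personality) != 4:
            raise ValueError("r_emotion needs 6 entries, r_personality 4")
        for r in (*self.r_emotion, *self.r_personality):
            if abs(r) > 1:
                raise ValueError("correlation targets must lie in [-1, 1]")
        if self.vocab_size < 200:
            raise ValueError("vocabulary must contain at least 200 words")


def generate_vocabulary(cfg: GeneratorConfig) -> dict[int, list[str]]:
    """Closed vocabulary keyed by syllable count (1..3); deterministic."""
    rng = np.random.default_rng(cfg.seed + 11)
    seen: set[str] = set()
    by_syll: dict[int, list[str]] = {1: [], 2: [], 3: []}
    target = {1: cfg.vocab_size // 3, 2: cfg.vocab_size // 3,
              3: cfg.vocab_size - 2 * (cfg.vocab_size // 3)}

    def syllable() -> str:
        return (_ONSETS[rng.integers(len(_ONSETS))]
                + _VOWELS[rng.integers(len(_VOWELS))]
                + _CODAS[rng.integers(len(_CODAS))])

    for n_syll in (1, 2, 3):
        while len(by_syll[n_syll]) < target[n_syll]:
            word = "".join(syllable() for _ in range(n_syll))
            if word not in seen:
                seen.add(word)
                by_syll[n_syll].append(word)
    return by_syll


# ---------------------------------------------------------------------------
# lexicons

def generate_lexicons(cfg: GeneratorConfig) -> dict[str, Lexicon]:
    """Seven slot lexicons whose categories/norms match the default
    registry layout; category word lists are disjoint within each slot."""
    vocab = generate_vocabulary(cfg)
    flat = vocab[1] + vocab[2] + vocab[3]
    rng = np.random.default_rng(cfg.seed + 23)
    lexicons: dict[str, Lexicon] = {}
    for slot in LEXICON_SLOTS:
        kind, targets, _stats = LBF_SLOT_LAYOUT[slot]
        lex = Lexicon(slot=slot)
        if kind == "categorical":
            n_per_cat = max(2, min(4, len(flat) // (2 * len(targets))))
            order = rng.permutation(len(flat))
            pos = 0
            for cat in targets:
                for _ in range(n_per_cat):
                    lex.add(flat[order[pos % len(flat)]], cat)
                    pos += 1
            # one bigram entry per slot exercises bigram matching
            lex.add(f"{flat[order[0]]} {flat[order[1]]}", targets[0])
        else:
            n_words = min(len(flat), 120)
            chosen = rng.permutation(len(flat))[:n_words]
            lo, hi = (1.0, 9.0) if slot == "ANEW" else (-1.0, 1.0)
            for widx in chosen:
                for norm in targets:
                    lex.add_norm(flat[widx], norm, round(float(rng.uniform(lo, hi)), 3))
        lexicons[slot] = lex
    return lexicons


def write_lexicon_files(lexicons: dict[str, Lexicon], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for slot, lex in lexicons.items():
        path = outdir / f"{slot.lower().replace('-', '_')}.tsv"
        write_lexicon(lex, path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# corpus

_BASE_SENT_SD = 2.0


def _make_sentence(rng, vocab, n_words: int, label: int, cfg: GeneratorConfig,
                   planted_words: list[str], prev_content: list[str]) -> list[str]:
    d = cfg.effect_size if label == 1 else 0.0
    p_poly = min(0.2 + (0.12 * d if cfg.planted_group == "readability" else 0.0), 0.9)
    p_repeat = min(0.15 + (0.18 * d if cfg.planted_group == "lexical" else 0.0), 0.9)
    p_cohere = min(0.15 + (0.20 * d if cfg.planted_group == "cohesion" else 0.0), 0.9)
    p_common = min(0.3 + (0.15 * d if cfg.planted_group == "stylistic" else 0.0), 0.95)

    words: list[str] = []
    for _ in range(n_words):
        if prev_content and rng.random() < p_cohere:
            words.append(prev_content[rng.integers(len(prev_content))])
        elif words and rng.random() < p_repeat:
            words.append(words[rng.integers(len(words))])
        else:
            if rng.random() < p_poly:
                pool = vocab[3]
            elif rng.random() < p_common:
                pool = vocab[1]
            else:
                pool = vocab[2]
            words.append(pool[rng.integers(len(pool))])
    p_emit = cfg.p_case if label == 1 else cfg.p_control
    if planted_words and rng.random() < p_emit:
        words[rng.integers(len(words))] = planted_words[rng.integers(len(planted_words))]
    return words


def generate_corpus(cfg: GeneratorConfig,
                    lexicons: dict[str, Lexicon] | None = None) -> list[Document]:
    """A labeled JSONL-ready corpus with the configured planted signal.

    Case documents shift the planted GLF group's underlying parameter by
    ``effect_size`` standard deviations and emit planted lexicon words at
    ``p_case`` (vs ``p_control``) per sentence.  Fully deterministic under
    ``seed``.
    """
    if lexicons is None:
        lexicons = generate_lexicons(cfg)
    planted_words = sorted(
        lexicons[cfg.planted_slot].words_in_category(cfg.planted_category))
    planted_words = [w for w in planted_words if " " not in w]
    planted_set = set(planted_words)
    # planted words enter only through the emission mechanism, so per-class
    # emission rates stay analytically exact
    vocab = {k: [w for w in v if w not in planted_set] or v
             for k, v in generate_vocabulary(cfg).items()}
    rng = np.random.default_rng(cfg.seed)
    labels = (rng.random(cfg.n_docs) < cfg.class_balance).astype(int)
    f_train, f_val, _ = cfg.split_fractions
    u = rng.random(cfg.n_docs)
    splits = np.where(u < f_train, "train",
                      np.where(u < f_train + f_val, "val", "test"))
    docs: list[Document] = []
    for i in range(cfg.n_docs):
        label = int(labels[i])
        T = max(int(rng.poisson(cfg.sentence_mean)), 1)
        sentences = []
        prev_content: list[str] = []
        for _ in range(T):
            mu = 8.0 + (
                cfg.effect_size * _BASE_SENT_SD
                if (label == 1 and cfg.planted_group == "morphosyntactic") else 0.0)
            n_words = max(int(round(rng.normal(mu, _BASE_SENT_SD))), 3)
            words = _make_sentence(rng, vocab, n_words, label, cfg,
                                   planted_words, prev_content)
            prev_content = [w for w in words if w not in planted_set]
            sentences.append(words[0].capitalize() + " " + " ".join(words[1:]) + ".")
        docs.append(Document(
            doc_id=f"doc{i:05d}", text=" ".join(sentences), label=label,
            split=str(splits[i]),
        ))
    return docs


# ---------------------------------------------------------------------------
# auxiliary labels

def _conditional_rates(p: float, q: float, r: float) -> tuple[float, float]:
    """P(a=1 | y=1) and P(a=1 | y=0) for Bernoulli labels with marginals
    p (condition), q (auxiliary) and phi coefficient r."""
    s = np.sqrt(q * (1 - q))
    t = np.sqrt(p * (1 - p))
    p1 = q + r * s * (1 - p) / t
    p0 = q - r * s * p / t
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p0 <= 1.0):
        lo = -min(np.sqrt(p * q / ((1 - p) * (1 - q))),
                  np.sqrt((1 - p) * (1 - q) / (p * q)))
        hi = min(np.sqrt(p * (1 - q) / ((1 - p) * q)),
                 np.sqrt((1 - p) * q / (p * (1 - q))))
        raise ValueError(
            f"correlation {r} infeasible for marginals p={p:.3f}, q={q:.3f}; "
            f"feasible range is [{lo:.3f}, {hi:.3f}]")
    return float(p1), float(p0)


def generate_auxiliary(cfg: GeneratorConfig, docs: list[Document],
                       aux_marginal: float = 0.5) -> list[Document]:
    """Attach gold emotion (6) and personality (4) labels whose Pearson
    correlation with the condition label matches the configured targets
    within sampling error."""
    y = np.array([d.label for d in docs], dtype=float)
    p = float(y.mean())
    if p in (0.0, 1.0):
        raise ValueError("condition labels are constant; correlations undefined")
    rng = np.random.default_rng(cfg.seed + 37)

    def draw(r: float) -> np.ndarray:
        if abs(r) == 1.0 and abs(p - aux_marginal) < 1e-12:
            return (y if r > 0 else 1 - y).astype(int)
        p1, p0 = _conditional_rates(p, aux_marginal, r)
        u = rng.random(len(y))
        return np.where(y == 1, u < p1, u < p0).astype(int)

    emotion = np.stack([draw(r) for r in cfg.r_emotion], axis=1)
    personality = np.stack([draw(r) for r in cfg.r_personality], axis=1)
    for i, doc in enumerate(docs):
        doc.emotion = emotion[i].tolist()
        doc.personality = personality[i].tolist()
    return docs


# ---------------------------------------------------------------------------
# fixture suite

def write_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """The small deterministic corpus + lexicon suite used by the tests
    and the CLI demo."""
    from .corpus import write_corpus

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(n_docs=60, effect_size=1.5, p_case=0.4,
                          p_control=0.05, r_emotion=(0.5, 0, 0, 0, 0, 0),
                          r_personality=(0.4, 0, 0, 0), seed=seed)
    lexicons = generate_lexicons(cfg)
    lex_paths = write_lexicon_files(lexicons, outdir / "lexicons")
    docs = generate_auxiliary(cfg, generate_corpus(cfg, lexicons))
    corpus_path = outdir / "corpus.jsonl"
    write_corpus(docs, corpus_path)
    return {"corpus": corpus_path, "lexicons": lex_paths[0].parent}
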