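"""Scorer implementations for the general linguistic features (GLFs).

Each scorer maps a window (a list of annotated sentences, with the
sentence immediately preceding the window available for cohesion
measures) to one finite real value.  Degenerate windows never produce
NaN/inf: divisions floor their denominators at one and missing material
scores zero.

Formulas of note (documented here; exercised by hand-computed tests):

* Flesch-Kincaid grade = 0.39*(words/sentences) + 11.8*(syllables/words) - 15.59
* type-token ratio = distinct word surfaces / word tokens
* adjacent-sentence content overlap = |A ∩ B| / |A ∪ B| over content lemmas
* register n-gram frequency scores = mean log(frequency + 1) over window
  n-grams against a per-register frequency table
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..annotation import Token
from .registry import FeatureSpec, REGISTERS

Sentence = list[Token]

_SUBORDINATORS = frozenset(
    "because although though while if unless since whereas when whenever "
    "whether that after before until".split()
)
_COORDINATORS = frozenset("and or but nor so yet".split())
_MODALS = frozenset("will would can could shall should may might must".split())
_NEGATIONS = frozenset("not n't never no nothing nobody none neither".split())

CONNECTIVES: dict[str, frozenset[str]] = {
    "additive": frozenset("and also moreover furthermore besides additionally plus".split()),
    "adversative": frozenset("but however yet although though nevertheless nonetheless whereas instead".split()),
    "causal": frozenset("because since so therefore thus hence consequently".split()),
    "temporal": frozenset("then when while before after meanwhile until later".split()),
    "sequential": frozenset("first second third next finally lastly subsequently".split()),
    "conditional": frozenset("if unless otherwise provided".split()),
    "illustrative": frozenset("example instance namely specifically".split()),
    "emphatic": frozenset("indeed certainly clearly obviously surely".split()),
    "summative": frozenset("overall conclusion sum summary altogether".split()),
    "comparative": frozenset("similarly likewise conversely equally".split()),
}

# A compact familiar-word list standing in for the graded vocabularies used
# by the Dale-Chall and Spache formulas.
EASY_WORDS = frozenset(
    """a about after again all an and any are as at back be because been
    before big boy but by call came can come could day did do down eat for
    from get go good had has have he her here him his home house how i if
    in into is it its just know like little long look made make man many
    may me men more most mother much must my new no not now of off old on
    one or other our out over people put red right run said saw say see
    she so some than that the their them then there these they this time
    to two up us very was we well went were what when where which who will
    with work would year you your cat sat mat dog sleep ran hid slept woke
    """.split()
)


# ---------------------------------------------------------------------------
# register n-gram tables

@dataclass
class RegisterTable:
    """Per-register n-gram frequency/rank table for stylistic features."""

    tables: dict[str, dict[str, tuple[float, int]]] = field(default_factory=dict)

    def lookup(self, register: str, ngram: str) -> tuple[float, int] | None:
        return self.tables.get(register, {}).get(ngram)

    def add(self, ngram: str, register: str, frequency: float, rank: int) -> None:
        self.tables.setdefault(register, {})[ngram.lower()] = (float(frequency), int(rank))

    @classmethod
    def load_tsv(cls, path: str | Path) -> "RegisterTable":
        """Load ``ngram<TAB>register<TAB>frequency<TAB>rank`` lines."""
        table = cls()
        with Path(path).open("r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
                table.add(parts[0], parts[1], float(parts[2]), int(parts[3]))
        return table

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for register in sorted(self.tables):
                for ngram in sorted(self.tables[register]):
                    freq, rank = self.tables[register][ngram]
                    fh.write(f"{ngram}\t{register}\t{freq:g}\t{rank}\n")


_DEFAULT_TABLE: RegisterTable | None = None

_BASE_VOCAB = sorted(EASY_WORDS | frozenset(
    """feeling thought mind world life night morning heavy quiet empty
    bright calm worry fear hope joy anger sadness surprise trust panic
    restless tired awake asleep alone together friend family doctor
    therapy medicine routine focus energy mood swing racing slow fast
    deadline pressure message screen window street river mountain paper
    coffee breakfast dinner walking running reading writing talking
    listening thinking remember forget struggle effort change moment
    """.split()
))


def default_register_table() -> RegisterTable:
    """A small deterministic Zipf-shaped table over a built-in vocabulary.

    Ranks are a register-specific permutation (seeded once, never from
    global state) so the seven registers give distinct but reproducible
    frequency profiles; frequencies follow freq = 1e6 / rank**1.1.
    """
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        table = RegisterTable()
        vocab = list(_BASE_VOCAB)
        for ridx, register in enumerate(REGISTERS):
            rng = np.random.default_rng(7_000 + ridx)
            order = rng.permutation(len(vocab))
            for rank0, widx in enumerate(order):
                rank = rank0 + 1
                freq = 1e6 / rank ** 1.1
                table.add(vocab[widx], register, freq, rank)
            # a handful of bigrams per register, built from the top unigrams
            top = [vocab[i] for i in order[:40]]
            for b0 in range(0, 38, 2):
                bigram = f"{top[b0]} {top[b0 + 1]}"
                rank = b0 // 2 + 1
                table.add(bigram, register, 2e5 / rank ** 1.1, rank)
        _DEFAULT_TABLE = table
    return _DEFAULT_TABLE


def default_prevalence(word: str, registers: RegisterTable) -> float:
    """Word-prevalence stand-in: log-frequency in the general register,
    falling back to a length-based estimate for out-of-table words."""
    hit = registers.lookup("general", word.lower())
    if hit is not None:
        return math.log(hit[0] + 1.0)
    return max(1.0, 8.0 - 0.5 * len(word))


# ---------------------------------------------------------------------------
# window context and helpers

@dataclass
class ScoreContext:
    """Everything a scorer may consult besides the window itself."""

    prev_sentence: Sentence | None = None
    registers: RegisterTable | None = None

    def register_table(self) -> RegisterTable:
        return self.registers if self.registers is not None else default_register_table()


def _words(window: list[Sentence]) -> list[Token]:
    return [t for s in window for t in s if t.pos != "PUNCT"]


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def _content_lemmas(sentence: Sentence) -> set[str]:
    return {t.lemma for t in sentence if t.is_content}


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _adjacent_pairs(window: list[Sentence], prev: Sentence | None) -> list[tuple[Sentence, Sentence]]:
    pairs = []
    if prev is not None and window:
        pairs.append((prev, window[0]))
    for i in range(len(window) - 1):
        pairs.append((window[i], window[i + 1]))
    return pairs


def _pair_mean(window, ctx, fn) -> float:
    pairs = _adjacent_pairs(window, ctx.prev_sentence)
    if not pairs:
        return 0.0
    return float(np.mean([fn(a, b) for a, b in pairs]))


# ---------------------------------------------------------------------------
# morphosyntactic scorers

def _score_morphosyntactic(params: tuple, window: list[Sentence], ctx: ScoreContext) -> float:
    words = _words(window)
    all_tokens = [t for s in window for t in s]
    n_words = len(words)
    n_sent = max(len(window), 1)
    key = params[0]
    if key == "pos_prop":
        tag = params[1]
        return _safe_div(sum(1 for t in all_tokens if t.pos == tag), len(all_tokens))
    if key == "pos_per_sentence":
        tag = params[1]
        return sum(1 for t in all_tokens if t.pos == tag) / n_sent
    if key == "mean_sentence_length_words":
        return n_words / n_sent
    if key == "mean_sentence_length_chars":
        return sum(len(t.surface) for t in words) / n_sent
    if key == "mean_sentence_length_syllables":
        return sum(t.syllables for t in words) / n_sent
    if key == "mean_word_length_chars":
        return _safe_div(sum(len(t.surface) for t in words), n_words)
    finite = sum(1 for t in words if t.is_finite_verb)
    verbs = sum(1 for t in words if t.pos in ("VERB", "AUX"))
    if key == "finite_verbs_per_sentence":
        return finite / n_sent
    if key == "finite_verb_ratio":
        return _safe_div(finite, verbs)
    if key == "tokens_per_finite_verb":
        return _safe_div(n_words, max(finite, 1)) if n_words else 0.0
    lows = [t.surface.lower() for t in words]
    if key == "subordinator_rate":
        return _safe_div(sum(1 for w in lows if w in _SUBORDINATORS), n_words)
    if key == "subordinators_per_sentence":
        return sum(1 for w in lows if w in _SUBORDINATORS) / n_sent
    if key == "coordinator_rate":
        return _safe_div(sum(1 for w in lows if w in _COORDINATORS), n_words)
    if key == "coordinators_per_sentence":
        return sum(1 for w in lows if w in _COORDINATORS) / n_sent
    counts = {tag: sum(1 for t in words if t.pos == tag) for tag in
              ("NOUN", "VERB", "ADJ", "ADV", "PRON")}
    if key == "noun_verb_ratio":
        return _safe_div(counts["NOUN"], max(counts["VERB"], 1))
    if key == "adj_noun_ratio":
        return _safe_div(counts["ADJ"], max(counts["NOUN"], 1))
    if key == "adv_verb_ratio":
        return _safe_div(counts["ADV"], max(counts["VERB"], 1))
    if key == "pronoun_noun_ratio":
        return _safe_div(counts["PRON"], max(counts["NOUN"], 1))
    if key == "function_content_ratio":
        content = sum(1 for t in words if t.is_content)
        return _safe_div(n_words - content, max(content, 1))
    if key == "question_rate":
        return sum(1 for s in window if s and s[-1].surface == "?") / n_sent
    if key == "exclamation_rate":
        return sum(1 for s in window if s and s[-1].surface == "!") / n_sent
    if key == "negation_rate":
        return _safe_div(sum(1 for w in lows if w in _NEGATIONS), n_words)
    if key == "to_infinitive_rate":
        hits = 0
        for s in window:
            for i in range(len(s) - 1):
                if s[i].surface.lower() == "to" and s[i + 1].pos in ("VERB", "AUX"):
                    hits += 1
        return _safe_div(hits, n_words)
    if key == "comparative_rate":
        hits = sum(1 for w in lows if w == "more" or (w.endswith("er") and len(w) > 4))
        return _safe_div(hits, n_words)
    if key == "superlative_rate":
        hits = sum(1 for w in lows if w == "most" or (w.endswith("est") and len(w) > 4))
        return _safe_div(hits, n_words)
    if key == "passive_like_rate":
        hits = 0
        for s in window:
            for i in range(len(s) - 1):
                if s[i].pos == "AUX" and s[i + 1].surface.lower().endswith("ed"):
                    hits += 1
        return _safe_div(hits, n_words)
    if key == "modal_rate":
        return _safe_div(sum(1 for w in lows if w in _MODALS), n_words)
    raise KeyError(f"unknown morphosyntactic scorer {key!r}")


# ---------------------------------------------------------------------------
# lexical scorers

def _score_lexical(params: tuple, window: list[Sentence], ctx: ScoreContext) -> float:
    key = params[0]
    words = _words(window)
    n = len(words)
    lows = [t.surface.lower() for t in words]
    types = set(lows)
    if key == "ttr":
        return _safe_div(len(types), n)
    if key == "root_ttr":
        return _safe_div(len(types), math.sqrt(n)) if n else 0.0
    if key == "log_ttr":
        return _safe_div(math.log(len(types) + 1), math.log(n + 1)) if n else 0.0
    if key == "maas_index":
        if n < 2 or len(types) < 1:
            return 0.0
        return max((math.log(n) - math.log(len(types))) / (math.log(n) ** 2), 0.0)
    content = [t for t in words if t.is_content]
    if key == "content_ttr":
        return _safe_div(len({t.surface.lower() for t in content}), len(content))
    for tag, kname in (("NOUN", "noun_ttr"), ("VERB", "verb_ttr"),
                       ("ADJ", "adj_ttr"), ("ADV", "adv_ttr")):
        if key == kname:
            sel = [t.surface.lower() for t in words if t.pos == tag]
            return _safe_div(len(set(sel)), len(sel))
    if key == "lemma_ttr":
        return _safe_div(len({t.lemma for t in words}), n)
    if key == "hapax_rate":
        from collections import Counter
        counts = Counter(lows)
        return _safe_div(sum(1 for c in counts.values() if c == 1), n)
    if key == "bigram_ttr":
        bigrams = list(zip(lows, lows[1:]))
        return _safe_div(len(set(bigrams)), len(bigrams))
    if key == "lexical_density":
        return _safe_div(len(content), n)
    for tag, kname in (("NOUN", "noun_density"), ("VERB", "verb_density"),
                       ("ADJ", "adj_density"), ("ADV", "adv_density")):
        if key == kname:
            return _safe_div(sum(1 for t in words if t.pos == tag), n)
    if key == "function_density":
        return _safe_div(n - len(content), n)
    if key == "mean_content_word_length":
        return _safe_div(sum(len(t.surface) for t in content), len(content))
    if key == "mean_syllables_per_word":
        return _safe_div(sum(t.syllables for t in words), n)
    if key == "prop_long_words":
        return _safe_div(sum(1 for t in words if len(t.surface) > 6), n)
    if key == "prop_polysyllabic":
        return _safe_div(sum(1 for t in words if t.syllables >= 3), n)
    if key == "prop_monosyllabic":
        return _safe_div(sum(1 for t in words if t.syllables == 1), n)

    table = ctx.register_table()

    def logfreq(word: str) -> float:
        hit = table.lookup("general", word)
        return math.log(hit[0] + 1.0) if hit is not None else 0.0

    def logrank(word: str) -> float:
        hit = table.lookup("general", word)
        return math.log(hit[1]) if hit is not None else math.log(1e5)

    if key == "mean_log_freq_all":
        return _safe_div(sum(logfreq(w) for w in lows), n)
    if key == "mean_log_freq_content":
        sel = [t.surface.lower() for t in content]
        return _safe_div(sum(logfreq(w) for w in sel), len(sel))
    if key == "prop_low_freq":
        hits = sum(1 for w in lows
                   if (h := table.lookup("general", w)) is None or h[1] > 100)
        return _safe_div(hits, n)
    if key == "mean_logrank_all":
        return _safe_div(sum(logrank(w) for w in lows), n)
    if key == "mean_logrank_content":
        sel = [t.surface.lower() for t in content]
        return _safe_div(sum(logrank(w) for w in sel), len(sel))
    if key.startswith("freq_band"):
        band = int(key[9])  # 1..4 -> rank quartile bands of 50
        lo, hi = (band - 1) * 50, band * 50
        hits = 0
        for w in lows:
            h = table.lookup("general", w)
            if h is not None and lo < h[1] <= hi:
                hits += 1
        return _safe_div(hits, n)
    if key == "oov_rate":
        return _safe_div(sum(1 for w in lows if table.lookup("general", w) is None), n)

    prevs = [default_prevalence(w, table) for w in lows]
    cprevs = [default_prevalence(t.surface.lower(), table) for t in content]
    if key == "prevalence_mean_all":
        return float(np.mean(prevs)) if prevs else 0.0
    if key == "prevalence_mean_content":
        return float(np.mean(cprevs)) if cprevs else 0.0
    if key == "prevalence_min_all":
        return float(np.min(prevs)) if prevs else 0.0
    if key == "prevalence_min_content":
        return float(np.min(cprevs)) if cprevs else 0.0
    if key == "prevalence_max_all":
        return float(np.max(prevs)) if prevs else 0.0
    if key == "prevalence_max_content":
        return float(np.max(cprevs)) if cprevs else 0.0
    if key == "prevalence_sd_all":
        return float(np.std(prevs)) if prevs else 0.0
    if key == "prevalence_sd_content":
        return float(np.std(cprevs)) if cprevs else 0.0
    if key == "prevalence_range":
        return float(np.max(prevs) - np.min(prevs)) if prevs else 0.0
    if key == "prevalence_median":
        return float(np.median(prevs)) if prevs else 0.0
    if key == "prop_low_prevalence":
        return _safe_div(sum(1 for p in prevs if p < 4.0), n)
    if key == "prop_high_prevalence":
        return _safe_div(sum(1 for p in prevs if p >= 8.0), n)
    raise KeyError(f"unknown lexical scorer {key!r}")


# ---------------------------------------------------------------------------
# readability scorers

def _score_readability(index: str, window: list[Sentence], ctx: ScoreContext) -> float:
    words = _words(window)
    n_words = max(len(words), 1)
    n_sent = max(len(window), 1)
    syllables = sum(t.syllables for t in words) or 1
    chars = sum(len(t.surface) for t in words)
    poly = sum(1 for t in words if t.syllables >= 3)
    mono = sum(1 for t in words if t.syllables == 1)
    long_words = sum(1 for t in words if len(t.surface) > 6)
    wps = len(words) / n_sent
    spw = syllables / n_words

    if index == "flesch_reading_ease":
        return 206.835 - 1.015 * wps - 84.6 * spw
    if index == "flesch_kincaid_grade":
        return 0.39 * wps + 11.8 * spw - 15.59
    if index == "gunning_fog":
        return 0.4 * (wps + 100.0 * poly / n_words)
    if index == "smog":
        return 1.043 * math.sqrt(poly * 30.0 / n_sent) + 3.1291
    if index == "ari":
        return 4.71 * chars / n_words + 0.5 * wps - 21.43
    if index == "coleman_liau":
        return 5.88 * chars / n_words - 29.6 * (n_sent / n_words) - 15.8
    if index == "lix":
        return wps + 100.0 * long_words / n_words
    if index == "rix":
        return long_words / n_sent
    unfamiliar = sum(1 for t in words if t.surface.lower() not in EASY_WORDS)
    if index == "dale_chall":
        pdw = 100.0 * unfamiliar / n_words
        score = 0.1579 * pdw + 0.0496 * wps
        return score + 3.6365 if pdw > 5.0 else score
    if index == "linsear_write":
        easy = mono + sum(1 for t in words if t.syllables == 2)
        raw = (easy + 3.0 * poly) / n_sent
        return raw / 2.0 if raw > 20 else raw / 2.0 - 1.0
    if index == "forcast":
        return 20.0 - (mono * 150.0 / n_words) / 10.0
    if index == "strain_index":
        # syllable load of the first three sentences, scaled
        first3 = window[:3]
        syl3 = sum(t.syllables for s in first3 for t in s if t.pos != "PUNCT")
        return syl3 / 10.0
    if index == "spache":
        return 0.121 * wps + 0.082 * (100.0 * unfamiliar / n_words) + 0.659
    raise KeyError(f"unknown readability index {index!r}")


# ---------------------------------------------------------------------------
# cohesion scorers

def _score_cohesion(params: tuple, window: list[Sentence], ctx: ScoreContext) -> float:
    key = params[0]
    if key == "jaccard_content":
        return _pair_mean(window, ctx, lambda a, b: _jaccard(_content_lemmas(a), _content_lemmas(b)))
    if key == "jaccard_noun":
        return _pair_mean(window, ctx, lambda a, b: _jaccard(
            {t.lemma for t in a if t.pos == "NOUN"}, {t.lemma for t in b if t.pos == "NOUN"}))
    if key == "jaccard_verb":
        return _pair_mean(window, ctx, lambda a, b: _jaccard(
            {t.lemma for t in a if t.pos in ("VERB", "AUX")},
            {t.lemma for t in b if t.pos in ("VERB", "AUX")}))
    if key == "jaccard_all_lemma":
        return _pair_mean(window, ctx, lambda a, b: _jaccard(
            {t.lemma for t in a if t.pos != "PUNCT"}, {t.lemma for t in b if t.pos != "PUNCT"}))
    if key == "jaccard_surface":
        return _pair_mean(window, ctx, lambda a, b: _jaccard(
            {t.surface.lower() for t in a if t.pos != "PUNCT"},
            {t.surface.lower() for t in b if t.pos != "PUNCT"}))
    if key == "overlap_min_content":
        def fn(a, b):
            sa, sb = _content_lemmas(a), _content_lemmas(b)
            m = min(len(sa), len(sb))
            return len(sa & sb) / m if m else 0.0
        return _pair_mean(window, ctx, fn)
    if key == "shared_content_count":
        return _pair_mean(window, ctx, lambda a, b: float(len(_content_lemmas(a) & _content_lemmas(b))))
    if key == "binary_content_overlap":
        return _pair_mean(window, ctx, lambda a, b: float(bool(_content_lemmas(a) & _content_lemmas(b))))
    if key == "shared_noun_count":
        return _pair_mean(window, ctx, lambda a, b: float(len(
            {t.lemma for t in a if t.pos == "NOUN"} & {t.lemma for t in b if t.pos == "NOUN"})))
    if key == "binary_noun_overlap":
        return _pair_mean(window, ctx, lambda a, b: float(bool(
            {t.lemma for t in a if t.pos == "NOUN"} & {t.lemma for t in b if t.pos == "NOUN"})))
    if key in ("connective_rate", "connective_per_sentence"):
        cat = params[1]
        vocab = CONNECTIVES[cat]
        words = _words(window)
        hits = sum(1 for t in words if t.surface.lower() in vocab)
        if key == "connective_rate":
            return _safe_div(hits, len(words))
        return hits / max(len(window), 1)
    raise KeyError(f"unknown cohesion scorer {key!r}")


# ---------------------------------------------------------------------------
# stylistic scorers

def _score_stylistic(params: tuple, window: list[Sentence], ctx: ScoreContext) -> float:
    _, register, measure = params
    table = ctx.register_table()
    lows = [t.surface.lower() for t in _words(window)]
    if measure.startswith("unigram"):
        grams = lows
    else:
        grams = [f"{a} {b}" for a, b in zip(lows, lows[1:])]
    if not grams:
        return 0.0
    hits = [table.lookup(register, g) for g in grams]
    if measure.endswith("mean_logfreq"):
        return float(np.mean([math.log(h[0] + 1.0) if h else 0.0 for h in hits]))
    if measure.endswith("mean_logrank"):
        return float(np.mean([math.log(h[1]) if h else math.log(1e5) for h in hits]))
    if measure.endswith("common_prop"):
        return float(np.mean([1.0 if h and h[1] <= 100 else 0.0 for h in hits]))
    if measure.endswith("oov_prop"):
        return float(np.mean([1.0 if h is None else 0.0 for h in hits]))
    raise KeyError(f"unknown stylistic measure {measure!r}")


_GROUP_DISPATCH = {
    "morphosyntactic": _score_morphosyntactic,
    "lexical": _score_lexical,
    "cohesion": _score_cohesion,
    "stylistic": _score_stylistic,
}


def glf_score(spec: FeatureSpec, window: list[Sentence], ctx: ScoreContext | None = None) -> float:
    """Score one GLF on one window; always finite."""
    if ctx is None:
        ctx = ScoreContext()
    if not window:
        return 0.0
    if spec.group == "readability":
        value = _score_readability(spec.params[1], window, ctx)
    else:
        value = _GROUP_DISPATCH[spec.group](spec.params, window, ctx)
    if not math.isfinite(value):
        return 0.0
    return float(value)
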