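"""Sentence segmentation, tokenization and coarse linguistic annotation.

The default backend is a fully deterministic rule system (regex sentence
splitter with an abbreviation list, closed-class word lists plus suffix
rules for coarse part-of-speech tagging, a rule lemmatizer and a
vowel-group syllable counter).  Alternative backends can be registered at
runtime through :func:`register_backend`; everything downstream only
depends on the :class:`AnnotatedText` contract.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Callable, Iterable

__all__ = [
    "Token",
    "AnnotatedText",
    "split_sentences",
    "tokenize",
    "annotate",
    "count_syllables",
    "register_backend",
    "available_backends",
    "POS_TAGS",
]

#: The fixed coarse part-of-speech tag set.
POS_TAGS = (
    "NOUN", "VERB", "AUX", "ADJ", "ADV", "PRON",
    "DET", "ADP", "CONJ", "NUM", "PUNCT", "OTHER",
)

CONTENT_TAGS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})


@dataclass(frozen=True)
class Token:
    """A single token with the annotations every feature scorer needs."""

    surface: str
    lemma: str
    pos: str
    is_content: bool
    is_finite_verb: bool
    syllables: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if self.pos not in POS_TAGS:
            raise ValueError(f"unknown POS tag {self.pos!r}")
        if self.syllables < 1:
            raise ValueError("syllables must be >= 1")


@dataclass
class AnnotatedText:
    """A document as an ordered list of annotated sentences."""

    doc_id: str
    sentences: list[list[Token]] = field(default_factory=list)

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def words(self, lowercase: bool = True) -> list[str]:
        """All non-punctuation surfaces in order."""
        out = []
        for sent in self.sentences:
            for tok in sent:
                if tok.pos != "PUNCT":
                    out.append(tok.surface.lower() if lowercase else tok.surface)
        return out

    def to_json(self) -> str:
        payload = {
            "doc_id": self.doc_id,
            "sentences": [
                [
                    [t.surface, t.lemma, t.pos, int(t.is_content),
                     int(t.is_finite_verb), t.syllables]
                    for t in sent
                ]
                for sent in self.sentences
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnnotatedText":
        payload = json.loads(text)
        sentences = [
            [
                Token(surface=t[0], lemma=t[1], pos=t[2], is_content=bool(t[3]),
                      is_finite_verb=bool(t[4]), syllables=int(t[5]))
                for t in sent
            ]
            for sent in payload["sentences"]
        ]
        return cls(doc_id=payload["doc_id"], sentences=sentences)


# --------------------------------------------------------------------------
# sentence splitting

# Tokens after which a period does not terminate a sentence.
ABBREVIATIONS = frozenset({
    "dr", "mr", "mrs", "ms", "prof", "sr", "jr", "st", "vs", "etc",
    "fig", "no", "al", "dept", "est", "inc", "ltd", "co", "gen", "rev",
    "e.g", "i.e", "cf", "approx",
})

_TERMINATOR = re.compile(r"([.!?]+)(\s+|$)")


def split_sentences(text: str) -> list[str]:
    """Split ``text`` into sentences on ``. ! ?`` followed by whitespace.

    A period is not treated as a terminator when the preceding word is on
    the abbreviation list or is a single capital letter (an initial).
    Whitespace-only input yields an empty list.
    """
    if not text or not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _TERMINATOR.finditer(text):
        if "." in m.group(1) and m.group(1) == ".":
            prev = text[start:m.start()].split()
            if prev:
                w = prev[-1].rstrip(".").lower()
                if w in ABBREVIATIONS or (len(w) == 1 and w.isalpha()):
                    continue
        chunk = text[start:m.end(1)].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# --------------------------------------------------------------------------
# tokenization

_TOKEN = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)*|\d+(?:[.,]\d+)*|[^\w\s]")


def tokenize(sentence: str) -> list[str]:
    """Unicode-normalised word tokenizer splitting contractions.

    ``don't`` becomes ``do`` + ``n't``; possessives and clitics split at
    the apostrophe (``she's`` -> ``she`` + ``'s``).
    """
    sentence = unicodedata.normalize("NFC", sentence)
    out: list[str] = []
    for raw in _TOKEN.findall(sentence):
        if "'" in raw and raw[0] != "'":
            low = raw.lower()
            if low.endswith("n't"):
                out.extend([raw[:-3], raw[-3:]])
                continue
            head, _, clitic = raw.partition("'")
            if clitic:
                out.extend([head, "'" + clitic])
                continue
        out.append(raw)
    return [t for t in out if t]


# --------------------------------------------------------------------------
# syllable counting

_VOWEL_GROUP = re.compile(r"[aeiouy]+")


def count_syllables(word: str) -> int:
    """Count syllables by vowel groups with a silent-e correction.

    Groups of ``aeiouy`` each count one syllable; a terminal ``e`` that is
    not part of ``-le`` drops one group when more than one was found.
    Non-alphabetic input (after stripping) counts as one syllable.
    """
    w = re.sub(r"[^a-z]", "", word.lower())
    if not w:
        return 1
    n = len(_VOWEL_GROUP.findall(w))
    if n > 1 and w.endswith("e") and not w.endswith("le"):
        n -= 1
    return max(n, 1)


# --------------------------------------------------------------------------
# coarse tagging

_PRONOUNS = frozenset(
    "i you he she it we they me him her us them my your his its our their "
    "mine yours hers ours theirs myself yourself himself herself itself "
    "ourselves themselves who whom whose this that these those someone "
    "anyone everyone nobody something anything everything nothing".split()
)
_DETERMINERS = frozenset("the a an some any each every no another such".split())
_ADPOSITIONS = frozenset(
    "in on at by for with about against between into through during before "
    "after above below to from up down out off over under of near".split()
)
_CONJUNCTIONS = frozenset(
    "and or but nor so yet because although though while if unless since "
    "whereas when whenever whether".split()
)
_AUXILIARIES = frozenset(
    "be am is are was were been being have has had having do does did will "
    "would can could shall should may might must 'll 've 'd 'm 're 's".split()
)
_ADVERBS = frozenset(
    "not n't very too quite rather never always often sometimes seldom "
    "here there now then soon still already again perhaps maybe almost "
    "just even only also well".split()
)

# (past form, participle?) -> lemma for common irregular verbs
_IRREGULAR_VERBS = {
    "ran": "run", "sat": "sit", "hid": "hide", "slept": "sleep",
    "woke": "wake", "went": "go", "came": "come", "saw": "see",
    "said": "say", "got": "get", "made": "make", "took": "take",
    "knew": "know", "thought": "think", "felt": "feel", "found": "find",
    "told": "tell", "left": "leave", "kept": "keep", "held": "hold",
    "wrote": "write", "stood": "stand", "heard": "hear", "let": "let",
    "meant": "mean", "met": "meet", "paid": "pay", "ate": "eat",
    "spoke": "speak", "broke": "break", "gave": "give", "grew": "grow",
    "fell": "fall", "lost": "lose", "read": "read", "ran": "run",
    "sang": "sing", "drank": "drink", "swam": "swim", "began": "begin",
    "threw": "throw", "flew": "fly", "drove": "drive", "rose": "rise",
    "chose": "choose", "put": "put", "cut": "cut", "hit": "hit",
    "cried": "cry", "tried": "try", "worried": "worry",
}

_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ic", "ish", "less", "est")
_NOUN_SUFFIXES = ("tion", "sion", "ness", "ment", "ity", "ism", "ance", "ence",
                  "ship", "hood", "dom")


def _tag_word(word: str) -> str:
    low = word.lower()
    if not any(c.isalnum() for c in word):
        return "PUNCT"
    if low[0].isdigit():
        return "NUM"
    if low in _PRONOUNS:
        return "PRON"
    if low in _DETERMINERS:
        return "DET"
    if low in _ADPOSITIONS:
        return "ADP"
    if low in _CONJUNCTIONS:
        return "CONJ"
    if low in _AUXILIARIES:
        return "AUX"
    if low in _ADVERBS:
        return "ADV"
    if low in _IRREGULAR_VERBS:
        return "VERB"
    if low.endswith("ly") and len(low) > 3:
        return "ADV"
    if low.endswith(_NOUN_SUFFIXES):
        return "NOUN"
    if low.endswith(_ADJ_SUFFIXES) and len(low) > 4:
        return "ADJ"
    if low.endswith(("ing", "ed")) and len(low) > 4:
        return "VERB"
    if low.endswith("es") and len(low) > 4:
        return "NOUN"
    return "NOUN"


def _lemmatize(word: str, pos: str) -> str:
    low = word.lower()
    if low in _IRREGULAR_VERBS:
        return _IRREGULAR_VERBS[low]
    if pos == "VERB":
        for suf in ("ing", "ed"):
            if low.endswith(suf) and len(low) > len(suf) + 2:
                stem = low[: -len(suf)]
                if len(stem) > 2 and stem[-1] == stem[-2]:
                    stem = stem[:-1]  # running -> run
                return stem
    if pos == "NOUN":
        if low.endswith("ies") and len(low) > 4:
            return low[:-3] + "y"
        if low.endswith("es") and len(low) > 4 and low[-3] in "sxz":
            return low[:-2]
        if low.endswith("s") and not low.endswith("ss") and len(low) > 3:
            return low[:-1]
    return low


def _rule_annotate_sentence(sentence: str) -> list[Token]:
    surfaces = tokenize(sentence)
    tags = [_tag_word(s) for s in surfaces]
    tokens: list[Token] = []
    for idx, (surface, pos) in enumerate(zip(surfaces, tags)):
        low = surface.lower()
        prev_low = surfaces[idx - 1].lower() if idx else ""
        prev_tag = tags[idx - 1] if idx else ""
        is_content = pos in CONTENT_TAGS
        participle = low.endswith("ing") or (
            low.endswith("ed") and prev_tag == "AUX"
        )
        is_finite = (
            pos in ("VERB", "AUX") and prev_low != "to" and not participle
        )
        tokens.append(
            Token(
                surface=surface,
                lemma=_lemmatize(surface, pos),
                pos=pos,
                is_content=is_content,
                is_finite_verb=is_finite,
                syllables=count_syllables(surface) if pos != "PUNCT" else 1,
            )
        )
    return tokens


def _rule_backend(text: str, doc_id: str) -> AnnotatedText:
    sentences = [_rule_annotate_sentence(s) for s in split_sentences(text)]
    sentences = [s for s in sentences if s]
    return AnnotatedText(doc_id=doc_id, sentences=sentences)


Backend = Callable[[str, str], AnnotatedText]

_BACKENDS: dict[str, Backend] = {"rule": _rule_backend}


def register_backend(name: str, fn: Backend) -> None:
    _BACKENDS[name] = fn


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def annotate(text: str, backend: str = "rule", doc_id: str = "doc") -> AnnotatedText:
    """Annotate ``text`` with the given backend.

    Raises ``KeyError`` naming the available backends when ``backend`` is
    unknown.  Deterministic: the same input, backend and package version
    always produce an identical :class:`AnnotatedText`.
    """
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise KeyError(
            f"unknown annotation backend {backend!r}; "
            f"available: {available_backends()}"
        ) from None
    return fn(text, doc_id)
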