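"""Sliding-window contour extraction and per-feature standardization.

A window of ``window_len`` consecutive sentences slides across the
document with stride 1, producing ``W = max(T - w + 1, 0)`` windows.
GLFs fill a dense ``W x N`` matrix; LBFs produce a sparse set of
``(feature_id, window_id, score)`` 3-tuples containing only non-zero
scores.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import splev, splrep

from ..annotation import AnnotatedText, Token
from .lexicon import LEXICON_SLOTS, Lexicon
from .registry import FeatureRegistry
from .scorers import RegisterTable, ScoreContext, glf_score

Sentence = list[Token]


@dataclass
class ContourMatrix:
    doc_id: str
    values: np.ndarray  # W x N
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return int(self.values.shape[0])

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("contour matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contour matrix entries must be finite")


@dataclass
class SparseContour:
    doc_id: str
    entries: set[tuple[int, int, float]] = field(default_factory=set)
    n_windows: int = 0
    n_features: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for j, i, score in self.entries:
            if score == 0:
                raise ValueError("sparse contour must not contain zero scores")
            if (j, i) in seen:
                raise ValueError(f"duplicate (feature, window) pair ({j}, {i})")
            if not 0 <= i < max(self.n_windows, 1):
                raise ValueError(f"window id {i} out of range")
            seen.add((j, i))

    def densify(self) -> np.ndarray:
        out = np.zeros((self.n_windows, self.n_features))
        for j, i, score in self.entries:
            out[i, j] = score
        return out

    @classmethod
    def from_dense(cls, doc_id: str, dense: np.ndarray) -> "SparseContour":
        dense = np.asarray(dense, dtype=float)
        entries = {
            (int(j), int(i), float(dense[i, j]))
            for i, j in zip(*np.nonzero(dense))
        }
        return cls(doc_id=doc_id, entries=entries,
                   n_windows=dense.shape[0], n_features=dense.shape[1])


# ---------------------------------------------------------------------------
# LBF scoring

def _window_match(window: list[Sentence], lexicon: Lexicon):
    """Match window tokens (and adjacent-word bigrams) against a lexicon.

    Returns (category -> hit count, category -> matched keys,
    norm values per norm name, n_words, n_content).
    """
    words = [t for s in window for t in s if t.pos != "PUNCT"]
    keys: list[str] = []
    for t in words:
        low = t.surface.lower()
        if low in lexicon.categorical or low in lexicon.norms:
            keys.append(low)
        elif t.lemma != low and (t.lemma in lexicon.categorical or t.lemma in lexicon.norms):
            keys.append(t.lemma)
        else:
            keys.append("")
    lows = [t.surface.lower() for t in words]
    bigram_keys = [f"{a} {b}" for a, b in zip(lows, lows[1:])
                   if f"{a} {b}" in lexicon.categorical]

    cat_hits: dict[str, int] = {}
    cat_types: dict[str, set[str]] = {}
    norm_values: dict[str, list[float]] = {}
    for key in keys:
        if not key:
            continue
        for cat in lexicon.categorical.get(key, ()):
            cat_hits[cat] = cat_hits.get(cat, 0) + 1
            cat_types.setdefault(cat, set()).add(key)
        for norm, value in lexicon.norms.get(key, {}).items():
            norm_values.setdefault(norm, []).append(value)
    for key in bigram_keys:
        for cat in lexicon.categorical.get(key, ()):
            cat_hits[cat] = cat_hits.get(cat, 0) + 1
            cat_types.setdefault(cat, set()).add(key)
    n_content = sum(1 for t in words if t.is_content)
    return cat_hits, cat_types, norm_values, len(words), n_content


def _categorical_stat(stat: str, hits: int, types: int, n_words: int,
                      n_content: int, n_sent: int) -> float:
    if stat == "rate":
        return hits / n_words if n_words else 0.0
    if stat == "count":
        return float(hits)
    if stat == "presence":
        return 1.0 if hits else 0.0
    if stat == "type_count":
        return float(types)
    if stat == "type_rate":
        return types / n_words if n_words else 0.0
    if stat == "per_sentence":
        return hits / max(n_sent, 1)
    if stat == "log_count":
        return math.log1p(hits)
    if stat == "content_rate":
        return hits / n_content if n_content else 0.0
    raise KeyError(stat)


def _norm_stat(stat: str, values: list[float], n_words: int) -> float:
    if not values:
        return 0.0
    arr = np.asarray(values, dtype=float)
    if stat == "mean":
        return float(arr.mean())
    if stat == "min":
        return float(arr.min())
    if stat == "max":
        return float(arr.max())
    if stat == "sd":
        return float(arr.std()) if arr.size > 1 else 0.0
    if stat == "range":
        return float(arr.max() - arr.min())
    if stat == "frac_high":
        # fraction above the midpoint of a 1..9 affective rating scale
        return float((arr > 5.0).mean())
    if stat == "coverage":
        return arr.size / n_words if n_words else 0.0
    raise KeyError(stat)


# ---------------------------------------------------------------------------
# extraction

def extract_contours(
    doc: AnnotatedText,
    registry: FeatureRegistry,
    lexicons: dict[str, Lexicon],
    window_len: int = 1,
    registers: RegisterTable | None = None,
) -> tuple[ContourMatrix, SparseContour]:
    """Slide a ``window_len``-sentence window across ``doc`` and score
    every registry feature on every window.

    With ``window_len=1`` window ``i`` covers exactly sentence ``i``.
    An empty document yields a 0-row matrix and an empty tuple set.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    missing = [s for s in LEXICON_SLOTS if s not in lexicons]
    if missing:
        raise ValueError(f"missing lexicons for slots: {missing}")

    T = doc.n_sentences
    W = max(T - window_len + 1, 0)
    dense = np.zeros((W, registry.n_glf))
    entries: set[tuple[int, int, float]] = set()

    for i in range(W):
        window = doc.sentences[i:i + window_len]
        prev = doc.sentences[i - 1] if i > 0 else None
        ctx = ScoreContext(prev_sentence=prev, registers=registers)
        for col, spec in enumerate(registry.glf):
            dense[i, col] = glf_score(spec, window, ctx)

        n_sent = len(window)
        per_slot = {
            slot: _window_match(window, lexicons[slot]) for slot in LEXICON_SLOTS
        }
        for j, spec in enumerate(registry.lbf):
            kind, target, stat = spec.params
            cat_hits, cat_types, norm_values, n_words, n_content = per_slot[spec.group]
            if kind == "categorical":
                score = _categorical_stat(
                    stat, cat_hits.get(target, 0),
                    len(cat_types.get(target, ())), n_words, n_content, n_sent,
                )
            else:
                score = _norm_stat(stat, norm_values.get(target, []), n_words)
            if score != 0.0:
                entries.add((j, i, float(score)))

    matrix = ContourMatrix(
        doc_id=doc.doc_id, values=dense,
        feature_names=[s.name for s in registry.glf],
    )
    sparse = SparseContour(
        doc_id=doc.doc_id, entries=entries,
        n_windows=W, n_features=registry.n_lbf,
    )
    return matrix, sparse


def combined_input(matrix: ContourMatrix, sparse: SparseContour) -> np.ndarray:
    """Concatenate the dense GLF matrix and the densified LBF tuples along
    the feature axis: a ``W x (N + K)`` classifier input."""
    if matrix.n_windows != sparse.n_windows:
        raise ValueError("window counts differ between dense and sparse contours")
    return np.concatenate([matrix.values, sparse.densify()], axis=1)


# ---------------------------------------------------------------------------
# standardization and smoothing

def standardize(seq) -> np.ndarray:
    """Population z-scores; an (effectively) zero-variance sequence maps to
    all zeros instead of dividing by zero."""
    arr = np.asarray(seq, dtype=float)
    if arr.size == 0:
        return arr.copy()
    sd = arr.std()
    if sd < 1e-12:
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def standardize_and_smooth(seq, oversample: int = 1) -> np.ndarray:
    """Z-standardize then smooth with an interpolating cubic b-spline.

    With ``oversample=1`` the spline is evaluated at the original sample
    points, so the length (and, being an interpolant, the values) are
    preserved; larger factors give the dense curve used for plotting.
    Sequences too short for a cubic fit are returned unsmoothed.
    """
    z = standardize(seq)
    n = z.size
    if n < 4:
        return np.repeat(z, oversample) if oversample > 1 else z
    x = np.arange(n, dtype=float)
    tck = splrep(x, z, k=3, s=0)
    xs = np.linspace(0, n - 1, n * oversample) if oversample > 1 else x
    return np.asarray(splev(xs, tck), dtype=float)


class ContourStandardizer:
    """Per-feature z-standardization with statistics from the training split
    only, applied to the combined dense+sparse classifier input."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, inputs: list[np.ndarray]) -> "ContourStandardizer":
        stacked = np.concatenate([x for x in inputs if x.shape[0] > 0], axis=0)
        self.mean_ = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        sd[sd < 1e-12] = 1.0
        self.sd_ = sd
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        return (x - self.mean_) / self.sd_


# ---------------------------------------------------------------------------
# CSV caches

def write_contours_csv(matrix: ContourMatrix, sparse: SparseContour,
                       dense_path: str | Path, sparse_path: str | Path) -> None:
    with Path(dense_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["window_id"] + matrix.feature_names)
        for i in range(matrix.n_windows):
            writer.writerow([i] + [f"{v:.10g}" for v in matrix.values[i]])
    with Path(sparse_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["feature_id", "window_id", "score"])
        for j, i, score in sorted(sparse.entries):
            writer.writerow([j, i, f"{score:.10g}"])
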