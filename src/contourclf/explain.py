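"""Layered model explanations.

* :func:`lime_explain` — local surrogate explanation in bag-of-unigrams
  space for any text classifier exposing ``predict_proba`` over token
  lists (ridge surrogate, exponential proximity kernel).
* :func:`lime_feature_weights` / :func:`sp_lime_group_importance` —
  feature-space LIME for contour classifiers and its submodular-pick
  aggregation into normalized per-group global importance.
* :func:`agrad_attribution` — attention-gradient attribution
  ``A_i = -(dL/d alpha_i) * alpha_i`` on the final encoder layer, summed
  over heads; positive scores are loss-reducing.
* :func:`top_k_unigrams`, :func:`category_coverage`,
  :func:`label_correlations` — downstream aggregation of attributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .features.lexicon import Lexicon
from .models.autodiff import Tensor, binary_cross_entropy
from .models.train import TrainedEncoderModel, TrainedModel

logger = logging.getLogger(__name__)

#: LIME defaults: reference-implementation values.
LIME_N_SAMPLES = 1000
LIME_KERNEL_WIDTH = 25.0
SPLIME_TOPK_PER_INSTANCE = 10


@dataclass(frozen=True)
class AttributionRecord:
    doc_id: str
    token: str       # lowercased word surface
    position: int
    importance: float
    method: str      # "LIME" | "AGRAD"

    def __post_init__(self):
        if not np.isfinite(self.importance):
            raise ValueError("importance must be finite")


@dataclass
class GroupImportanceTable:
    """Rows = feature groups / lexicon slots, columns = conditions,
    cells = normalized importance percentages summing to 100 per column."""

    groups: list[str]
    columns: dict[str, dict[str, float]]

    def __post_init__(self):
        for condition, col in self.columns.items():
            total = sum(col.values())
            if abs(total - 100.0) > 0.01:
                raise ValueError(
                    f"column {condition!r} sums to {total}, expected 100")

    def ranks(self, condition: str) -> dict[str, int]:
        col = self.columns[condition]
        ordered = sorted(self.groups, key=lambda g: -col[g])
        return {g: i + 1 for i, g in enumerate(ordered)}

    def to_rows(self) -> list[list]:
        header = ["group"] + list(self.columns)
        rows = [header]
        for g in self.groups:
            rows.append([g] + [round(self.columns[c][g], 2) for c in self.columns])
        return rows


# ---------------------------------------------------------------------------
# LIME in bag-of-unigrams space

def _kernel(distances: np.ndarray, width: float) -> np.ndarray:
    return np.sqrt(np.exp(-(distances ** 2) / width ** 2))


def lime_explain(model, tokens: list[str], n_samples: int = LIME_N_SAMPLES,
                 seed: int = 0, doc_id: str = "doc",
                 kernel_width: float = LIME_KERNEL_WIDTH) -> list[AttributionRecord]:
    """Explain one prediction by a weighted ridge surrogate over random
    unigram-deletion perturbations.

    ``model`` must expose ``predict_proba(list of token lists)``; one
    record per distinct unigram is returned (position = first occurrence).
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if not tokens:
        raise ValueError("cannot explain an empty document")
    uniq: list[str] = []
    first_pos: dict[str, int] = {}
    for i, tok in enumerate(tokens):
        low = tok.lower()
        if low not in first_pos:
            first_pos[low] = i
            uniq.append(low)
    d = len(uniq)
    rng = np.random.default_rng(seed)
    Z = rng.integers(0, 2, size=(n_samples, d))
    Z[0] = 1  # the unperturbed instance anchors the fit
    texts = []
    for z in Z:
        keep = {uniq[j] for j in range(d) if z[j]}
        texts.append([t for t in tokens if t.lower() in keep] or ["."])
    preds = np.asarray(model.predict_proba(texts), dtype=float)
    distances = 100.0 * (1.0 - Z.mean(axis=1))
    weights = _kernel(distances, kernel_width)
    surrogate = Ridge(alpha=1.0, random_state=0)
    surrogate.fit(Z, preds, sample_weight=weights)
    return [
        AttributionRecord(doc_id=doc_id, token=uniq[j], position=first_pos[uniq[j]],
                          importance=float(surrogate.coef_[j]), method="LIME")
        for j in range(d)
    ]


# ---------------------------------------------------------------------------
# feature-space LIME and SP-LIME for contour models

def lime_feature_weights(model: TrainedModel, x: np.ndarray,
                         n_samples: int = 300, seed: int = 0) -> np.ndarray:
    """Per-feature surrogate weights for one contour input ``x`` (W x F).

    Perturbation masks whole feature columns to zero (the training mean
    after standardization); the ridge surrogate is fit on the binary
    feature-presence vectors.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    F = x.shape[1]
    rng = np.random.default_rng(seed)
    Z = rng.integers(0, 2, size=(n_samples, F))
    Z[0] = 1
    perturbed = [x * z[None, :] for z in Z]
    preds = np.asarray(model.predict_proba(perturbed), dtype=float)
    distances = 100.0 * (1.0 - Z.mean(axis=1))
    weights = _kernel(distances, LIME_KERNEL_WIDTH)
    surrogate = Ridge(alpha=1.0, random_state=0)
    surrogate.fit(Z, preds, sample_weight=weights)
    return np.asarray(surrogate.coef_, dtype=float)


def _greedy_pick(weight_matrix: np.ndarray, budget: int) -> list[int]:
    """Submodular pick: greedily choose instances maximizing coverage of
    globally important features (top-k weights per instance count as
    covered)."""
    n, F = weight_matrix.shape
    mask = np.zeros_like(weight_matrix, dtype=bool)
    k = min(SPLIME_TOPK_PER_INSTANCE, F)
    for i in range(n):
        top = np.argsort(-np.abs(weight_matrix[i]))[:k]
        mask[i, top] = True
    importance = np.sqrt(np.abs(weight_matrix).sum(axis=0))
    picked: list[int] = []
    covered = np.zeros(F, dtype=bool)
    for _ in range(min(budget, n)):
        gains = np.array([
            importance[~covered & mask[i]].sum() if i not in picked else -1.0
            for i in range(n)
        ])
        best = int(np.argmax(gains))
        if gains[best] <= 0 and picked:
            # coverage saturated; fill the budget in candidate order
            remaining = [i for i in range(n) if i not in picked]
            picked.extend(remaining[: budget - len(picked)])
            break
        picked.append(best)
        covered |= mask[best]
    return picked


def sp_lime_group_importance(model: TrainedModel, inputs: list[np.ndarray],
                             grouping: dict[str, list[int]],
                             budget: int | None = None, seed: int = 0,
                             n_samples: int = 300) -> dict[str, float]:
    """One condition column of the group-importance table.

    Per-group score = sum over greedily picked instances of the summed
    absolute surrogate weights of the group's features, normalized so the
    groups total 100%.
    """
    F = inputs[0].shape[1]
    claimed = sorted(i for idxs in grouping.values() for i in idxs)
    if claimed != list(range(F)):
        raise ValueError("grouping must partition the model's feature columns")
    if budget is None:
        budget = min(50, len(inputs))
    weights = np.stack([
        lime_feature_weights(model, x, n_samples=n_samples, seed=seed + i)
        for i, x in enumerate(inputs)
    ])
    picked = _greedy_pick(weights, budget)
    raw = {
        group: float(np.abs(weights[picked][:, idxs]).sum())
        for group, idxs in grouping.items()
    }
    total = sum(raw.values())
    if total == 0:
        return {g: 100.0 / len(raw) for g in raw}
    return {g: 100.0 * v / total for g, v in raw.items()}


# ---------------------------------------------------------------------------
# AGRAD

def agrad_attribution(model: TrainedEncoderModel, tokens: list[str],
                      target_label: int, doc_id: str = "doc") -> list[AttributionRecord]:
    """Attention-gradient attribution on the final encoder layer.

    ``A_i = -(dL/d alpha_i) * alpha_i`` per attention position, taken at
    the classification-token query row and summed over heads.  Positive
    scores reduce the loss (support the prediction).
    """
    if not isinstance(model, TrainedEncoderModel):
        raise TypeError("AGRAD requires a model exposing attention weights")
    net = model.net
    ids = net.prepare_ids([model.vocab.encode(tokens)])
    B, T = ids.shape
    deltas = [
        Tensor(np.zeros((B, net.n_heads, T, T)), requires_grad=True)
        for _ in net.layers
    ]
    probs, alphas = net.forward(ids, attn_deltas=deltas)
    loss = binary_cross_entropy(
        probs["primary"], np.array([[float(target_label)]]))
    loss.backward()
    alpha = alphas[-1].data[0]          # [heads, T, T]
    grad = deltas[-1].grad[0]           # [heads, T, T]
    A = (-grad * alpha)[:, 0, :].sum(axis=0)  # CLS query row, summed over heads
    n_words = min(len(tokens), net.max_tokens)
    return [
        AttributionRecord(doc_id=doc_id, token=tokens[i].lower(), position=i,
                          importance=float(A[i + 1]), method="AGRAD")
        for i in range(n_words)
    ]


# ---------------------------------------------------------------------------
# aggregation

def top_k_unigrams(records: list[AttributionRecord], k: int = 10
                   ) -> dict[str, list[AttributionRecord]]:
    """Per-document top-``k`` records by descending importance, ties
    broken by earlier position; short documents contribute all records."""
    if k < 1:
        raise ValueError("k must be >= 1")
    by_doc: dict[str, list[AttributionRecord]] = {}
    for rec in records:
        by_doc.setdefault(rec.doc_id, []).append(rec)
    return {
        doc_id: sorted(recs, key=lambda r: (-r.importance, r.position))[:k]
        for doc_id, recs in by_doc.items()
    }


@dataclass(frozen=True)
class CategoryCoverage:
    model_label: str
    category: str
    percentage: float

    def __post_init__(self):
        if not 0.0 <= self.percentage <= 100.0:
            raise ValueError("percentage must lie in [0, 100]")


def category_coverage(topk: dict[str, list[AttributionRecord]], lexicon: Lexicon,
                      categories: list[str], model_label: str = "model"
                      ) -> list[CategoryCoverage]:
    """Percentage of all selected word tokens that belong to each category
    (unigram matches only; a multi-category word counts once per
    category).  An empty selection reports 0 with a warning."""
    known = lexicon.categories()
    for cat in categories:
        if cat not in known:
            raise ValueError(f"category {cat!r} not present in lexicon {lexicon.slot}")
    selected = [rec.token for recs in topk.values() for rec in recs]
    if not selected:
        logger.warning("empty unigram selection; coverage undefined, reporting 0")
        return [CategoryCoverage(model_label, c, 0.0) for c in categories]
    out = []
    for cat in categories:
        hits = sum(1 for w in selected if cat in lexicon.categorical.get(w, ()))
        out.append(CategoryCoverage(model_label, cat, 100.0 * hits / len(selected)))
    return out


def label_correlations(gold: np.ndarray, silver: np.ndarray,
                       names: list[str] | None = None
                       ) -> dict[str, tuple[float, bool]]:
    """Pearson r between the binary condition labels and each silver-label
    column; a constant vector yields ``(0.0, True)`` (flagged cell)."""
    gold = np.asarray(gold, dtype=float)
    silver = np.asarray(silver, dtype=float)
    if silver.ndim == 1:
        silver = silver[:, None]
    if len(gold) != silver.shape[0]:
        raise ValueError("gold and silver label lengths differ")
    if names is None:
        names = [f"label_{i}" for i in range(silver.shape[1])]
    out: dict[str, tuple[float, bool]] = {}
    for j, name in enumerate(names):
        col = silver[:, j]
        if gold.std() == 0 or col.std() == 0:
            out[name] = (0.0, True)
        else:
            r = float(np.corrcoef(gold, col)[0, 1])
            out[name] = (r, False)
    return out
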