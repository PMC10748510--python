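# contourclf

Sliding-window **text contours**, interpretable-feature classifiers and a
layered explanation stack for binary text classification, with a fully
deterministic synthetic-data harness so the entire pipeline is testable
offline.

## What it does

1. **Annotation** (`contourclf.annotation`) — sentence splitting,
   tokenization, coarse 12-tag POS tagging, rule lemmatization and
   syllable counting via a pluggable backend whose bundled fallback is
   deterministic and dependency-free.
2. **Features** (`contourclf.features`) — a default registry of **498
   feature definitions**: 192 general linguistic features (GLFs) in five
   groups (morphosyntactic 48, lexical 45, readability 13, cohesion 30,
   stylistic 56) and 306 lexicon-based features (LBFs) over seven lexicon
   slots (ANEW, ANEW-Emo, GI, GALC, LIWC, EmoLex, SenticNet). A window
   slides over the document sentence-by-sentence, producing a dense
   `W x 192` GLF matrix and a sparse set of non-zero
   `(feature_id, window_id, score)` LBF 3-tuples, concatenated to a
   `W x 498` classifier input. Contours can be z-standardized
   (training-split statistics) and b-spline smoothed for plotting.
3. **Models** (`contourclf.models`) — a stacked BiLSTM contour classifier
   (default 3 layers, hidden 512, two-layer ReLU head with logistic
   output), a compact multi-head attention-encoder text classifier
   (CLS-token pooling, word-level vocabulary, 512-token truncation), and
   multi-task fusion training with the weighted loss
   `L = lambda * L_primary + (1 - lambda) * L_secondary` over silver
   emotion (6 Ekman) and personality (4 MBTI) labels. Everything runs on
   a small numpy reverse-mode autodiff core (`models.autodiff`) —
   no deep-learning framework required.
4. **Explanations** (`contourclf.explain`) — LIME in bag-of-unigrams
   space (ridge surrogate, exponential proximity kernel), feature-space
   LIME + submodular-pick aggregation into per-group importance columns
   normalized to 100 %, attention-gradient attribution
   `A_i = -(dL/d alpha_i) * alpha_i` with exact loss gradients from the
   autodiff graph, per-document top-k unigram selection, lexicon-category
   coverage percentages and gold/silver label correlation tables.
5. **Synthetic data** (`contourclf.synthetic`) — seeded generators for
   corpora with planted GLF-group shifts (standardized effect size `d`),
   planted lexicon-word emission rates, auxiliary labels with target
   phi/Pearson correlation to the condition label, and the seven slot
   lexicons in a generic TSV dictionary format.
6. **Evaluation** (`contourclf.evaluation`) — accuracy/precision/recall/F1
   rows (macro or positive-class), F1-gap and infusion-gain deltas,
   total-importance sums and report rendering.

## CLI

```bash
contourclf simulate --n-docs 200 --effect-size 1.0 --seed 1 --out data/
contourclf extract  --corpus data/corpus.jsonl --lexicons data/lexicons --out contours/
contourclf train    --corpus data/corpus.jsonl --lexicons data/lexicons \
                    --feature-set both --out model/
contourclf explain  --corpus data/corpus.jsonl --lexicons data/lexicons --out explain/
contourclf report   --metrics model/metrics.json --out report.md
contourclf fixtures --out fixtures/      # small deterministic demo suite
```

Corpus format: line-delimited JSON with `id`, `text`, `label` (0/1) and
optional `split`, `emotion` (6 binary labels), `personality` (4 binary
labels). Lexicons: `word<TAB>category` or `word<TAB>norm<TAB>value` TSV.

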