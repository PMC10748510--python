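"""End-to-end helpers wiring corpus records through annotation, contour
extraction and dataset assembly.

Standardization statistics always come from the training split only.
"""

from __future__ import annotations

import numpy as np

from .annotation import annotate
from .corpus import Document
from .features import (
    ContourStandardizer,
    FeatureRegistry,
    combined_input,
    extract_contours,
)
from .models import ContourDataset

FEATURE_SETS = ("glf", "lbf", "both")


def contour_datasets(
    docs: list[Document],
    registry: FeatureRegistry,
    lexicons: dict,
    feature_set: str = "both",
    window_len: int = 1,
) -> dict[str, ContourDataset]:
    """Extract contours for every document and return standardized
    train/val/test :class:`ContourDataset` splits."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    inputs, labels, splits, ids = [], [], [], []
    for doc in docs:
        ann = annotate(doc.text, doc_id=doc.doc_id)
        matrix, sparse = extract_contours(ann, registry, lexicons, window_len)
        if feature_set == "glf":
            x = matrix.values
        elif feature_set == "lbf":
            x = sparse.densify()
        else:
            x = combined_input(matrix, sparse)
        inputs.append(x)
        labels.append(doc.label)
        splits.append(doc.split)
        ids.append(doc.doc_id)
    train_inputs = [x for x, s in zip(inputs, splits) if s == "train" and x.shape[0] > 0]
    std = ContourStandardizer().fit(train_inputs)
    inputs = [std.transform(x) for x in inputs]
    out: dict[str, ContourDataset] = {}
    for name in ("train", "val", "test"):
        idx = [i for i, s in enumerate(splits) if s == name]
        out[name] = ContourDataset(
            inputs=[inputs[i] for i in idx],
            labels=np.array([labels[i] for i in idx], dtype=int),
            doc_ids=[ids[i] for i in idx],
        )
    return out
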