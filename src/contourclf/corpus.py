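"""Line-delimited JSON corpus records and their readers/writers.

One record per line: ``{"id": ..., "text": ..., "label": 0/1}`` with
optional ``"split"`` (train/val/test), ``"emotion"`` (6 binary labels,
Ekman order: anger, disgust, fear, joy, sadness, surprise) and
``"personality"`` (4 binary MBTI dimensions: E/I, S/N, T/F, J/P).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

EMOTION_LABELS = ("anger", "disgust", "fear", "joy", "sadness", "surprise")
PERSONALITY_LABELS = ("extraversion", "intuition", "thinking", "judging")


@dataclass
class Document:
    doc_id: str
    text: str
    label: int
    split: str = "train"
    emotion: list[int] | None = None
    personality: list[int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.emotion is not None and len(self.emotion) != len(EMOTION_LABELS):
            raise ValueError("emotion labels must have length 6")
        if self.personality is not None and len(self.personality) != len(PERSONALITY_LABELS):
            raise ValueError("personality labels must have length 4")


def read_corpus(path: str | Path) -> list[Document]:
    docs: list[Document] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from None
            docs.append(Document(
                doc_id=str(rec["id"]),
                text=rec["text"],
                label=int(rec["label"]),
                split=rec.get("split", "train"),
                emotion=rec.get("emotion"),
                personality=rec.get("personality"),
                meta={k: v for k, v in rec.items()
                      if k not in ("id", "text", "label", "split", "emotion", "personality")},
            ))
    return docs


def write_corpus(docs: list[Document], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in docs:
            rec: dict = {"id": doc.doc_id, "text": doc.text,
                         "label": doc.label, "split": doc.split}
            if doc.emotion is not None:
                rec["emotion"] = list(doc.emotion)
            if doc.personality is not None:
                rec["personality"] = list(doc.personality)
            rec.update(doc.meta)
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def split_docs(docs: list[Document]) -> dict[str, list[Document]]:
    out: dict[str, list[Document]] = {}
    for doc in docs:
        out.setdefault(doc.split, []).append(doc)
    return out
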