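"""Training routines, configs and the fusion loss.

The training contract mirrors the classifier conventions used throughout:
batch size 32, 8 epochs, Adam with weight decay, and model selection by
best validation accuracy.  The multi-task fusion loss is the weighted sum

    L_tot = lambda * L_primary + (1 - lambda) * L_secondary

with ``lambda`` in [0, 1]; with both secondary tasks active,
``L_secondary`` is the unweighted mean of the per-task losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..corpus import Document
from . import autodiff as ad
from .autodiff import Tensor, binary_cross_entropy
from .nets import AttentionEncoder, BiLSTMClassifier, Module, Vocabulary

logger = logging.getLogger(__name__)

SECONDARY_TASKS = {"emotion": 6, "personality": 4}


# ---------------------------------------------------------------------------
# configs

@dataclass
class BiLSTMConfig:
    input_width: int
    n_layers: int = 3
    hidden_dim: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")


@dataclass
class AttentionEncoderConfig:
    n_layers: int = 2
    n_heads: int = 4
    model_dim: int = 128
    max_tokens: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.model_dim % self.n_heads:
            raise ValueError("model_dim must be divisible by n_heads")


@dataclass
class FusionConfig:
    lambda_mhc: float = 0.5
    secondary_tasks: tuple[str, ...] = ("emotion",)

    def __post_init__(self):
        if not 0.0 <= self.lambda_mhc <= 1.0:
            raise ValueError("lambda_mhc must lie in [0, 1]")
        if not self.secondary_tasks:
            raise ValueError("fusion requires at least one secondary task")
        for task in self.secondary_tasks:
            if task not in SECONDARY_TASKS:
                raise ValueError(f"unknown secondary task {task!r}")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 32
    epochs: int = 8
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")


# ---------------------------------------------------------------------------
# fusion loss

def fusion_loss(l_mhc, l_sec, lambda_mhc: float):
    """Weighted sum ``lambda*l_mhc + (1-lambda)*l_sec``.

    Accepts floats or autodiff tensors; exact at the lambda boundaries.
    """
    if not 0.0 <= lambda_mhc <= 1.0:
        raise ValueError("lambda_mhc must lie in [0, 1]")
    for name, v in (("l_mhc", l_mhc), ("l_sec", l_sec)):
        val = v.data if isinstance(v, Tensor) else v
        if not np.all(np.isfinite(val)):
            raise ValueError(f"{name} must be finite")
    return lambda_mhc * l_mhc + (1.0 - lambda_mhc) * l_sec


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# datasets

@dataclass
class ContourDataset:
    """Per-document combined (dense + densified sparse) contour inputs."""

    inputs: list[np.ndarray]
    labels: np.ndarray
    doc_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.inputs) != len(self.labels):
            raise ValueError("inputs and labels length mismatch")
        widths = {x.shape[1] for x in self.inputs}
        if len(widths) > 1:
            raise ValueError(f"inconsistent feature widths: {sorted(widths)}")
        keep = [i for i, x in enumerate(self.inputs) if x.shape[0] > 0]
        if len(keep) < len(self.inputs):
            logger.warning("dropping %d document(s) with zero windows",
                           len(self.inputs) - len(keep))
            self.inputs = [self.inputs[i] for i in keep]
            self.labels = self.labels[keep]
            if self.doc_ids:
                self.doc_ids = [self.doc_ids[i] for i in keep]

    @property
    def width(self) -> int:
        return self.inputs[0].shape[1]

    def __len__(self) -> int:
        return len(self.inputs)


def pad_batch(inputs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([x.shape[0] for x in inputs], dtype=int)
    T = int(lengths.max())
    out = np.zeros((len(inputs), T, inputs[0].shape[1]))
    for i, x in enumerate(inputs):
        out[i, : x.shape[0]] = x
    return out, lengths


@dataclass
class TokenDataset:
    """Word-level inputs for the attention encoder."""

    token_lists: list[list[str]]
    labels: np.ndarray
    doc_ids: list[str] = field(default_factory=list)
    emotion: np.ndarray | None = None      # [n, 6]
    personality: np.ndarray | None = None  # [n, 4]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.token_lists) != len(self.labels):
            raise ValueError("token lists and labels length mismatch")

    def __len__(self) -> int:
        return len(self.token_lists)


def tokens_from_text(text: str) -> list[str]:
    from ..annotation import split_sentences, tokenize
    out: list[str] = []
    for sent in split_sentences(text):
        out.extend(w.lower() for w in tokenize(sent))
    return out


def token_dataset_from_docs(docs: list[Document]) -> TokenDataset:
    emotion = (np.array([d.emotion for d in docs], dtype=int)
               if all(d.emotion is not None for d in docs) and docs else None)
    personality = (np.array([d.personality for d in docs], dtype=int)
                   if all(d.personality is not None for d in docs) and docs else None)
    return TokenDataset(
        token_lists=[tokens_from_text(d.text) for d in docs],
        labels=np.array([d.label for d in docs], dtype=int),
        doc_ids=[d.doc_id for d in docs],
        emotion=emotion,
        personality=personality,
    )


# ---------------------------------------------------------------------------
# trained-model wrappers

class TrainedModel:
    """A fitted classifier: prediction, per-example loss and (for encoder
    kinds) attention access.  Deterministic given a fixed checkpoint."""

    kind: str

    def predict_proba(self, inputs) -> np.ndarray:
        raise NotImplementedError

    def predict(self, inputs) -> np.ndarray:
        return (self.predict_proba(inputs) >= 0.5).astype(int)

    def example_losses(self, inputs, labels) -> np.ndarray:
        p = np.clip(self.predict_proba(inputs), 1e-9, 1 - 1e-9)
        y = np.asarray(labels, dtype=float)
        return -(y * np.log(p) + (1 - y) * np.log(1 - p))


class TrainedContourModel(TrainedModel):
    kind = "bilstm"

    def __init__(self, net: BiLSTMClassifier, history: list[dict]):
        self.net = net
        self.history = history

    def predict_proba(self, inputs: list[np.ndarray]) -> np.ndarray:
        out = np.empty(len(inputs))
        for start in range(0, len(inputs), 64):
            chunk = inputs[start:start + 64]
            x, lengths = pad_batch(chunk)
            out[start:start + len(chunk)] = self.net.forward(x, lengths).data[:, 0]
        return out


class TrainedEncoderModel(TrainedModel):
    def __init__(self, net: AttentionEncoder, vocab: Vocabulary,
                 history: list[dict], kind: str = "encoder",
                 tasks: tuple[str, ...] = ()):
        self.net = net
        self.vocab = vocab
        self.history = history
        self.kind = kind
        self.tasks = tasks

    def _forward(self, token_lists: list[list[str]], head: str) -> np.ndarray:
        out = []
        for start in range(0, len(token_lists), 32):
            chunk = token_lists[start:start + 32]
            ids = self.net.prepare_ids([self.vocab.encode(t) for t in chunk])
            probs, _ = self.net.forward(ids)
            out.append(probs[head].data)
        return np.concatenate(out, axis=0)

    def predict_proba(self, token_lists: list[list[str]]) -> np.ndarray:
        return self._forward(token_lists, "primary")[:, 0]

    def predict_task_proba(self, token_lists: list[list[str]], task: str) -> np.ndarray:
        if task not in self.net.heads:
            raise ValueError(f"model has no head for task {task!r}; has {list(self.net.heads)}")
        return self._forward(token_lists, task)

    def loss_components(self, token_lists, labels, lambda_mhc: float = 0.5,
                        emotion=None, personality=None) -> dict[str, float]:
        """Primary/secondary/total loss decomposition on one batch."""
        ids = self.net.prepare_ids([self.vocab.encode(t) for t in token_lists])
        probs, _ = self.net.forward(ids)
        primary = float(binary_cross_entropy(
            probs["primary"], np.asarray(labels, float).reshape(-1, 1)).data)
        sec_losses = []
        if "emotion" in probs and emotion is not None:
            sec_losses.append(float(binary_cross_entropy(
                probs["emotion"], np.asarray(emotion, float)).data))
        if "personality" in probs and personality is not None:
            sec_losses.append(float(binary_cross_entropy(
                probs["personality"], np.asarray(personality, float)).data))
        secondary = float(np.mean(sec_losses)) if sec_losses else 0.0
        return {
            "primary": primary,
            "secondary": secondary,
            "total": fusion_loss(primary, secondary, lambda_mhc),
        }


# ---------------------------------------------------------------------------
# training loops

def _accuracy(p: np.ndarray, y: np.ndarray) -> float:
    return float(((p >= 0.5).astype(int) == y).mean())


def train_bilstm(train: ContourDataset, val: ContourDataset,
                 cfg: BiLSTMConfig, tcfg: TrainConfig) -> TrainedContourModel:
    """Fit a BiLSTM contour classifier, keeping the epoch checkpoint with
    the highest validation accuracy."""
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty training or validation split")
    if train.width != cfg.input_width or val.width != cfg.input_width:
        raise ValueError(
            f"feature width mismatch: data {train.width}/{val.width} "
            f"vs config {cfg.input_width}")
    net = BiLSTMClassifier(cfg.input_width, cfg.hidden_dim, cfg.n_layers, seed=cfg.seed)
    model = TrainedContourModel(net, history=[])

    def batch_loss(idx: np.ndarray) -> Tensor:
        x, lengths = pad_batch([train.inputs[i] for i in idx])
        p = net.forward(x, lengths)
        return binary_cross_entropy(p, train.labels[idx].reshape(-1, 1).astype(float))

    _fit(net, model, batch_loss, len(train),
         lambda: _accuracy(model.predict_proba(val.inputs), val.labels), tcfg)
    return model


def _fit(net: Module, model: TrainedModel, batch_loss, n_train: int,
         val_accuracy, tcfg: TrainConfig) -> None:
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(net.parameters(), tcfg.learning_rate, tcfg.weight_decay)
    best_acc, best_state = -1.0, net.get_state()
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            net.zero_grad()
            loss = batch_loss(idx)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        acc = val_accuracy()
        model.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": acc})
        if acc > best_acc:
            best_acc, best_state = acc, net.get_state()
    net.set_state(best_state)


def _build_encoder(train: TokenDataset, cfg: AttentionEncoderConfig,
                   heads: dict[str, int]) -> tuple[AttentionEncoder, Vocabulary]:
    vocab = Vocabulary([w for toks in train.token_lists for w in toks])
    net = AttentionEncoder(
        vocab_size=len(vocab), model_dim=cfg.model_dim, n_heads=cfg.n_heads,
        n_layers=cfg.n_layers, max_tokens=cfg.max_tokens,
        n_outputs=heads, seed=cfg.seed)
    return net, vocab


def train_encoder(train: TokenDataset, val: TokenDataset,
                  cfg: AttentionEncoderConfig, tcfg: TrainConfig) -> TrainedEncoderModel:
    """Fit the compact attention-encoder classifier on word sequences."""
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty training or validation split")
    net, vocab = _build_encoder(train, cfg, {"primary": 1})
    model = TrainedEncoderModel(net, vocab, history=[])

    def batch_loss(idx: np.ndarray) -> Tensor:
        ids = net.prepare_ids([vocab.encode(train.token_lists[i]) for i in idx])
        probs, _ = net.forward(ids)
        return binary_cross_entropy(
            probs["primary"], train.labels[idx].reshape(-1, 1).astype(float))

    _fit(net, model, batch_loss, len(train),
         lambda: _accuracy(model.predict_proba(val.token_lists), val.labels), tcfg)
    return model


def silver_label(aux_model: TrainedEncoderModel, docs: list[Document],
                 task: str) -> list[Document]:
    """Attach thresholded auxiliary predictions as silver labels.

    Probability exactly 0.5 labels 1 (``>=`` threshold).  Gold condition
    labels are untouched; returns the same Document objects mutated.
    """
    if task not in SECONDARY_TASKS:
        raise ValueError(f"unknown task {task!r}")
    if task not in aux_model.net.heads:
        raise ValueError(
            f"model predicts {list(aux_model.net.heads)}, not {task!r}")
    token_lists = [tokens_from_text(d.text) for d in docs]
    probs = aux_model.predict_task_proba(token_lists, task)
    labels = (probs >= 0.5).astype(int)
    for doc, row in zip(docs, labels):
        if task == "emotion":
            doc.emotion = row.tolist()
        else:
            doc.personality = row.tolist()
    return docs


def train_aux_encoder(train: TokenDataset, val: TokenDataset, task: str,
                      cfg: AttentionEncoderConfig, tcfg: TrainConfig) -> TrainedEncoderModel:
    """Fit an auxiliary-task (emotion or personality) multi-label encoder."""
    n_out = SECONDARY_TASKS[task]
    targets_train = getattr(train, task)
    targets_val = getattr(val, task)
    if targets_train is None or targets_val is None:
        raise ValueError(f"dataset lacks {task} labels")
    net, vocab = _build_encoder(train, cfg, {task: n_out})
    model = TrainedEncoderModel(net, vocab, history=[], kind="encoder", tasks=(task,))

    def batch_loss(idx: np.ndarray) -> Tensor:
        ids = net.prepare_ids([vocab.encode(train.token_lists[i]) for i in idx])
        probs, _ = net.forward(ids)
        return binary_cross_entropy(probs[task], targets_train[idx].astype(float))

    def val_acc() -> float:
        p = model.predict_task_proba(val.token_lists, task)
        return float(((p >= 0.5).astype(int) == targets_val).mean())

    _fit(net, model, batch_loss, len(train), val_acc, tcfg)
    return model


def train_fusion(train: TokenDataset, val: TokenDataset,
                 fcfg: FusionConfig, cfg: AttentionEncoderConfig,
                 tcfg: TrainConfig) -> TrainedEncoderModel:
    """Joint training of the primary head and the configured secondary
    heads over one shared encoder with the weighted fusion loss."""
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty training or validation split")
    for task in fcfg.secondary_tasks:
        if getattr(train, task) is None:
            raise ValueError(f"missing silver labels for secondary task {task!r}")
    heads = {"primary": 1}
    heads.update({t: SECONDARY_TASKS[t] for t in fcfg.secondary_tasks})
    net, vocab = _build_encoder(train, cfg, heads)
    model = TrainedEncoderModel(net, vocab, history=[], kind="fusion",
                                tasks=tuple(fcfg.secondary_tasks))

    def batch_loss(idx: np.ndarray) -> Tensor:
        ids = net.prepare_ids([vocab.encode(train.token_lists[i]) for i in idx])
        probs, _ = net.forward(ids)
        primary = binary_cross_entropy(
            probs["primary"], train.labels[idx].reshape(-1, 1).astype(float))
        sec_losses = [
            binary_cross_entropy(probs[t], getattr(train, t)[idx].astype(float))
            for t in fcfg.secondary_tasks
        ]
        secondary = sec_losses[0]
        for extra in sec_losses[1:]:
            secondary = secondary + extra
        secondary = secondary * (1.0 / len(sec_losses))
        return fusion_loss(primary, secondary, fcfg.lambda_mhc)

    _fit(net, model, batch_loss, len(train),
         lambda: _accuracy(model.predict_proba(val.token_lists), val.labels), tcfg)
    return model
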