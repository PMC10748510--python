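"""Network architectures built on the numpy autodiff core.

* :class:`BiLSTMClassifier` — stacked bidirectional LSTM over per-window
  feature vectors; the last forward and backward hidden states of the top
  layer are concatenated and passed through a two-layer ReLU feed-forward
  head, a final affine layer and a logistic output.
* :class:`AttentionEncoder` — a compact multi-head self-attention encoder
  over word ids with a classification token; exposes attention weights
  and their loss gradients for attention-gradient attribution.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

PAD, UNK, CLS = 0, 1, 2


def _param(rng: np.random.Generator, shape, scale: float | None = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class LSTMDirection(Module):
    """One direction of one LSTM layer (fused gate weights, single bias)."""

    def __init__(self, rng, input_dim: int, hidden_dim: int):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.W = _param(rng, (input_dim + hidden_dim, 4 * hidden_dim))
        self.b = Tensor(np.zeros(4 * hidden_dim), requires_grad=True)

    def parameters(self):
        return [self.W, self.b]

    def run(self, x: Tensor) -> Tensor:
        """x: [B, T, D] -> hidden sequence [B, T, H]."""
        B, T, _ = x.shape
        H = self.hidden_dim
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            xt = x[:, t, :]
            z = ad.concat([xt, h], axis=1) @ self.W + self.b
            i = ad.sigmoid(z[:, 0 * H:1 * H])
            f = ad.sigmoid(z[:, 1 * H:2 * H])
            g = ad.tanh(z[:, 2 * H:3 * H])
            o = ad.sigmoid(z[:, 3 * H:4 * H])
            c = f * c + i * g
            h = o * ad.tanh(c)
            outs.append(h)
        return ad.stack(outs, axis=1)


class FeedForwardHead(Module):
    """Two ReLU layers, then an affine map to one (or more) logits."""

    def __init__(self, rng, in_dim: int, hidden: int, out_dim: int = 1):
        self.W1 = _param(rng, (in_dim, hidden))
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = _param(rng, (hidden, hidden))
        self.b2 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W3 = _param(rng, (hidden, out_dim))
        self.b3 = Tensor(np.zeros(out_dim), requires_grad=True)

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def forward(self, h: Tensor) -> Tensor:
        h = ad.relu(h @ self.W1 + self.b1)
        h = ad.relu(h @ self.W2 + self.b2)
        return ad.sigmoid(h @ self.W3 + self.b3)


class BiLSTMClassifier(Module):
    def __init__(self, input_width: int, hidden_dim: int = 512, n_layers: int = 3,
                 head_hidden: int | None = None, seed: int = 0):
        if n_layers < 1 or hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")
        rng = np.random.default_rng(seed)
        self.input_width = input_width
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.layers: list[tuple[LSTMDirection, LSTMDirection]] = []
        dim = input_width
        for _ in range(n_layers):
            self.layers.append((
                LSTMDirection(rng, dim, hidden_dim),
                LSTMDirection(rng, dim, hidden_dim),
            ))
            dim = 2 * hidden_dim
        self.head = FeedForwardHead(rng, 2 * hidden_dim,
                                    head_hidden or max(hidden_dim // 2, 8))

    def parameters(self):
        out = []
        for fwd, bwd in self.layers:
            out.extend(fwd.parameters())
            out.extend(bwd.parameters())
        out.extend(self.head.parameters())
        return out

    def lstm_parameter_count(self) -> int:
        """Closed-form-checkable count of the recurrent-stack parameters."""
        return sum(fwd.W.data.size + fwd.b.data.size +
                   bwd.W.data.size + bwd.b.data.size
                   for fwd, bwd in self.layers)

    @staticmethod
    def _reverse_index(lengths: np.ndarray, T: int) -> np.ndarray:
        B = len(lengths)
        idx = np.tile(np.arange(T), (B, 1))
        for b, L in enumerate(lengths):
            idx[b, :L] = np.arange(L - 1, -1, -1)
        return idx

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> Tensor:
        """x: padded [B, T, input_width]; lengths: true window counts.

        Returns predicted probabilities [B, 1].
        """
        B, T, _ = x.shape
        rev = self._reverse_index(lengths, T)
        rows = np.arange(B)[:, None]
        inp = Tensor(x)
        hf = hb_r = None
        for fwd, bwd in self.layers:
            hf = fwd.run(inp)
            hb_r = bwd.run(inp[rows, rev])
            hb = hb_r[rows, rev]
            inp = ad.concat([hf, hb], axis=2)
        last = lengths - 1
        h_fwd = hf[np.arange(B), last]
        h_bwd = hb_r[np.arange(B), last]
        return self.head.forward(ad.concat([h_fwd, h_bwd], axis=1))


class EncoderLayer(Module):
    def __init__(self, rng, dim: int, n_heads: int, ffn_dim: int):
        if dim % n_heads:
            raise ValueError("model_dim must be divisible by n_heads")
        self.dim, self.n_heads = dim, n_heads
        self.head_dim = dim // n_heads
        self.Wq = _param(rng, (dim, dim))
        self.Wk = _param(rng, (dim, dim))
        self.Wv = _param(rng, (dim, dim))
        self.Wo = _param(rng, (dim, dim))
        self.Wf1 = _param(rng, (dim, ffn_dim))
        self.bf1 = Tensor(np.zeros(ffn_dim), requires_grad=True)
        self.Wf2 = _param(rng, (ffn_dim, dim))
        self.bf2 = Tensor(np.zeros(dim), requires_grad=True)

    def parameters(self):
        return [self.Wq, self.Wk, self.Wv, self.Wo,
                self.Wf1, self.bf1, self.Wf2, self.bf2]

    def forward(self, x: Tensor, pad_mask: np.ndarray,
                attn_delta: Tensor | None = None):
        """x: [B, T, D]; pad_mask: [B, T] True at padding.

        ``attn_delta`` ([B, heads, T, T], requires_grad) is added to the
        softmaxed attention weights; its gradient after ``backward`` is
        exactly the loss gradient with respect to those weights.
        Returns (output, attention weights actually used).
        """
        B, T, D = x.shape
        h, dh = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(x @ self.Wq), split(x @ self.Wk), split(x @ self.Wv)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        bias = np.where(pad_mask[:, None, None, :], -1e9, 0.0)
        alpha = ad.softmax(scores + Tensor(bias), axis=-1)
        if attn_delta is not None:
            alpha = alpha + attn_delta
        ctx = alpha @ v  # [B, h, T, dh]
        merged = ctx.transpose(0, 2, 1, 3).reshape(B, T, D)
        x = x + merged @ self.Wo
        x = x + ad.relu(x @ self.Wf1 + self.bf1) @ self.Wf2 + self.bf2
        return x, alpha


class AttentionEncoder(Module):
    """Word-level attention-encoder classifier with a CLS token at
    position 0 and sigmoid output heads."""

    def __init__(self, vocab_size: int, model_dim: int = 128, n_heads: int = 4,
                 n_layers: int = 2, max_tokens: int = 512,
                 n_outputs: dict[str, int] | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.vocab_size = vocab_size
        self.model_dim = model_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.max_tokens = max_tokens
        self.embedding = _param(rng, (vocab_size, model_dim), scale=0.1)
        self.positions = _param(rng, (max_tokens + 1, model_dim), scale=0.1)
        self.layers = [EncoderLayer(rng, model_dim, n_heads, 2 * model_dim)
                       for _ in range(n_layers)]
        heads = n_outputs or {"primary": 1}
        self.heads = {name: FeedForwardHead(rng, model_dim, model_dim, k)
                      for name, k in heads.items()}

    def parameters(self):
        out = [self.embedding, self.positions]
        for layer in self.layers:
            out.extend(layer.parameters())
        for head in self.heads.values():
            out.extend(head.parameters())
        return out

    def forward(self, ids: np.ndarray, attn_deltas: list[Tensor] | None = None):
        """ids: [B, T] (already CLS-prefixed, PAD-padded, truncated).

        Returns (probs per head, attention-weight tensors per layer).
        """
        B, T = ids.shape
        pad_mask = ids == PAD
        x = self.embedding[ids] + self.positions[np.arange(T)]
        alphas = []
        for li, layer in enumerate(self.layers):
            delta = attn_deltas[li] if attn_deltas is not None else None
            x, alpha = layer.forward(x, pad_mask, delta)
            alphas.append(alpha)
        cls = x[:, 0, :]
        probs = {name: head.forward(cls) for name, head in self.heads.items()}
        return probs, alphas

    def prepare_ids(self, token_id_seqs: list[list[int]]) -> np.ndarray:
        """CLS-prefix, truncate to max_tokens and pad a batch of id lists."""
        seqs = [[CLS] + seq[: self.max_tokens] for seq in token_id_seqs]
        T = max(len(s) for s in seqs)
        out = np.full((len(seqs), T), PAD, dtype=int)
        for i, s in enumerate(seqs):
            out[i, : len(s)] = s
        return out


class Vocabulary:
    """Word-level vocabulary built from training data; ids 0..2 reserved
    for PAD/UNK/CLS."""

    def __init__(self, words: list[str]):
        uniq = sorted(set(words))
        self.word_to_id = {w: i + 3 for i, w in enumerate(uniq)}

    def __len__(self) -> int:
        return len(self.word_to_id) + 3

    def encode(self, words: list[str]) -> list[int]:
        return [self.word_to_id.get(w.lower(), UNK) for w in words]
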