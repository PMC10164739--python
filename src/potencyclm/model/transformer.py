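"""Encoder–decoder transformer with explicit backward passes.

Pre-norm residual blocks: the encoder stacks self-attention + feed-forward
sub-layers; each decoder layer stacks masked self-attention, cross-attention
over the encoder output, and a feed-forward sub-layer. Token and positional
embeddings are shared between encoder and decoder (one vocabulary covers
source and target sequences); the output head is a separate projection.
Training minimizes token-level cross-entropy under teacher forcing, with
padding positions excluded from loss and attention.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .nn import (
    Adam,
    Dense,
    Dropout,
    Embedding,
    Layer,
    LayerNorm,
    MultiHeadAttention,
    FeedForward,
    sinusoidal_encoding,
    softmax,
)


class EncoderLayer(Layer):
    def __init__(self, cfg: ModelConfig, rng, dtype):
        d = cfg.encoding_dim
        self.ln1 = LayerNorm(d, dtype)
        self.attn = MultiHeadAttention(d, cfg.n_heads, rng, dtype, cfg.dropout)
        self.ln2 = LayerNorm(d, dtype)
        self.ff = FeedForward(d, cfg.ff_dim, rng, dtype, cfg.dropout)

    def forward(self, x, mask, train):
        h = self.ln1.forward(x)
        x = x + self.attn.forward(h, h, mask, train)
        x = x + self.ff.forward(self.ln2.forward(x), train)
        return x

    def backward(self, d):
        d = d + self.ln2.backward(self.ff.backward(d))
        dq, dkv = self.attn.backward(d)
        d = d + self.ln1.backward(dq + dkv)
        return d


class DecoderLayer(Layer):
    def __init__(self, cfg: ModelConfig, rng, dtype):
        d = cfg.encoding_dim
        self.ln1 = LayerNorm(d, dtype)
        self.self_attn = MultiHeadAttention(d, cfg.n_heads, rng, dtype, cfg.dropout)
        self.ln2 = LayerNorm(d, dtype)
        self.cross_attn = MultiHeadAttention(d, cfg.n_heads, rng, dtype, cfg.dropout)
        self.ln3 = LayerNorm(d, dtype)
        self.ff = FeedForward(d, cfg.ff_dim, rng, dtype, cfg.dropout)

    def forward(self, x, enc_out, self_mask, cross_mask, train):
        h = self.ln1.forward(x)
        x = x + self.self_attn.forward(h, h, self_mask, train)
        x = x + self.cross_attn.forward(self.ln2.forward(x), enc_out, cross_mask, train)
        x = x + self.ff.forward(self.ln3.forward(x), train)
        return x

    def backward(self, d):
        """Returns (dx, d_enc_out)."""
        d = d + self.ln3.backward(self.ff.backward(d))
        dq, d_enc = self.cross_attn.backward(d)
        d = d + self.ln2.backward(dq)
        dq2, dkv2 = self.self_attn.backward(d)
        d = d + self.ln1.backward(dq2 + dkv2)
        return d, d_enc


class Seq2SeqTransformer(Layer):
    """The full conditional sequence model.

    Integer token ids in, next-token logits out. Index 0 must be the padding
    token; padding positions contribute neither to attention nor to loss.
    """

    PAD_ID = 0

    def __init__(self, vocab_size: int, cfg: ModelConfig, dtype=np.float32):
        self.cfg = cfg
        self.vocab_size = vocab_size
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        self.rng = rng
        d = cfg.encoding_dim
        self.embed = Embedding(vocab_size, d, rng, dtype)
        self.pos = sinusoidal_encoding(cfg.max_len, d, dtype)
        self.enc_drop = Dropout(cfg.dropout, rng)
        self.dec_drop = Dropout(cfg.dropout, rng)
        self.enc_layers = [EncoderLayer(cfg, rng, dtype) for _ in range(cfg.n_encoder_layers)]
        self.enc_norm = LayerNorm(d, dtype)
        self.dec_layers = [DecoderLayer(cfg, rng, dtype) for _ in range(cfg.n_decoder_layers)]
        self.dec_norm = LayerNorm(d, dtype)
        self.out_proj = Dense(d, vocab_size, rng, dtype)
        self._scale = float(np.sqrt(d))
        self._src_ids = None
        self._tgt_ids = None

    # -- masks --------------------------------------------------------------

    def _pad_mask(self, ids: np.ndarray) -> np.ndarray:
        # (B, 1, 1, S): broadcast over heads and query positions
        return (ids != self.PAD_ID)[:, None, None, :]

    @staticmethod
    def _causal_mask(t: int) -> np.ndarray:
        return np.tril(np.ones((t, t), dtype=bool))[None, None, :, :]

    # -- forward / backward -------------------------------------------------

    def encode(self, src: np.ndarray, train: bool = False) -> np.ndarray:
        b, s = src.shape
        if s > self.cfg.max_len:
            raise ValueError(f"source length {s} exceeds max_len {self.cfg.max_len}")
        self._src_ids = src
        x = self.embed.table.value[src] * self._scale + self.pos[:s]
        x = self.enc_drop.forward(x.astype(self.dtype), train)
        mask = self._pad_mask(src)
        for layer in self.enc_layers:
            x = layer.forward(x, mask, train)
        return self.enc_norm.forward(x)

    def decode(self, tgt_in: np.ndarray, enc_out: np.ndarray, src: np.ndarray,
               train: bool = False) -> np.ndarray:
        b, t = tgt_in.shape
        if t > self.cfg.max_len:
            raise ValueError(f"target length {t} exceeds max_len {self.cfg.max_len}")
        self._tgt_ids = tgt_in
        x = self.embed.table.value[tgt_in] * self._scale + self.pos[:t]
        x = self.dec_drop.forward(x.astype(self.dtype), train)
        self_mask = self._causal_mask(t) & self._pad_mask(tgt_in)
        cross_mask = self._pad_mask(src)
        for layer in self.dec_layers:
            x = layer.forward(x, enc_out, self_mask, cross_mask, train)
        x = self.dec_norm.forward(x)
        return self.out_proj.forward(x)

    def forward(self, src: np.ndarray, tgt_in: np.ndarray, train: bool = True) -> np.ndarray:
        """Teacher-forced logits of shape (B, T, V)."""
        enc_out = self.encode(src, train)
        return self.decode(tgt_in, enc_out, src, train)

    def loss_and_backward(self, src, tgt_in, tgt_out, train=True, backward=True):
        """Mean cross-entropy per non-pad target token; accumulates gradients
        when ``backward``. Returns the scalar loss."""
        logits = self.forward(src, tgt_in, train=train)
        mask = tgt_out != self.PAD_ID
        n = int(mask.sum())
        if n == 0:
            raise ValueError("batch contains no target tokens")
        probs = softmax(logits.astype(np.float64))
        b, t = tgt_out.shape
        idx = (np.arange(b)[:, None], np.arange(t)[None, :], tgt_out)
        loss = float(-(np.log(np.maximum(probs[idx], 1e-300)) * mask).sum() / n)
        if backward:
            dlogits = probs
            dlogits[idx] -= 1.0
            dlogits *= mask[..., None] / n
            self._backward(dlogits.astype(self.dtype))
        return loss

    def _backward(self, dlogits: np.ndarray):
        # decoder stack
        d = self.dec_norm.backward(self.out_proj.backward(dlogits))
        d_enc_total = np.zeros(1, dtype=self.dtype)
        for layer in reversed(self.dec_layers):
            d, d_enc = layer.backward(d)
            d_enc_total = d_enc_total + d_enc
        d = self.dec_drop.backward(d)
        np.add.at(self.embed.table.grad, self._tgt_ids.reshape(-1),
                  (d * self._scale).reshape(-1, d.shape[-1]))
        # encoder stack
        de = self.enc_norm.backward(d_enc_total)
        for layer in reversed(self.enc_layers):
            de = layer.backward(de)
        de = self.enc_drop.backward(de)
        np.add.at(self.embed.table.grad, self._src_ids.reshape(-1),
                  (de * self._scale).reshape(-1, de.shape[-1]))

    def evaluate_loss(self, src, tgt_in, tgt_out) -> float:
        return self.loss_and_backward(src, tgt_in, tgt_out, train=False, backward=False)

    # -- parameter plumbing --------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]):
        params = self.params()
        if len(params) != len(arrays):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.value[...] = a.astype(p.value.dtype)

    def make_optimizer(self) -> Adam:
        return Adam(self.params(), lr=self.cfg.learning_rate)
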