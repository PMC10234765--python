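"""The four-block multi-label peptide classifier and its variants.

Blocks, in composition order for the full model:

1. **Embedding** — learned lookup of residue codes 0..20 into d-dimensional
   vectors (code 0 is the learned pad vector), plus the closed-form sinusoidal
   positional encoding, refined by multi-head self-attention with pad keys
   masked out.
2. **TextCNN** — 1-D convolutions with kernel widths 2..5 (the minimum peptide
   length is 5) and global max pooling, concatenated across kernel widths.
3. **Feed-forward** — two-layer perceptron with ReLU, residual connection and
   layer normalization: ``FFN(Y) = LN(max(0, Y w1 + b1) w2 + b2 + Y)``.
4. **Classification** — fully connected layer to M label scores, sigmoid.

Alternative backbones (attention-only, BiLSTM+attention, TextCNN-only,
TextCNN+FFN) and ablation switches (positional encoding, FFN, TextCNN) are
configuration options; without the TextCNN block the length dimension is
collapsed by mean pooling over non-pad positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, embedding, stack

__all__ = ["NetworkConfig", "Network", "positional_encoding", "BACKBONES"]

BACKBONES = ("etfc", "mhsa_cb", "bilstm_mhsa_cb", "textcnn_cb", "textcnn_ffb_cb")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters; defaults follow the full-size model."""

    label_dim: int
    embed_dim: int = 192
    max_seq_len: int = 50
    vocab_size: int = 21
    n_heads: int = 8
    n_attention_layers: int = 1
    kernel_sizes: tuple[int, ...] = (2, 3, 4, 5)
    filters_per_kernel: int = 128
    ffn_hidden: int | None = None  # default: 2 x pooled feature width
    dropout: float = 0.1
    use_pos: bool = True
    use_ffn: bool = True
    use_textcnn: bool = True
    backbone: str = "etfc"
    dtype: str = "float32"

    def __post_init__(self):
        if self.label_dim < 2:
            raise ValueError("label_dim must be >= 2")
        if self.embed_dim % 2:
            raise ValueError("embed_dim must be even (sin/cos pairs)")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if min(self.kernel_sizes) < 2 or min(self.kernel_sizes) > 5:
            raise ValueError("smallest kernel must be 2..5 (minimum peptide length)")
        if max(self.kernel_sizes) > self.max_seq_len:
            raise ValueError("kernel size exceeds max_seq_len")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)

    @property
    def pooled_width(self) -> int:
        """Feature width entering the FFN / classification head."""
        if self.backbone in ("mhsa_cb", "bilstm_mhsa_cb"):
            return self.embed_dim
        if self.backbone == "etfc" and not self.use_textcnn:
            return self.embed_dim
        return len(self.kernel_sizes) * self.filters_per_kernel

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def positional_encoding(n: int, d: int) -> np.ndarray:
    """Sinusoidal absolute position matrix.

    Entry (i, 2j) = sin(i / 10000^(2j/d)); entry (i, 2j+1) = cos of the same
    argument — each embedding dimension is one sinusoid over positions.
    """
    if n < 1 or d < 2:
        raise ValueError("need n >= 1 and d >= 2")
    if d % 2:
        raise ValueError("d must be even")
    i = np.arange(n, dtype=np.float64)[:, None]
    j2 = np.arange(0, d, 2, dtype=np.float64)[None, :]
    angle = i / np.power(10000.0, j2 / d)
    P = np.empty((n, d), dtype=np.float64)
    P[:, 0::2] = np.sin(angle)
    P[:, 1::2] = np.cos(angle)
    return P


def _xavier(rng, fan_in, fan_out, dtype):
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(dtype)


class Network:
    """Parameterized classifier; ``forward`` maps code batches to probabilities."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(self.seed))
        self._pos = positional_encoding(
            config.max_seq_len, config.embed_dim).astype(config.np_dtype)

    # -- parameters --------------------------------------------------------

    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True, name=name)

    def _init_params(self, rng) -> None:
        c = self.config
        dt = c.np_dtype
        d = c.embed_dim
        self._add("emb", (rng.standard_normal((c.vocab_size, d)) *
                          (1.0 / np.sqrt(d))).astype(dt))
        if c.backbone in ("etfc", "mhsa_cb", "bilstm_mhsa_cb"):
            for l in range(c.n_attention_layers):
                for nm in ("wq", "wk", "wv", "wo"):
                    self._add(f"attn{l}_{nm}", _xavier(rng, d, d, dt))
                self._add(f"attn{l}_bo", np.zeros(d, dtype=dt))
        if c.backbone == "bilstm_mhsa_cb":
            H = d // 2
            for direction in ("f", "b"):
                self._add(f"lstm_{direction}_wih", _xavier(rng, d, 4 * H, dt))
                self._add(f"lstm_{direction}_whh", _xavier(rng, H, 4 * H, dt))
                self._add(f"lstm_{direction}_b", np.zeros(4 * H, dtype=dt))
        uses_cnn = c.backbone in ("etfc", "textcnn_cb", "textcnn_ffb_cb") and (
            c.use_textcnn or c.backbone != "etfc")
        if uses_cnn:
            for k in c.kernel_sizes:
                self._add(f"conv{k}_w", _xavier(rng, k * d, c.filters_per_kernel, dt))
                self._add(f"conv{k}_b", np.zeros(c.filters_per_kernel, dtype=dt))
        kf = c.pooled_width
        uses_ffn = (c.backbone == "etfc" and c.use_ffn) or c.backbone == "textcnn_ffb_cb"
        if uses_ffn:
            hidden = c.ffn_hidden or 2 * kf
            self._add("ffn_w1", _xavier(rng, kf, hidden, dt))
            self._add("ffn_b1", np.zeros(hidden, dtype=dt))
            self._add("ffn_w2", _xavier(rng, hidden, kf, dt))
            self._add("ffn_b2", np.zeros(kf, dtype=dt))
            self._add("ffn_gamma", np.ones(kf, dtype=dt))
            self._add("ffn_beta", np.zeros(kf, dtype=dt))
        self._add("head_w", _xavier(rng, kf, c.label_dim, dt))
        self._add("head_b", np.zeros(c.label_dim, dtype=dt))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    # -- blocks ------------------------------------------------------------

    @staticmethod
    def _pad_mask(codes: np.ndarray) -> np.ndarray:
        """1.0 at real residues, 0.0 at pads; rejects all-pad rows."""
        mask = (np.asarray(codes) != 0).astype(np.float64)
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("all-pad sequence: attention cannot be normalized")
        return mask

    def embed(self, codes: np.ndarray) -> Tensor:
        """Semantic lookup plus (optionally) the sinusoidal position matrix."""
        codes = np.asarray(codes)
        if ((codes < 0) | (codes >= self.config.vocab_size)).any():
            raise ValueError("codes must lie in 0..vocab_size-1")
        x = embedding(self.params["emb"], codes)
        if self.config.use_pos:
            x = x + Tensor(self._pos[None, :codes.shape[1], :])
        return x

    def mhsa_block(self, x: Tensor, pad_mask: np.ndarray, layer: int = 0,
                   return_weights: bool = False):
        """Scaled-dot-product multi-head self-attention; pad keys masked out."""
        c = self.config
        N, n, d = x.shape
        h, dh = c.n_heads, d // c.n_heads
        q = x @ self.params[f"attn{layer}_wq"]
        k = x @ self.params[f"attn{layer}_wk"]
        v = x @ self.params[f"attn{layer}_wv"]

        def split(t):
            return t.reshape(N, n, h, dh).transpose(0, 2, 1, 3)  # (N, h, n, dh)

        q, k, v = split(q), split(k), split(v)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        neg = np.where(pad_mask[:, None, None, :] > 0, 0.0, -1e9)
        weights = (scores + Tensor(neg.astype(scores.data.dtype))).softmax(axis=-1)
        out = (weights @ v).transpose(0, 2, 1, 3).reshape(N, n, d)
        out = out @ self.params[f"attn{layer}_wo"] + self.params[f"attn{layer}_bo"]
        if return_weights:
            return out, weights
        return out

    def textcnn_block(self, x: Tensor) -> Tensor:
        """Multi-width 1-D convolutions + ReLU + global max pooling, concatenated."""
        c = self.config
        N, n, d = x.shape
        pooled = []
        for k in c.kernel_sizes:
            if k > n:
                raise ValueError(f"kernel size {k} exceeds sequence length {n}")
            win = concat([x[:, j:j + n - k + 1, :] for j in range(k)], axis=-1)
            conv = (win @ self.params[f"conv{k}_w"] + self.params[f"conv{k}_b"]).relu()
            pooled.append(conv.max(axis=1))
        return concat(pooled, axis=-1)

    def ffn_block(self, y: Tensor) -> Tensor:
        """LN(max(0, Y w1 + b1) w2 + b2 + Y): residual two-layer perceptron."""
        inner = (y @ self.params["ffn_w1"] + self.params["ffn_b1"]).relu()
        z = inner @ self.params["ffn_w2"] + self.params["ffn_b2"] + y
        mu = z.mean(axis=-1, keepdims=True)
        var = ((z - mu) ** 2).mean(axis=-1, keepdims=True)
        normed = (z - mu) * ((var + 1e-5) ** -0.5)
        return normed * self.params["ffn_gamma"] + self.params["ffn_beta"]

    def classification_head(self, feat: Tensor) -> Tensor:
        return (feat @ self.params["head_w"] + self.params["head_b"]).sigmoid()

    def _bilstm(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        """Single bidirectional recurrent layer, hidden d/2 per direction."""
        c = self.config
        N, n, d = x.shape
        H = d // 2
        outs = {}
        for direction, order in (("f", range(n)), ("b", range(n - 1, -1, -1))):
            wih = self.params[f"lstm_{direction}_wih"]
            whh = self.params[f"lstm_{direction}_whh"]
            b = self.params[f"lstm_{direction}_b"]
            ht = Tensor(np.zeros((N, H), dtype=c.np_dtype))
            ct = Tensor(np.zeros((N, H), dtype=c.np_dtype))
            seq = [None] * n
            for t in order:
                gates = x[:, t, :] @ wih + ht @ whh + b
                i = gates[:, 0:H].sigmoid()
                f = gates[:, H:2 * H].sigmoid()
                g = gates[:, 2 * H:3 * H].tanh()
                o = gates[:, 3 * H:4 * H].sigmoid()
                ct = f * ct + i * g
                ht = o * ct.tanh()
                seq[t] = ht
            outs[direction] = stack(seq, axis=1)  # (N, n, H)
        return concat([outs["f"], outs["b"]], axis=-1)

    @staticmethod
    def _mean_pool(x: Tensor, pad_mask: np.ndarray) -> Tensor:
        m = pad_mask[:, :, None].astype(x.data.dtype)
        return (x * Tensor(m)).sum(axis=1) * Tensor(
            (1.0 / pad_mask.sum(axis=1, keepdims=True)).astype(x.data.dtype))

    def _dropout(self, x: Tensor, rng, training: bool) -> Tensor:
        p = self.config.dropout
        if not training or p == 0.0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
        return x * Tensor(keep)

    # -- forward -----------------------------------------------------------

    def forward(self, codes: np.ndarray, *, training: bool = False,
                dropout_rng=None) -> Tensor:
        """Probability matrix (N, M) for a batch of code vectors."""
        c = self.config
        codes = np.asarray(codes)
        pad_mask = self._pad_mask(codes)
        x = self.embed(codes)
        x = self._dropout(x, dropout_rng, training)

        if c.backbone == "bilstm_mhsa_cb":
            x = self._bilstm(x, pad_mask)
        if c.backbone in ("etfc", "mhsa_cb", "bilstm_mhsa_cb"):
            for l in range(c.n_attention_layers):
                x = self.mhsa_block(x, pad_mask, layer=l)

        if c.backbone in ("mhsa_cb", "bilstm_mhsa_cb"):
            feat = self._mean_pool(x, pad_mask)
        elif c.backbone == "etfc" and not c.use_textcnn:
            feat = self._mean_pool(x, pad_mask)
        else:
            feat = self.textcnn_block(x)
        feat = self._dropout(feat, dropout_rng, training)

        if (c.backbone == "etfc" and c.use_ffn) or c.backbone == "textcnn_ffb_cb":
            feat = self.ffn_block(feat)
        return self.classification_head(feat)

    # -- persistence -------------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, path: str | Path, label_names: list[str] | None = None,
             extra: dict | None = None) -> None:
        meta = {
            "version": self.CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "seed": self.seed,
            "label_names": label_names,
            "extra": extra or {},
        }
        arrays = {name: p.data for name, p in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["Network", dict]:
        with np.load(path) as zf:
            meta = json.loads(bytes(zf["__meta__"].tobytes()).decode())
            cfg_dict = meta["config"]
            cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
            config = NetworkConfig(**cfg_dict)
            net = cls(config, seed=meta["seed"])
            for name in net.params:
                net.params[name] = Tensor(zf[name].copy(), requires_grad=True, name=name)
        return net, meta
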