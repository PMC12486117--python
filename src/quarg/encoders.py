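"""Classical modality encoders and the fusion head.

The imaging branch is a compact residual convolutional encoder (conv stem,
``n_res_blocks`` two-conv identity-skip blocks with stride-2 downsampling
between blocks, global average pooling, linear projection).  The genomic
branch is a small transformer: the standardized expression vector is chunked
into tokens, linearly embedded, given sinusoidal positional encodings, and
passed through multi-head self-attention + feed-forward layers with residual
connections and layer normalization, then mean-pooled.  The head
concatenates [z_img || z_gen || z_q] and maps it through one hidden ReLU
layer to a logistic probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, conv2d, softmax


@dataclass
class ImageEncoderConfig:
    n_res_blocks: int = 3
    base_channels: int = 8
    d_img: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_res_blocks, self.base_channels, self.d_img) < 1:
            raise ValueError("all image-encoder sizes must be >= 1")


@dataclass
class GenomicEncoderConfig:
    token_size: int = 4
    d_model: int = 32
    n_heads: int = 4
    n_layers: int = 2
    d_gen: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def attention(Qm, Km, Vm, d_k: int):
    """softmax(Q K^T / sqrt(d_k)) V, row-wise; accepts arrays or Tensors.

    Matrices may carry leading batch/head axes; the last two axes are
    (tokens, d_k) for Q/K and (tokens, d_v) for V.
    """
    Qm = Qm if isinstance(Qm, Tensor) else Tensor(Qm)
    Km = Km if isinstance(Km, Tensor) else Tensor(Km)
    Vm = Vm if isinstance(Vm, Tensor) else Tensor(Vm)
    if Qm.shape[-1] != Km.shape[-1] or Km.shape[-2] != Vm.shape[-2]:
        raise ValueError("attention dimensions do not agree")
    kt = Km.transpose(*range(Km.data.ndim - 2), Km.data.ndim - 1, Km.data.ndim - 2)
    scores = (Qm @ kt) * (1.0 / np.sqrt(d_k))
    return softmax(scores, axis=-1) @ Vm


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + eps) ** 0.5) * gamma + beta


class ImageEncoder:
    MIN_SIZE = 16

    def __init__(self, config: ImageEncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.base_channels
        p: dict[str, Tensor] = {}
        p["stem_w"] = Tensor(_he(rng, (C, 1, 3, 3), 9), requires_grad=True)
        p["stem_b"] = Tensor(np.zeros(C), requires_grad=True)
        for b in range(config.n_res_blocks):
            if b > 0:
                p[f"down{b}_w"] = Tensor(_he(rng, (C, C, 3, 3), 9 * C), requires_grad=True)
                p[f"down{b}_b"] = Tensor(np.zeros(C), requires_grad=True)
            for c in (1, 2):
                p[f"block{b}_conv{c}_w"] = Tensor(_he(rng, (C, C, 3, 3), 9 * C), requires_grad=True)
                p[f"block{b}_conv{c}_b"] = Tensor(np.zeros(C), requires_grad=True)
        p["fc_w"] = Tensor(_he(rng, (C, config.d_img), C), requires_grad=True)
        p["fc_b"] = Tensor(np.zeros(config.d_img), requires_grad=True)
        self.params = p

    def forward(self, patches: np.ndarray) -> Tensor:
        """patches: (B, H, W) or (B, 1, H, W) -> (B, d_img)."""
        x = np.asarray(patches, dtype=float)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[-1] < self.MIN_SIZE or x.shape[-2] < self.MIN_SIZE:
            raise ValueError(f"patches must be at least {self.MIN_SIZE}x{self.MIN_SIZE}")
        p = self.params
        h = conv2d(Tensor(x), p["stem_w"], p["stem_b"]).relu()
        for b in range(self.config.n_res_blocks):
            if b > 0:
                h = conv2d(h, p[f"down{b}_w"], p[f"down{b}_b"], stride=2).relu()
            r = conv2d(h, p[f"block{b}_conv1_w"], p[f"block{b}_conv1_b"]).relu()
            r = conv2d(r, p[f"block{b}_conv2_w"], p[f"block{b}_conv2_b"])
            h = (h + r).relu()
        pooled = h.mean(axis=(2, 3))  # global average pool -> (B, C)
        return pooled @ p["fc_w"] + p["fc_b"]


def sinusoidal_positions(n_tokens: int, d_model: int) -> np.ndarray:
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class GenomicEncoder:
    def __init__(self, config: GenomicEncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        p: dict[str, Tensor] = {}
        p["tok_w"] = Tensor(_he(rng, (config.token_size, d), config.token_size), requires_grad=True)
        p["tok_b"] = Tensor(np.zeros(d), requires_grad=True)
        for l in range(config.n_layers):
            for name in ("wq", "wk", "wv", "wo"):
                p[f"l{l}_{name}"] = Tensor(_he(rng, (d, d), d), requires_grad=True)
            p[f"l{l}_ln1_g"] = Tensor(np.ones(d), requires_grad=True)
            p[f"l{l}_ln1_b"] = Tensor(np.zeros(d), requires_grad=True)
            p[f"l{l}_ff1_w"] = Tensor(_he(rng, (d, 2 * d), d), requires_grad=True)
            p[f"l{l}_ff1_b"] = Tensor(np.zeros(2 * d), requires_grad=True)
            p[f"l{l}_ff2_w"] = Tensor(_he(rng, (2 * d, d), 2 * d), requires_grad=True)
            p[f"l{l}_ff2_b"] = Tensor(np.zeros(d), requires_grad=True)
            p[f"l{l}_ln2_g"] = Tensor(np.ones(d), requires_grad=True)
            p[f"l{l}_ln2_b"] = Tensor(np.zeros(d), requires_grad=True)
        p["out_w"] = Tensor(_he(rng, (d, config.d_gen), d), requires_grad=True)
        p["out_b"] = Tensor(np.zeros(config.d_gen), requires_grad=True)
        self.params = p

    def forward(self, g: np.ndarray) -> Tensor:
        """g: (B, n_features) standardized genomic vectors -> (B, d_gen)."""
        g = np.asarray(g, dtype=float)
        if g.ndim == 1:
            g = g[None]
        if g.shape[1] == 0:
            raise ValueError("empty genomic vector")
        cfg = self.config
        B, G = g.shape
        T = -(-G // cfg.token_size)  # ceil
        padded = np.zeros((B, T * cfg.token_size))
        padded[:, :G] = g
        tokens = padded.reshape(B, T, cfg.token_size)
        p = self.params
        x = Tensor(tokens) @ p["tok_w"] + p["tok_b"]
        x = x + Tensor(sinusoidal_positions(T, cfg.d_model))
        h = cfg.n_heads
        dk = cfg.d_model // h
        for l in range(cfg.n_layers):
            q = (x @ p[f"l{l}_wq"]).reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            k = (x @ p[f"l{l}_wk"]).reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            v = (x @ p[f"l{l}_wv"]).reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            att = attention(q, k, v, dk).transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
            x = _layer_norm(x + att @ p[f"l{l}_wo"], p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
            ff = ((x @ p[f"l{l}_ff1_w"] + p[f"l{l}_ff1_b"]).relu()) @ p[f"l{l}_ff2_w"] + p[f"l{l}_ff2_b"]
            x = _layer_norm(x + ff, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
        pooled = x.mean(axis=1)  # (B, d_model)
        return pooled @ p["out_w"] + p["out_b"]


class FusionHead:
    def __init__(self, d_in: int, hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d_in = d_in
        self.hidden = hidden
        self.params = {
            "w1": Tensor(_he(rng, (d_in, hidden), d_in), requires_grad=True),
            "b1": Tensor(np.zeros(hidden), requires_grad=True),
            "w2": Tensor(_he(rng, (hidden, 1), hidden), requires_grad=True),
            "b2": Tensor(np.zeros(1), requires_grad=True),
        }

    def forward(self, z: Tensor) -> Tensor:
        """Joint embedding -> logit (B,)."""
        if z.shape[-1] != self.d_in:
            raise ValueError(f"head expects dimension {self.d_in}, got {z.shape[-1]}")
        p = self.params
        h = (z @ p["w1"] + p["b1"]).relu()
        return (h @ p["w2"] + p["b2"]).reshape(-1)


def fuse_predict(z_img: Tensor, z_gen: Tensor, z_q: Tensor, head: FusionHead) -> Tensor:
    """Concatenate in the fixed (image, genomic, quantum) order -> probability."""
    return head.forward(concat([z_img, z_gen, z_q], axis=-1)).sigmoid()
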