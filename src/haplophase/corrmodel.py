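"""The learnable read-correlation model.

A convolutional encoder maps each one-hot-encoded fragment row to a d_r-dim
embedding; a transformer encoder (multi-head self-attention over the reads)
refines the embeddings and a dense head produces row-normalised vectors whose
Gram matrix Sigma = Q~ Q~^T is a positive semi-definite read-read kernel with
unit diagonal. Training signals: a contrastive loss that pushes Sigma toward
+1 for read pairs currently assigned to the same haplotype and -1 otherwise,
a consistency regularizer tying Sigma to the correlations measurable from
read overlaps, and a sparsity regularizer on off-diagonal entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, conv1d_same
from .fragments import ReadFragmentMatrix

__all__ = [
    "EncoderConfig",
    "CorrelationEncoder",
    "measured_correlations",
    "pair_indicator",
    "contrastive_loss",
    "consistency_regularizer",
    "sparsity_regularizer",
    "total_loss",
]

_LN_EPS = 1e-5


@dataclass
class EncoderConfig:
    """Architecture hyperparameters of the correlation encoder.

    The defaults are the full-size model: embedding dimension d_r=128 with
    convolution kernels (4,5), (1,5), (1,3) and filter counts 32/64/128
    (the first kernel consumes the 4-channel nucleotide axis), three
    transformer encoder layers with four attention heads each, and a
    correlation head of dimension d_q = d_r/2. Filter counts and d_q scale
    with d_r when reduced models are requested.
    """

    d_r: int = 128
    n_layers: int = 3
    n_heads: int = 4
    d_q: int | None = None
    conv_filters: tuple[int, int, int] | None = None
    conv_kernels: tuple[int, int, int] = (5, 5, 3)  # widths; first layer spans all 4 channels
    ffn_mult: int = 4
    prelu_init: float = 0.25

    def __post_init__(self):
        if self.d_q is None:
            self.d_q = self.d_r // 2
        if self.conv_filters is None:
            self.conv_filters = (max(1, self.d_r // 4), max(1, self.d_r // 2), self.d_r)
        if self.d_r % self.n_heads:
            raise ValueError("d_r must be divisible by n_heads")

    def to_dict(self) -> dict:
        return {
            "d_r": self.d_r,
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "d_q": self.d_q,
            "conv_filters": list(self.conv_filters),
            "conv_kernels": list(self.conv_kernels),
            "ffn_mult": self.ffn_mult,
            "prelu_init": self.prelu_init,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        d["conv_kernels"] = tuple(d["conv_kernels"])
        return cls(**d)


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class CorrelationEncoder:
    """Convolutional + transformer encoder producing the read kernel Sigma.

    Parameters are plain autodiff tensors keyed by name; the model is bound
    to a fixed block length ``seq_len`` (the flatten->dense layer depends on
    it).
    """

    def __init__(self, cfg: EncoderConfig, seq_len: int,
                 rng: np.random.Generator | int | None = None):
        if seq_len < 2:
            raise ValueError("haplotype block too short")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.seq_len = int(seq_len)
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)

    # -- parameters ----------------------------------------------------------
    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        c_in = 4
        for i, (c_out, kw) in enumerate(zip(cfg.conv_filters, cfg.conv_kernels)):
            self._add(f"conv{i}_W", _glorot(rng, (kw, c_in, c_out)))
            self._add(f"conv{i}_b", np.zeros(c_out))
            self._add(f"conv{i}_slope", np.full((), cfg.prelu_init))
            c_in = c_out
        flat = cfg.conv_filters[-1] * self.seq_len
        self._add("embed_W", _glorot(rng, (flat, cfg.d_r)))
        self._add("embed_b", np.zeros(cfg.d_r))
        d, dff = cfg.d_r, cfg.ffn_mult * cfg.d_r
        for i in range(cfg.n_layers):
            for nm in ("q", "k", "v", "o"):
                self._add(f"te{i}_W{nm}", _glorot(rng, (d, d)))
                self._add(f"te{i}_b{nm}", np.zeros(d))
            self._add(f"te{i}_ln1_g", np.ones(d))
            self._add(f"te{i}_ln1_b", np.zeros(d))
            self._add(f"te{i}_ffn_W1", _glorot(rng, (d, dff)))
            self._add(f"te{i}_ffn_b1", np.zeros(dff))
            self._add(f"te{i}_ffn_W2", _glorot(rng, (dff, d)))
            self._add(f"te{i}_ffn_b2", np.zeros(d))
            self._add(f"te{i}_ln2_g", np.ones(d))
            self._add(f"te{i}_ln2_b", np.zeros(d))
        self._add("head_W", _glorot(rng, (d, cfg.d_q)))
        self._add("head_b", np.zeros(cfg.d_q))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def make_optimizer(self, lr: float = 1e-5) -> Adam:
        return Adam(self.parameters(), lr=lr)

    # -- forward pieces -------------------------------------------------------
    def encode_reads(self, reads: np.ndarray) -> Tensor:
        """Embed one-hot reads (n, 4, l) into (n, d_r).

        Convolutions run in channels-last layout; the flatten before the
        dense layer is position-major, i.e. the (l * filters) features are
        ordered (position 0 channels, position 1 channels, ...).
        """
        reads = np.asarray(reads, dtype=np.float64)
        if reads.ndim != 3 or reads.shape[1] != 4:
            raise ValueError("expected one-hot reads of shape (n, 4, l)")
        if reads.shape[2] != self.seq_len:
            raise ValueError("block length does not match the model's seq_len")
        x = Tensor(np.ascontiguousarray(reads.transpose(0, 2, 1)))  # (n, l, 4)
        p = self.params
        for i in range(len(self.cfg.conv_kernels)):
            x = conv1d_same(x, p[f"conv{i}_W"], p[f"conv{i}_b"])
            x = x.prelu(p[f"conv{i}_slope"])
        n = reads.shape[0]
        x = x.reshape(n, -1)
        return x @ p["embed_W"] + p["embed_b"]

    @staticmethod
    def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
        return x.layer_norm(gamma, beta, eps=_LN_EPS)

    def _encoder_layer(self, x: Tensor, i: int) -> Tensor:
        p, cfg = self.params, self.cfg
        n, d = x.shape
        h, dh = cfg.n_heads, d // cfg.n_heads

        def heads(t: Tensor) -> Tensor:
            return t.reshape(n, h, dh).transpose(1, 0, 2)  # (h, n, dh)

        q = heads(x @ p[f"te{i}_Wq"] + p[f"te{i}_bq"])
        k = heads(x @ p[f"te{i}_Wk"] + p[f"te{i}_bk"])
        v = heads(x @ p[f"te{i}_Wv"] + p[f"te{i}_bv"])
        scores = (q @ k.swapaxes(-1, -2)) / np.sqrt(dh)
        attn = scores.softmax() @ v                       # (h, n, dh)
        merged = attn.transpose(1, 0, 2).reshape(n, d)
        x = self._layer_norm(x + merged @ p[f"te{i}_Wo"] + p[f"te{i}_bo"],
                             p[f"te{i}_ln1_g"], p[f"te{i}_ln1_b"])
        ffn = (x @ p[f"te{i}_ffn_W1"] + p[f"te{i}_ffn_b1"]).relu()
        ffn = ffn @ p[f"te{i}_ffn_W2"] + p[f"te{i}_ffn_b2"]
        return self._layer_norm(x + ffn, p[f"te{i}_ln2_g"], p[f"te{i}_ln2_b"])

    def normalized_head(self, z: Tensor) -> Tensor:
        """Transformer layers + dense head + row L2-normalization: (n, d_q)."""
        for i in range(self.cfg.n_layers):
            z = self._encoder_layer(z, i)
        q = z @ self.params["head_W"] + self.params["head_b"]
        norm = (q * q).sum(axis=-1, keepdims=True).sqrt()
        # rows with vanishing norm are left as zeros rather than divided by ~0
        guard = (norm.data < 1e-8).astype(float)
        return q / (norm + Tensor(guard))

    def correlation_forward(self, z: Tensor) -> Tensor:
        """Transformer layers + correlation head: (n, d_r) -> Sigma (n, n)."""
        qn = self.normalized_head(z)
        sigma = qn @ qn.transpose()
        n = sigma.shape[0]
        eye = np.eye(n)
        return sigma * Tensor(1.0 - eye) + Tensor(eye)  # force exact unit diagonal

    def forward(self, reads: np.ndarray) -> Tensor:
        """Full pass: one-hot reads -> Sigma."""
        return self.correlation_forward(self.encode_reads(reads))

    def sigma(self, reads: np.ndarray) -> np.ndarray:
        """Inference-only Sigma as a plain array."""
        return self.forward(reads).data

    # -- serialization --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {name: t.data for name, t in self.params.items()}
        meta = json.dumps({"config": self.cfg.to_dict(), "seq_len": self.seq_len})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "CorrelationEncoder":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(EncoderConfig.from_dict(meta["config"]), meta["seq_len"], rng=0)
            for name in model.params:
                model.params[name].data = np.asarray(data[name], dtype=np.float64)
        return model


# ---------------------------------------------------------------------------
# measured correlations and loss terms
# ---------------------------------------------------------------------------

def measured_correlations(m: ReadFragmentMatrix) -> np.ndarray:
    """Pairwise read correlations measurable from overlaps.

    For reads i, j sharing covered columns, C_ij = (k_sim - k_dissim) /
    (k_sim + k_dissim) with agreements/disagreements counted over the shared
    columns; C_ij = 0 for non-overlapping pairs, and the diagonal is 1.
    """
    cov = m.covered().astype(np.float64)
    shared = cov @ cov.T
    sim = np.zeros_like(shared)
    for b in range(4):
        mb = (m.entries == b).astype(np.float64)
        sim += mb @ mb.T
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(shared > 0, (2.0 * sim - shared) / shared, 0.0)
    np.fill_diagonal(c, 1.0)
    return c


def pair_indicator(labels: np.ndarray) -> np.ndarray:
    """Binary matrix p with p_ij = 1 iff reads i and j share a cluster."""
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(np.float64)


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def contrastive_loss(sigma, p):
    """Sum over unordered pairs i<j of p(1-Sigma)^2 + (1-p)(1+Sigma)^2."""
    s, is_tensor = _wrap(sigma)
    p = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    n = s.shape[0]
    upper = np.triu(np.ones((n, n)), k=1)
    pt = Tensor(p)
    term = pt * (1.0 - s).square() + (1.0 - pt) * (1.0 + s).square()
    loss = (term * Tensor(upper)).sum()
    return loss if is_tensor else loss.item()


def consistency_regularizer(sigma, c):
    """Frobenius norm of (Sigma - C) masked to the support of C."""
    s, is_tensor = _wrap(sigma)
    c = c.data if isinstance(c, Tensor) else np.asarray(c, dtype=np.float64)
    mask = (c != 0).astype(np.float64)
    diff = (s - Tensor(c)) * Tensor(mask)
    # tiny floor keeps the norm's gradient finite at exactly zero
    loss = (diff.square().sum() + 1e-24).sqrt()
    return loss if is_tensor else loss.item()


def sparsity_regularizer(sigma):
    """Sum of absolute off-diagonal entries of Sigma (both orderings)."""
    s, is_tensor = _wrap(sigma)
    n = s.shape[0]
    off = 1.0 - np.eye(n)
    loss = (s.abs() * Tensor(off)).sum()
    return loss if is_tensor else loss.item()


def total_loss(sigma, c, p, lambda_r: float = 100.0, lambda_s: float = 10.0):
    """L = L_contrastive + lambda_r * L_consistency + lambda_s * L_sparsity."""
    s, is_tensor = _wrap(sigma)
    loss = (
        contrastive_loss(s, p)
        + lambda_r * consistency_regularizer(s, c)
        + lambda_s * sparsity_regularizer(s)
    )
    return loss if is_tensor else loss.item()
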