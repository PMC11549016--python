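"""The dual-path ac4C classifier as a differentiable computation graph.

Path 1 treats the window as a sequence: integer codes are embedded, summed
with a sinusoidal positional encoding, run through a bidirectional GRU, and
refined by multi-head self-attention.  Path 2 treats the window as a
composition profile: the PseKNC vector enters a stack of three 1-D
convolution blocks (conv -> ReLU -> max-pool) plus a final max-pool, whose
spatial positions are then attended over.  Each path is mean-pooled to a
fixed-width vector; the two vectors are concatenated and classified by a
two-layer softmax head.

Every architectural width lives in :class:`NetworkConfig`, the single source
of truth for model shape; ablation flags on the same object switch paths,
positional encoding and attention on or off, and unused parameter groups are
simply never constructed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .dataio import RnaRecord
from .encoders import integer_encode, one_hot_encode, positional_encoding, pseknc


FeatureScheme = Literal["integer", "onehot"]
PoolMode = Literal["mean", "max", "flatten"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architectural hyperparameters of the dual-path network.

    Defaults follow the production configuration: embedding width
    ``d_model=512`` (so per-head width d_k = 512/8 = 64), bidirectional GRU
    with 512 hidden units per direction, 8 attention heads, convolution
    kernel 4 with padding 2.  Channel widths, pooling and classifier widths
    are conventional defaults; all are overridable.
    """

    d_model: int = 512
    gru_hidden: int = 512
    bidirectional: bool = True
    heads: int = 8
    conv_kernel: int = 4
    conv_padding: int = 2
    conv_channels: tuple[int, int, int] = (32, 64, 128)
    pool_width: int = 2
    classifier_hidden: int = 256
    dropout: float = 0.2
    pe_base: int = 10000
    k: int = 2  # PseKNC k-mer order; path-2 input width is 4**k + 2
    # ablation switches
    use_path1: bool = True
    use_path2: bool = True
    use_positional_encoding: bool = True
    use_attention: bool = True
    feature_scheme: FeatureScheme = "integer"
    pool_mode: PoolMode = "mean"

    def __post_init__(self) -> None:
        if self.d_model % self.heads != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by heads ({self.heads})"
            )
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even for sinusoidal encoding")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not (self.use_path1 or self.use_path2):
            raise ValueError("at least one path must be enabled")
        for name in ("d_model", "gru_hidden", "heads", "conv_kernel",
                     "pool_width", "classifier_hidden", "k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def d_k(self) -> int:
        return self.d_model // self.heads

    @property
    def pseknc_width(self) -> int:
        return 4 ** self.k + 2

    def ablate(self, **changes) -> "NetworkConfig":
        return replace(self, **changes)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class _Module:
    """Minimal parameter container with recursive traversal."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor):
                out[key] = val
            elif isinstance(val, _Module):
                out.update(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, _Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())


class Linear(_Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class GRUCell(_Module):
    """Single-direction GRU with explicit update (z) and reset (r) gates.

    The recurrence is ``h_t = (1 - z_t) * h_prev + z_t * tanh(W_hx x_t +
    b_hx + r_t * (W_hh h_prev + b_hh))`` with sigmoid gates each combining a
    hidden-to-hidden and an input-to-hidden affine map.
    """

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.W_zx = Tensor(_glorot(rng, d_in, hidden), requires_grad=True)
        self.W_zh = Tensor(_glorot(rng, hidden, hidden), requires_grad=True)
        self.b_zx = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_zh = Tensor(np.zeros(hidden), requires_grad=True)
        self.W_rx = Tensor(_glorot(rng, d_in, hidden), requires_grad=True)
        self.W_rh = Tensor(_glorot(rng, hidden, hidden), requires_grad=True)
        self.b_rx = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_rh = Tensor(np.zeros(hidden), requires_grad=True)
        self.W_hx = Tensor(_glorot(rng, d_in, hidden), requires_grad=True)
        self.W_hh = Tensor(_glorot(rng, hidden, hidden), requires_grad=True)
        self.b_hx = Tensor(np.zeros(hidden), requires_grad=True)
        self.b_hh = Tensor(np.zeros(hidden), requires_grad=True)
        self.hidden = hidden

    def step(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        z = (h_prev @ self.W_zh + x_t @ self.W_zx + self.b_zh + self.b_zx).sigmoid()
        r = (h_prev @ self.W_rh + x_t @ self.W_rx + self.b_rh + self.b_rx).sigmoid()
        cand = (x_t @ self.W_hx + self.b_hx + r * (h_prev @ self.W_hh + self.b_hh)).tanh()
        return (1.0 - z) * h_prev + z * cand

    def run(self, X: Tensor, reverse: bool = False) -> list[Tensor]:
        """Hidden states over a (B, L, d_in) input, in input time order."""
        B, L, _ = X.shape
        h = Tensor(np.zeros((B, self.hidden)))
        states: list[Tensor] = []
        steps = range(L - 1, -1, -1) if reverse else range(L)
        for t in steps:
            h = self.step(X[:, t, :], h)
            states.append(h)
        if reverse:
            states.reverse()
        return states


class BiGRU(_Module):
    """Forward and backward GRUs; output row t is [h_t^f, h_t^b]."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int,
                 bidirectional: bool = True):
        self.fwd = GRUCell(rng, d_in, hidden)
        self.bwd = GRUCell(rng, d_in, hidden) if bidirectional else None

    @property
    def out_width(self) -> int:
        return self.fwd.hidden * (2 if self.bwd is not None else 1)

    def __call__(self, X: Tensor) -> Tensor:
        f_states = self.fwd.run(X)
        if self.bwd is None:
            return ag.stack(f_states, axis=1)
        b_states = self.bwd.run(X, reverse=True)
        rows = [ag.concatenate([f, b], axis=-1) for f, b in zip(f_states, b_states)]
        return ag.stack(rows, axis=1)


class MultiHeadAttention(_Module):
    """Scaled dot-product self-attention with h parallel heads, no masking."""

    def __init__(self, rng: np.random.Generator, d_model: int, heads: int):
        if d_model % heads != 0:
            raise ValueError("d_model must be divisible by heads")
        self.W_Q = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.W_K = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.W_V = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.W_o = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.heads = heads
        self.d_model = d_model

    def _split(self, X: Tensor) -> Tensor:
        B, L, _ = X.shape
        d_k = self.d_model // self.heads
        return X.reshape(B, L, self.heads, d_k).swapaxes(1, 2)  # (B,h,L,d_k)

    def __call__(self, X: Tensor, return_weights: bool = False):
        B, L, _ = X.shape
        d_k = self.d_model // self.heads
        Q = self._split(X @ self.W_Q)
        K = self._split(X @ self.W_K)
        V = self._split(X @ self.W_V)
        scores = (Q @ K.swapaxes(-1, -2)) / np.sqrt(d_k)
        weights = scores.softmax(axis=-1)
        heads = weights @ V  # (B,h,L,d_k)
        merged = heads.swapaxes(1, 2).reshape(B, L, self.d_model)
        out = merged @ self.W_o
        if return_weights:
            return out, weights
        return out


class ConvBlock(_Module):
    """conv -> ReLU -> non-overlapping max-pool, on (B, C, L) signals."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int, padding: int, pool_width: int):
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.W = Tensor(_glorot(rng, fan_in, fan_out, shape=(c_out, c_in, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.padding = padding
        self.pool_width = pool_width

    def __call__(self, x: Tensor) -> Tensor:
        return ag.maxpool1d(ag.conv1d(x, self.W, self.b, self.padding).relu(),
                            self.pool_width)


def pool_path(X: Tensor, mode: PoolMode = "mean") -> Tensor:
    """Reduce a (B, n, d) per-position representation to (B, d) (or flatten)."""
    if X.shape[-2] < 1:
        raise ValueError("cannot pool an empty sequence axis")
    if mode == "mean":
        return X.mean(axis=-2)
    if mode == "max":
        return X.amax(axis=-2)
    if mode == "flatten":
        B = X.shape[0]
        return X.reshape(B, -1)
    raise ValueError(f"unknown pool mode {mode!r}")


class Classifier(_Module):
    """Two-layer head: ReLU hidden layer, softmax output over {neg, pos}."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int,
                 dropout: float):
        self.lin1 = Linear(rng, d_in, hidden)
        self.lin2 = Linear(rng, hidden, 2)
        self.dropout = dropout

    def logits(self, v: Tensor, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        h = self.lin1(v).relu()
        if train and self.dropout > 0.0:
            if rng is None:
                raise ValueError("dropout in train mode needs an rng")
            mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h = h * Tensor(mask)
        return self.lin2(h)

    def __call__(self, v: Tensor) -> Tensor:
        return self.logits(v).softmax(axis=-1)


class DualPathClassifier(_Module):
    """The full two-path model over (integer codes, PseKNC vector) pairs."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.seed = seed
        d = config.d_model

        if config.use_path1:
            self.embedding = Tensor(rng.normal(0.0, 0.1, size=(4, d)),
                                    requires_grad=True)
            self.gru = BiGRU(rng, d, config.gru_hidden, config.bidirectional)
            self.bridge1 = Linear(rng, self.gru.out_width, d)
            if config.use_attention:
                self.attn1 = MultiHeadAttention(rng, d, config.heads)

        if config.use_path2:
            chans = config.conv_channels
            self.conv_blocks = [
                ConvBlock(rng, c_in, c_out, config.conv_kernel,
                          config.conv_padding, config.pool_width)
                for c_in, c_out in zip((1,) + tuple(chans[:-1]), chans)
            ]
            self.bridge2 = Linear(rng, chans[-1], d)
            if config.use_attention:
                self.attn2 = MultiHeadAttention(rng, d, config.heads)

        n_paths = int(config.use_path1) + int(config.use_path2)
        self.classifier = Classifier(rng, n_paths * d, config.classifier_hidden,
                                     config.dropout)

    # -- feature preparation -------------------------------------------------

    def encode_batch(self, records: Sequence[RnaRecord]) -> tuple[np.ndarray, np.ndarray]:
        """(integer-code matrix, PseKNC matrix) for a batch of records."""
        codes = np.stack([integer_encode(r) for r in records])
        feats = np.stack(
            [pseknc(r, k=self.config.k, mode="full-lexicographic").F for r in records]
        )
        return codes, feats

    # -- forward passes ------------------------------------------------------

    def _path1(self, codes: np.ndarray, taps: dict | None,
               delta_embed: np.ndarray | None) -> Tensor:
        cfg = self.config
        if cfg.feature_scheme == "onehot":
            B, L = codes.shape
            hot = np.zeros((B, L, 4))
            hot[np.arange(B)[:, None], np.arange(L)[None, :], codes] = 1.0
            x = Tensor(hot) @ self.embedding
        else:
            x = ag.embedding(self.embedding, codes)
        if delta_embed is not None:
            x = x + Tensor(delta_embed)
        if taps is not None:
            taps["embedded"] = x
        if cfg.use_positional_encoding:
            pe = positional_encoding(codes.shape[1], cfg.d_model, cfg.pe_base)
            x = x + Tensor(pe)
        x = self.bridge1(self.gru(x))
        if cfg.use_attention:
            x = self.attn1(x)
        return pool_path(x, cfg.pool_mode)

    def _path2(self, feats: np.ndarray, taps: dict | None,
               delta_feat: np.ndarray | None) -> Tensor:
        cfg = self.config
        x = Tensor(feats, requires_grad=True)
        if taps is not None:
            taps["features"] = x
        if delta_feat is not None:
            x = x + Tensor(delta_feat)
            if taps is not None:
                taps["features"] = x
        B, F = feats.shape
        sig = x.reshape(B, 1, F)
        for block in self.conv_blocks:
            sig = block(sig)
        x = self.bridge2(sig.swapaxes(1, 2))  # (B, L', d_model)
        if cfg.use_attention:
            x = self.attn2(x)
        return pool_path(x, cfg.pool_mode)

    def forward_logits(
        self,
        codes: np.ndarray | None,
        feats: np.ndarray | None,
        *,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
        taps: dict | None = None,
        delta_embed: np.ndarray | None = None,
        delta_feat: np.ndarray | None = None,
    ) -> Tensor:
        cfg = self.config
        parts: list[Tensor] = []
        if cfg.use_path1:
            if codes is None:
                raise ValueError("path 1 enabled but no integer codes given")
            parts.append(self._path1(codes, taps, delta_embed))
        if cfg.use_path2:
            if feats is None:
                raise ValueError("path 2 enabled but no PseKNC features given")
            parts.append(self._path2(feats, taps, delta_feat))
        v = parts[0] if len(parts) == 1 else ag.concatenate(parts, axis=-1)
        return self.classifier.logits(v, train=train, rng=dropout_rng)

    def predict_proba(self, records: Sequence[RnaRecord],
                      batch_size: int = 128) -> np.ndarray:
        """Evaluation-mode P(ac4C) per record (dropout off, deterministic)."""
        probs: list[np.ndarray] = []
        for start in range(0, len(records), batch_size):
            batch = records[start : start + batch_size]
            codes, feats = self.encode_batch(batch)
            logits = self.forward_logits(
                codes if self.config.use_path1 else None,
                feats if self.config.use_path2 else None,
            )
            probs.append(logits.softmax(axis=-1).data[:, 1])
        return np.concatenate(probs)

    def forward(self, record: RnaRecord) -> float:
        """Probability that the central cytidine of one window is acetylated."""
        return float(self.predict_proba([record])[0])

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpointing -------------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        """Single-file checkpoint: config + seed + all parameter arrays."""
        named = self.named_parameters()
        header = {
            "version": self.CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "seed": self.seed,
            "metadata": metadata or {},
        }
        np.savez(
            path,
            __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            **{name: t.data for name, t in named.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "DualPathClassifier":
        with np.load(path) as npz:
            header = json.loads(bytes(npz["__header__"].tobytes()).decode())
            if header["version"] != cls.CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {header['version']}")
            cfg_dict = header["config"]
            for key in ("conv_channels",):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(NetworkConfig(**cfg_dict), seed=header["seed"])
            named = model.named_parameters()
            for name, tensor in named.items():
                tensor.data = npz[name].copy()
        return model
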