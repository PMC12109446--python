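"""The three stance-detection sequence models.

All three map an (ω × C) sensor window to a scalar stance probability:

* ``tcn_gru`` — causal dilated-convolution residual stack, unidirectional
  GRU, sigmoid head on the final hidden state.
* ``bitcn_bigru`` — forward + time-reversed TCN stacks (features
  concatenated), bidirectional GRU, mean-pooled sigmoid head.
* ``bitcn_bigru_crossattn`` — as above, plus multi-head scaled dot-product
  cross-attention whose queries come from the BiGRU sequence and whose
  keys/values come from the BiTCN features (wiring reversible in config),
  then mean pooling and the sigmoid head.

The sigmoid head keeps outputs in [0, 1], so training against the binary
stance label with an L1 loss is well-posed and predicted traces can be
overlaid directly on the reference trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from ._layers import (
    BiGRU,
    BiTCN,
    Dense,
    GRU,
    Module,
    MultiHeadCrossAttention,
    TCN,
)

ARCHITECTURES = ("tcn_gru", "bitcn_bigru", "bitcn_bigru_crossattn")


@dataclass
class ModelConfig:
    architecture: str = "bitcn_bigru_crossattn"
    tcn_channels: int = 64
    tcn_kernel: int = 3
    tcn_dilations: tuple[int, ...] = (1, 2, 4)
    gru_hidden: int = 64
    attn_heads: int = 4
    attn_query: str = "bigru"  # or "bitcn": reversed cross-attention wiring
    dropout: float = 0.2
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0
    shared_bitcn: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.attn_query not in ("bigru", "bitcn"):
            raise ValueError(f"unknown attn_query {self.attn_query!r}")
        if min(self.tcn_channels, self.tcn_kernel, self.gru_hidden,
               self.attn_heads, *self.tcn_dilations) < 1:
            raise ValueError("all model dimensions must be >= 1")


class TcnGru(Module):
    def __init__(self, cfg: ModelConfig, in_channels: int, rng: np.random.Generator):
        self.tcn = TCN(rng, in_channels, cfg.tcn_channels, cfg.tcn_kernel,
                       cfg.tcn_dilations, cfg.dropout)
        self.gru = GRU(rng, cfg.tcn_channels, cfg.gru_hidden)
        self.head = Dense(rng, cfg.gru_hidden, 1)

    def __call__(self, x: Tensor) -> Tensor:
        seq = self.gru(self.tcn(x))
        last = seq[:, -1, :]
        return self.head(last).sigmoid().reshape(x.shape[0])


class BitcnBigru(Module):
    def __init__(self, cfg: ModelConfig, in_channels: int, rng: np.random.Generator):
        self.bitcn = BiTCN(rng, in_channels, cfg.tcn_channels, cfg.tcn_kernel,
                           cfg.tcn_dilations, cfg.dropout,
                           shared_weights=cfg.shared_bitcn)
        self.bigru = BiGRU(rng, 2 * cfg.tcn_channels, cfg.gru_hidden)
        self.head = Dense(rng, 2 * cfg.gru_hidden, 1)

    def __call__(self, x: Tensor) -> Tensor:
        seq = self.bigru(self.bitcn(x))
        pooled = seq.mean(axis=1)
        return self.head(pooled).sigmoid().reshape(x.shape[0])


class BitcnBigruCrossAttention(Module):
    def __init__(self, cfg: ModelConfig, in_channels: int, rng: np.random.Generator):
        self.attn_query = cfg.attn_query
        self.bitcn = BiTCN(rng, in_channels, cfg.tcn_channels, cfg.tcn_kernel,
                           cfg.tcn_dilations, cfg.dropout,
                           shared_weights=cfg.shared_bitcn)
        self.bigru = BiGRU(rng, 2 * cfg.tcn_channels, cfg.gru_hidden)
        model_dim = 2 * cfg.gru_hidden
        if cfg.attn_query == "bigru":
            q_dim, kv_dim = 2 * cfg.gru_hidden, 2 * cfg.tcn_channels
        else:
            q_dim, kv_dim = 2 * cfg.tcn_channels, 2 * cfg.gru_hidden
        self.attn = MultiHeadCrossAttention(rng, q_dim, kv_dim, model_dim,
                                            cfg.attn_heads)
        self.head = Dense(rng, model_dim, 1)

    def __call__(self, x: Tensor) -> Tensor:
        feats = self.bitcn(x)
        seq = self.bigru(feats)
        if self.attn_query == "bigru":
            ctx = self.attn(seq, feats)
        else:
            ctx = self.attn(feats, seq)
        pooled = ctx.mean(axis=1)
        return self.head(pooled).sigmoid().reshape(x.shape[0])


_BUILDERS = {
    "tcn_gru": TcnGru,
    "bitcn_bigru": BitcnBigru,
    "bitcn_bigru_crossattn": BitcnBigruCrossAttention,
}


def build_network(cfg: ModelConfig, in_channels: int) -> Module:
    """Instantiate an untrained network with seed-deterministic weights."""
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    return _BUILDERS[cfg.architecture](cfg, in_channels, rng)
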