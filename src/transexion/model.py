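"""The similarity network: per-row encoders, two transformer towers, fusion.

Each tower consumes one aligned token grid (fragment or neutral loss). A row
encoder maps every row of the grid independently to a d-dimensional vector:
token embedding -> flatten -> a stack of head-split blocks (dropout + a
shared affine applied to each head + ReLU) -> a final affine. A standard
post-norm transformer encoder (no positional encoding: fragments are an
unordered set) then lets rows attend to each other, and the CLS row's output
is the tower embedding. The two tower embeddings are concatenated and a
small feed-forward head with a sigmoid produces the similarity score
y_sim in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .encoding import CLS_TOKEN, NOMINAL_CUTOFF, PAD_TOKEN, VOCAB_SIZE, PairEncoding
from .nn import Adam, Embedding, Linear, Module, Tensor, TransformerEncoder, concat

__all__ = [
    "ModelConfig",
    "RowEncoder",
    "Tower",
    "SimilarityModel",
    "init_model",
    "row_encode",
    "predict_similarity",
    "predict_batch",
    "pack_batch",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the similarity network.

    Defaults: 32-dim mass-defect embedding; two head-split blocks with 100
    and 20 heads and hidden width 128; a 2-layer transformer encoder with
    4 attention heads, feed-forward width 256 and model width 128; dropout
    0.1 throughout.
    """

    embed_dim: int = 32
    num_blocks: int = 2
    heads_per_block: Tuple[int, ...] = (100, 20)
    hidden_dim: int = 128
    row_dropout: float = 0.1
    tx_layers: int = 2
    tx_attn_heads: int = 4
    tx_ffn_dim: int = 256
    tx_dropout: float = 0.1
    n_columns: int = NOMINAL_CUTOFF
    vocab_size: int = VOCAB_SIZE
    seed: int = 0

    def validate(self) -> None:
        if len(self.heads_per_block) != self.num_blocks:
            raise ValueError("heads_per_block length must equal num_blocks")
        width = self.n_columns * self.embed_dim
        for i, k in enumerate(self.heads_per_block):
            if width % k:
                raise ValueError(
                    f"row width {width} not divisible by head count {k} "
                    f"(block {i + 1})"
                )
            width = k * self.hidden_dim


class RowEncoder(Module):
    """Maps each aligned-matrix row independently to a hidden_dim vector."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.embed = self.add_child(
            "embed", Embedding(cfg.vocab_size, cfg.embed_dim, rng)
        )
        width = cfg.n_columns * cfg.embed_dim
        self.blocks: List[Linear] = []
        for i, k in enumerate(cfg.heads_per_block):
            self.blocks.append(
                self.add_child(f"block{i}", Linear(width // k, cfg.hidden_dim, rng))
            )
            width = k * cfg.hidden_dim
        self.out = self.add_child("out", Linear(width, cfg.hidden_dim, rng))
        # kept after each forward: embedded tokens, for relevance distribution
        self.last_embedded: Optional[Tensor] = None

    def __call__(self, tokens: np.ndarray, rng: np.random.Generator) -> Tensor:
        B, R, C = tokens.shape
        cfg = self.cfg
        emb = self.embed(tokens)  # (B,R,C,E)
        self.last_embedded = emb
        x = emb.reshape(B * R, C * cfg.embed_dim)
        width = C * cfg.embed_dim
        for k, block in zip(cfg.heads_per_block, self.blocks):
            x = x.reshape(B * R * k, width // k)
            x = x.dropout(cfg.row_dropout, rng, self.training)
            x = block(x, relu=True)
            width = k * cfg.hidden_dim
            x = x.reshape(B * R, width)
        x = self.out(x)
        return x.reshape(B, R, cfg.hidden_dim)


class Tower(Module):
    """Row encoder + transformer encoder; output is the CLS row embedding."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.rows = self.add_child("rows", RowEncoder(cfg, rng))
        self.encoder = self.add_child(
            "encoder",
            TransformerEncoder(
                cfg.hidden_dim,
                cfg.tx_attn_heads,
                cfg.tx_ffn_dim,
                cfg.tx_layers,
                cfg.tx_dropout,
                rng,
            ),
        )
        self.last_cls: Optional[Tensor] = None

    def __call__(
        self, tokens: np.ndarray, mask: Optional[np.ndarray], rng: np.random.Generator
    ) -> Tensor:
        h = self.rows(tokens, rng)
        h = self.encoder(h, mask, rng)
        cls = h[:, 0, :]
        self.last_cls = cls
        return cls


class SimilarityModel(Module):
    """Two independent towers (fragments, neutral losses) + fusion head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.fragment_tower = self.add_child("fragment_tower", Tower(cfg, rng))
        self.loss_tower = self.add_child("loss_tower", Tower(cfg, rng))
        d = cfg.hidden_dim
        self.fuse1 = self.add_child("fuse1", Linear(2 * d, d, rng))
        self.fuse2 = self.add_child("fuse2", Linear(d, 1, rng))
        self.dropout_rng = np.random.default_rng(cfg.seed + 1)
        self.last_fused_input: Optional[Tensor] = None

    def forward(
        self,
        frag_tokens: np.ndarray,
        frag_mask: Optional[np.ndarray],
        loss_tokens: np.ndarray,
        loss_mask: Optional[np.ndarray],
    ) -> Tensor:
        rng = self.dropout_rng
        cf = self.fragment_tower(frag_tokens, frag_mask, rng)
        cl = self.loss_tower(loss_tokens, loss_mask, rng)
        z = concat([cf, cl], axis=-1)
        self.last_fused_input = z
        h = self.fuse1(z, relu=True).dropout(self.cfg.row_dropout, rng, self.training)
        y = self.fuse2(h).sigmoid()
        return y.reshape(y.shape[0])


def init_model(config: ModelConfig | None = None) -> SimilarityModel:
    """Build a model with deterministic initialization given ``config.seed``."""
    return SimilarityModel(config or ModelConfig())


def pack_batch(
    pairs: Sequence[PairEncoding],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad a list of pair encodings to common row counts, with row masks.

    Padded rows are all-PAD token rows; the boolean masks flag real rows so
    attention never routes information through padding.
    """
    B = len(pairs)
    C = pairs[0].fragment_matrix.tokens.shape[1]
    rf = max(p.fragment_matrix.tokens.shape[0] for p in pairs)
    rl = max(p.loss_matrix.tokens.shape[0] for p in pairs)
    frag = np.full((B, rf, C), PAD_TOKEN, dtype=np.int64)
    loss = np.full((B, rl, C), PAD_TOKEN, dtype=np.int64)
    fmask = np.zeros((B, rf), dtype=bool)
    lmask = np.zeros((B, rl), dtype=bool)
    for i, p in enumerate(pairs):
        tf, tl = p.fragment_matrix.tokens, p.loss_matrix.tokens
        frag[i, : tf.shape[0]] = tf
        loss[i, : tl.shape[0]] = tl
        fmask[i, : tf.shape[0]] = True
        lmask[i, : tl.shape[0]] = True
    return frag, fmask, loss, lmask


def row_encode(tower: Tower, aligned) -> np.ndarray:
    """Row embeddings ((n+1) x hidden_dim) of one aligned matrix, eval mode."""
    was_training = tower.training
    tower.eval()
    try:
        out = tower.rows(aligned.tokens[None, :, :], np.random.default_rng(0))
        return out.data[0]
    finally:
        if was_training:
            tower.train()


def predict_batch(model: SimilarityModel, pairs: Sequence[PairEncoding]) -> np.ndarray:
    """Scores for a batch of pair encodings (eval mode, deterministic)."""
    was_training = model.training
    model.eval()
    try:
        y = model.forward(*pack_batch(pairs))
        return y.data.copy()
    finally:
        if was_training:
            model.train()


def predict_similarity(model: SimilarityModel, pair: PairEncoding) -> float:
    """Similarity score y_sim in [0, 1] for one encoded pair."""
    return float(predict_batch(model, [pair])[0])


def save_model(model: SimilarityModel, path: str | Path) -> None:
    """Single-file checkpoint: config JSON + parameter arrays."""
    params = {k: v.data for k, v in model.parameters().items()}
    cfg = asdict(model.cfg)
    cfg["heads_per_block"] = list(cfg["heads_per_block"])
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **params)


def load_model(path: str | Path) -> SimilarityModel:
    with np.load(path) as npz:
        cfg_raw = json.loads(npz["__config__"].tobytes().decode())
        cfg_raw["heads_per_block"] = tuple(cfg_raw["heads_per_block"])
        cfg = ModelConfig(**cfg_raw)
        model = SimilarityModel(cfg)
        params = model.parameters()
        for k in params:
            if k not in npz:
                raise ValueError(f"checkpoint missing parameter {k!r}")
            if params[k].data.shape != npz[k].shape:
                raise ValueError(f"checkpoint shape mismatch for {k!r}")
            params[k].data = npz[k].astype(np.float32)
    return model
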