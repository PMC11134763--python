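"""Neural-network building blocks on top of the autodiff core.

Linear / Embedding / LayerNorm layers, multi-head self-attention with key
masking, and a post-norm transformer encoder layer (attention -> add&norm ->
feed-forward -> add&norm). Attention probability tensors are kept on the
encoder after each forward pass so that gradient-weighted attention
relevance can be read off after ``backward()``.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from .autograd import Tensor, affine, concat

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "TransformerEncoder",
]


class Module:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._children: Dict[str, "Module"] = {}
        self.training = True

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.parameters(prefix + name + "."))
        return out

    def train(self) -> None:
        self.training = True
        for c in self._children.values():
            c.train()

    def eval(self) -> None:
        self.training = False
        for c in self._children.values():
            c.eval()

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        # Glorot-uniform weights, zero bias
        lim = np.sqrt(6.0 / (d_in + d_out))
        self.W = self.register("W", rng.uniform(-lim, lim, size=(d_in, d_out)))
        self.b = self.register("b", np.zeros(d_out))

    def __call__(self, x: Tensor, relu: bool = False) -> Tensor:
        if len(x.shape) == 2:
            return affine(x, self.W, self.b, relu=relu)
        lead = x.shape[:-1]
        out = affine(
            x.reshape(int(np.prod(lead)), x.shape[-1]), self.W, self.b, relu=relu
        )
        return out.reshape(*lead, self.W.shape[-1])


class Embedding(Module):
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.table = self.register("table", rng.normal(0.0, 1.0, size=(vocab, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table.embedding(idx)


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(dim))
        self.beta = self.register("beta", np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over rows, with padded-key masking.

    After each call, ``last_attention`` holds the (B, H, R, R) attention
    probabilities tensor of that forward pass.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = self.add_child("wq", Linear(d_model, d_model, rng))
        self.wk = self.add_child("wk", Linear(d_model, d_model, rng))
        self.wv = self.add_child("wv", Linear(d_model, d_model, rng))
        self.wo = self.add_child("wo", Linear(d_model, d_model, rng))
        self.last_attention: Optional[Tensor] = None

    def __call__(self, x: Tensor, key_mask: Optional[np.ndarray]) -> Tensor:
        B, R, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, R, H, dh).transpose(0, 2, 1, 3)  # (B,H,R,dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        if key_mask is not None:
            bias = np.where(key_mask[:, None, None, :], 0.0, -1e9).astype(np.float32)
            logits = logits.add_bias_mask(bias)
        attn = logits.softmax(axis=-1)
        self.last_attention = attn
        ctx = attn @ v  # (B,H,R,dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, R, D)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer as in the original transformer."""

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        d_ffn: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.attn = self.add_child(
            "attn", MultiHeadSelfAttention(d_model, n_heads, rng)
        )
        self.norm1 = self.add_child("norm1", LayerNorm(d_model))
        self.ff1 = self.add_child("ff1", Linear(d_model, d_ffn, rng))
        self.ff2 = self.add_child("ff2", Linear(d_ffn, d_model, rng))
        self.norm2 = self.add_child("norm2", LayerNorm(d_model))
        self.p_drop = dropout

    def __call__(
        self, x: Tensor, key_mask: Optional[np.ndarray], rng: np.random.Generator
    ) -> Tensor:
        a = self.attn(x, key_mask).dropout(self.p_drop, rng, self.training)
        x = self.norm1(x + a)
        f = self.ff2(self.ff1(x, relu=True)).dropout(self.p_drop, rng, self.training)
        return self.norm2(x + f)


class TransformerEncoder(Module):
    def __init__(
        self,
        d_model: int,
        n_heads: int,
        d_ffn: int,
        n_layers: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.layers: List[TransformerEncoderLayer] = [
            self.add_child(
                f"layer{i}",
                TransformerEncoderLayer(d_model, n_heads, d_ffn, dropout, rng),
            )
            for i in range(n_layers)
        ]

    def __call__(
        self, x: Tensor, key_mask: Optional[np.ndarray], rng: np.random.Generator
    ) -> Tensor:
        for layer in self.layers:
            x = layer(x, key_mask, rng)
        return x

    @property
    def attention_maps(self) -> List[Tensor]:
        return [layer.attn.last_attention for layer in self.layers]
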