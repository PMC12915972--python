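"""Bidirectional multi-head cross-attention fusion of modality embeddings.

Each entity (a miRNA or a drug) carries two embeddings of the working
dimension d: a projected language-model vector (global semantics) and an
intrinsic encoder vector (local sequence motifs / molecular topology).
One cross-attention block attends from one modality (queries) to the
other (keys/values) with H heads of width d_k = d/H, concatenates head
outputs, projects them, and applies a residual connection with layer
normalization. Fusing both directions and summing the two block outputs
yields the final entity embedding:

    Z = LayerNorm(Z_a + MHAtten(Z_a, Z_b)) + LayerNorm(Z_b + MHAtten(Z_b, Z_a))

Entity embeddings here are single vectors, i.e. length-1 token
sequences, so each softmax runs over a singleton key axis; the block is
nevertheless implemented generically over token axes so matrix-valued
inputs work unchanged.

A note on the value projection: the source formulation reuses the key
projection for values; the standard reading with a distinct W_V is the
default, and ``share_kv=True`` reproduces the shared-projection variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, glorot_uniform, layer_norm


@dataclass
class AttentionParams:
    """Projection and normalization parameters for one attention block."""

    Wq: Tensor
    Wk: Tensor
    Wv: Tensor
    Wo: Tensor
    gamma: Tensor
    beta: Tensor
    n_heads: int
    share_kv: bool = False

    def __post_init__(self):
        d = self.Wq.shape[0]
        if d % self.n_heads != 0:
            raise ValueError(f"head count {self.n_heads} does not divide d={d}")

    @property
    def d(self) -> int:
        return self.Wq.shape[0]

    @property
    def d_k(self) -> int:
        return self.d // self.n_heads

    @classmethod
    def init(cls, d: int, n_heads: int, rng: np.random.Generator,
             share_kv: bool = False) -> "AttentionParams":
        if d % n_heads != 0:
            raise ValueError(f"head count {n_heads} does not divide d={d}")
        Wk = Tensor(glorot_uniform(rng, (d, d)), requires_grad=True)
        Wv = Wk if share_kv else Tensor(glorot_uniform(rng, (d, d)),
                                        requires_grad=True)
        return cls(
            Wq=Tensor(glorot_uniform(rng, (d, d)), requires_grad=True),
            Wk=Wk, Wv=Wv,
            Wo=Tensor(glorot_uniform(rng, (d, d)), requires_grad=True),
            gamma=Tensor(np.ones(d), requires_grad=True),
            beta=Tensor(np.zeros(d), requires_grad=True),
            n_heads=n_heads, share_kv=share_kv,
        )

    def named(self, prefix: str) -> dict[str, Tensor]:
        out = {f"{prefix}.Wq": self.Wq, f"{prefix}.Wk": self.Wk,
               f"{prefix}.Wo": self.Wo, f"{prefix}.gamma": self.gamma,
               f"{prefix}.beta": self.beta}
        if not self.share_kv:
            out[f"{prefix}.Wv"] = self.Wv
        return out


def _promote(x) -> tuple[Tensor, int]:
    """Lift input to a (batch, tokens, d) Tensor; remember original rank."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    rank = t.ndim
    if rank == 1:
        t = t.reshape(1, 1, t.shape[0])
    elif rank == 2:
        t = t.reshape(1, *t.shape)
    elif rank != 3:
        raise ValueError("expected rank 1, 2 or 3 input")
    return t, rank


def _split_heads(x: Tensor, H: int) -> Tensor:
    b, T, d = x.shape
    return x.reshape(b, T, H, d // H).swapaxes(1, 2)  # (b, H, T, d_k)


def _merge_heads(x: Tensor) -> Tensor:
    b, H, T, dk = x.shape
    return x.swapaxes(1, 2).reshape(b, T, H * dk)


def cross_attention_block(query_emb, kv_emb, params: AttentionParams,
                          return_weights: bool = False):
    """Attend from ``query_emb`` to ``kv_emb``; residual + LayerNorm output.

    Accepts vectors (d,), token matrices (T, d), or batched (n, T, d);
    the output matches the query's shape. Tensor inputs stay on the
    autodiff tape; ndarray inputs return ndarrays.
    """
    q_in, rank = _promote(query_emb)
    kv_in, _ = _promote(kv_emb)
    d = params.d
    if q_in.shape[-1] != d or kv_in.shape[-1] != d:
        raise ValueError(f"embedding width mismatch with attention d={d}")
    q = _split_heads(q_in @ params.Wq, params.n_heads)
    k = _split_heads(kv_in @ params.Wk, params.n_heads)
    v = _split_heads(kv_in @ (params.Wk if params.share_kv else params.Wv),
                     params.n_heads)
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(params.d_k))
    weights = scores.softmax(axis=-1)  # over the key axis
    attended = _merge_heads(weights @ v) @ params.Wo
    out = layer_norm(q_in + attended, params.gamma, params.beta)
    if rank == 1:
        out = out.reshape(d)
    elif rank == 2:
        out = out.reshape(out.shape[1], d)
    if not isinstance(query_emb, Tensor):
        out = out.data
        weights = weights.data
    if return_weights:
        return out, weights
    return out


def passthrough_norm(emb, params: AttentionParams):
    """Single-modality fallback used by ablation variants: LayerNorm only."""
    t = emb if isinstance(emb, Tensor) else Tensor(np.asarray(emb))
    out = layer_norm(t, params.gamma, params.beta)
    return out if isinstance(emb, Tensor) else out.data


def bidirectional_fuse(emb_a, emb_b, params_ab: AttentionParams,
                       params_ba: AttentionParams):
    """Sum of the two directed cross-attention outputs (the fused embedding)."""
    if params_ab.d != params_ba.d:
        raise ValueError("direction parameter dimensions differ")
    out_ab = cross_attention_block(emb_a, emb_b, params_ab)
    out_ba = cross_attention_block(emb_b, emb_a, params_ba)
    return out_ab + out_ba
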