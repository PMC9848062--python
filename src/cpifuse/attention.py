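"""Cross-attention fusion and the interaction head.

The two 1-D compound views are reshaped into short token sequences and fused
by cross-attention with queries from the fingerprint view and keys/values
from the graph view; a stack of self-attention blocks refines the fused
compound latents; a final cross-attention maps the latents onto the protein
positions (queries from the compound, keys/values from the protein) and the
pooled output feeds a small regression head.

Energies use the scaled dot product softmax(Q K^T / sqrt(C/d)) per head by
default; the alternative literal scaling Q K^T * (C/d) is available via
``energy_scale="linear"``.
"""

from __future__ import annotations

import numpy as np

from cpifuse.nn import Tensor, Module, Linear, MLP, LayerNorm


class CrossAttention(Module):
    """Multi-head (default single-head) cross-attention with output projection.

    ``f_Q``/``f_K``/``f_V`` are learned affine maps to the shared embedding
    dimension ``C``; ``f_0`` projects the attended values to ``out_dim``.
    """

    def __init__(self, d_q_in: int, d_kv_in: int, embed_dim: int,
                 rng: np.random.Generator, heads: int = 1,
                 out_dim: int | None = None, energy_scale: str = "sqrt",
                 norm_inputs: bool = False):
        if heads < 1:
            raise ValueError("need at least one head")
        if embed_dim % heads != 0:
            raise ValueError(
                f"embedding dim {embed_dim} not divisible by {heads} heads"
            )
        if energy_scale not in ("sqrt", "linear"):
            raise ValueError("energy_scale must be 'sqrt' or 'linear'")
        self.embed_dim = embed_dim
        self.heads = heads
        self.energy_scale = energy_scale
        self.f_Q = Linear(d_q_in, embed_dim, rng)
        self.f_K = Linear(d_kv_in, embed_dim, rng)
        self.f_V = Linear(d_kv_in, embed_dim, rng)
        self.f_0 = Linear(embed_dim, out_dim or embed_dim, rng)
        # optional pre-projection layer norm: keeps attention logits O(1)
        # during training so the softmax cannot saturate into a dead
        # (zero-gradient) one-hot regime
        self.norm_q = LayerNorm(d_q_in) if norm_inputs else None
        self.norm_kv = LayerNorm(d_kv_in) if norm_inputs else None

    def _split_heads(self, x: Tensor) -> Tensor:
        # (..., n, C) -> (..., h, n, C/h)
        *lead, n, C = x.shape
        h = self.heads
        x = x.reshape(*lead, n, h, C // h)
        return x.swapaxes(-2, -3)

    def _merge_heads(self, x: Tensor) -> Tensor:
        *lead, h, n, d = x.shape
        x = x.swapaxes(-2, -3)
        return x.reshape(*lead, n, h * d)

    def energies(self, q_tokens: Tensor, kv_tokens: Tensor,
                 kv_mask: np.ndarray | None = None) -> Tensor:
        """Softmax attention map, shape (..., heads, n_q, n_kv).

        ``kv_mask`` (..., n_kv) marks valid key positions; masked-out keys
        receive (numerically) zero energy.
        """
        if not (np.all(np.isfinite(q_tokens.data))
                and np.all(np.isfinite(kv_tokens.data))):
            raise FloatingPointError("non-finite attention inputs")
        if self.norm_q is not None:
            q_tokens = self.norm_q(q_tokens)
        Q = self._split_heads(self.f_Q(q_tokens))
        K = self._split_heads(self.f_K(self.norm_kv(kv_tokens)
                                       if self.norm_kv else kv_tokens))
        d_head = self.embed_dim / self.heads
        if self.energy_scale == "sqrt":
            scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_head))
        else:
            scores = (Q @ K.swapaxes(-1, -2)) * d_head
        if kv_mask is not None:
            bias = np.where(np.asarray(kv_mask, dtype=bool), 0.0, -1e9)
            scores = scores + bias[..., None, None, :]
        return scores.softmax(axis=-1)

    def forward(self, q_tokens, kv_tokens,
                kv_mask: np.ndarray | None = None) -> Tensor:
        q_tokens = Tensor.as_tensor(q_tokens)
        kv_tokens = Tensor.as_tensor(kv_tokens)
        energy = self.energies(q_tokens, kv_tokens, kv_mask)
        if self.norm_kv is not None:
            kv_tokens = self.norm_kv(kv_tokens)
        V = self._split_heads(self.f_V(kv_tokens))
        out = self._merge_heads(energy @ V)
        return self.f_0(out)


def _to_tokens(vec: Tensor, n_tokens: int) -> Tensor:
    """Reshape trailing feature axis of a (batch,) or (batch, D) tensor."""
    *lead, D = vec.shape
    if D % n_tokens != 0:
        raise ValueError(
            f"vector length {D} is not divisible by n_tokens={n_tokens}"
        )
    return vec.reshape(*lead, n_tokens, D // n_tokens)


class CompoundFusion(Module):
    """Fuse fingerprint and graph views: Q from O_Ms, K/V from O_Gs."""

    def __init__(self, d_ms: int, d_gs: int, n_tokens: int, embed_dim: int,
                 rng: np.random.Generator, heads: int = 1,
                 energy_scale: str = "sqrt", norm_inputs: bool = False):
        if n_tokens < 1:
            raise ValueError("n_tokens must be >= 1")
        if d_ms % n_tokens or d_gs % n_tokens:
            raise ValueError(
                f"view lengths ({d_ms}, {d_gs}) must be divisible by "
                f"n_tokens={n_tokens}"
            )
        self.n_tokens = n_tokens
        self.attn = CrossAttention(
            d_ms // n_tokens, d_gs // n_tokens, embed_dim, rng,
            heads=heads, energy_scale=energy_scale, norm_inputs=norm_inputs,
        )
        self.out_dim = n_tokens * embed_dim

    def forward(self, o_ms: Tensor, o_gs: Tensor) -> Tensor:
        """Returns the fused 1-D compound representation Comp_s."""
        q = _to_tokens(Tensor.as_tensor(o_ms), self.n_tokens)
        kv = _to_tokens(Tensor.as_tensor(o_gs), self.n_tokens)
        out = self.attn(q, kv)  # (..., n_tokens, C)
        *lead, n, C = out.shape
        return out.reshape(*lead, n * C)


class SelfAttentionBlock(Module):
    """Pre-activation self-attention + position-wise FFN, both residual."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator,
                 heads: int = 1, ff_expand: int = 2,
                 energy_scale: str = "sqrt", norm_inputs: bool = False):
        self.attn = CrossAttention(dim, dim, dim, rng, heads=heads,
                                   energy_scale=energy_scale,
                                   norm_inputs=norm_inputs)
        self.ff = MLP([dim, ff_expand * dim, dim], rng)
        self.norm_ff = LayerNorm(dim) if norm_inputs else None

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(x, x)
        h = self.norm_ff(x) if self.norm_ff is not None else x
        return x + self.ff(h)


class LatentStack(Module):
    """A series of self-attention blocks refining the compound latents.

    ``blocks = 0`` is the identity on the reshaped latent grid.
    """

    def __init__(self, n_tokens: int, dim: int, blocks: int,
                 rng: np.random.Generator, heads: int = 1,
                 ff_expand: int = 2, energy_scale: str = "sqrt",
                 norm_inputs: bool = False):
        if blocks < 0:
            raise ValueError("blocks must be >= 0")
        self.n_tokens = n_tokens
        self.dim = dim
        self.blocks = [
            SelfAttentionBlock(n_tokens, dim, rng, heads=heads,
                               ff_expand=ff_expand, energy_scale=energy_scale,
                               norm_inputs=norm_inputs)
            for _ in range(blocks)
        ]

    def forward(self, comp: Tensor) -> Tensor:
        """1-D Comp_s (batch, n_tokens*dim) -> latent grid (batch, n_tokens, dim)."""
        x = _to_tokens(Tensor.as_tensor(comp), self.n_tokens)
        for block in self.blocks:
            x = block(x)
        return x


class InteractionAttention(Module):
    """Final cross-attention: Q from compound latents, K/V from Prot_t."""

    def __init__(self, latent_dim: int, protein_channels: int, embed_dim: int,
                 rng: np.random.Generator, heads: int = 1,
                 energy_scale: str = "sqrt", norm_inputs: bool = False,
                 residual_query: bool = False, pool: str = "mean"):
        if residual_query and latent_dim != embed_dim:
            raise ValueError(
                "query residual needs latent_dim == embed_dim "
                f"({latent_dim} != {embed_dim})"
            )
        if pool not in ("mean", "flatten"):
            raise ValueError("pool must be 'mean' or 'flatten'")
        self.attn = CrossAttention(latent_dim, protein_channels, embed_dim,
                                   rng, heads=heads, energy_scale=energy_scale,
                                   norm_inputs=norm_inputs)
        self.residual_query = residual_query
        self.pool = pool

    def forward(self, latents: Tensor, prot: Tensor,
                prot_mask: np.ndarray | None = None) -> Tensor:
        """Mean-pool the attended queries into one interaction vector.

        ``prot_mask`` (batch, positions) restricts attention to non-pad
        protein positions.  With ``residual_query`` the compound latents are
        added back to the attended output (query-stream residual, as in the
        Perceiver block structure) before pooling.
        """
        out = self.attn(latents, prot, kv_mask=prot_mask)
        if self.residual_query:
            out = out + latents
        if self.pool == "flatten":
            *lead, n, c = out.shape
            return out.reshape(*lead, n * c)
        return out.mean(axis=-2)


class AffinityHead(Module):
    """Small MLP regression head producing the scalar affinity."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.mlp = MLP([dim, hidden, 1], rng)

    def forward(self, interaction: Tensor) -> Tensor:
        out = self.mlp(interaction)
        *lead, _ = out.shape
        return out.reshape(*lead) if lead else out.reshape(())
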