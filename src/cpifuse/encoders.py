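"""The three feature encoders.

* :class:`DMPNNEncoder` -- directed message passing over bonds.  Hidden states
  live on directed bonds; the message into bond v->w averages the projected
  atom features of v and of each neighbour k with the hidden state of bond
  k->v, excluding the reverse bond w->v so information never immediately
  backtracks.  Readout averages incoming-bond hiddens per atom and then
  averages atoms into the graph vector O_Gs.
* :class:`FingerprintEncoder` -- an MLP over the Morgan fingerprint, O_Ms.
* :class:`ProteinEncoder` -- token embedding, a stem convolution, then M
  residual blocks ``emb_out = LN(Conv1D(emb_in) + emb_in * lambda)`` followed
  by a gated linear unit, producing the position x channel matrix Prot_t.

All encoders operate on mini-batches; molecular graphs are batched by
concatenating atoms and bonds with per-graph segment ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cpifuse.featurize import ATOM_FDIM, BOND_FDIM, MolGraph, ProteinTokens, PAD_ID, VOCAB_SIZE
from cpifuse.nn import (
    Tensor,
    Module,
    Linear,
    MLP,
    Embedding,
    Conv1d,
    LayerNorm,
    glu,
    concat,
    gather,
    segment_sum,
)


@dataclass
class BatchMolGraph:
    """Several molecular graphs packed into one index space."""

    n_graphs: int
    n_atoms: int
    n_bonds: int
    atom_feats: np.ndarray
    bond_feats: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    rev: np.ndarray
    atom_graph: np.ndarray  # atom -> graph id
    in_degree: np.ndarray  # atom -> number of incoming directed bonds

    @staticmethod
    def from_graphs(graphs: list[MolGraph]) -> "BatchMolGraph":
        a_off = 0
        b_off = 0
        afeats, bfeats, src, dst, rev, agraph = [], [], [], [], [], []
        for gi, g in enumerate(graphs):
            afeats.append(g.atom_feats)
            bfeats.append(g.bond_feats)
            src.append(g.src + a_off)
            dst.append(g.dst + a_off)
            rev.append(g.rev + b_off)
            agraph.append(np.full(g.n_atoms, gi, dtype=np.intp))
            a_off += g.n_atoms
            b_off += g.n_directed_bonds
        src = np.concatenate(src) if src else np.zeros(0, dtype=np.intp)
        dst = np.concatenate(dst) if dst else np.zeros(0, dtype=np.intp)
        in_degree = np.bincount(dst, minlength=a_off).astype(np.float64)
        return BatchMolGraph(
            n_graphs=len(graphs),
            n_atoms=a_off,
            n_bonds=b_off,
            atom_feats=np.concatenate(afeats) if afeats else np.zeros((0, ATOM_FDIM)),
            bond_feats=np.concatenate(bfeats) if bfeats else np.zeros((0, BOND_FDIM)),
            src=src.astype(np.intp),
            dst=dst.astype(np.intp),
            rev=np.concatenate(rev).astype(np.intp) if rev else np.zeros(0, dtype=np.intp),
            atom_graph=np.concatenate(agraph) if agraph else np.zeros(0, dtype=np.intp),
            in_degree=in_degree,
        )


@dataclass
class MPNNState:
    """Per-directed-bond hidden vectors; ``h0`` stays fixed after init."""

    h: Tensor
    h0: Tensor
    atom_proj: Tensor  # projected atom features x~, cached per batch
    step: int
    n_bonds: int


class DMPNNEncoder(Module):
    """Directed message-passing encoder producing the graph view O_Gs."""

    def __init__(self, hidden: int, depth: int, rng: np.random.Generator,
                 atom_fdim: int = ATOM_FDIM, bond_fdim: int = BOND_FDIM):
        if depth < 1:
            raise ValueError("message-passing depth must be >= 1")
        self.hidden = hidden
        self.depth = depth
        self.W_in = Linear(atom_fdim + bond_fdim, hidden, rng)
        self.atom_proj = Linear(atom_fdim, hidden, rng)
        self.W_m = Linear(hidden, hidden, rng)

    # -- spec operations -----------------------------------------------------
    def init_hidden(self, batch: BatchMolGraph) -> MPNNState:
        """h0_{vw} = ReLU(W_in . concat(x_v, e_vw)); h = h0; step = 0."""
        x_src = Tensor(batch.atom_feats[batch.src])
        e = Tensor(batch.bond_feats)
        h0 = self.W_in(concat([x_src, e], axis=-1)).relu()
        xt = self.atom_proj(Tensor(batch.atom_feats))
        return MPNNState(h=h0, h0=h0, atom_proj=xt, step=0,
                         n_bonds=batch.n_bonds)

    def message_step(self, state: MPNNState, batch: BatchMolGraph) -> MPNNState:
        """One update of m_{vw} = sum_{k in N(v)\\w} mean(x~_v, x~_k, h_{kv}).

        Implemented as a segment sum of per-bond contributions into the
        destination atom minus the reverse bond's own contribution, which is
        exactly the backtracking exclusion.
        """
        if state.n_bonds != batch.n_bonds:
            raise ValueError("state does not match this graph batch")
        if batch.n_bonds == 0:
            return MPNNState(h=state.h, h0=state.h0, atom_proj=state.atom_proj,
                             step=state.step + 1, n_bonds=batch.n_bonds)
        xt = state.atom_proj
        # contribution of bond b = k->v into atom v
        contrib = (gather(xt, batch.dst) + gather(xt, batch.src) + state.h) * (1.0 / 3.0)
        s = segment_sum(contrib, batch.dst, batch.n_atoms)
        m = gather(s, batch.src) - gather(contrib, batch.rev)
        h_new = (state.h0 + self.W_m(m)).relu()
        return MPNNState(h=h_new, h0=state.h0, atom_proj=state.atom_proj,
                         step=state.step + 1, n_bonds=batch.n_bonds)

    def readout(self, state: MPNNState, batch: BatchMolGraph) -> Tensor:
        """Mean of incoming-bond hiddens per atom, then mean over atoms."""
        if batch.n_bonds > 0:
            atom_sum = segment_sum(state.h, batch.dst, batch.n_atoms)
            deg = np.maximum(batch.in_degree, 1.0)[:, None]
            atom_vec = atom_sum * Tensor(1.0 / deg)
        else:
            atom_vec = Tensor(np.zeros((batch.n_atoms, self.hidden)))
        graph_sum = segment_sum(atom_vec, batch.atom_graph, batch.n_graphs)
        counts = np.bincount(batch.atom_graph, minlength=batch.n_graphs)
        counts = np.maximum(counts, 1).astype(np.float64)[:, None]
        return graph_sum * Tensor(1.0 / counts)

    def forward(self, batch: BatchMolGraph) -> Tensor:
        state = self.init_hidden(batch)
        for _ in range(self.depth):
            state = self.message_step(state, batch)
        return self.readout(state, batch)


class FingerprintEncoder(Module):
    """MLP over the Morgan fingerprint bits, producing O_Ms."""

    def __init__(self, n_bits: int, sizes: list[int], rng: np.random.Generator):
        self.mlp = MLP([n_bits] + list(sizes), rng)
        self.n_bits = n_bits

    def forward(self, bits: np.ndarray | Tensor) -> Tensor:
        x = Tensor.as_tensor(bits)
        if x.shape[-1] != self.n_bits:
            raise ValueError(
                f"fingerprint length {x.shape[-1]} does not match encoder "
                f"input {self.n_bits}"
            )
        return self.mlp(x)


class ProteinEncoder(Module):
    """Residual gated-convolution encoder over tokenized sequences.

    Stem: embedding -> Conv1D to ``channels``.  Each of the ``blocks``
    residual blocks widens to 2*channels, adds the lambda-scaled input
    (duplicated along channels so every term appears once), layer-normalizes
    and gates back down to ``channels`` with a GLU.  With ``mask_pad`` the
    pad positions are zeroed after the stem and after every block so the
    non-pad rows of Prot_t are independent of pad-region token values.
    """

    def __init__(self, channels: int, kernel: int, blocks: int,
                 scale: float, emb_dim: int, rng: np.random.Generator,
                 vocab_size: int = VOCAB_SIZE, mask_pad: bool = True):
        if blocks < 1:
            raise ValueError("need at least one residual block")
        self.channels = channels
        self.scale = scale
        self.mask_pad = mask_pad
        self.embedding = Embedding(vocab_size, emb_dim, rng)
        self.stem = Conv1d(emb_dim, channels, kernel, rng)
        self.convs = [Conv1d(channels, 2 * channels, kernel, rng)
                      for _ in range(blocks)]
        self.norms = [LayerNorm(2 * channels) for _ in range(blocks)]

    def forward(self, ids: np.ndarray) -> Tensor:
        """ids: (batch, max_len) integer tokens -> (batch, max_len, channels)."""
        ids = np.asarray(ids, dtype=np.intp)
        if ids.ndim == 1:
            ids = ids[None, :]
        mask = (ids != PAD_ID).astype(np.float64)[:, :, None]
        emb = self.embedding(ids)
        x = self.stem(emb)
        if self.mask_pad:
            x = x * Tensor(mask)
        for conv, norm in zip(self.convs, self.norms):
            u = conv(x)
            r = concat([x, x], axis=-1) * self.scale
            x = glu(norm(u + r))
            if self.mask_pad:
                x = x * Tensor(mask)
        return x

    def encode(self, tokens: ProteinTokens) -> Tensor:
        """Single-sequence convenience wrapper: (max_len, channels)."""
        out = self.forward(tokens.ids[None, :])
        return out.reshape(out.shape[1], out.shape[2])
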