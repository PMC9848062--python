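"""The end-to-end affinity model.

``AffinityModel`` wires together the directed message-passing graph encoder,
the fingerprint MLP, the residual gated-convolution protein encoder, the
compound-view cross-attention fusion, the latent self-attention stack, the
final compound-to-protein cross-attention and the regression head.  A
:class:`ModelConfig` freezes every width/depth choice; checkpoints store the
weights together with the config that produced them, and loading a
checkpoint whose config disagrees with the model is an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from cpifuse.featurize import (
    ATOM_FDIM,
    BOND_FDIM,
    DEFAULT_MAX_LEN,
    MolGraph,
    smiles_to_molgraph,
    smiles_to_fingerprint,
    tokenize_protein,
)
from cpifuse.encoders import (
    BatchMolGraph,
    DMPNNEncoder,
    FingerprintEncoder,
    ProteinEncoder,
)
from cpifuse.attention import (
    CompoundFusion,
    LatentStack,
    InteractionAttention,
    AffinityHead,
)
from cpifuse.nn import Tensor, Module


@dataclass
class ModelConfig:
    """Architecture hyperparameters (tuning is out of scope; all overridable).

    ``n_tokens`` must divide both compound-view lengths (``mpnn_hidden`` and
    the last entry of ``fp_sizes``); the fused latent grid is
    ``n_tokens x embed_dim``.
    """

    fp_bits: int = 2048
    fp_radius: int = 2
    fp_sizes: tuple[int, ...] = (512, 300)
    mpnn_hidden: int = 300
    mpnn_depth: int = 3
    max_len: int = DEFAULT_MAX_LEN
    prot_channels: int = 128
    prot_kernel: int = 7
    prot_blocks: int = 3
    prot_scale: float = 0.5
    prot_emb_dim: int = 64
    mask_pad: bool = True
    n_tokens: int = 4
    embed_dim: int = 64
    heads: int = 1
    latent_blocks: int = 2
    ff_expand: int = 2
    head_hidden: int = 64
    energy_scale: str = "sqrt"
    attn_norm: bool = True
    interact_residual: bool = True
    interact_pool: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if self.mpnn_hidden % self.n_tokens:
            raise ValueError(
                f"n_tokens={self.n_tokens} must divide mpnn_hidden="
                f"{self.mpnn_hidden}"
            )
        if self.fp_sizes[-1] % self.n_tokens:
            raise ValueError(
                f"n_tokens={self.n_tokens} must divide the fingerprint "
                f"embedding size {self.fp_sizes[-1]}"
            )
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")


class AffinityModel(Module):
    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.mpnn = DMPNNEncoder(cfg.mpnn_hidden, cfg.mpnn_depth, rng)
        self.fp_enc = FingerprintEncoder(cfg.fp_bits, list(cfg.fp_sizes), rng)
        self.prot_enc = ProteinEncoder(
            cfg.prot_channels, cfg.prot_kernel, cfg.prot_blocks,
            cfg.prot_scale, cfg.prot_emb_dim, rng, mask_pad=cfg.mask_pad,
        )
        self.fusion = CompoundFusion(
            cfg.fp_sizes[-1], cfg.mpnn_hidden, cfg.n_tokens, cfg.embed_dim,
            rng, heads=cfg.heads, energy_scale=cfg.energy_scale,
            norm_inputs=cfg.attn_norm,
        )
        self.latents = LatentStack(
            cfg.n_tokens, cfg.embed_dim, cfg.latent_blocks, rng,
            heads=cfg.heads, ff_expand=cfg.ff_expand,
            energy_scale=cfg.energy_scale, norm_inputs=cfg.attn_norm,
        )
        self.interaction = InteractionAttention(
            cfg.embed_dim, cfg.prot_channels, cfg.embed_dim, rng,
            heads=cfg.heads, energy_scale=cfg.energy_scale,
            norm_inputs=cfg.attn_norm,
            residual_query=cfg.interact_residual,
            pool=cfg.interact_pool,
        )
        head_in = (cfg.embed_dim * cfg.n_tokens
                   if cfg.interact_pool == "flatten" else cfg.embed_dim)
        self.head = AffinityHead(head_in, cfg.head_hidden, rng)

    # -- featurization --------------------------------------------------------
    def featurize_batch(
        self, smiles: list[str], sequences: list[str]
    ) -> tuple[BatchMolGraph, np.ndarray, np.ndarray]:
        cfg = self.config
        graphs = [smiles_to_molgraph(s) for s in smiles]
        fps = np.stack([
            smiles_to_fingerprint(s, cfg.fp_radius, cfg.fp_bits).bits
            for s in smiles
        ])
        toks = np.stack([
            tokenize_protein(seq, cfg.max_len).ids for seq in sequences
        ])
        return BatchMolGraph.from_graphs(graphs), fps, toks

    # -- forward --------------------------------------------------------------
    def forward_features(
        self, batch: BatchMolGraph, fps: np.ndarray, tokens: np.ndarray
    ) -> Tensor:
        o_gs = self.mpnn(batch)
        o_ms = self.fp_enc(fps)
        prot = self.prot_enc(tokens)
        comp = self.fusion(o_ms, o_gs)
        lat = self.latents(comp)
        tokens = np.asarray(tokens)
        if tokens.ndim == 1:
            tokens = tokens[None, :]
        prot_mask = tokens != 0 if self.config.mask_pad else None
        inter = self.interaction(lat, prot, prot_mask=prot_mask)
        return self.head(inter)

    def forward(self, smiles: list[str], sequences: list[str]) -> Tensor:
        if len(smiles) != len(sequences):
            raise ValueError("need one protein sequence per compound")
        batch, fps, toks = self.featurize_batch(smiles, sequences)
        return self.forward_features(batch, fps, toks)

    def predict(self, smiles: list[str], sequences: list[str]) -> np.ndarray:
        """Affinity predictions without building the gradient graph."""
        return self.forward(smiles, sequences).numpy()

    # -- checkpointing --------------------------------------------------------
    def save_checkpoint(self, path: str) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @staticmethod
    def load_checkpoint(path: str) -> "AffinityModel":
        with np.load(path) as archive:
            cfg_raw = bytes(archive["__config__"].tobytes()).decode()
            cfg_dict = json.loads(cfg_raw)
            cfg_dict["fp_sizes"] = tuple(cfg_dict["fp_sizes"])
            config = ModelConfig(**cfg_dict)
            model = AffinityModel(config)
            state = {k: archive[k] for k in archive.files if k != "__config__"}
        model.load_state_dict(state)
        return model
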