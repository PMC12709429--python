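"""Graph-encoder / SMILES-decoder variational autoencoder.

The encoder is a stack of graph-attention layers with DenseNet-style
connections: the input of layer l is a linear projection of the
concatenation of the atom embeddings and all previous layer outputs, so
every layer keeps a direct path to the loss (counteracting
over-smoothing and vanishing gradients in deep message passing).  Each
layer applies two GAT sublayers and a position-wise feed-forward
sublayer, every sublayer wrapped in a residual connection followed by
layer normalization.  A global-add-pool readout sums the final node
vectors per molecule, and two linear heads map the pooled vector to the
mean and log-sigma of the diagonal Gaussian posterior q(z|x).

The decoder is a standard transformer decoder (sinusoidal positions,
causal self-attention, feed-forward) except that its cross-attention
attends to the latent vector z, presented as a memory sequence of
length one.  It emits SMILES tokens autoregressively.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, segment_sum
from .chem import MolecularGraph
from .nn import (
    Dropout,
    Embedding,
    FeedForward,
    GraphAttention,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    causal_mask,
    sinusoidal_positions,
)
from .tokenizer import Vocabulary

#: bond-type codes 0..3 plus a self-loop code so every node (including
#: isolated single-atom molecules) attends to itself
SELF_LOOP_CODE = 4
N_EDGE_TYPES = 5


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale settings: eight encoder and decoder
    blocks, hidden width 512, feed-forward width 1024, one GAT head in
    the encoder (2/4/8 configurable) and 16 decoder attention heads.
    The latent width defaults to the hidden width.
    """

    vocab_size: int
    n_atom_types: int
    n_layers: int = 8
    hidden_dim: int = 512
    ffn_dim: int = 1024
    encoder_gat_heads: int = 1
    decoder_heads: int = 16
    latent_dim: int | None = None
    max_len: int = 128
    dropout: float = 0.1

    def __post_init__(self):
        if self.latent_dim is None:
            self.latent_dim = self.hidden_dim
        if self.hidden_dim % self.decoder_heads:
            raise ValueError("hidden_dim must be divisible by decoder_heads")
        for name in ("n_layers", "hidden_dim", "ffn_dim", "encoder_gat_heads",
                     "decoder_heads", "latent_dim", "max_len", "vocab_size",
                     "n_atom_types"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LatentDistribution:
    """Diagonal-Gaussian posterior parameters, one row per molecule.

    ``sigma = exp(log_sigma)``; parameterizing log-sigma keeps the scale
    strictly positive without constraints.
    """

    mu: Tensor
    log_sigma: Tensor

    @property
    def sigma(self) -> Tensor:
        return self.log_sigma.exp()


class AtomVocabulary:
    """Bijection between atom symbols and embedding-row indices."""

    UNK = "<unk>"

    def __init__(self, symbols):
        self.symbols = sorted(set(symbols))
        self.index = {s: i for i, s in enumerate(self.symbols)}
        self.index[self.UNK] = len(self.symbols)

    def __len__(self):
        return len(self.symbols) + 1

    def encode(self, symbols) -> np.ndarray:
        unk = self.index[self.UNK]
        return np.array([self.index.get(s, unk) for s in symbols], dtype=np.int64)


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs: one block-diagonal graph with a
    molecule-id vector so global add pooling segments correctly."""

    node_ids: np.ndarray       # (n_total,) atom-type indices
    edge_src: np.ndarray       # (e_total,) with self-loops appended
    edge_dst: np.ndarray
    edge_type: np.ndarray
    mol_index: np.ndarray      # (n_total,) molecule id of each node
    n_mols: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph], atom_vocab: AtomVocabulary):
        if not graphs:
            raise ValueError("empty batch")
        node_ids, src, dst, typ, mol_index = [], [], [], [], []
        offset = 0
        for i, g in enumerate(graphs):
            if g.n_nodes == 0:
                raise ValueError(f"graph {i} has no nodes")
            node_ids.append(atom_vocab.encode(g.node_symbols))
            src.append(g.edge_index[0] + offset)
            dst.append(g.edge_index[1] + offset)
            typ.append(g.edge_types)
            # self-loops: every node attends to itself
            loops = np.arange(offset, offset + g.n_nodes)
            src.append(loops)
            dst.append(loops)
            typ.append(np.full(g.n_nodes, SELF_LOOP_CODE, dtype=np.int64))
            mol_index.append(np.full(g.n_nodes, i, dtype=np.int64))
            offset += g.n_nodes
        return cls(
            node_ids=np.concatenate(node_ids),
            edge_src=np.concatenate(src),
            edge_dst=np.concatenate(dst),
            edge_type=np.concatenate(typ),
            mol_index=np.concatenate(mol_index),
            n_mols=len(graphs),
        )


class EncoderLayer(Module):
    def __init__(self, rng, cfg: ModelConfig, layer_idx: int):
        super().__init__()
        d = cfg.hidden_dim
        # dense connection: project [embeddings, out_1, ..., out_{l-1}] -> d
        self.dense_proj = Linear(rng, (layer_idx + 1) * d, d)
        self.gat1 = GraphAttention(rng, d, cfg.encoder_gat_heads, N_EDGE_TYPES, cfg.dropout)
        self.gat2 = GraphAttention(rng, d, cfg.encoder_gat_heads, N_EDGE_TYPES, cfg.dropout)
        self.ffn = FeedForward(rng, d, cfg.ffn_dim, cfg.dropout)
        self.ln1, self.ln2, self.ln3 = LayerNorm(d), LayerNorm(d), LayerNorm(d)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, history: list[Tensor], batch: GraphBatch, rng=None) -> Tensor:
        x = self.dense_proj(history[0] if len(history) == 1 else concat(history, axis=1))
        x = self.ln1(x + self.drop(
            self.gat1(x, batch.edge_src, batch.edge_dst, batch.edge_type, rng), rng))
        x = self.ln2(x + self.drop(
            self.gat2(x, batch.edge_src, batch.edge_dst, batch.edge_type, rng), rng))
        x = self.ln3(x + self.drop(self.ffn(x, rng), rng))
        return x


class GraphEncoder(Module):
    def __init__(self, rng, cfg: ModelConfig, dense_connections: bool = True):
        super().__init__()
        self.cfg = cfg
        self.dense_connections = dense_connections
        self.atom_emb = Embedding(rng, cfg.n_atom_types, cfg.hidden_dim)
        self.layers = [
            EncoderLayer(rng, cfg, i if dense_connections else 0)
            for i in range(cfg.n_layers)
        ]
        # global-add-pool output scales with molecule size; start the latent
        # heads small so the posterior opens near N(0, 1) instead of with
        # astronomically large sigma
        self.mu_head = Linear(rng, cfg.hidden_dim, cfg.latent_dim)
        self.mu_head.weight.data *= 0.1
        self.sigma_head = Linear(rng, cfg.hidden_dim, cfg.latent_dim)
        self.sigma_head.weight.data *= 0.01

    def node_states(self, batch: GraphBatch, rng=None) -> Tensor:
        """Final per-node representations (pre-readout)."""
        history = [self.atom_emb(batch.node_ids)]
        for layer in self.layers:
            out = layer(history if self.dense_connections else [history[-1]], batch, rng)
            history.append(out)
        return history[-1]

    def __call__(self, batch: GraphBatch, rng=None) -> LatentDistribution:
        h = self.node_states(batch, rng)
        pooled = segment_sum(h, batch.mol_index, batch.n_mols)  # global add pool
        return LatentDistribution(mu=self.mu_head(pooled), log_sigma=self.sigma_head(pooled))


class DecoderLayer(Module):
    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        d = cfg.hidden_dim
        self.self_attn = MultiHeadAttention(rng, d, cfg.decoder_heads, cfg.dropout)
        self.cross_attn = MultiHeadAttention(rng, d, cfg.decoder_heads, cfg.dropout)
        self.ffn = FeedForward(rng, d, cfg.ffn_dim, cfg.dropout)
        self.ln1, self.ln2, self.ln3 = LayerNorm(d), LayerNorm(d), LayerNorm(d)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, memory: Tensor, mask: np.ndarray, rng=None) -> Tensor:
        x = self.ln1(x + self.drop(self.self_attn(x, x, mask, rng), rng))
        x = self.ln2(x + self.drop(self.cross_attn(x, memory, None, rng), rng))
        x = self.ln3(x + self.drop(self.ffn(x, rng), rng))
        return x


class SmilesDecoder(Module):
    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        d = cfg.hidden_dim
        self.token_emb = Embedding(rng, cfg.vocab_size, d)
        self.pos_table = sinusoidal_positions(cfg.max_len + 1, d)
        self.latent_proj = Linear(rng, cfg.latent_dim, d)
        self.layers = [DecoderLayer(rng, cfg) for _ in range(cfg.n_layers)]
        self.out_proj = Linear(rng, d, cfg.vocab_size)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, z: Tensor, tokens: np.ndarray, rng=None) -> Tensor:
        """Teacher-forced logits, (B, L, vocab); position t sees z and
        tokens < t only (causal mask)."""
        B, L = tokens.shape
        if L > self.cfg.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.cfg.max_len}")
        x = self.token_emb(tokens) * np.sqrt(self.cfg.hidden_dim)
        x = x + self.pos_table[:L]
        x = self.drop(x, rng)
        memory = self.latent_proj(z).reshape(z.shape[0], 1, -1)  # length-1 memory
        mask = causal_mask(L)
        for layer in self.layers:
            x = layer(x, memory, mask, rng)
        return self.out_proj(x)


class GraphSmilesNetwork(Module):
    """Full VAE: graph encoder, Gaussian latent, autoregressive decoder."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dense_connections: bool = True):
        super().__init__()
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.encoder = GraphEncoder(rng, cfg, dense_connections)
        self.decoder = SmilesDecoder(rng, cfg)

    # -- core operations -----------------------------------------------------
    def encode(self, batch: GraphBatch, rng=None) -> LatentDistribution:
        return self.encoder(batch, rng)

    @staticmethod
    def reparameterize(dist: LatentDistribution, eps: np.ndarray) -> Tensor:
        """z = mu + eps * sigma; gradients flow through mu and sigma only."""
        eps = np.asarray(eps, dtype=np.float64)
        if eps.shape != dist.mu.shape:
            raise ValueError(f"eps shape {eps.shape} != mu shape {dist.mu.shape}")
        return dist.mu + dist.sigma * eps

    def decode_teacher_forced(self, z: Tensor, tokens: np.ndarray, rng=None) -> Tensor:
        return self.decoder(z, tokens, rng)

    def prior_sample(self, n: int, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
        """n i.i.d. standard-normal latent vectors (the prior p(z))."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(seed)
        return rng.standard_normal((n, self.cfg.latent_dim))

    def generate(self, z, vocab: Vocabulary, mode: str = "greedy",
                 temperature: float = 1.0, seed: int | None = None,
                 max_len: int | None = None):
        """Decode SMILES strings autoregressively from latent vectors.

        Returns ``(smiles, truncated)``: strings exclude BOS/EOS/PAD;
        ``truncated[i]`` flags sequences that never emitted EOS within
        ``max_len`` steps.  Greedy mode takes the argmax at each step;
        sample mode draws from the temperature-scaled categorical with a
        seeded RNG, so fixed seeds reproduce exactly.
        """
        if mode not in ("greedy", "sample"):
            raise ValueError(f"unknown generation mode {mode!r}")
        was_training = self.training
        self.eval()
        try:
            zt = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float64))
            B = zt.shape[0]
            max_len = min(max_len or self.cfg.max_len, self.cfg.max_len)
            rng = np.random.default_rng(seed)
            tokens = np.full((B, 1), vocab.bos_id, dtype=np.int64)
            finished = np.zeros(B, dtype=bool)
            while tokens.shape[1] < max_len and not finished.all():
                logits = self.decoder(zt, tokens).data[:, -1, :]  # (B, V)
                if mode == "greedy":
                    nxt = logits.argmax(axis=1)
                else:
                    scaled = logits / max(temperature, 1e-8)
                    scaled -= scaled.max(axis=1, keepdims=True)
                    probs = np.exp(scaled)
                    probs /= probs.sum(axis=1, keepdims=True)
                    nxt = np.array([rng.choice(len(p), p=p) for p in probs])
                nxt = np.where(finished, vocab.pad_id, nxt)
                tokens = np.concatenate([tokens, nxt[:, None]], axis=1)
                finished |= nxt == vocab.eos_id
            smiles = [vocab.decode(row) for row in tokens]
            return smiles, ~finished
        finally:
            self.train(was_training)

    # -- persistence ---------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: p.data for name, p in self.named_parameters()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(arrays)
        if missing:
            raise ValueError(f"checkpoint missing parameters: {sorted(missing)[:5]} ...")
        for name, p in params.items():
            arr = np.asarray(arrays[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr
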