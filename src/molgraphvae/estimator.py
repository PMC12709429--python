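"""scikit-learn style estimator facade over the graph-to-SMILES VAE.

``MolGraphVAE`` follows the sklearn estimator contract — all
hyperparameters are constructor arguments mirrored by
``get_params``/``set_params``, fitted state lives in trailing-underscore
attributes, and ``fit``/``transform`` accept a sequence of SMILES
strings — so it composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .chem import smiles_to_graph
from .model import GraphBatch, ModelConfig
from .objective import BetaSchedule
from .training import (
    TrainConfig,
    TrainedModel,
    fit as _fit,
    generate_set,
    load_checkpoint,
    save_checkpoint,
    teacher_forced_accuracy,
)


class MolGraphVAE(TransformerMixin, BaseEstimator):
    """Variational autoencoder from molecular graphs to SMILES strings.

    The encoder is a densely connected stack of graph-attention layers
    with a global-add-pool readout and Gaussian latent heads; the
    decoder is a transformer that cross-attends to the latent vector and
    emits SMILES tokens autoregressively.  Trained with the
    beta-weighted ELBO ``beta * KL + NLL`` under a monotonic or cyclical
    beta schedule.

    Parameters
    ----------
    n_layers, hidden_dim, ffn_dim, encoder_gat_heads, decoder_heads :
        Architecture widths; defaults are the full-scale settings
        (8 blocks, 512 hidden, 1024 feed-forward, 1 GAT head, 16 decoder
        heads).
    latent_dim : int or None
        Width of z; None means equal to ``hidden_dim``.
    max_len : int
        Longest token sequence the decoder handles.
    dropout : float
        Dropout rate in every sublayer.
    learning_rate, weight_decay, epochs, batch_size :
        Adam settings; defaults 3e-4 / 1e-6 / 100 / 256.
    beta_mode, beta_low, beta_high, n_cycles :
        KL-weight schedule over the epoch horizon.
    grad_clip : float or None
        Optional global-norm gradient clip.
    seed : int
        Controls parameter init, shuffling, noise draws and sampling.

    Attributes
    ----------
    network_ : the trained network
    vocab_ : token vocabulary built from the training corpus
    atom_vocab_ : atom-symbol vocabulary
    model_config_ : resolved architecture configuration
    history_ : list of per-epoch loss records (epoch, beta, kl, recon, total)

    Examples
    --------
    >>> est = MolGraphVAE(n_layers=2, hidden_dim=64, ffn_dim=128,
    ...                   decoder_heads=4, latent_dim=32, epochs=20)
    >>> est.fit(["CCO", "CCN", "CCC"])           # doctest: +SKIP
    >>> est.sample(5, seed=1)                     # doctest: +SKIP
    """

    def __init__(
        self,
        n_layers: int = 8,
        hidden_dim: int = 512,
        ffn_dim: int = 1024,
        encoder_gat_heads: int = 1,
        decoder_heads: int = 16,
        latent_dim: int | None = None,
        max_len: int = 128,
        dropout: float = 0.1,
        learning_rate: float = 3e-4,
        weight_decay: float = 1e-6,
        epochs: int = 100,
        batch_size: int = 256,
        beta_mode: str = "monotonic",
        beta_low: float = 5e-5,
        beta_high: float = 1e-4,
        n_cycles: int = 1,
        grad_clip: float | None = None,
        seed: int = 0,
    ):
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.ffn_dim = ffn_dim
        self.encoder_gat_heads = encoder_gat_heads
        self.decoder_heads = decoder_heads
        self.latent_dim = latent_dim
        self.max_len = max_len
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.beta_mode = beta_mode
        self.beta_low = beta_low
        self.beta_high = beta_high
        self.n_cycles = n_cycles
        self.grad_clip = grad_clip
        self.seed = seed

    # -- config assembly -----------------------------------------------------
    def _train_config(self) -> TrainConfig:
        schedule = BetaSchedule(
            mode=self.beta_mode,
            beta_low=self.beta_low,
            beta_high=self.beta_high,
            n_cycles=self.n_cycles,
            total_steps=self.epochs,
        )
        return TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
            grad_clip=self.grad_clip,
            schedule=schedule,
        )

    def _model_config_dict(self) -> dict:
        return dict(
            n_layers=self.n_layers,
            hidden_dim=self.hidden_dim,
            ffn_dim=self.ffn_dim,
            encoder_gat_heads=self.encoder_gat_heads,
            decoder_heads=self.decoder_heads,
            latent_dim=self.latent_dim,
            max_len=self.max_len,
            dropout=self.dropout,
        )

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y=None, checkpoint_dir=None):
        """Train on a sequence of SMILES strings ``X``."""
        X = list(X)
        trained = _fit(
            X,
            model_config=self._model_config_dict(),
            train_config=self._train_config(),
            checkpoint_dir=checkpoint_dir,
        )
        self._adopt(trained)
        return self

    def _adopt(self, trained: TrainedModel) -> "MolGraphVAE":
        self.network_ = trained.network
        self.vocab_ = trained.vocab
        self.atom_vocab_ = trained.atom_vocab
        self.model_config_ = trained.model_config
        self.train_config_ = trained.train_config
        self.history_ = trained.history
        self.epochs_done_ = trained.epochs_done
        return self

    def _trained(self) -> TrainedModel:
        check_is_fitted(self, "network_")
        return TrainedModel(
            self.network_, self.vocab_, self.atom_vocab_, self.model_config_,
            self.train_config_, self.history_, self.epochs_done_,
        )

    def transform(self, X) -> np.ndarray:
        """Posterior means mu(x), shape (n_molecules, latent_dim)."""
        check_is_fitted(self, "network_")
        self.network_.eval()
        graphs = [smiles_to_graph(s) for s in X]
        batch = GraphBatch.from_graphs(graphs, self.atom_vocab_)
        return self.network_.encode(batch).mu.data.copy()

    def sample(self, n: int, seed: int | None = None, temperature: float = 1.0) -> list[str]:
        """Generate ``n`` SMILES strings from the prior (sample mode)."""
        check_is_fitted(self, "network_")
        return generate_set(self._trained(), n,
                            seed=self.seed if seed is None else seed,
                            temperature=temperature)

    def reconstruct(self, X) -> list[str]:
        """Greedy decode from the posterior mean of each input molecule."""
        check_is_fitted(self, "network_")
        self.network_.eval()
        mu = self.transform(X)
        smiles, _ = self.network_.generate(mu, self.vocab_, mode="greedy")
        return smiles

    def score(self, X, y=None) -> float:
        """Teacher-forced next-token accuracy on ``X`` (higher is better)."""
        return teacher_forced_accuracy(self._trained(), list(X))

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "network_")
        t = self._trained()
        save_checkpoint(path, t.network, t.vocab, t.atom_vocab, t.model_config,
                        t.train_config, t.epochs_done, t.history)

    @classmethod
    def load(cls, path) -> "MolGraphVAE":
        trained = load_checkpoint(path)
        mc, tc = trained.model_config, trained.train_config
        est = cls(
            n_layers=mc.n_layers, hidden_dim=mc.hidden_dim, ffn_dim=mc.ffn_dim,
            encoder_gat_heads=mc.encoder_gat_heads, decoder_heads=mc.decoder_heads,
            latent_dim=mc.latent_dim, max_len=mc.max_len, dropout=mc.dropout,
            learning_rate=tc.learning_rate, weight_decay=tc.weight_decay,
            epochs=tc.epochs, batch_size=tc.batch_size,
            beta_mode=tc.schedule.mode, beta_low=tc.schedule.beta_low,
            beta_high=tc.schedule.beta_high, n_cycles=tc.schedule.n_cycles,
            grad_clip=tc.grad_clip, seed=tc.seed,
        )
        return est._adopt(trained)
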