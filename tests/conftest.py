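import numpy as np
import pytest

from molgraphvae import (
    GraphBatch,
    ModelConfig,
    TrainConfig,
    build_vocabulary,
    fit,
    generate_fixture_corpus,
)
from molgraphvae.model import AtomVocabulary, GraphSmilesNetwork
from molgraphvae.objective import BetaSchedule
from molgraphvae.chem import mol_from_smiles


TINY_MODEL = dict(
    n_layers=2, hidden_dim=32, ffn_dim=64, encoder_gat_heads=1,
    decoder_heads=4, latent_dim=16, max_len=64, dropout=0.0,
)


@pytest.fixture(scope="session")
def strict_corpus():
    """100 drug-like molecules passing the corpus filter."""
    return generate_fixture_corpus(100, seed=23)


@pytest.fixture(scope="session")
def small_corpus():
    """16 small molecules (no filter) for fast model plumbing tests."""
    return generate_fixture_corpus(16, seed=5, strict=False)


def _vocabularies(corpus):
    vocab = build_vocabulary(corpus)
    symbols = set()
    for s in corpus:
        symbols.update(a.GetSymbol() for a in mol_from_smiles(s).GetAtoms())
    return vocab, AtomVocabulary(symbols)


@pytest.fixture(scope="session")
def tiny_setup(strict_corpus):
    """Randomly initialized tiny network + vocabularies over the strict corpus."""
    vocab, atom_vocab = _vocabularies(strict_corpus)
    cfg = ModelConfig(vocab_size=len(vocab), n_atom_types=len(atom_vocab), **TINY_MODEL)
    net = GraphSmilesNetwork(cfg, seed=0)
    net.eval()
    return net, cfg, vocab, atom_vocab


@pytest.fixture(scope="session")
def tiny_trained(small_corpus, tmp_path_factory):
    """A briefly trained tiny model with checkpoints on disk."""
    ckdir = tmp_path_factory.mktemp("ck")
    tc = TrainConfig(epochs=30, batch_size=16, seed=3,
                     schedule=BetaSchedule(total_steps=30), grad_clip=5.0)
    trained = fit(small_corpus, TINY_MODEL, tc, checkpoint_dir=ckdir)
    return trained, ckdir
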