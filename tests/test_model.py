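import numpy as np
import pytest

from molgraphvae import GraphBatch, LatentDistribution, ModelConfig
from molgraphvae.autodiff import Tensor
from molgraphvae.chem import MolecularGraph, smiles_to_graph
from molgraphvae.model import GraphSmilesNetwork


def permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    inv = np.argsort(perm)
    return MolecularGraph(
        node_symbols=[g.node_symbols[i] for i in perm],
        edge_index=inv[g.edge_index],
        edge_types=g.edge_types.copy(),
    )


class TestModelConfig:
    def test_latent_defaults_to_hidden(self):
        cfg = ModelConfig(vocab_size=10, n_atom_types=5, hidden_dim=64,
                          decoder_heads=4)
        assert cfg.latent_dim == 64

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=10, n_atom_types=5, hidden_dim=65, decoder_heads=4)

    def test_positive_dims_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=10, n_atom_types=5, n_layers=0)


class TestEncode:
    def test_single_atom_graph_finite(self, tiny_setup):
        net, cfg, vocab, av = tiny_setup
        dist = net.encode(GraphBatch.from_graphs([smiles_to_graph("C")], av))
        assert dist.mu.shape == (1, cfg.latent_dim)
        assert np.isfinite(dist.mu.data).all() and np.isfinite(dist.log_sigma.data).all()

    def test_permutation_invariance(self, tiny_setup, strict_corpus):
        net, _, _, av = tiny_setup
        rng = np.random.default_rng(0)
        for s in strict_corpus[:50]:
            g = smiles_to_graph(s)
            gp = permute_graph(g, rng.permutation(g.n_nodes))
            d0 = net.encode(GraphBatch.from_graphs([g], av))
            d1 = net.encode(GraphBatch.from_graphs([gp], av))
            scale = np.abs(d0.mu.data).max() + 1e-12
            assert np.abs(d0.mu.data - d1.mu.data).max() / scale < 1e-4
            assert np.abs(d0.log_sigma.data - d1.log_sigma.data).max() < 1e-4 * (
                np.abs(d0.log_sigma.data).max() + 1e-12)

    def test_batch_independence(self, tiny_setup, strict_corpus):
        net, _, _, av = tiny_setup
        g1, g2 = smiles_to_graph(strict_corpus[0]), smiles_to_graph(strict_corpus[1])
        both = net.encode(GraphBatch.from_graphs([g1, g2], av))
        solo1 = net.encode(GraphBatch.from_graphs([g1], av))
        solo2 = net.encode(GraphBatch.from_graphs([g2], av))
        stacked = np.vstack([solo1.mu.data, solo2.mu.data])
        assert np.allclose(both.mu.data, stacked, atol=1e-10)

    def test_empty_batch_rejected(self, tiny_setup):
        _, _, _, av = tiny_setup
        with pytest.raises(ValueError):
            GraphBatch.from_graphs([], av)

    def test_zero_node_graph_rejected(self, tiny_setup):
        _, _, _, av = tiny_setup
        empty = MolecularGraph([], np.zeros((2, 0), dtype=np.int64),
                               np.zeros(0, dtype=np.int64))
        with pytest.raises(ValueError):
            GraphBatch.from_graphs([empty], av)


class TestReparameterize:
    def test_zero_eps_returns_mu(self):
        mu = Tensor(np.array([[1.0, -2.0]]))
        dist = LatentDistribution(mu=mu, log_sigma=Tensor(np.zeros((1, 2))))
        z = GraphSmilesNetwork.reparameterize(dist, np.zeros((1, 2)))
        assert np.allclose(z.data, mu.data)

    def test_standard_posterior_returns_eps(self):
        dist = LatentDistribution(mu=Tensor(np.zeros((1, 3))),
                                  log_sigma=Tensor(np.zeros((1, 3))))
        eps = np.array([[0.3, -1.2, 2.0]])
        z = GraphSmilesNetwork.reparameterize(dist, eps)
        assert np.allclose(z.data, eps)

    def test_shape_mismatch_rejected(self):
        dist = LatentDistribution(mu=Tensor(np.zeros((1, 3))),
                                  log_sigma=Tensor(np.zeros((1, 3))))
        with pytest.raises(ValueError):
            GraphSmilesNetwork.reparameterize(dist, np.zeros((1, 4)))

    def test_monte_carlo_moments(self):
        mu_v, sig_v = np.array([0.5, -1.0]), np.array([2.0, 0.5])
        dist = LatentDistribution(mu=Tensor(mu_v[None, :]),
                                  log_sigma=Tensor(np.log(sig_v)[None, :]))
        rng = np.random.default_rng(1)
        n = 10_000
        zs = np.stack([
            GraphSmilesNetwork.reparameterize(dist, rng.standard_normal((1, 2))).data[0]
            for _ in range(n)
        ])
        se_mean = sig_v / np.sqrt(n)
        assert (np.abs(zs.mean(axis=0) - mu_v) < 3 * se_mean).all()
        se_sd = sig_v / np.sqrt(2 * (n - 1))
        assert (np.abs(zs.std(axis=0, ddof=1) - sig_v) < 3 * se_sd).all()

    def test_gradient_flows_through_mu_and_sigma(self):
        mu = Tensor(np.zeros((1, 2)), requires_grad=True)
        log_sigma = Tensor(np.zeros((1, 2)), requires_grad=True)
        dist = LatentDistribution(mu=mu, log_sigma=log_sigma)
        z = GraphSmilesNetwork.reparameterize(dist, np.ones((1, 2)))
        z.sum().backward()
        assert mu.grad is not None and log_sigma.grad is not None


class TestDecoder:
    def test_causality(self, tiny_setup, strict_corpus):
        net, cfg, vocab, av = tiny_setup
        seq = np.array([vocab.encode(strict_corpus[0])])
        z = Tensor(np.random.default_rng(0).standard_normal((1, cfg.latent_dim)))
        base = net.decode_teacher_forced(z, seq[:, :-1]).data
        L = seq.shape[1] - 1
        for t in [1, L // 2, L - 1]:
            mutated = seq.copy()
            mutated[0, t + 1] = (mutated[0, t + 1] + 1) % cfg.vocab_size
            out = net.decode_teacher_forced(z, mutated[:, :-1]).data
            assert np.allclose(out[0, : t + 1], base[0, : t + 1], atol=1e-12)
            if t + 1 < L:
                assert not np.allclose(out[0, t + 1 :], base[0, t + 1 :])

    def test_logits_shape_and_finite(self, tiny_setup, strict_corpus):
        net, cfg, vocab, av = tiny_setup
        from molgraphvae.tokenizer import pad_batch

        seqs = [vocab.encode(s) for s in strict_corpus[:4]]
        ids, _ = pad_batch(seqs, vocab.pad_id)
        z = Tensor(np.zeros((4, cfg.latent_dim)))
        logits = net.decode_teacher_forced(z, ids[:, :-1])
        assert logits.shape == (4, ids.shape[1] - 1, cfg.vocab_size)
        assert np.isfinite(logits.data).all()

    def test_eval_mode_deterministic(self, tiny_setup, strict_corpus):
        net, cfg, vocab, _ = tiny_setup
        seq = np.array([vocab.encode(strict_corpus[0])])[:, :-1]
        z = Tensor(np.ones((1, cfg.latent_dim)))
        a = net.decode_teacher_forced(z, seq).data
        b = net.decode_teacher_forced(z, seq).data
        assert np.array_equal(a, b)

    def test_too_long_rejected(self, tiny_setup):
        net, cfg, vocab, _ = tiny_setup
        with pytest.raises(ValueError):
            net.decode_teacher_forced(
                Tensor(np.zeros((1, cfg.latent_dim))),
                np.zeros((1, cfg.max_len + 1), dtype=np.int64),
            )


class TestGenerate:
    def test_greedy_repeatable(self, tiny_setup):
        net, cfg, vocab, _ = tiny_setup
        z = np.random.default_rng(2).standard_normal((4, cfg.latent_dim))
        a, _ = net.generate(z, vocab, mode="greedy")
        b, _ = net.generate(z, vocab, mode="greedy")
        assert a == b

    def test_sampling_seed_repeatable(self, tiny_setup):
        net, cfg, vocab, _ = tiny_setup
        z = np.random.default_rng(2).standard_normal((4, cfg.latent_dim))
        a, _ = net.generate(z, vocab, mode="sample", seed=9)
        b, _ = net.generate(z, vocab, mode="sample", seed=9)
        assert a == b

    def test_unknown_mode_rejected(self, tiny_setup):
        net, cfg, vocab, _ = tiny_setup
        with pytest.raises(ValueError):
            net.generate(np.zeros((1, cfg.latent_dim)), vocab, mode="beam")

    def test_truncation_flagged_at_max_len(self, tiny_setup):
        net, cfg, vocab, _ = tiny_setup
        z = np.random.default_rng(0).standard_normal((8, cfg.latent_dim)) * 5
        smiles, truncated = net.generate(z, vocab, mode="sample", seed=0, max_len=4)
        assert len(smiles) == 8
        # any sequence without EOS in 4 steps must carry the flag
        assert truncated.dtype == bool


class TestPriorSample:
    def test_seeded_repeatable(self, tiny_setup):
        net = tiny_setup[0]
        assert np.array_equal(net.prior_sample(3, seed=1), net.prior_sample(3, seed=1))

    def test_standard_normal_moments(self, tiny_setup):
        net, cfg, _, _ = tiny_setup
        z = net.prior_sample(10_000, seed=7)
        se = 1 / np.sqrt(10_000)
        assert (np.abs(z.mean(axis=0)) < 3 * se).all()
        var_se = np.sqrt(2 / (10_000 - 1))
        assert (np.abs(z.var(axis=0, ddof=1) - 1) < 3 * var_se).all()

    def test_n_validation(self, tiny_setup):
        with pytest.raises(ValueError):
            tiny_setup[0].prior_sample(0)


class TestArchitecture:
    def test_first_layer_receives_gradient(self, tiny_setup, strict_corpus):
        """Dense connections give layer 1 a direct path to the loss."""
        net, cfg, vocab, av = tiny_setup
        net.train(True)
        try:
            graphs = [smiles_to_graph(s) for s in strict_corpus[:4]]
            batch = GraphBatch.from_graphs(graphs, av)
            dist = net.encode(batch)
            (dist.mu.sum() + dist.log_sigma.sum()).backward()
            norms = [float(np.abs(p.grad).sum())
                     for _, p in net.encoder.layers[0].named_parameters()
                     if p.grad is not None]
            assert norms and sum(norms) > 0
        finally:
            net.zero_grad()
            net.eval()

    def test_oversmoothing_probe_dense_vs_ablated(self, strict_corpus, tiny_setup):
        """Mean pairwise cosine similarity of final node states, dense vs
        ablated dense connections, at initialization.  Reported for
        inspection; only sanity bounds are asserted."""
        _, cfg, vocab, av = tiny_setup
        graphs = [smiles_to_graph(s) for s in strict_corpus[:8]]
        batch = GraphBatch.from_graphs(graphs, av)

        def mean_cos(dense):
            net = GraphSmilesNetwork(cfg, seed=0, dense_connections=dense).eval()
            h = net.encoder.node_states(batch).data
            sims = []
            for m in range(batch.n_mols):
                x = h[batch.mol_index == m]
                x = x / np.linalg.norm(x, axis=1, keepdims=True)
                c = x @ x.T
                n = len(x)
                sims.append((c.sum() - n) / (n * (n - 1)))
            return float(np.mean(sims))

        dense, ablated = mean_cos(True), mean_cos(False)
        print(f"\nover-smoothing probe: dense={dense:.4f} ablated={ablated:.4f}")
        assert -1.0 <= dense <= 1.0 and -1.0 <= ablated <= 1.0
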