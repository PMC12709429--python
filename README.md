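# molgraphvae

A variational autoencoder for de-novo molecular design that **encodes
molecules as graphs and decodes them as SMILES strings**, together with
the benchmark metric suite used to judge generative models of drug-like
chemistry (validity, Unique@K, novelty, internal diversity, scaffold
similarity, property-distribution distances).

## The model

A molecule is represented by three matrices: a node vector *V* (one
atom-symbol token per heavy atom), a 2×e directed edge index (every bond
appears in both directions), and a length-e bond-type vector coded
single = 0, double = 1, triple = 2, aromatic = 3.

The **encoder** is a stack of N graph-attention (GAT) layers. Each block
applies two GAT sublayers and a position-wise feed-forward sublayer,
each wrapped in a residual connection and layer normalization. To fight
over-smoothing in deep message passing, the blocks are densely
connected: block ℓ receives a linear projection of the concatenation of
the atom embeddings and all previous block outputs, so every block has
a direct path to the loss. A global-add-pool readout sums the final
node states per molecule, and two linear heads produce μ_φ(x) and
log σ_φ(x) of the approximate posterior

  q_φ(z|x) = N(μ_φ(x), σ_φ(x)),  z = μ_φ(x) + ε·σ_φ(x), ε ~ N(0, I).

The **decoder** is a standard transformer decoder (causal
self-attention, sinusoidal positions) whose cross-attention attends to
the latent vector z, presented as a length-one memory; it emits SMILES
tokens autoregressively. Training minimizes the β-weighted ELBO

  L = β·D_KL(q_φ(z|x) ‖ N(0, I)) + NLL(x | z),

with β scheduled from 5·10⁻⁵ to 1·10⁻⁴ — either one monotonic linear
ramp over the training horizon or n equal cyclical ramps that reset at
each cycle boundary — to hold off posterior collapse.

Full-scale defaults: 8 encoder/decoder blocks, hidden width 512,
feed-forward width 1024, 1 GAT head, 16 decoder heads, Adam with
learning rate 3·10⁻⁴ and weight decay 10⁻⁶, 100 epochs.

The network, its automatic differentiation and the optimizer are
implemented in NumPy inside this package; chemistry (parsing,
canonicalization, fingerprints, scaffolds, descriptors) is RDKit.

## Worked example

A deliberately tiny desk-scale run — 64 synthetic drug-like molecules,
a 2-block model, one minute on a laptop CPU:

```python
from molgraphvae import MolGraphVAE, generate_fixture_corpus, evaluate

corpus = generate_fixture_corpus(64, seed=7)   # MW 250-350, neutral, organic subset
est = MolGraphVAE(n_layers=2, hidden_dim=64, ffn_dim=128, decoder_heads=4,
                  latent_dim=32, max_len=64, dropout=0.0, epochs=60,
                  batch_size=32, grad_clip=5.0, seed=0)
est.fit(corpus)
print("next-token accuracy:", round(est.score(corpus), 3))
gen = est.sample(200, seed=1)
report = evaluate(gen, train=corpus)
print("validity:", report.validity)
print("unique@10k:", report.unique_at_k)
print("novelty:", report.novelty)
```

prints

```
next-token accuracy: 0.608
validity: 0.035
unique@10k: 1.0
novelty: 1.0
```

After 60 epochs the decoder predicts 61 % of next tokens and only a few
prior samples are chemically valid — a model this size needs a few
hundred epochs to memorize its corpus (the integration tests drive one
to >0.95 accuracy), and orders of magnitude more data to generalize.
The valid samples it does produce are all distinct (`unique@10k 1.0`)
and none replicate the training set (`novelty 1.0`): exactly the
quantities the metric suite is built to separate.

The same pipeline is available from a shell:

```bash
molgraphvae fixtures -n 1000 --seed 0 --out corpus.smi
molgraphvae train corpus.smi --config config.yaml --seed 0 --out runs/a
molgraphvae generate runs/a/last.npz -n 30000 --seed 1 --out gen.smi
molgraphvae evaluate gen.smi --train corpus.smi --report report.json
```

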