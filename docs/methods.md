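# Methods

## Molecular representation

A molecule is a directed multigraph over its heavy atoms. Node features
are atom-symbol tokens only (C, N, O, S, F, Cl, Br and their aromatic
forms collapse to the bare symbol); hydrogens are implicit, matching
standard SMILES graph practice. Each chemical bond contributes two
directed edges with equal bond-type codes (single 0, double 1, triple 2,
aromatic 3). RDKit's default aromaticity perception decides code-3
bonds, and kekulized input is re-aromatized before conversion, so the
encoding is independent of input spelling. Stereochemistry is stripped:
stereo symbols multiply the token alphabet without adding information
the graph encoder sees.

Because the node feature is the bare symbol, the explicit hydrogen of
pyrrole-type aromatic nitrogens is not encoded. The graph→molecule
reconstruction used by the round-trip checks repairs this by assigning
one H to degree-2 aromatic nitrogens (smallest subset first) until the
ring system kekulizes; on the fixture chemistry this recovers every
molecule exactly.

Tokenization is regex based: bracket expressions, the two-letter
elements Cl/Br, `%nn` ring closures and every other SMILES symbol are
single tokens, so detokenization is exact concatenation. Four reserved
ids (pad = 0, begin, end, unknown) precede the corpus tokens, which are
id'd in sorted order — vocabularies are independent of corpus ordering.

## Architecture

Encoder blocks hold two edge-aware GAT sublayers and one position-wise
feed-forward sublayer, each wrapped residual + LayerNorm (post-norm).
GAT attention logits are additive:
`LeakyReLU(a_src·Wh_u + a_dst·Wh_v + a_edge·e_uv)` with a learned
embedding `e_uv` of the bond-type code, normalized over the in-edges of
each node; messages are `Wh_u + e_uv`. Self-loops with a fifth
bond-type code let every node (including single-atom molecules) attend
to itself. Multi-head variants (2/4/8) concatenate full-width head
outputs and project back to the hidden width.

Dense connections are DenseNet style: block ℓ's input is a linear
projection of `[embeddings, out_1, …, out_{ℓ-1}]`. The probe test
reports the mean pairwise cosine similarity of final node states with
and without these connections; the gradient smoke test asserts block 1
receives nonzero gradient through the direct path.

The latent width defaults to the hidden width; the μ and log σ heads are
linear maps from the pooled graph vector. Parameterizing log σ keeps the
scale positive without constraints. Because global add pooling sums
O(1)-normalized node states, its output scales with molecule size; the
latent heads are therefore initialized small (weights ×0.1 for μ, ×0.01
for log σ) so the posterior opens near N(0, I) instead of with
astronomically large σ — without this the KL term starts around 10³⁰.

The decoder presents z to cross-attention as a memory sequence of
length one (the simplest reading of "attend to the latent"); expanding
z into a multi-token memory is a possible variant not implemented.
Token embeddings are scaled by √d and given sinusoidal positions;
self-attention is causally masked.

## Objective

Closed-form diagonal-Gaussian KL, `Σ_d ½(μ_d² + σ_d² − 1 − ln σ_d²)`,
summed over latent dimensions and averaged over molecules.
Reconstruction NLL is summed over non-pad token positions and averaged
over molecules. The asymmetric reduction is deliberate: with
β ∈ [5·10⁻⁵, 10⁻⁴] a per-token-mean reconstruction would make the KL
term numerically irrelevant; sum-over-tokens keeps the printed β range
meaningful. One ε draw per molecule per forward pass (single-sample
ELBO).

β advances per epoch by default (per-step by config). The monotonic
schedule interpolates linearly from β_low at step 0 to β_high at the
final step, endpoints exact. The cyclical schedule splits the horizon
into n equal cycles, each a pure linear ramp β_low→β_high that resets
at the cycle boundary (the within-cycle shape is a design choice; a
ramp-then-hold variant would change nothing tested here). Both bounds
are shared between the two modes.

## Training

Adam (lr 3·10⁻⁴, weight decay 10⁻⁶ folded into the gradient), seeded
shuffling, disjoint-union graph batching with a molecule-id vector so
global add pooling segments correctly. One integer seed drives
parameter init, shuffles, ε draws, dropout and sampling; two runs with
the same config produce bitwise-identical loss logs. Optional
global-norm gradient clipping (off by default, 5.0 in the desk-scale
tests) protects the tiny-β regime, where early σ excursions otherwise
destabilize small models. Checkpoints (last and best-total-loss) store
weights, config, vocabulary, seed and history; resuming continues the β
schedule at the correct step. Learning rates well above 3·10⁻⁴
destabilized desk-scale runs (KL diverging, reconstruction plateauing),
so the full-scale default is kept everywhere.

## Synthetic corpora

The fixture generator assembles molecules from a grammar of ring
scaffolds (benzene, pyridine, pyrimidine, thiophene, furan, piperidine,
pyrrolidine, tetrahydropyran, naphthalene, indole, …), short linkers
(alkyl, ether, thioether, amine, amide, carbonyl) and substituents
(halogens, methyl/ethyl, methoxy, nitrile, …) over C/N/S/O/F/Cl/Br. In
strict mode (the default) every emitted molecule passes the drug-like
corpus filter — MW 250–350 g/mol, ≤7 rotatable bonds, logP ≤ 3.5,
largest ring ≤ 8 atoms, neutral atoms only — which forces two- or
three-ring assemblies, the size class of lead-like screening corpora.
Non-strict mode also emits single rings and short chains for cheap
plumbing tests. Output is canonicalized, deduplicated and fully
determined by the seed; requesting more molecules than the grammar can
enumerate raises a capacity error.

What the generator does *not* emulate: the scale (10⁶ molecules) and
long-tail structural variety of real screening corpora, fused-ring
systems beyond the few in the grammar, charged species and
stereochemistry. Passing tests therefore demonstrate mechanical and
statistical correctness of representation, objective and metrics, and
that the optimization can memorize a small corpus — not generation
quality at benchmark scale.

## Evaluation metrics

All set-membership metrics canonicalize first, so spelling variants of
one molecule cannot inflate uniqueness or novelty, and operate on the
valid subset of the generated pool. Unique@K takes the first K valid
molecules in generation order (all valid molecules if fewer than K).
Tanimoto similarity uses binary Morgan fingerprints, radius 2, 1024
bits (the common benchmark convention; the RDKit version is recorded
in every report). IntDiv_p normalizes by |G|², i.e. over all ordered
pairs including self-pairs, exactly as the 1/|G|² double sum reads; the
off-diagonal-only convention used by some reference implementations is
one flag away. Scaffold similarity is the cosine of Bemis-Murcko
scaffold frequency vectors over the union scaffold set; acyclic
molecules map to the empty scaffold, which is excluded from the union
by default (the metric concerns ring systems and linkers) and an
all-zero vector scores 0, logged. Property distributions (MW, logP,
QED, synthetic accessibility) are compared by the 1-D Wasserstein
distance; QED, logP and SA delegate to RDKit's standard
implementations.

## Problem sizes used by the checks

The automated checks run the graph suite on 1,000 generated molecules,
the KL Monte-Carlo comparison with 20 random posteriors × 10⁵ draws,
model contracts on a 2-block/32-hidden network over 50 molecules, and
the integration run on 32 molecules with a 3-block/128-hidden model for
300 epochs — the smallest configuration that reliably memorizes its
corpus (≥95 % teacher-forced accuracy, ≥50 % exact greedy
reconstructions). Prior-sample validity after such a desk-scale overfit
is a weak sanity floor (≥1 valid molecule per 100 draws at the tested
conditions): a 32-molecule model maps almost none of the prior's mass,
so most prior samples decode to invalid strings, and the measured
fraction varies strongly with the seed. Benchmark-scale validity
requires training on corpora orders of magnitude larger.

## Known limitations

- No property- or scaffold-conditioned decoding, no beam search.
- No free-bits or other posterior-collapse remedies beyond β scheduling.
- Single device, no learning-rate warmup/decay, no early stopping
  beyond best-loss checkpointing.
- The NumPy implementation is exact but slow relative to GPU
  frameworks; full benchmark scale (10⁶ molecules, 100 epochs, 30,000
  generated) is out of desk reach, which is why the shipped checks are
  property-based.
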