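"""Deterministic synthetic SMILES corpora.

Stands in for a large public training corpus: molecules are assembled
from a small grammar of ring scaffolds, linkers and substituents over the
organic subset (C, N, S, O, F, Cl, Br), then canonicalized, deduplicated
and — in strict mode — admitted only if they pass the drug-like corpus
filter (MW 250-350 g/mol, <= 7 rotatable bonds, logP <= 3.5, rings <= 8
atoms, no charges).  The same seed always yields the same corpus.

The grammar produces two- or three-ring molecules joined by short
linkers, which is what the strict MW window demands; non-strict mode
also emits single-ring and acyclic molecules and is the cheap option for
tokenizer and model plumbing tests.
"""

from __future__ import annotations

import numpy as np

from .chem import CorpusFilterRule, canonicalize_smiles, corpus_filter, is_valid_smiles

# ring fragments; chain attaches at the first written atom (prefix) and
# after the closing atom (suffix); one optional branch slot "{}"
RINGS = [
    "c1ccc({})cc1",
    "c1ccc(cc1){}",
    "c1cc({})ccc1",
    "c1ccncc1",
    "c1ccc({})nc1",
    "c1cncc({})c1",
    "c1ccsc1",
    "c1ccoc1",
    "c1cc({})sc1",
    "C1CCN({})CC1",
    "C1CCCCC1",
    "C1CCOCC1",
    "C1CCNC1",
    "c1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1",
    "c1cnc2ccccc2c1",
    "C1CCC({})CC1",
    "c1ncc({})cn1",
]

LINKERS = ["C", "CC", "CCC", "O", "OC", "CO", "S", "N", "NC", "C(=O)", "C(=O)N", "NC(=O)", "CN", "COC", "C(C)"]

SUBSTITUENTS = ["F", "Cl", "Br", "C", "CC", "OC", "O", "N", "C#N", "C(C)C", "CF", "SC", "OCC", ""]


class FixtureCapacityError(RuntimeError):
    """Requested more distinct molecules than the grammar can enumerate."""


def _assemble(rng: np.random.Generator) -> str:
    def ring() -> str:
        template = RINGS[rng.integers(len(RINGS))]
        if "{}" in template:
            return template.format(SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))])
        return template

    n_rings = int(rng.integers(2, 4))  # 2 or 3 rings
    parts = [ring()]
    for _ in range(n_rings - 1):
        parts.append(LINKERS[rng.integers(len(LINKERS))])
        parts.append(ring())
    return "".join(parts)


def _assemble_small(rng: np.random.Generator) -> str:
    """Single-ring / acyclic molecules for the non-strict mode."""
    kind = rng.integers(3)
    if kind == 0:  # short chain
        atoms = ["C", "C", "N", "O", "S", "C", "C"]
        n = int(rng.integers(2, 7))
        return "".join(atoms[int(rng.integers(len(atoms)))] for _ in range(n))
    template = RINGS[rng.integers(len(RINGS))]
    sub = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
    return template.format(sub) if "{}" in template else template


def generate_fixture_corpus(
    n: int,
    seed: int,
    strict: bool = True,
    rule: CorpusFilterRule | None = None,
    max_attempts_per_molecule: int = 500,
) -> list[str]:
    """Return ``n`` distinct, valid, canonical SMILES from the seeded grammar.

    Parameters
    ----------
    n : int
        Corpus size; must be >= 1.
    seed : int
        RNG seed; identical seeds yield identical corpora.
    strict : bool
        If True (default) every emitted molecule passes
        :func:`~molgraphvae.chem.corpus_filter`; if False the grammar also
        emits small single-ring and acyclic molecules with no filter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rule = rule or CorpusFilterRule()
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    budget = max_attempts_per_molecule * n
    while len(out) < n:
        if attempts >= budget:
            raise FixtureCapacityError(
                f"could only enumerate {len(out)} distinct molecules in "
                f"{budget} attempts; requested n={n} exceeds grammar capacity"
            )
        attempts += 1
        raw = _assemble(rng) if strict else (
            _assemble(rng) if rng.random() < 0.4 else _assemble_small(rng)
        )
        if not is_valid_smiles(raw):
            continue
        can = canonicalize_smiles(raw)
        if can in seen:
            continue
        if strict and not corpus_filter(can, rule):
            continue
        seen.add(can)
        out.append(can)
    return out
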