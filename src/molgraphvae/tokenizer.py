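"""SMILES tokenization and vocabulary handling.

The tokenizer is regex based: bracket atoms ``[...]``, the two-letter
organic-subset elements Cl and Br, two-digit ring closures ``%nn`` and
every other SMILES symbol (atoms, bond orders, branches, ring digits)
are each a single token, so detokenization is exact concatenation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[A-Za-z]|\d|[=#\-\+\(\)/\\@\.~:\*\$])"
)

BOS, EOS, PAD, UNK = "<bos>", "<eos>", "<pad>", "<unk>"
RESERVED = (PAD, BOS, EOS, UNK)  # PAD fixed at id 0


def split_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into atomic tokens; lossless by construction."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"cannot tokenize SMILES: {smiles!r}")
    return tokens


@dataclass
class Vocabulary:
    """Total bijection between tokens and integer ids, with reserved ids
    for padding, begin/end-of-sequence and unknown tokens."""

    token_to_id: dict[str, int]

    def __post_init__(self):
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}
        if len(self.id_to_token) != len(self.token_to_id):
            raise ValueError("token->id map is not a bijection")
        for tok in RESERVED:
            if tok not in self.token_to_id:
                raise ValueError(f"reserved token {tok} missing")

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def encode(self, smiles: str) -> list[int]:
        """Token ids of ``smiles`` wrapped in BOS/EOS; unknown tokens map
        to the unknown id (logged, never fatal)."""
        ids = [self.bos_id]
        for tok in split_smiles(smiles):
            tid = self.token_to_id.get(tok)
            if tid is None:
                logger.warning("unknown token %r in %r", tok, smiles)
                tid = self.unk_id
            ids.append(tid)
        ids.append(self.eos_id)
        return ids

    def decode(self, ids) -> str:
        """Inverse of :meth:`encode`: drops BOS/PAD, stops at first EOS."""
        out = []
        for tid in ids:
            tid = int(tid)
            if tid == self.eos_id:
                break
            if tid in (self.bos_id, self.pad_id):
                continue
            out.append(self.id_to_token.get(tid, UNK))
        return "".join(out)

    def to_json(self) -> str:
        return json.dumps(self.token_to_id, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        return cls(json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_vocabulary(corpus) -> Vocabulary:
    """Vocabulary over every token occurring in ``corpus``.

    Non-reserved tokens are id'd in sorted order after the four reserved
    ids, so the mapping is independent of corpus ordering.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    tokens = set()
    for smiles in corpus:
        tokens.update(split_smiles(smiles))
    mapping = {tok: i for i, tok in enumerate(RESERVED)}
    for i, tok in enumerate(sorted(tokens - set(RESERVED))):
        mapping[tok] = len(RESERVED) + i
    return Vocabulary(mapping)


def tokenize_smiles(smiles: str, vocab: Vocabulary) -> list[int]:
    """BOS-prefixed, EOS-terminated token ids of ``smiles``."""
    return vocab.encode(smiles)


def pad_batch(sequences: list[list[int]], pad_id: int, max_len: int | None = None):
    """Right-pad to a rectangle; returns (ids array, pad mask array)."""
    import numpy as np

    L = max(len(s) for s in sequences)
    if max_len is not None:
        if L > max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {max_len}")
    ids = np.full((len(sequences), L), pad_id, dtype=np.int64)
    for i, s in enumerate(sequences):
        ids[i, : len(s)] = s
    return ids, ids != pad_id
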