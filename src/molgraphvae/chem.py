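"""SMILES parsing, canonicalization, corpus filtering and molecular graphs.

Molecules are represented for the encoder as a three-part graph encoding:
a node-symbol vector (one atom-symbol token per heavy atom), a 2 x e
directed edge-index matrix, and a length-e bond-type vector.  Every
chemical bond contributes two directed columns (u, v) and (v, u), so that
message passing runs in both directions.  Bond types are coded
single=0, double=1, triple=2, aromatic=3.  Hydrogens are implicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: bond-type code per RDKit bond type
BOND_CODES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
CODE_TO_BOND = {v: k for k, v in BOND_CODES.items()}


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed into a sane molecule."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize; raise :class:`InvalidMoleculeError` on failure."""
    if not isinstance(smiles, str) or not smiles:
        raise InvalidMoleculeError(str(smiles), "empty or non-string SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(smiles)
    return mol


def canonicalize_smiles(smiles: str, strip_stereo: bool = True) -> str:
    """Return the unique canonical SMILES of ``smiles``.

    Stereochemistry is stripped by default: stereo symbols only add
    variance the generator never models.  Idempotent.
    """
    mol = mol_from_smiles(smiles)
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def is_valid_smiles(smiles: str) -> bool:
    """True iff the string parses and sanitizes (valence, aromaticity)."""
    if not isinstance(smiles, str) or not smiles:
        return False
    return Chem.MolFromSmiles(smiles) is not None


@dataclass
class MolecularGraph:
    """Directed multigraph encoding of one molecule.

    Attributes
    ----------
    node_symbols : list of str
        Atom symbol of each heavy atom, in parse order (matrix ``V``).
    edge_index : ndarray, shape (2, e)
        Directed bonds; column k runs from atom ``edge_index[0, k]`` to
        ``edge_index[1, k]``.  Each bond appears in both directions.
    edge_types : ndarray, shape (e,)
        Bond-type code of each column (0 single, 1 double, 2 triple,
        3 aromatic); equal for a column and its reverse.
    """

    node_symbols: list[str]
    edge_index: np.ndarray
    edge_types: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_symbols)

    @property
    def n_edges(self) -> int:
        return int(self.edge_index.shape[1])

    def validate(self) -> None:
        """Assert the structural invariants; raise ValueError otherwise."""
        n = self.n_nodes
        if self.edge_index.shape[0] != 2:
            raise ValueError("edge_index must be 2 x e")
        if self.edge_index.size and (
            self.edge_index.min() < 0 or self.edge_index.max() >= n
        ):
            raise ValueError("edge_index entries out of [0, n_nodes)")
        if self.edge_types.shape != (self.n_edges,):
            raise ValueError("edge_types length must equal number of edges")
        if self.edge_types.size and not np.isin(self.edge_types, [0, 1, 2, 3]).all():
            raise ValueError("edge_types must be in {0,1,2,3}")
        # every directed column must have its reverse, with equal bond code
        seen = {}
        for k in range(self.n_edges):
            u, v, t = int(self.edge_index[0, k]), int(self.edge_index[1, k]), int(self.edge_types[k])
            seen[(u, v)] = t
        for (u, v), t in seen.items():
            if seen.get((v, u)) != t:
                raise ValueError(f"missing or mismatched reverse edge for ({u},{v})")


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Convert a SMILES string to its directed-graph encoding.

    Heavy atoms become nodes in RDKit parse order (0-based); each bond
    yields two directed columns with equal bond-type codes.  Kekulized
    input is re-aromatized by RDKit's default sanitization, so aromatic
    bonds always carry code 3 regardless of input spelling.
    """
    mol = mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    symbols = [atom.GetSymbol() for atom in mol.GetAtoms()]
    src, dst, types = [], [], []
    for bond in mol.GetBonds():
        code = BOND_CODES.get(bond.GetBondType())
        if code is None:
            raise InvalidMoleculeError(smiles, f"unsupported bond type {bond.GetBondType()}")
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [u, v]
        dst += [v, u]
        types += [code, code]
    return MolecularGraph(
        node_symbols=symbols,
        edge_index=np.array([src, dst], dtype=np.int64).reshape(2, -1),
        edge_types=np.array(types, dtype=np.int64),
    )


def graph_to_smiles(graph: MolecularGraph) -> str:
    """Rebuild a molecule from its graph encoding, returning canonical SMILES.

    Inverse of :func:`smiles_to_graph` up to canonicalization, used by the
    round-trip checks.  Aromaticity is reconstructed from code-3 bonds.
    """
    def build(nh_atoms=()):
        # a failed SanitizeMol mutates bonds in place, so every attempt
        # rebuilds the molecule from the graph
        rw = Chem.RWMol()
        for sym in graph.node_symbols:
            rw.AddAtom(Chem.Atom(sym))
        added = set()
        aromatic_atoms = set()
        for k in range(graph.n_edges):
            u, v = int(graph.edge_index[0, k]), int(graph.edge_index[1, k])
            if (v, u) in added or (u, v) in added:
                continue
            code = int(graph.edge_types[k])
            rw.AddBond(u, v, CODE_TO_BOND[code])
            if code == 3:
                aromatic_atoms.update((u, v))
            added.add((u, v))
        mol = rw.GetMol()
        for idx in aromatic_atoms:
            mol.GetAtomWithIdx(idx).SetIsAromatic(True)
        for idx in nh_atoms:
            mol.GetAtomWithIdx(idx).SetNumExplicitHs(1)
        return mol

    mol = build()
    try:
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Chem.KekulizeException:
        pass
    except Exception as exc:
        raise InvalidMoleculeError(Chem.MolToSmiles(mol, canonical=False), str(exc))
    # Node features carry only the atom symbol, so the explicit hydrogen of
    # pyrrole-type aromatic nitrogens is not encoded.  Repair by assigning
    # one H to degree-2 aromatic nitrogens until the ring system kekulizes.
    candidates = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "N" and a.GetIsAromatic() and a.GetDegree() == 2
    ]
    from itertools import combinations

    for size in range(1, len(candidates) + 1):
        for subset in combinations(candidates, size):
            trial = build(subset)
            try:
                Chem.SanitizeMol(trial)
                return Chem.MolToSmiles(trial)
            except Chem.KekulizeException:
                continue
    raise InvalidMoleculeError(
        Chem.MolToSmiles(build(), canonical=False), "cannot kekulize reconstructed molecule"
    )


# --------------------------------------------------------------------------
# corpus filter


@dataclass(frozen=True)
class CorpusFilterRule:
    """Dataset admission rule for drug-like training corpora.

    Defaults reproduce the ZINC Clean Leads style filter used by the MOSES
    benchmark: MW in [250, 350] g/mol, at most 7 rotatable bonds,
    logP <= 3.5, organic-subset elements only, largest ring <= 8 atoms,
    no formally charged atoms.
    """

    mw_min: float = 250.0
    mw_max: float = 350.0
    max_rotatable_bonds: int = 7
    max_logp: float = 3.5
    allowed_elements: frozenset[str] = frozenset({"C", "N", "S", "O", "F", "Cl", "Br", "H"})
    max_ring_size: int = 8
    allow_charged: bool = False

    def __post_init__(self):
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if min(self.max_rotatable_bonds, self.max_logp, self.max_ring_size) < 0:
            raise ValueError("thresholds must be positive")


def corpus_filter(smiles: str, rule: CorpusFilterRule | None = None) -> bool:
    """True iff the molecule satisfies every clause of ``rule``."""
    rule = rule or CorpusFilterRule()
    mol = mol_from_smiles(smiles)
    if not rule.mw_min <= Descriptors.MolWt(mol) <= rule.mw_max:
        return False
    if Descriptors.NumRotatableBonds(mol) > rule.max_rotatable_bonds:
        return False
    if Crippen.MolLogP(mol) > rule.max_logp:
        return False
    if any(a.GetSymbol() not in rule.allowed_elements for a in mol.GetAtoms()):
        return False
    rings = mol.GetRingInfo().AtomRings()
    if rings and max(len(r) for r in rings) > rule.max_ring_size:
        return False
    if not rule.allow_charged and any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        return False
    return True


# --------------------------------------------------------------------------
# corpus I/O: plain text (one SMILES per line) and MOSES-dialect CSV


def read_corpus(path, split: str | None = None) -> list[str]:
    """Read SMILES from plain text or CSV (``SMILES`` column, optional
    ``SPLIT`` column with train/test/test_scaffolds values)."""
    path = str(path)
    if path.endswith(".csv"):
        import pandas as pd

        df = pd.read_csv(path)
        if "SMILES" not in df.columns:
            raise ValueError(f"{path}: CSV corpus needs a SMILES column")
        if split is not None and "SPLIT" in df.columns:
            df = df[df["SPLIT"] == split]
        return df["SMILES"].astype(str).tolist()
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_corpus(smiles: list[str], path) -> None:
    path = str(path)
    if path.endswith(".csv"):
        import pandas as pd

        pd.DataFrame({"SMILES": smiles}).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(smiles) + ("\n" if smiles else ""))
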