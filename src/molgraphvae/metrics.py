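"""Generation-quality metrics in the MOSES benchmark style.

Validity, Unique@K, novelty, internal diversity (IntDiv1/IntDiv2),
Bemis-Murcko scaffold cosine similarity, and 1-D Wasserstein distances
between property distributions (MW, logP, QED, SA), plus a descriptor
profile (HBD, HBA, NH/OH groups, heavy atoms).  All set-membership
metrics operate on canonical SMILES of the *valid* subset of the
generated pool; Tanimoto similarity uses binary Morgan fingerprints of
radius 2 and 1024 bits.
"""

from __future__ import annotations

import logging
import math
import os
import sys
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.stats import wasserstein_distance

from .chem import InvalidMoleculeError, canonicalize_smiles, mol_from_smiles

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib synthetic-accessibility score)

logger = logging.getLogger(__name__)

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


@dataclass
class GeneratedSet:
    """A generated pool G: raw strings plus its valid canonical subset."""

    smiles: list[str]
    valid_subset: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.smiles:
            raise ValueError("empty generated set")
        if not self.valid_subset:
            self.valid_subset = []
            for s in self.smiles:
                mol = Chem.MolFromSmiles(s) if isinstance(s, str) and s else None
                if mol is not None:
                    Chem.RemoveStereochemistry(mol)
                    self.valid_subset.append(Chem.MolToSmiles(mol))


@dataclass
class ReferenceSet:
    """A reference corpus R (train, test or scaffold-test), canonicalized."""

    smiles: list[str]

    def __post_init__(self):
        if not self.smiles:
            raise ValueError("empty reference set")
        self.smiles = [canonicalize_smiles(s) for s in self.smiles]


def validity_fraction(G: GeneratedSet) -> float:
    """#(parseable, sanitizable strings) / #(generated)."""
    return len(G.valid_subset) / len(G.smiles)


def unique_at_k(G: GeneratedSet, K: int = 10_000) -> float:
    """Distinct canonical molecules among the first K valid ones, / K.

    If fewer than K molecules are valid, uniqueness is computed over all
    valid molecules instead.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not G.valid_subset:
        raise ValueError("no valid molecules to compute uniqueness on")
    pool = G.valid_subset[:K]
    return len(set(pool)) / len(pool)


def novelty(G: GeneratedSet, train: ReferenceSet) -> float:
    """Fraction of valid generated molecules absent from the training set."""
    if not G.valid_subset:
        raise ValueError("no valid molecules to compute novelty on")
    train_set = set(train.smiles)
    return sum(s not in train_set for s in G.valid_subset) / len(G.valid_subset)


def _fingerprint(mol_or_smiles):
    mol = (
        mol_from_smiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else mol_or_smiles
    )
    return _FP_GEN.GetFingerprint(mol)


def tanimoto(m1, m2) -> float:
    """Jaccard similarity of the two molecules' Morgan bit sets."""
    from rdkit import DataStructs

    return float(DataStructs.TanimotoSimilarity(_fingerprint(m1), _fingerprint(m2)))


def _fp_matrix(smiles_list) -> np.ndarray:
    mat = np.zeros((len(smiles_list), 1024), dtype=np.float64)
    for i, s in enumerate(smiles_list):
        fp = _fingerprint(s)
        mat[i, list(fp.GetOnBits())] = 1.0
    return mat


def pairwise_tanimoto(smiles_list) -> np.ndarray:
    """Dense |G| x |G| Tanimoto matrix (vectorized over bit vectors)."""
    A = _fp_matrix(smiles_list)
    inter = A @ A.T
    counts = A.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore"):
        T = np.where(union > 0, inter / np.maximum(union, 1e-12), 1.0)
    return T


def internal_diversity(G: GeneratedSet, p: int = 1, include_self_pairs: bool = True) -> float:
    """IntDiv_p(G) = 1 - (1/|G|^2) * sum over ordered pairs of T(m1,m2)^p.

    The normalization runs over all ordered pairs *including* self-pairs,
    exactly as the 1/|G|^2 double sum reads; ``include_self_pairs=False``
    switches to the off-diagonal-only convention used by some reference
    implementations.
    """
    if p not in (1, 2):
        raise ValueError("p must be 1 or 2")
    if not G.valid_subset:
        raise ValueError("no valid molecules to compute IntDiv on")
    T = pairwise_tanimoto(G.valid_subset) ** p
    n = T.shape[0]
    if include_self_pairs:
        return float(1.0 - T.sum() / n**2)
    if n == 1:
        return 0.0
    off = T.sum() - np.trace(T)
    return float(1.0 - off / (n * (n - 1)))


def murcko_scaffold(mol_or_smiles) -> str:
    """Canonical Bemis-Murcko scaffold SMILES; '' for acyclic molecules."""
    mol = (
        mol_from_smiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else mol_or_smiles
    )
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def scaffold_similarity(G: GeneratedSet, R: ReferenceSet,
                        include_empty: bool = False) -> float:
    """Cosine similarity of scaffold-frequency vectors of G and R.

    Frequencies are counted over the union of scaffolds in either set.
    The empty scaffold (acyclic molecules) is excluded by default since
    the metric concerns ring systems and linkers; two sets with disjoint
    scaffold sets score 0.  An all-zero vector also yields 0 (logged).
    """
    cg = Counter(murcko_scaffold(s) for s in G.valid_subset)
    cr = Counter(murcko_scaffold(s) for s in R.smiles)
    if not include_empty:
        cg.pop("", None)
        cr.pop("", None)
    union = set(cg) | set(cr)
    if not union:
        logger.warning("no ring-containing scaffolds in either set; similarity 0")
        return 0.0
    vg = np.array([cg.get(s, 0) for s in union], dtype=float)
    vr = np.array([cr.get(s, 0) for s in union], dtype=float)
    ng, nr = np.linalg.norm(vg), np.linalg.norm(vr)
    if ng == 0 or nr == 0:
        logger.warning("all-zero scaffold frequency vector; similarity 0")
        return 0.0
    return float(vg @ vr / (ng * nr))


_DESCRIPTORS = {
    "mw": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "qed": QED.qed,
    "sa": sascorer.calculateScore,
    "hbd": Lipinski.NumHDonors,
    "hba": Lipinski.NumHAcceptors,
    "nh_oh": Lipinski.NHOHCount,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
}


def property_profile(smiles_list) -> pd.DataFrame:
    """Per-molecule descriptor table.

    Columns: smiles, valid, mw (g/mol), logp, qed, sa, hbd, hba, nh_oh,
    heavy_atoms.  Invalid rows are flagged ``valid=False`` with NaN
    descriptors and excluded from any downstream summary.
    """
    rows = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s) if isinstance(s, str) and s else None
        if mol is None:
            rows.append({"smiles": s, "valid": False,
                         **{k: math.nan for k in _DESCRIPTORS}})
            continue
        rows.append({"smiles": s, "valid": True,
                     **{k: float(f(mol)) for k, f in _DESCRIPTORS.items()}})
    return pd.DataFrame(rows)


def wasserstein_1d(a, b) -> float:
    """First-order Wasserstein distance between two 1-D samples."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return float(wasserstein_distance(a, b))


@dataclass
class MetricsReport:
    """One bundle of every generation metric for a G set."""

    n_generated: int
    n_valid: int
    validity: float
    unique_at_k: float
    k: int
    novelty: float
    intdiv1: float
    intdiv2: float
    scaffold_similarity: dict
    property_wasserstein: dict
    descriptor_means: dict
    toolkit_version: str

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    def validate_ranges(self) -> None:
        for name in ("validity", "unique_at_k", "novelty", "intdiv1", "intdiv2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        for v in self.scaffold_similarity.values():
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError("scaffold similarity outside [0, 1]")


def evaluate(
    G,
    train,
    test=None,
    scaffold_test=None,
    K: int = 10_000,
    intdiv_subsample: int | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Assemble the full metric suite for a generated pool.

    ``G`` may be a list of strings or a :class:`GeneratedSet`; reference
    arguments likewise.  Scaffold similarity is reported against every
    reference set provided (the scaffold-test set is the benchmark's
    headline column); property Wasserstein distances are computed
    against ``test`` (falling back to ``train``).  ``intdiv_subsample``
    caps the size of the pairwise Tanimoto matrix with a seeded
    subsample.
    """
    if not isinstance(G, GeneratedSet):
        G = GeneratedSet(list(G))
    train = train if isinstance(train, ReferenceSet) else ReferenceSet(list(train))
    test = (
        None if test is None
        else test if isinstance(test, ReferenceSet) else ReferenceSet(list(test))
    )
    scaffold_test = (
        None if scaffold_test is None
        else scaffold_test if isinstance(scaffold_test, ReferenceSet)
        else ReferenceSet(list(scaffold_test))
    )

    div_G = G
    if intdiv_subsample is not None and len(G.valid_subset) > intdiv_subsample:
        rng = np.random.default_rng(seed)
        sub = [G.valid_subset[i] for i in
               rng.choice(len(G.valid_subset), intdiv_subsample, replace=False)]
        div_G = GeneratedSet(sub, valid_subset=sub)

    scaf = {"train": scaffold_similarity(G, train)}
    if test is not None:
        scaf["test"] = scaffold_similarity(G, test)
    if scaffold_test is not None:
        scaf["scaffold_test"] = scaffold_similarity(G, scaffold_test)

    prop_ref = test if test is not None else train
    gen_props = property_profile(G.valid_subset)
    ref_props = property_profile(prop_ref.smiles)
    wdist = {
        k: wasserstein_1d(gen_props[k], ref_props[k])
        for k in ("mw", "logp", "qed", "sa")
    }
    desc_means = {
        k: float(gen_props[k].mean())
        for k in ("hbd", "hba", "nh_oh", "heavy_atoms")
    }

    from rdkit import rdBase

    report = MetricsReport(
        n_generated=len(G.smiles),
        n_valid=len(G.valid_subset),
        validity=validity_fraction(G),
        unique_at_k=unique_at_k(G, K),
        k=K,
        novelty=novelty(G, train),
        intdiv1=internal_diversity(div_G, p=1),
        intdiv2=internal_diversity(div_G, p=2),
        scaffold_similarity=scaf,
        property_wasserstein=wdist,
        descriptor_means=desc_means,
        toolkit_version=rdBase.rdkitVersion,
    )
    report.validate_ranges()
    return report
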