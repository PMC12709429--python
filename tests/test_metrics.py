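import numpy as np
import pytest

from molgraphvae import (
    GeneratedSet,
    ReferenceSet,
    evaluate,
    internal_diversity,
    murcko_scaffold,
    novelty,
    property_profile,
    scaffold_similarity,
    tanimoto,
    unique_at_k,
    validity_fraction,
    wasserstein_1d,
)


class TestValidity:
    def test_all_valid(self):
        assert validity_fraction(GeneratedSet(["CCO", "C1CC1"])) == 1.0

    def test_half_valid(self):
        assert validity_fraction(GeneratedSet(["CCO", "C1CC"])) == 0.5

    def test_corpus_as_its_own_g(self, strict_corpus):
        assert validity_fraction(GeneratedSet(list(strict_corpus))) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            GeneratedSet([])


class TestUniqueAtK:
    def test_duplicates(self):
        assert unique_at_k(GeneratedSet(["CCO"] * 10), K=10) == pytest.approx(0.1)

    def test_fewer_valid_than_k_falls_back(self):
        g = GeneratedSet(["CCO", "CCN", "CCC", "CCF", "CCCl"])
        assert unique_at_k(g, K=10_000) == 1.0

    def test_distinct_set(self, strict_corpus):
        assert unique_at_k(GeneratedSet(list(strict_corpus)), K=10_000) == 1.0

    def test_spelling_invariance(self):
        # same molecule spelled two ways counts once
        assert unique_at_k(GeneratedSet(["CCO", "OCC"]), K=10) == 0.5

    def test_no_valid_rejected(self):
        with pytest.raises(ValueError):
            unique_at_k(GeneratedSet(["C1CC"]), K=10)


class TestNovelty:
    def test_identical_to_train_is_zero(self, strict_corpus):
        ref = ReferenceSet(list(strict_corpus))
        assert novelty(GeneratedSet(list(strict_corpus)), ref) == 0.0

    def test_disjoint_is_one(self):
        assert novelty(GeneratedSet(["CCO", "CCN"]), ReferenceSet(["CCC"])) == 1.0

    def test_half_overlap(self):
        g = GeneratedSet(["CCO", "CCN"])
        assert novelty(g, ReferenceSet(["CCO", "CCC"])) == 0.5

    def test_spelling_invariance(self):
        # raw spelling differs but it is the training molecule
        assert novelty(GeneratedSet(["OCC"]), ReferenceSet(["CCO"])) == 0.0


class TestTanimoto:
    def test_self_similarity_one(self):
        assert tanimoto("c1ccccc1O", "c1ccccc1O") == 1.0

    def test_disjoint_bits_zero(self):
        assert tanimoto("C", "N") == 0.0

    def test_symmetric(self, strict_corpus):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = rng.choice(strict_corpus, 2, replace=False)
            assert tanimoto(a, b) == pytest.approx(tanimoto(b, a), abs=1e-12)

    def test_range(self, strict_corpus):
        for a, b in zip(strict_corpus[:20], strict_corpus[20:40]):
            assert 0.0 <= tanimoto(a, b) <= 1.0


def intdiv_brute_force(smiles, p):
    """O(n^2) double-loop oracle over ordered pairs incl. self-pairs."""
    n = len(smiles)
    acc = 0.0
    for a in smiles:
        for b in smiles:
            acc += tanimoto(a, b) ** p
    return 1.0 - acc / n**2


class TestInternalDiversity:
    def test_duplicate_pair_is_zero(self):
        g = GeneratedSet(["CCO", "CCO"])
        assert internal_diversity(g, p=1) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_fingerprints_formula(self):
        # all off-diagonal T = 0 with self-pairs: IntDiv = 1 - 1/n
        g = GeneratedSet(["C", "N", "O"])
        assert internal_diversity(g, p=1) == pytest.approx(1 - 1 / 3)
        assert internal_diversity(g, p=2) == pytest.approx(1 - 1 / 3)

    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_brute_force_oracle(self, strict_corpus, p):
        sub = list(strict_corpus[:20])
        g = GeneratedSet(sub)
        assert internal_diversity(g, p=p) == pytest.approx(
            intdiv_brute_force(sub, p), abs=1e-10)

    def test_self_pair_flag(self):
        g = GeneratedSet(["C", "N"])
        assert internal_diversity(g, p=1, include_self_pairs=False) == 1.0
        assert internal_diversity(g, p=1) == pytest.approx(0.5)

    def test_range(self, strict_corpus):
        g = GeneratedSet(list(strict_corpus[:30]))
        for p in (1, 2):
            assert 0.0 <= internal_diversity(g, p=p) <= 1.0

    def test_bad_p_rejected(self):
        with pytest.raises(ValueError):
            internal_diversity(GeneratedSet(["C"]), p=3)


class TestMurckoScaffold:
    def test_benzene_is_own_scaffold(self):
        assert murcko_scaffold("c1ccccc1") == "c1ccccc1"

    def test_toluene_side_chain_removed(self):
        assert murcko_scaffold("Cc1ccccc1") == "c1ccccc1"

    def test_acyclic_empty(self):
        assert murcko_scaffold("CCO") == ""

    def test_linker_retained(self):
        s = murcko_scaffold("Cc1ccc(CC2CCCCC2C)cc1")
        assert s == murcko_scaffold("c1ccc(CC2CCCCC2)cc1")


class TestScaffoldSimilarity:
    def test_identical_sets_one(self, strict_corpus):
        g = GeneratedSet(list(strict_corpus[:20]))
        r = ReferenceSet(list(strict_corpus[:20]))
        assert scaffold_similarity(g, r) == pytest.approx(1.0)

    def test_disjoint_scaffolds_zero(self):
        g = GeneratedSet(["Cc1ccccc1", "CCc1ccccc1"])     # benzene scaffold
        r = ReferenceSet(["CC1CCCCC1", "CCC1CCCCC1"])     # cyclohexane scaffold
        assert scaffold_similarity(g, r) == 0.0

    def test_hand_computed_cosine(self):
        # counts (2,1) vs (1,1) over {benzene, cyclohexane}:
        # cos = (2*1 + 1*1) / (sqrt(5) * sqrt(2)) = 3/sqrt(10)
        g = GeneratedSet(["Cc1ccccc1", "CCc1ccccc1", "CC1CCCCC1"])
        r = ReferenceSet(["c1ccccc1", "C1CCCCC1"])
        assert scaffold_similarity(g, r) == pytest.approx(3 / np.sqrt(10), abs=1e-6)

    def test_symmetric(self, strict_corpus):
        a = list(strict_corpus[:15])
        b = list(strict_corpus[15:30])
        ab = scaffold_similarity(GeneratedSet(a), ReferenceSet(b))
        ba = scaffold_similarity(GeneratedSet(b), ReferenceSet(a))
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_acyclic_only_sets_zero(self):
        g = GeneratedSet(["CCO", "CCC"])
        r = ReferenceSet(["CCN"])
        assert scaffold_similarity(g, r) == 0.0


class TestPropertyProfile:
    def test_ethanol_descriptors(self):
        row = property_profile(["CCO"]).iloc[0]
        assert row["mw"] == pytest.approx(46.07, abs=0.01)
        assert row["hbd"] == 1 and row["hba"] >= 1
        assert row["heavy_atoms"] == 3

    def test_invalid_row_flagged(self):
        df = property_profile(["CCO", "C1CC"])
        assert df["valid"].tolist() == [True, False]
        assert np.isnan(df.loc[1, "mw"])

    def test_all_columns_present(self, strict_corpus):
        df = property_profile(list(strict_corpus[:5]))
        for col in ("mw", "logp", "qed", "sa", "hbd", "hba", "nh_oh", "heavy_atoms"):
            assert df[col].notna().all()


class TestWasserstein:
    def test_identity_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert wasserstein_1d(a, a) == 0.0

    def test_dirac_pair_distance(self):
        assert wasserstein_1d([0.0], [2.5]) == pytest.approx(2.5)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(50), rng.standard_normal(80) + 1
        assert wasserstein_1d(a, b) == pytest.approx(wasserstein_1d(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])


class TestEvaluate:
    def test_self_evaluation_identities(self, strict_corpus):
        sub = list(strict_corpus[:30])
        report = evaluate(sub, train=sub, test=sub)
        assert report.validity == 1.0
        assert report.novelty == 0.0
        assert report.unique_at_k == 1.0
        assert report.scaffold_similarity["train"] == pytest.approx(1.0)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in report.property_wasserstein.values())

    def test_report_ranges_and_determinism(self, strict_corpus):
        g = list(strict_corpus[:20])
        ref = list(strict_corpus[20:60])
        r1 = evaluate(g, train=ref)
        r2 = evaluate(g, train=ref)
        r1.validate_ranges()
        assert r1.to_dict() == r2.to_dict()

    def test_subsampled_intdiv(self, strict_corpus):
        g = list(strict_corpus[:30])
        r = evaluate(g, train=g, intdiv_subsample=10, seed=1)
        assert 0.0 <= r.intdiv1 <= 1.0
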