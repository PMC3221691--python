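"""Property filtering, decoys, screening, ROC enrichment, Tanimoto."""

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from sklearn.metrics import roc_auc_score

from pharmscreen.screening import (
    BitFingerprint,
    ReferenceStats,
    UndefinedROCError,
    build_decoy_set,
    property_filter,
    roc_enrichment,
    screen,
    similarity_matrix,
    tanimoto,
)
from pharmscreen.synthdata import gen_decoys

from conftest import mol_3d, mol_from_smiles


class TestPropertyFilter:
    def test_window_and_charge_rule(self, small_actives):
        stats = ReferenceStats.from_molecules(small_actives)
        kept = property_filter(small_actives, stats, k_sd=4.0, charge_rule=True)
        assert kept == small_actives  # the reference set sits inside its own window

    def test_negative_charge_rejected(self, small_actives):
        stats = ReferenceStats.from_molecules(small_actives)
        anion = mol_from_smiles("CC(=O)[O-]", "anion")
        assert property_filter([anion], stats, charge_rule=True) == []

    def test_out_of_window_rejected(self, small_actives):
        stats = ReferenceStats.from_molecules(small_actives)
        big = mol_from_smiles("C" * 60, "molwt_outlier")  # mw far beyond mean+4SD
        assert property_filter([big], stats, charge_rule=False) == []

    def test_idempotent_and_subset(self, small_actives):
        stats = ReferenceStats.from_molecules(small_actives)
        once = property_filter(small_actives, stats)
        twice = property_filter(once, stats)
        assert twice == once
        assert set(m.id for m in once) <= set(m.id for m in small_actives)


class TestDecoySet:
    def test_seeded_sampling_deterministic(self, small_actives, ref_model):
        stats = ReferenceStats.from_molecules(small_actives)
        pool = gen_decoys(stats, n=30, seed=9, model=ref_model)
        a = build_decoy_set(small_actives, pool, n=10, seed=4)
        b = build_decoy_set(small_actives, pool, n=10, seed=4)
        assert [m.id for m in a] == [m.id for m in b]
        assert len(a) == 10

    def test_n_zero_empty(self, small_actives):
        assert build_decoy_set(small_actives, [], n=0, seed=1) == []

    def test_pool_too_small(self, small_actives, ref_model):
        stats = ReferenceStats.from_molecules(small_actives)
        pool = gen_decoys(stats, n=3, seed=9, model=ref_model)
        with pytest.raises(ValueError):
            build_decoy_set(small_actives, pool, n=10, seed=1)

    def test_all_decoys_inside_window(self, small_actives, ref_model):
        stats = ReferenceStats.from_molecules(small_actives)
        pool = gen_decoys(stats, n=20, seed=9, model=ref_model)
        chosen = build_decoy_set(small_actives, pool, n=15, seed=2)
        from pharmscreen.chemstruct import compute_properties

        assert all(stats.contains(compute_properties(m), 4.0) for m in chosen)


class TestScreen:
    def test_references_score_near_k(self, ref_model, small_actives):
        hits = screen(ref_model, small_actives)
        assert len(hits) == len(small_actives)
        assert all(fit > 3.5 for _, fit in hits)

    def test_featureless_library_empty(self, ref_model):
        alkanes = [mol_3d(s, f"alk{i}") for i, s in enumerate(["CCCCC", "CCCCCC"])]
        assert screen(ref_model, alkanes) == []

    def test_order_invariance(self, ref_model, small_actives):
        fwd = screen(ref_model, small_actives)
        rev = screen(ref_model, list(reversed(small_actives)))
        assert fwd == rev


class TestROC:
    def test_hand_swept_case(self):
        scores = [("a1", 3.0), ("a2", 2.9), ("d1", 2.0), ("d2", 1.0)]
        r = roc_enrichment(scores, {"a1", "a2"})
        assert r.auc == pytest.approx(1.0)
        assert r.full_recall_cutoff == pytest.approx(2.9)
        assert r.retrieved_at_cutoff() == ["a1", "a2"]

    def test_identical_scores_auc_half(self):
        scores = [("a", 1.0), ("b", 1.0), ("c", 1.0), ("d", 1.0)]
        r = roc_enrichment(scores, {"a", "b"})
        assert r.auc == pytest.approx(0.5)

    def test_matches_sklearn_auc(self, rng):
        ids = [f"m{i}" for i in range(60)]
        scores = list(zip(ids, rng.normal(size=60)))
        active = set(rng.choice(ids, size=20, replace=False))
        r = roc_enrichment(scores, active)
        labels = [i in active for i, _ in scores]
        vals = [s for _, s in scores]
        assert r.auc == pytest.approx(roc_auc_score(labels, vals), abs=1e-9)

    def test_monotone_curve_and_score_transform_invariance(self, rng):
        ids = [f"m{i}" for i in range(40)]
        scores = list(zip(ids, rng.uniform(0, 4, size=40)))
        active = set(ids[:10])
        r = roc_enrichment(scores, active)
        fpr = np.array([p[0] for p in r.roc_points])
        tpr = np.array([p[1] for p in r.roc_points])
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        # monotone transform of the scores leaves the curve unchanged
        r2 = roc_enrichment([(i, np.exp(s)) for i, s in scores], active)
        assert r2.auc == pytest.approx(r.auc)
        assert np.allclose(
            np.array(r2.roc_points), np.array(r.roc_points)
        )

    def test_unscored_molecules_not_retrieved(self):
        scores = [("a1", 3.0), ("d1", 2.0)]
        r = roc_enrichment(scores, {"a1"}, all_ids=["a1", "d1", "d2", "d3"])
        assert r.ranked[-1][1] == -np.inf
        assert "d2" not in r.retrieved_at_cutoff()

    def test_no_actives_raises(self):
        with pytest.raises(UndefinedROCError):
            roc_enrichment([("d1", 1.0)], {"nope"})


class TestTanimoto:
    def _fp(self, bits, length=2048):
        return BitFingerprint(bits=frozenset(bits), length=length)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({1, 5, 9}, {1, 5, 9}, 1.0),   # identical
            ({1, 2}, {3, 4}, 0.0),          # disjoint
            ({1, 2, 3}, {2, 3, 4}, 0.5),    # SA=2, SB=1, SC=1
            (set(), set(), 0.0),            # empty convention
        ],
    )
    def test_formula(self, a, b, expected):
        assert tanimoto(self._fp(a), self._fp(b)) == pytest.approx(expected)

    def test_symmetry_and_identity(self, rng):
        for _ in range(20):
            a = self._fp(set(rng.integers(0, 2048, size=30).tolist()))
            b = self._fp(set(rng.integers(0, 2048, size=30).tolist()))
            assert tanimoto(a, b) == pytest.approx(tanimoto(b, a))
            assert tanimoto(a, a) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(self._fp({1}), self._fp({1}, length=1024))

    def test_matches_rdkit_on_real_molecules(self):
        from pharmscreen.screening import FINGERPRINT_BITS, FINGERPRINT_MAX_PATH

        ma = mol_from_smiles("CC(=O)Nc1ccc(O)cc1", "a")
        mb = mol_from_smiles("CC(=O)Oc1ccccc1C(=O)O", "b")
        ours = tanimoto(
            BitFingerprint.from_molecule(ma), BitFingerprint.from_molecule(mb)
        )
        fa = Chem.RDKFingerprint(ma.rdmol, maxPath=FINGERPRINT_MAX_PATH, fpSize=FINGERPRINT_BITS)
        fb = Chem.RDKFingerprint(mb.rdmol, maxPath=FINGERPRINT_MAX_PATH, fpSize=FINGERPRINT_BITS)
        assert ours == pytest.approx(DataStructs.TanimotoSimilarity(fa, fb), abs=1e-12)


class TestSimilarityMatrix:
    def test_self_similarity_diagonal(self, small_actives):
        mols = small_actives[:3]
        sim = similarity_matrix(mols, mols)
        assert np.allclose(np.diag(sim), 1.0)

    def test_elementwise_matches_scalar_calls(self):
        a = [mol_from_smiles("CCO", "a0"), mol_from_smiles("c1ccccc1", "a1")]
        b = [mol_from_smiles("CCN", "b0"), mol_from_smiles("CCCC", "b1")]
        sim = similarity_matrix(a, b)
        for i, ma in enumerate(a):
            for j, mb in enumerate(b):
                expected = tanimoto(
                    BitFingerprint.from_molecule(ma), BitFingerprint.from_molecule(mb)
                )
                assert sim[i, j] == pytest.approx(expected)

    def test_unrelated_sets_stay_below_similarity_convention(self, small_actives):
        unrelated = [mol_from_smiles(s, f"u{i}") for i, s in enumerate(
            ["OCC(O)C(O)C(O)C(O)CO", "c1ccc2ccccc2c1", "CC(C)(C)OC(=O)N1CCCC1"]
        )]
        sim = similarity_matrix(unrelated, small_actives)
        assert sim.max() < 0.85
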