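"""Fit value, ligand mapping (with brute-force oracle), model construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from pharmscreen.chemstruct import ChemFeatureKind, perceive_features
from pharmscreen.pharmacophore import (
    PharmacophoreFeature,
    PharmacophoreModel,
    build_common_feature_model,
    fit_value,
    map_ligand,
)
from pharmscreen.synthdata import gen_actives, reference_pharmacophore

from conftest import mol_3d


class TestFitValue:
    @pytest.mark.parametrize(
        "displacements,expected",
        [
            ([(0.0, 1.6)] * 4, 4.0),                      # perfect 4-feature mapping
            ([(1.6, 1.6)] + [(0.0, 1.6)] * 3, 3.0),       # one feature at its radius
            ([(0.8, 1.6)], 0.75),                         # d = r/2 -> 1 - 1/4
            ([(2.0, 1.6)], 0.0),                          # beyond tolerance -> 0
        ],
    )
    def test_formula(self, displacements, expected):
        assert fit_value(displacements) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_value([(0.5, 0.0)])
        with pytest.raises(ValueError):
            fit_value([(-0.1, 1.6)])

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 5, allow_nan=False), st.floats(0.1, 5, allow_nan=False)
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=200)
    def test_bounded_and_monotone(self, pairs):
        fv = fit_value(pairs)
        assert 0.0 <= fv <= len(pairs) + 1e-12
        # increasing any displacement never increases the fit
        worse = [(d + 0.5, r) for d, r in pairs]
        assert fit_value(worse) <= fv + 1e-12


def _brute_force_map(model, mol):
    """Independent oracle: permutation enumeration + scipy superposition."""
    best = None
    for ci in range(mol.n_conformers):
        feats = perceive_features(mol, ci)
        pools = [
            [f for f in feats if f.kind == mf.kind] for mf in model.features
        ]
        if any(not p for p in pools):
            continue
        for combo in itertools.product(*pools):
            if len({id(f) for f in combo}) != len(combo):
                continue
            P = np.array([f.centroid for f in combo])
            Q = model.centers()
            rot, _rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
            moved = rot.apply(P - P.mean(0)) + Q.mean(0)
            ds = np.linalg.norm(moved - Q, axis=1)
            if np.any(ds > np.array([f.tolerance for f in model.features]) + 1e-9):
                continue
            fv = fit_value(
                [(float(d), mf.tolerance) for d, mf in zip(ds, model.features)]
            )
            if best is None or fv > best:
                best = fv
    return best


class TestMapLigand:
    def test_exact_replica_scores_maximal(self, ref_model, exact_actives):
        for m in exact_actives:
            r = map_ligand(ref_model, m)
            assert r is not None
            assert r.fit_value == pytest.approx(ref_model.k, abs=1e-9)
            assert all(d <= 1e-6 for d in r.displacements)

    def test_missing_kind_returns_none(self, ref_model):
        # no positive-ionizable feature anywhere, max_omitted = 0
        m = mol_3d("CC(=O)c1ccccc1CCCC")
        assert map_ligand(ref_model, m) is None

    def test_matches_brute_force_oracle(self, ref_model, small_actives):
        for m in small_actives[:4]:
            ours = map_ligand(ref_model, m)
            oracle = _brute_force_map(ref_model, m)
            assert ours is not None and oracle is not None
            assert ours.fit_value == pytest.approx(oracle, abs=1e-6)

    def test_rigid_invariance(self, ref_model, small_actives, rng):
        from pharmscreen.chemstruct import apply_rigid, random_rigid_transform

        m = small_actives[0]
        base = map_ligand(ref_model, m).fit_value
        moved = m.copy()
        R, t = random_rigid_transform(rng)
        conf = moved.rdmol.GetConformer(0)
        new = apply_rigid(m.conformer_coords(0), R, t)
        for i in range(moved.rdmol.GetNumAtoms()):
            conf.SetAtomPosition(i, tuple(float(x) for x in new[i]))
        assert map_ligand(ref_model, moved).fit_value == pytest.approx(base, abs=1e-6)

    def test_displacements_within_tolerance(self, ref_model, small_actives):
        r = map_ligand(ref_model, small_actives[0])
        for d, mf in zip(r.displacements, ref_model.features):
            assert d <= mf.tolerance + 1e-9


class TestModelValidation:
    def test_min_interfeature_distance_enforced(self):
        with pytest.raises(ValueError):
            PharmacophoreModel(
                features=[
                    PharmacophoreFeature(ChemFeatureKind.HBA, (0, 0, 0)),
                    PharmacophoreFeature(ChemFeatureKind.HBD, (0.5, 0, 0)),
                ]
            )

    def test_needs_two_features(self):
        with pytest.raises(ValueError):
            PharmacophoreModel(
                features=[PharmacophoreFeature(ChemFeatureKind.HBA, (0, 0, 0))]
            )

    def test_json_roundtrip(self, tmp_path, ref_model):
        path = tmp_path / "model.json"
        ref_model.to_json(path)
        back = PharmacophoreModel.from_json(path)
        assert back.kinds() == ref_model.kinds()
        assert np.allclose(back.centers(), ref_model.centers())
        assert back.to_json() == ref_model.to_json()


class TestCommonFeatureModel:
    def test_recovers_planted_kinds(self, ref_model):
        refs = gen_actives(ref_model, n=3, noise=0.2, seed=11)
        models = build_common_feature_model(refs, k_range=(4, 5))
        assert models
        assert sorted(k.value for k in models[0].kinds()) == [
            "AROMATIC", "HBA", "HYDROPHOBIC", "POS_IONIZABLE",
        ]

    def test_reference_recovery_bound(self, ref_model):
        """Some emitted model maps every reference with fit >= k(1-(2e/r)^2)."""
        noise, tol = 0.2, 1.6
        refs = gen_actives(ref_model, n=3, noise=noise, seed=11)
        models = build_common_feature_model(refs, k_range=(4, 5))
        bound = 4 * (1 - (2 * noise / tol) ** 2)
        assert any(
            all(
                (r := map_ligand(m, ref)) is not None and r.fit_value >= bound
                for ref in refs
            )
            for m in models
        )

    def test_zero_noise_references_map_perfectly(self, ref_model):
        refs = gen_actives(ref_model, n=3, noise=0.0, seed=11)
        top = build_common_feature_model(refs, k_range=(4, 5))[0]
        for ref in refs:
            assert map_ligand(top, ref).fit_value == pytest.approx(4.0, abs=1e-6)

    def test_disjoint_kinds_yield_empty(self):
        bz = mol_3d("c1ccccc1", "bz")
        hx = mol_3d("CCCCCC", "hx")
        assert build_common_feature_model([bz, hx], k_range=(2, 4)) == []

    def test_model_size_bounded_by_reference_features(self, ref_model):
        refs = gen_actives(ref_model, n=3, noise=0.2, seed=5)
        smallest = min(
            len(perceive_features(r, 0)) for r in refs
        )
        for m in build_common_feature_model(refs, k_range=(4, 5)):
            assert m.k <= smallest
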