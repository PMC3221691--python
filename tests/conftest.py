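"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from pharmscreen.chemstruct import Molecule, generate_conformers
from pharmscreen.synthdata import (
    gen_actives,
    gen_pose_set,
    reference_pharmacophore,
    site_residue_keys,
)


def mol_from_smiles(smiles: str, mol_id: str = "m") -> Molecule:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, smiles
    return Molecule(id=mol_id, rdmol=m)


def mol_3d(smiles: str, mol_id: str = "m", seed: int = 17, n_max: int = 5) -> Molecule:
    return generate_conformers(mol_from_smiles(smiles, mol_id), n_max=n_max, window=20, seed=seed)


@pytest.fixture(scope="session")
def ref_model():
    return reference_pharmacophore()


@pytest.fixture(scope="session")
def small_actives(ref_model):
    return gen_actives(ref_model, n=8, noise=0.2, seed=7)


@pytest.fixture(scope="session")
def exact_actives(ref_model):
    return gen_actives(ref_model, n=2, noise=0.0, seed=3)


@pytest.fixture(scope="session")
def pose_set():
    poses, labels = gen_pose_set(n_active=20, n_inactive=20, flip_prob=0.05, seed=0)
    return poses, labels


@pytest.fixture(scope="session")
def site_keys():
    return site_residue_keys()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
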