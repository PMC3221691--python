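"""Molecular data model, file I/O, properties, protonation, conformers, features.

The package-wide molecular container is an RDKit ``Mol`` wrapped in a thin
:class:`Molecule` dataclass that carries an identifier, an optional IC50
annotation (uM, from a calcium-mobilization antagonism assay) and per-conformer
energies.  All downstream stages (pharmacophore mapping, screening, SAR) work
on this type.

Chemical-feature perception follows a fixed, Catalyst-like rule set:

* HBD            -- N or O bearing at least one hydrogen.
* HBA            -- N or O with an available lone pair, excluding amide N,
                    aromatic N-H, positively charged N and the neutral N atoms
                    conjugated into an amidinium/guanidinium cation.
* POS_IONIZABLE  -- a group carrying +1 after rule-based protonation
                    (guanidinium, amidinium, protonated amine); the feature
                    centroid is the centroid of the group's heavy atoms.
* AROMATIC       -- each SSSR aromatic ring; centroid of the ring atoms with
                    the ring normal as the feature direction.
* HYDROPHOBIC    -- each connected fragment of >=3 non-aromatic carbons none
                    of which touches a heteroatom; centroid of the fragment.

Protonation is rule-based at a fixed biological pH of 7.5 (no pKa
prediction): guanidines, amidines and aliphatic amines are protonated (+1),
carboxylic acids deprotonated (-1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolAlign, rdMolDescriptors

logger = logging.getLogger("pharmscreen")
RDLogger.DisableLog("rdApp.*")

# pH at which rule-based protonation states are assigned.
BIOLOGICAL_PH = 7.5
# Conformer generation defaults: library size and energy window (kcal/mol).
DEFAULT_N_CONFORMERS = 50
DEFAULT_ENERGY_WINDOW = 20.0
# Conformers closer than this heavy-atom RMSD (Angstrom) are duplicates.
CONFORMER_DEDUP_RMSD = 0.5


class ChemFeatureKind(str, Enum):
    HBA = "HBA"
    HBD = "HBD"
    POS_IONIZABLE = "POS_IONIZABLE"
    AROMATIC = "AROMATIC"
    HYDROPHOBIC = "HYDROPHOBIC"


@dataclass(frozen=True)
class ChemFeature:
    """A perceived chemical feature on one conformer of a molecule."""

    kind: ChemFeatureKind
    centroid: tuple[float, float, float]
    direction: tuple[float, float, float] | None = None
    atom_indices: tuple[int, ...] = ()

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


@dataclass(frozen=True)
class PropertyVector:
    """Scalar molecular properties used for +-k*SD library pre-filtering."""

    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable: int
    formal_charge: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mw, self.logp, self.hbd, self.hba, self.rotatable, self.formal_charge],
            dtype=float,
        )

    FIELDS = ("mw", "logp", "hbd", "hba", "rotatable", "formal_charge")


@dataclass
class Molecule:
    """An identified small molecule with 0+ conformers and optional activity."""

    id: str
    rdmol: Chem.Mol
    ic50_uM: float | None = None
    conformer_energies: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ic50_uM is not None and not self.ic50_uM > 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50_uM}")

    @property
    def n_conformers(self) -> int:
        return self.rdmol.GetNumConformers()

    def conformer_coords(self, index: int = 0) -> np.ndarray:
        conf = self.rdmol.GetConformer(index)
        return np.array(conf.GetPositions(), dtype=float)

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.rdmol.GetAtoms() if a.GetAtomicNum() > 1)

    def copy(self) -> "Molecule":
        return Molecule(
            id=self.id,
            rdmol=Chem.Mol(self.rdmol),
            ic50_uM=self.ic50_uM,
            conformer_energies=list(self.conformer_energies),
        )


class EmptyInputError(ValueError):
    """Raised when an input file yields zero valid molecule records."""


class ConformerGenerationError(RuntimeError):
    """Raised when 3D embedding fails after the retry budget."""


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _mol_id(mol: Chem.Mol, fallback: str) -> str:
    if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
        return mol.GetProp("_Name").strip()
    return fallback


def read_molecules(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read molecules from an SDF, SMILES or MOL2 file, preserving order.

    Records that fail RDKit sanitization are skipped with a logged reason.
    Raises :class:`EmptyInputError` if no valid record remains.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if fmt is None:
        fmt = {".sdf": "sdf", ".smi": "smiles", ".smiles": "smiles", ".mol2": "mol2"}.get(
            path.suffix.lower(), "sdf"
        )
    mols: list[Molecule] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping record %d of %s: sanitization failed", i, path.name)
                continue
            m = Molecule(id=_mol_id(mol, f"{path.stem}_{i}"), rdmol=mol)
            if mol.HasProp("ic50_uM"):
                m.ic50_uM = float(mol.GetProp("ic50_uM"))
            mols.append(m)
    elif fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                logger.warning("skipping line %d of %s: unparseable SMILES", i, path.name)
                continue
            name = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{i}"
            mols.append(Molecule(id=name, rdmol=mol))
    elif fmt == "mol2":
        text = path.read_text()
        blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE") if b.strip()]
        for i, block in enumerate(blocks):
            mol = Chem.MolFromMol2Block(block, sanitize=True, removeHs=False)
            if mol is None:
                logger.warning("skipping MOL2 block %d of %s", i, path.name)
                continue
            mols.append(Molecule(id=_mol_id(mol, f"{path.stem}_{i}"), rdmol=mol))
    else:
        raise ValueError(f"unknown format: {fmt}")
    if not mols:
        raise EmptyInputError(f"no valid molecule records in {path}")
    return mols


def write_sdf(mols: Iterable[Molecule], path: str | Path, all_conformers: bool = False) -> None:
    """Write molecules (V2000 SDF).  IC50 annotations travel as an SD tag."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for m in mols:
        mol = Chem.Mol(m.rdmol)
        mol.SetProp("_Name", m.id)
        if m.ic50_uM is not None:
            mol.SetProp("ic50_uM", repr(m.ic50_uM))
        if mol.GetNumConformers() == 0:
            writer.write(mol)
        elif all_conformers:
            for conf in mol.GetConformers():
                writer.write(mol, confId=conf.GetId())
        else:
            writer.write(mol, confId=mol.GetConformers()[0].GetId())
    writer.close()


# ---------------------------------------------------------------------------
# Rule-based protonation (fixed pH 7.5)
# ---------------------------------------------------------------------------

_CARBOXYL = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_GUANIDINE_N = Chem.MolFromSmarts("[NX2;+0]=[CX3]([NX3;+0])[NX3;+0]")
_AMIDINE_N = Chem.MolFromSmarts("[NX2;+0]=[CX3]([#6,#1])[NX3;+0]")
# Aliphatic amine: neutral sp3 N whose heavy neighbours are all sp3 carbons,
# not adjacent to aromatic rings or carbonyl/imine carbons (anilines and
# amides stay neutral at pH 7.5).
_ALIPHATIC_AMINE = Chem.MolFromSmarts(
    "[NX3;+0;!$(N-a);!$(N-[#6]=[!#6]);!$(N-[!#6;!#1]);!$(N=*)]"
)


def assign_protonation(mol: Molecule, pH: float = BIOLOGICAL_PH) -> Molecule:
    """Return a copy with rule-based formal charges for the given pH.

    Only the fixed pH 7.5 rule table is implemented: guanidine/amidine sp2 N
    and aliphatic amines gain +1; carboxylic acids lose a proton (-1).
    Molecules without ionizable groups are returned unchanged.
    """
    rw = Chem.RWMol(mol.rdmol)
    changed = False
    # Deprotonate carboxylic acids (pKa ~4.8 < 7.5).
    for match in rw.GetSubstructMatches(_CARBOXYL):
        o = rw.GetAtomWithIdx(match[2])
        o.SetFormalCharge(-1)
        o.SetNumExplicitHs(0)
        o.SetNoImplicit(True)
        changed = True
    # Protonate guanidines/amidines on the sp2 nitrogen (pKa ~12.5 / ~11).
    protonated: set[int] = set()
    for pattern in (_GUANIDINE_N, _AMIDINE_N):
        for match in rw.GetSubstructMatches(pattern):
            n = rw.GetAtomWithIdx(match[0])
            if n.GetIdx() in protonated or n.GetFormalCharge() != 0:
                continue
            n.SetFormalCharge(1)
            n.SetNumExplicitHs(n.GetTotalNumHs() + 1)
            protonated.add(n.GetIdx())
            changed = True
    # Protonate aliphatic amines (pKa ~10.6).
    for match in rw.GetSubstructMatches(_ALIPHATIC_AMINE):
        n = rw.GetAtomWithIdx(match[0])
        if n.GetIdx() in protonated or n.GetFormalCharge() != 0:
            continue
        if any(nb.GetIsAromatic() for nb in n.GetNeighbors()):
            continue
        n.SetFormalCharge(1)
        n.SetNumExplicitHs(n.GetTotalNumHs() + 1)
        protonated.add(n.GetIdx())
        changed = True
    if not changed:
        return mol.copy()
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return replace(mol.copy(), rdmol=out)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

_HBD_PATTERN = Chem.MolFromSmarts("[#7,#8;!H0]")
_HBA_O = Chem.MolFromSmarts("[OX1,OX2;+0,-1]")
_HBA_N = Chem.MolFromSmarts(
    "[N;+0;!$([nH]);!$(N-C=O);!$(N-C=[N+]);!$(N=C-[N;+0])]"
)


def _hbd_atoms(mol: Chem.Mol) -> list[int]:
    return sorted({m[0] for m in mol.GetSubstructMatches(_HBD_PATTERN)})


def _hba_atoms(mol: Chem.Mol) -> list[int]:
    hits = {m[0] for m in mol.GetSubstructMatches(_HBA_O)}
    hits |= {m[0] for m in mol.GetSubstructMatches(_HBA_N)}
    return sorted(hits)


def compute_properties(mol: Molecule) -> PropertyVector:
    """Deterministic, conformer-independent property vector.

    ``logp`` is a Crippen atomic-contribution estimate -- internally
    consistent for +-k*SD window filtering, not a replica of any commercial
    AlogP implementation.
    """
    m = mol.rdmol
    return PropertyVector(
        mw=float(Descriptors.MolWt(m)),
        logp=float(Crippen.MolLogP(m)),
        hbd=len(_hbd_atoms(m)),
        hba=len(_hba_atoms(m)),
        rotatable=int(
            rdMolDescriptors.CalcNumRotatableBonds(
                m, rdMolDescriptors.NumRotatableBondsOptions.Strict
            )
        ),
        formal_charge=int(Chem.GetFormalCharge(m)),
    )


# ---------------------------------------------------------------------------
# Conformer generation
# ---------------------------------------------------------------------------

def generate_conformers(
    mol: Molecule,
    n_max: int = DEFAULT_N_CONFORMERS,
    window: float = DEFAULT_ENERGY_WINDOW,
    seed: int = 0,
) -> Molecule:
    """Generate up to ``n_max`` low-energy conformers within ``window`` kcal/mol.

    Distance-geometry embedding (ETKDG) followed by MMFF (UFF fallback)
    minimization; conformers are sorted by energy ascending, de-duplicated at
    0.5 A heavy-atom RMSD and cut at the energy window.  The seed is
    mandatory for reproducibility.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if window <= 0:
        raise ValueError("window must be > 0")
    work = Chem.AddHs(Chem.Mol(mol.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = False
    n_embed = max(2 * n_max, n_max + 4)
    cids = list(AllChem.EmbedMultipleConfs(work, numConfs=n_embed, params=params))
    if not cids:
        params.useRandomCoords = True
        cids = list(AllChem.EmbedMultipleConfs(work, numConfs=n_embed, params=params))
    if not cids:
        raise ConformerGenerationError(f"embedding failed for molecule {mol.id!r}")
    if AllChem.MMFFHasAllMoleculeParams(work):
        results = AllChem.MMFFOptimizeMoleculeConfs(work, maxIters=500)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(work, maxIters=500)
    energies = [(cid, e) for cid, (converged, e) in zip(cids, results)]
    energies.sort(key=lambda t: t[1])
    e_min = energies[0][1]
    noH = Chem.RemoveHs(work)
    kept: list[tuple[int, float]] = []
    for cid, e in energies:
        if e - e_min > window:
            continue
        duplicate = False
        for kept_cid, _ in kept:
            rms = rdMolAlign.GetBestRMS(noH, noH, prbId=cid, refId=kept_cid)
            if rms < CONFORMER_DEDUP_RMSD:
                duplicate = True
                break
        if not duplicate:
            kept.append((cid, e))
        if len(kept) >= n_max:
            break
    out = Chem.Mol(noH)
    out.RemoveAllConformers()
    for cid, _ in kept:
        conf = Chem.Conformer(noH.GetConformer(cid))
        out.AddConformer(conf, assignId=True)
    return Molecule(
        id=mol.id,
        rdmol=out,
        ic50_uM=mol.ic50_uM,
        conformer_energies=[e for _, e in kept],
    )


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------

_GUANIDINIUM_GROUP = Chem.MolFromSmarts("[CX3](=[N+])([N])[N]")
_AMIDINIUM_GROUP = Chem.MolFromSmarts("[CX3](=[N+])[N]")
_AMMONIUM = Chem.MolFromSmarts("[N+;X4,X3;!$([N+]=*)]")


def _pos_ionizable_groups(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Heavy-atom groups carrying +1 after protonation; largest motif wins."""
    groups: list[tuple[int, ...]] = []
    used: set[int] = set()
    for pattern in (_GUANIDINIUM_GROUP, _AMIDINIUM_GROUP):
        for match in mol.GetSubstructMatches(pattern):
            if used & set(match):
                continue
            groups.append(tuple(sorted(match)))
            used |= set(match)
    for match in mol.GetSubstructMatches(_AMMONIUM):
        if match[0] in used:
            continue
        groups.append((match[0],))
        used.add(match[0])
    return groups


def _hydrophobic_fragments(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Connected fragments of >=3 plain carbons (no heteroatom neighbours)."""
    def qualifies(atom: Chem.Atom) -> bool:
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            return False
        return all(nb.GetAtomicNum() in (1, 6) for nb in atom.GetNeighbors())

    ok = {a.GetIdx() for a in mol.GetAtoms() if qualifies(a)}
    seen: set[int] = set()
    fragments: list[tuple[int, ...]] = []
    for start in sorted(ok):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            idx = stack.pop()
            if idx in comp:
                continue
            comp.add(idx)
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nb.GetIdx() in ok and nb.GetIdx() not in comp:
                    stack.append(nb.GetIdx())
        seen |= comp
        if len(comp) >= 3:
            fragments.append(tuple(sorted(comp)))
    return fragments


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    return normal / np.linalg.norm(normal)


def perceive_features(mol: Molecule, conformer_index: int = 0) -> list[ChemFeature]:
    """Perceive chemical features on one conformer of a molecule.

    Aromatic features carry the ring normal as a direction; HBA features on
    atoms with a single heavy neighbour carry the lone-pair direction
    (acceptor atom minus its neighbour).  Other features are point features.
    """
    m = mol.rdmol
    coords = mol.conformer_coords(conformer_index)
    feats: list[ChemFeature] = []

    for idx in _hba_atoms(m):
        atom = m.GetAtomWithIdx(idx)
        direction = None
        heavy_nbrs = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1]
        if len(heavy_nbrs) == 1:
            v = coords[idx] - coords[heavy_nbrs[0]]
            norm = np.linalg.norm(v)
            if norm > 1e-9:
                direction = tuple((v / norm).tolist())
        feats.append(
            ChemFeature(ChemFeatureKind.HBA, tuple(coords[idx]), direction, (idx,))
        )
    for idx in _hbd_atoms(m):
        feats.append(ChemFeature(ChemFeatureKind.HBD, tuple(coords[idx]), None, (idx,)))
    for group in _pos_ionizable_groups(m):
        centroid = coords[list(group)].mean(axis=0)
        feats.append(
            ChemFeature(ChemFeatureKind.POS_IONIZABLE, tuple(centroid), None, group)
        )
    ring_info = m.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(m.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            ring_coords = coords[list(ring)]
            centroid = ring_coords.mean(axis=0)
            normal = _ring_normal(ring_coords)
            feats.append(
                ChemFeature(
                    ChemFeatureKind.AROMATIC,
                    tuple(centroid),
                    tuple(normal.tolist()),
                    tuple(sorted(ring)),
                )
            )
    for frag in _hydrophobic_fragments(m):
        centroid = coords[list(frag)].mean(axis=0)
        feats.append(ChemFeature(ChemFeatureKind.HYDROPHOBIC, tuple(centroid), None, frag))
    return feats


def write_property_table(mols: Sequence[Molecule], path: str | Path) -> None:
    """CSV property table: id,mw,logp,hbd,hba,rotatable,formal_charge."""
    import pandas as pd

    rows = []
    for m in mols:
        p = compute_properties(m)
        rows.append(
            {
                "id": m.id, "mw": p.mw, "logp": p.logp, "hbd": p.hbd,
                "hba": p.hba, "rotatable": p.rotatable, "formal_charge": p.formal_charge,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Shared rigid-body algebra
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) minimizing ||R P + t - Q||.

    P and Q are (n, 3) paired coordinate arrays; returns rotation matrix R
    (proper, det +1) and translation t so that ``P @ R.T + t`` approximates Q.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix()
    t = rng.uniform(-10.0, 10.0, size=3)
    return R, t
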