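"""Matched-pair structure-activity analysis on a fixed labeled scaffold.

Antagonist datasets built around one scaffold are split into actives
(IC50 < 0.05 uM in a calcium-mobilization assay) and inactives (IC50 > 1 uM);
compounds falling between the thresholds are excluded.  Each molecule is
decomposed into the shared core plus one substituent per labeled variable
position (A1, D, L2, Q on the guanidine-triazinedione scaffold).  An
(active, inactive) pair that differs at exactly one position localizes the
activity change to that substituent swap, and aggregating the chemical
feature kinds gained/lost across pairs yields per-position "required
feature" rules (e.g. an aromatic ring carrying an H-bond acceptor).

Decomposition uses R-group decomposition against a declared core pattern
with labeled attachment points rather than generic maximum-common-
substructure search, because the compounds share one fixed scaffold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from rdkit import Chem
from rdkit.Chem import rdRGroupDecomposition

from .chemstruct import (
    ChemFeatureKind,
    Molecule,
    _hba_atoms,
    _hbd_atoms,
    _hydrophobic_fragments,
    _pos_ionizable_groups,
    assign_protonation,
)

logger = logging.getLogger("pharmscreen")

# IC50 class thresholds (uM), strict inequalities.
ACTIVE_IC50_BELOW = 0.05
INACTIVE_IC50_ABOVE = 1.0


class ActivityClass(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class ActivityRecord:
    molecule_id: str
    ic50_uM: float
    activity: ActivityClass


def classify_activity(
    ic50_uM: float,
    low: float = ACTIVE_IC50_BELOW,
    high: float = INACTIVE_IC50_ABOVE,
) -> ActivityClass:
    """Active iff IC50 < low; inactive iff IC50 > high; excluded otherwise.

    Thresholds are strict: boundary values fall in the excluded class.
    """
    if not ic50_uM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_uM}")
    if ic50_uM < low:
        return ActivityClass.ACTIVE
    if ic50_uM > high:
        return ActivityClass.INACTIVE
    return ActivityClass.EXCLUDED


@dataclass(frozen=True)
class ScaffoldTemplate:
    """Core pattern with labeled attachment points.

    ``core_smiles`` uses atom-mapped dummy atoms ([*:1] ...); ``positions``
    maps each R-label number to a position name, e.g. {1: "A1", 2: "D",
    3: "L2", 4: "Q"}.
    """

    core_smiles: str
    positions: dict[int, str]

    def __post_init__(self) -> None:
        if len(set(self.positions.values())) != len(self.positions):
            raise ValueError("position labels must be unique")

    def core_mol(self) -> Chem.Mol:
        core = Chem.MolFromSmiles(self.core_smiles)
        if core is None:
            raise ValueError(f"unparseable core SMILES: {self.core_smiles}")
        return core


@dataclass(frozen=True)
class MatchedPair:
    active_id: str
    inactive_id: str
    position: str
    substituent_active: str  # canonical fragment SMILES
    substituent_inactive: str
    features_gained: frozenset[ChemFeatureKind]  # present in active side only
    features_lost: frozenset[ChemFeatureKind]


def _canonical_fragment(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
    return Chem.MolToSmiles(mol)


def substituent_feature_kinds(fragment_smiles: str) -> frozenset[ChemFeatureKind]:
    """Chemical feature kinds exposed by a substituent fragment.

    The attachment dummy atom is replaced by hydrogen, the fragment is
    protonated by the pH-7.5 rule table, and the atom-level perception rules
    from :mod:`pharmscreen.chemstruct` are applied (geometry-free: only the
    presence of a kind matters here).
    """
    frag = Chem.MolFromSmiles(fragment_smiles)
    if frag is None:
        return frozenset()
    rw = Chem.RWMol(frag)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    mol = Chem.RemoveHs(rw.GetMol())
    Chem.SanitizeMol(mol)
    mol = assign_protonation(Molecule(id="frag", rdmol=mol)).rdmol
    kinds: set[ChemFeatureKind] = set()
    if _hba_atoms(mol):
        kinds.add(ChemFeatureKind.HBA)
    if _hbd_atoms(mol):
        kinds.add(ChemFeatureKind.HBD)
    if _pos_ionizable_groups(mol):
        kinds.add(ChemFeatureKind.POS_IONIZABLE)
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        kinds.add(ChemFeatureKind.AROMATIC)
    if _hydrophobic_fragments(mol):
        kinds.add(ChemFeatureKind.HYDROPHOBIC)
    return frozenset(kinds)


def decompose(
    mols: list[Molecule], template: ScaffoldTemplate
) -> dict[str, dict[str, str]]:
    """Per-molecule substituent map {molecule id: {position: fragment SMILES}}.

    Molecules that do not match the core are excluded with a log entry.
    """
    core = template.core_mol()
    params = rdRGroupDecomposition.RGroupDecompositionParameters()
    params.removeHydrogensPostMatch = True
    params.onlyMatchAtRGroups = True
    decomp = rdRGroupDecomposition.RGroupDecomposition(core, params)
    kept: list[Molecule] = []
    for m in mols:
        # decomposition works on the molecular graph; drop conformers
        flat = Chem.MolFromSmiles(Chem.MolToSmiles(Chem.RemoveHs(m.rdmol)))
        if flat is None or decomp.Add(flat) < 0:
            logger.warning("molecule %s does not match the scaffold core", m.id)
            continue
        kept.append(m)
    if not kept:
        return {}
    decomp.Process()
    rows = decomp.GetRGroupsAsRows(asSmiles=True)
    out: dict[str, dict[str, str]] = {}
    for m, row in zip(kept, rows):
        subs: dict[str, str] = {}
        for label, name in template.positions.items():
            frag = row.get(f"R{label}", "")
            subs[name] = _canonical_fragment(frag)
        out[m.id] = subs
    return out


def find_matched_pairs(
    actives: list[Molecule],
    inactives: list[Molecule],
    template: ScaffoldTemplate,
) -> list[MatchedPair]:
    """(active, inactive) pairs identical at all labeled positions but one.

    Pairs are emitted in deterministic (active id, inactive id) order; the
    pair's feature delta is the set difference of substituent feature kinds
    at the differing position.
    """
    active_subs = decompose(actives, template)
    inactive_subs = decompose(inactives, template)
    positions = list(template.positions.values())
    pairs: list[MatchedPair] = []
    for aid in sorted(active_subs):
        for iid in sorted(inactive_subs):
            a, i = active_subs[aid], inactive_subs[iid]
            differing = [p for p in positions if a[p] != i[p]]
            if len(differing) != 1:
                continue
            pos = differing[0]
            kinds_a = substituent_feature_kinds(a[pos])
            kinds_i = substituent_feature_kinds(i[pos])
            pairs.append(
                MatchedPair(
                    active_id=aid,
                    inactive_id=iid,
                    position=pos,
                    substituent_active=a[pos],
                    substituent_inactive=i[pos],
                    features_gained=frozenset(kinds_a - kinds_i),
                    features_lost=frozenset(kinds_i - kinds_a),
                )
            )
    return pairs


@dataclass
class PositionRule:
    position: str
    required: frozenset[ChemFeatureKind]
    evidence: list[tuple[str, str]] = field(default_factory=list)

    @property
    def has_rule(self) -> bool:
        return bool(self.required)


def position_feature_rules(pairs: list[MatchedPair]) -> dict[str, PositionRule]:
    """Aggregate matched-pair feature deltas into per-position rules.

    A feature kind is flagged "required" at a position when it is present in
    every active-side substituent observed there and absent from at least
    one inactive counterpart.  Positions without a systematic delta get an
    empty rule.
    """
    by_pos: dict[str, list[MatchedPair]] = {}
    for p in pairs:
        by_pos.setdefault(p.position, []).append(p)
    rules: dict[str, PositionRule] = {}
    for pos, plist in sorted(by_pos.items()):
        active_kind_sets = [substituent_feature_kinds(p.substituent_active) for p in plist]
        inactive_kind_sets = [substituent_feature_kinds(p.substituent_inactive) for p in plist]
        always_active = frozenset.intersection(*active_kind_sets)
        required = frozenset(
            k for k in always_active if any(k not in s for s in inactive_kind_sets)
        )
        rules[pos] = PositionRule(
            position=pos,
            required=required,
            evidence=[(p.active_id, p.inactive_id) for p in plist],
        )
    return rules
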