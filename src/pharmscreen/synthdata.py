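"""Seeded synthetic-data generators for every input class of the pipeline.

The generators stand in for the proprietary/patent inputs of a GPCR
antagonist discovery campaign:

* ``gen_actives``       -- molecules built around an abstract guanidinium /
  aromatic / carbonyl / alkyl scaffold whose perceived features realize a
  4-feature pharmacophore arrangement (HBA, positive ionizable, aromatic
  ring, hydrophobic) up to a controllable geometric jitter, with IC50
  annotations below the activity threshold.
* ``gen_decoys``        -- property-matched molecules guaranteed to lack at
  least one model feature kind or to violate the model geometry by far more
  than the tolerance radius (inter-feature distances scaled x2).
* ``gen_matched_pairs`` -- active/inactive molecule pairs on a labeled
  triazinedione-like scaffold differing at exactly one position, with
  planted per-position feature rules.
* ``gen_toy_complex``   -- toy TM-binding-site complexes whose side-chain
  fragments (Glu, Arg, Thr, Phe, ...) are positioned so that interaction
  detection yields exactly a prescribed bit pattern.

All generators are pure functions of (parameters, seed); per-item RNG
streams are derived as ``default_rng([seed, item_index])`` so extending a
set never reshuffles earlier items.  Geometry is placed analytically
(straight-line linkers, ideal local group geometry) and is not force-field
relaxed: these are geometric constructs for exercising the pipeline, not
physically realistic conformations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemstruct import ChemFeatureKind, Molecule, perceive_features
from .complexes import (
    CHANNELS,
    ComplexStructure,
    PoseFilterRules,
    Residue,
    SiteAtom,
    interaction_fingerprint,
)
from .pharmacophore import (
    PharmacophoreFeature,
    PharmacophoreModel,
)
from .sar import ACTIVE_IC50_BELOW, INACTIVE_IC50_ABOVE, ScaffoldTemplate
from .screening import ReferenceStats

logger = logging.getLogger("pharmscreen")


class GeneratorError(RuntimeError):
    """Raised when a generator cannot realize the requested construct."""


def _rng(seed: int, index: int | None = None) -> np.random.Generator:
    return np.random.default_rng([seed] if index is None else [seed, index])


def _random_frame(rng: np.random.Generator) -> np.ndarray:
    """Random right-handed orthonormal basis (rows u, v, w)."""
    a = rng.normal(size=3)
    a /= np.linalg.norm(a)
    b = rng.normal(size=3)
    b -= a * np.dot(a, b)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    return np.vstack([a, b, c])


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise GeneratorError("degenerate direction")
    return v / n


def _perp(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r = rng.normal(size=3)
    r -= v * np.dot(v, r)
    return _unit(r)


# ---------------------------------------------------------------------------
# Stated-world pharmacophore
# ---------------------------------------------------------------------------

_REFERENCE_CENTERS = {
    ChemFeatureKind.HBA: (0.0, 0.0, 0.0),
    ChemFeatureKind.POS_IONIZABLE: (6.0, 0.0, 0.0),
    ChemFeatureKind.AROMATIC: (2.8, 3.5, 0.0),
    ChemFeatureKind.HYDROPHOBIC: (4.5, -2.5, 1.0),
}


def reference_pharmacophore(tolerance: float = 1.6) -> PharmacophoreModel:
    """The canonical 4-feature screening model of the synthetic world.

    One H-bond acceptor, one positive ionizable group, one aromatic ring and
    one hydrophobic feature at fixed mutual distances of 3-6.5 A -- the
    arrangement every generated active embeds.
    """
    return PharmacophoreModel(
        features=[
            PharmacophoreFeature(kind=k, center=c, tolerance=tolerance)
            for k, c in _REFERENCE_CENTERS.items()
        ]
    )


# ---------------------------------------------------------------------------
# Screening molecules (actives and decoys)
# ---------------------------------------------------------------------------

_RING_RADIUS = 1.39


def _model_targets(model: PharmacophoreModel) -> dict[ChemFeatureKind, np.ndarray]:
    targets: dict[ChemFeatureKind, np.ndarray] = {}
    for f in model.features:
        if f.kind in targets:
            raise GeneratorError("generator supports one feature per kind")
        targets[f.kind] = f.xyz.copy()
    required = {
        ChemFeatureKind.HBA,
        ChemFeatureKind.POS_IONIZABLE,
        ChemFeatureKind.AROMATIC,
        ChemFeatureKind.HYDROPHOBIC,
    }
    if set(targets) != required:
        raise GeneratorError(
            f"generator requires exactly the kinds {sorted(k.value for k in required)}"
        )
    return targets


@dataclass
class _Decorations:
    n_methyl: int
    n_methoxy: int
    chain_extra: int

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "_Decorations":
        return cls(
            n_methyl=int(rng.integers(0, 3)),
            n_methoxy=int(rng.integers(0, 2)),
            chain_extra=int(rng.integers(0, 3)),
        )


def _build_screen_molecule(
    mol_id: str,
    targets: dict[ChemFeatureKind, np.ndarray],
    rng: np.random.Generator,
    deco: _Decorations,
    aromatic_hub: bool = True,
    polyether_arm: bool = False,
) -> Molecule:
    """Assemble one screening molecule around the four feature targets.

    The aromatic (or, for decoys, saturated) six-ring is the hub; three arms
    carry a carbonyl acceptor, an aryl-guanidinium cation and an alkyl chain
    (or, for hydrophobic-free decoys, a short polyether).  Designated
    feature groups land exactly on their targets; linker-atom routing is
    randomized so only the designed arrangement is conserved across
    molecules.
    """
    t_hba = targets[ChemFeatureKind.HBA]
    t_pos = targets[ChemFeatureKind.POS_IONIZABLE]
    t_aro = targets[ChemFeatureKind.AROMATIC]
    t_hyd = targets[ChemFeatureKind.HYDROPHOBIC]

    rw = Chem.RWMol()
    coords: list[np.ndarray] = []

    def add_atom(symbol: str, pos: np.ndarray, charge: int = 0, n_h: int | None = None) -> int:
        atom = Chem.Atom(symbol)
        if charge:
            atom.SetFormalCharge(charge)
        if n_h is not None:
            atom.SetNumExplicitHs(n_h)
        idx = rw.AddAtom(atom)
        coords.append(np.asarray(pos, dtype=float))
        return idx

    frame = _random_frame(rng)
    u, v = frame[0], frame[1]
    ring_idx: list[int] = []
    for i in range(6):
        th = math.radians(60.0 * i)
        pos = t_aro + _RING_RADIUS * (math.cos(th) * u + math.sin(th) * v)
        ring_idx.append(add_atom("C", pos))
    # kekulized alternating bonds; sanitization perceives aromaticity
    bond_types = [Chem.BondType.DOUBLE, Chem.BondType.SINGLE] * 3
    for i in range(6):
        bt = bond_types[i] if aromatic_hub else Chem.BondType.SINGLE
        rw.AddBond(ring_idx[i], ring_idx[(i + 1) % 6], bt)

    # Assign each arm the ring atom pointing most toward its target.
    free = set(range(6))
    attach: dict[str, int] = {}
    for arm, target in (("hba", t_hba), ("pos", t_pos), ("hyd", t_hyd)):
        d = _unit(target - t_aro)
        best = max(free, key=lambda i: float(np.dot(coords[ring_idx[i]] - t_aro, d)))
        attach[arm] = best
        free.discard(best)

    # --- HBA arm: ring-C(=O)H aldehyde, O exactly on target ---
    ra = coords[ring_idx[attach["hba"]]]
    d = _unit(t_hba - ra)
    c_carb = add_atom("C", t_hba - 1.23 * d)
    o_carb = add_atom("O", t_hba)
    rw.AddBond(ring_idx[attach["hba"]], c_carb, Chem.BondType.SINGLE)
    rw.AddBond(c_carb, o_carb, Chem.BondType.DOUBLE)

    # --- positive-ionizable arm: aryl guanidinium, group centroid on target ---
    rp = coords[ring_idx[attach["pos"]]]
    dp = _unit(t_pos - rp)
    e1 = -dp
    p = _perp(dp, rng)
    e2 = math.cos(math.radians(120)) * e1 + math.sin(math.radians(120)) * p
    e3 = math.cos(math.radians(240)) * e1 + math.sin(math.radians(240)) * p
    c_gu = add_atom("C", t_pos)
    n_link = add_atom("N", t_pos + 1.33 * e1)
    n_plus = add_atom("N", t_pos + 1.33 * e2, charge=1, n_h=2)
    n_amine = add_atom("N", t_pos + 1.33 * e3)
    rw.AddBond(ring_idx[attach["pos"]], n_link, Chem.BondType.SINGLE)
    rw.AddBond(n_link, c_gu, Chem.BondType.SINGLE)
    rw.AddBond(c_gu, n_plus, Chem.BondType.DOUBLE)
    rw.AddBond(c_gu, n_amine, Chem.BondType.SINGLE)

    # --- hydrophobic (or polyether) arm ---
    rh = coords[ring_idx[attach["hyd"]]]
    dh = _unit(t_hyd - rh)
    bend = _perp(dh, rng) * rng.uniform(0.5, 1.8)
    if not polyether_arm:
        o_pos = t_hyd - 4.4 * dh
        n_linker = 1 + deco.chain_extra
        prev = ring_idx[attach["hyd"]]
        for j in range(1, n_linker + 1):
            frac = j / (n_linker + 1)
            pos = rh + (o_pos - rh) * frac + bend * math.sin(math.pi * frac)
            idx = add_atom("C", pos)
            rw.AddBond(prev, idx, Chem.BondType.SINGLE)
            prev = idx
        o_eth = add_atom("O", o_pos)
        rw.AddBond(prev, o_eth, Chem.BondType.SINGLE)
        c1 = add_atom("C", t_hyd - 3.0 * dh)
        c2 = add_atom("C", t_hyd - 1.5 * dh)
        c3 = add_atom("C", t_hyd)
        c4 = add_atom("C", t_hyd + 1.5 * dh)
        rw.AddBond(o_eth, c1, Chem.BondType.SINGLE)
        for a, b in ((c1, c2), (c2, c3), (c3, c4)):
            rw.AddBond(a, b, Chem.BondType.SINGLE)
    else:
        # -CH2-O-CH2-CH2-O-CH3: no 3 contiguous heteroatom-free carbons
        span = t_hyd - rh
        symbols = ["C", "O", "C", "C", "O", "C"]
        prev = ring_idx[attach["hyd"]]
        for j, sym in enumerate(symbols, start=1):
            frac = j / (len(symbols) + 1)
            pos = rh + span * frac * 0.9 + bend * math.sin(math.pi * frac)
            idx = add_atom(sym, pos)
            rw.AddBond(prev, idx, Chem.BondType.SINGLE)
            prev = idx
        # chain_extra is realized as extra methyl decorations instead of
        # chain carbons (which would create a hydrophobic fragment)

    # --- ring decorations on the remaining positions ---
    slots = sorted(free)
    n_methyl = deco.n_methyl + (deco.chain_extra if polyether_arm else 0)
    wanted = (["OC"] * deco.n_methoxy + ["C"] * n_methyl)[: len(slots)]
    for kind, slot in zip(wanted, slots):
        radial = _unit(coords[ring_idx[slot]] - t_aro)
        base = coords[ring_idx[slot]]
        if kind == "C":
            idx = add_atom("C", base + 1.5 * radial)
            rw.AddBond(ring_idx[slot], idx, Chem.BondType.SINGLE)
        else:
            o = add_atom("O", base + 1.4 * radial)
            c = add_atom("C", base + 2.8 * radial)
            rw.AddBond(ring_idx[slot], o, Chem.BondType.SINGLE)
            rw.AddBond(o, c, Chem.BondType.SINGLE)

    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, pos in enumerate(coords):
        conf.SetAtomPosition(i, tuple(float(x) for x in pos))
    mol.AddConformer(conf, assignId=True)
    mol = Chem.AddHs(mol, addCoords=True)
    # AddHs geometry can go non-finite at the deliberately unphysical bond
    # angles of this construction; park such hydrogens deterministically
    # next to their heavy atom (H positions carry no feature information)
    conf = mol.GetConformer(0)
    pos = conf.GetPositions()
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        if np.all(np.isfinite(pos[i])):
            continue
        heavy = next(nb.GetIdx() for nb in atom.GetNeighbors())
        offset = np.array([0.3, 0.5, 0.8]) * (1.0 + 0.01 * i)
        fixed = pos[heavy] + 1.09 * offset / np.linalg.norm(offset)
        conf.SetAtomPosition(i, tuple(float(x) for x in fixed))
    mol.SetProp("_Name", mol_id)
    return Molecule(id=mol_id, rdmol=mol, conformer_energies=[0.0])


def _jittered_targets(
    targets: dict[ChemFeatureKind, np.ndarray],
    noise: float,
    rng: np.random.Generator,
) -> dict[ChemFeatureKind, np.ndarray]:
    """Independent uniform-in-ball jitter (radius <= noise) per feature,
    followed by a random rigid placement of the whole arrangement."""
    frame = _random_frame(rng)
    shift = rng.uniform(-15.0, 15.0, size=3)
    out = {}
    for kind, center in targets.items():
        if noise > 0:
            direction = _unit(rng.normal(size=3))
            radius = noise * rng.uniform() ** (1.0 / 3.0)
            jitter = radius * direction
        else:
            jitter = np.zeros(3)
        out[kind] = frame @ (center + jitter) + shift
    return out


def gen_actives(
    model: PharmacophoreModel | None = None,
    n: int = 56,
    noise: float = 0.2,
    seed: int = 7,
) -> list[Molecule]:
    """Generate ``n`` actives embedding the model's feature arrangement.

    Each molecule's perceived features include every model kind within
    ``noise`` (A) of the model geometry (verified at build time); IC50
    annotations are sampled below the 0.05 uM activity threshold.
    """
    if model is None:
        model = reference_pharmacophore()
    targets = _model_targets(model)
    min_tol = min(f.tolerance for f in model.features)
    if not noise < min_tol:
        raise GeneratorError(f"noise {noise} must be below the smallest tolerance {min_tol}")
    out: list[Molecule] = []
    for i in range(n):
        rng = _rng(seed, i)
        placed = _jittered_targets(targets, noise, rng)
        mol = _build_screen_molecule(
            f"active_{i:03d}", placed, rng, _Decorations.sample(rng), aromatic_hub=True
        )
        mol.ic50_uM = float(10 ** rng.uniform(-3.0, math.log10(ACTIVE_IC50_BELOW) - 1e-9))
        _verify_embedding(mol, placed, noise)
        out.append(mol)
    return out


def _verify_embedding(
    mol: Molecule, placed: dict[ChemFeatureKind, np.ndarray], noise: float
) -> None:
    feats = perceive_features(mol, 0)
    for kind, target in placed.items():
        dists = [
            float(np.linalg.norm(f.xyz - target)) for f in feats if f.kind == kind
        ]
        if not dists or min(dists) > noise + 1e-6:
            raise GeneratorError(
                f"molecule {mol.id} fails to realize {kind.value} at its target"
            )


def gen_decoys(
    stats: ReferenceStats,
    n: int,
    seed: int,
    model: PharmacophoreModel | None = None,
    k_sd: float = 4.0,
    max_tries: int = 25,
) -> list[Molecule]:
    """Property-matched decoys that cannot map onto the model.

    Decoys cycle through three constructions: (a) the aromatic hub replaced
    by a saturated ring (no aromatic feature), (b) the alkyl arm replaced by
    a polyether (no hydrophobic feature), (c) full feature complement with
    all inter-feature distances scaled x2 (geometry violated far beyond the
    tolerance radius).  Decoration draws are retried until the molecule sits
    inside the +-k_sd*SD property window of the reference stats.
    """
    if model is None:
        model = reference_pharmacophore()
    targets = _model_targets(model)
    centroid = np.mean(list(targets.values()), axis=0)
    from .chemstruct import compute_properties

    out: list[Molecule] = []
    for i in range(n):
        rng = _rng(seed, 100_000 + i)
        variant = i % 3
        base = dict(targets)
        if variant == 2:
            base = {k: centroid + 2.0 * (t - centroid) for k, t in base.items()}
        mol = None
        for _ in range(max_tries):
            placed = _jittered_targets(base, 0.2, rng)
            cand = _build_screen_molecule(
                f"decoy_{i:04d}",
                placed,
                rng,
                _Decorations.sample(rng),
                aromatic_hub=(variant != 0),
                polyether_arm=(variant == 1),
            )
            if stats.contains(compute_properties(cand), k_sd):
                mol = cand
                break
        if mol is None:
            raise GeneratorError(f"decoy {i} never entered the property window")
        out.append(mol)
    return out


# ---------------------------------------------------------------------------
# Matched SAR pairs on a labeled scaffold
# ---------------------------------------------------------------------------

# The thiocarbonyl breaks the ring's mirror symmetry: with two identical
# carbonyls the N-bound positions D and L2 would be exchangeable by a graph
# automorphism and decomposition labels could flip between molecules.
_CORE_SMILES = "O=C1N([*:1])C(=S)N([*:2])C([*:4])N1[*:3]"
_POSITIONS = {1: "A1", 2: "D", 3: "L2", 4: "Q"}


def default_scaffold_template() -> ScaffoldTemplate:
    """Triazinone-like core (one C=O, one C=S) with four labeled positions."""
    return ScaffoldTemplate(core_smiles=_CORE_SMILES, positions=_POSITIONS)


# rule kinds -> (active substituent, inactive variants each dropping >=1 kind)
_RULE_REGISTRY: dict[frozenset[ChemFeatureKind], tuple[str, tuple[str, ...]]] = {
    frozenset({ChemFeatureKind.AROMATIC, ChemFeatureKind.HBA}): (
        "c2ccc(OC)cc2", ("c2ccccc2", "CCC")
    ),
    frozenset({ChemFeatureKind.AROMATIC}): ("c2ccccc2", ("CC",)),
    frozenset({ChemFeatureKind.HBA}): ("COC", ("CC",)),
    frozenset({ChemFeatureKind.HYDROPHOBIC}): ("CCCC", ("C", "CO")),
    frozenset({ChemFeatureKind.POS_IONIZABLE, ChemFeatureKind.HBD}): (
        "CNC(=N)N", ("CO", "CC")
    ),
}

_FILLERS = ("[H]", "C", "CC")

DEFAULT_ACTIVITY_RULE: dict[str, frozenset[ChemFeatureKind]] = {
    "D": frozenset({ChemFeatureKind.AROMATIC, ChemFeatureKind.HBA}),
    "Q": frozenset({ChemFeatureKind.POS_IONIZABLE, ChemFeatureKind.HBD}),
}


def _assemble(core_subs: dict[str, str], mol_id: str, ic50: float) -> Molecule:
    smiles = "O=C1N({A1})C(=S)N({D})C({Q})N1{L2}".format(**core_subs)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GeneratorError(f"assembly failed for {smiles}")
    from .chemstruct import assign_protonation

    m = assign_protonation(Molecule(id=mol_id, rdmol=mol, ic50_uM=ic50))
    return m


def gen_matched_pairs(
    template: ScaffoldTemplate | None = None,
    rule: dict[str, frozenset[ChemFeatureKind]] | None = None,
    n_pairs: int = 13,
    seed: int = 0,
) -> tuple[list[Molecule], list[Molecule]]:
    """Matched active/inactive pairs with planted per-position feature rules.

    Pair ``i`` differs from its partner only at one rule position (positions
    cycle); the active side carries exactly the planted feature kinds there
    and the inactive side cycles through variants so that, over the pair
    set, every planted kind is absent from at least one inactive
    counterpart (required for exact rule recovery).  IC50 values fall
    strictly on the correct sides of the 0.05 / 1 uM thresholds.
    """
    if template is None:
        template = default_scaffold_template()
    if rule is None:
        rule = DEFAULT_ACTIVITY_RULE
    for pos, kinds in rule.items():
        if pos not in template.positions.values():
            raise GeneratorError(f"rule position {pos} not in template")
        if frozenset(kinds) not in _RULE_REGISTRY:
            raise GeneratorError(f"no substituent registry entry for kinds {sorted(kinds)}")
    rule_positions = sorted(rule)
    actives, inactives = [], []
    per_pos_count: dict[str, int] = {p: 0 for p in rule_positions}
    for i in range(n_pairs):
        rng = _rng(seed, 200_000 + i)
        pos = rule_positions[i % len(rule_positions)]
        active_sub, variants = _RULE_REGISTRY[frozenset(rule[pos])]
        inactive_sub = variants[per_pos_count[pos] % len(variants)]
        per_pos_count[pos] += 1
        subs = {
            p: str(rng.choice(_FILLERS)) for p in template.positions.values()
        }
        # a pair-unique alkyl tag at one non-rule position keeps distinct
        # pairs from forming accidental cross-pairs (they then differ at
        # two or more positions)
        tag_pos = next(
            (p for p in template.positions.values() if p not in rule_positions), None
        )
        if tag_pos is not None:
            subs[tag_pos] = "C" * (1 + i)
        a_subs = dict(subs)
        i_subs = dict(subs)
        # non-varied rule positions carry the active substituent on BOTH
        # sides so each pair differs at exactly one position
        for other in rule_positions:
            if other != pos:
                a_subs[other] = i_subs[other] = _RULE_REGISTRY[frozenset(rule[other])][0]
        a_subs[pos] = active_sub
        i_subs[pos] = inactive_sub
        ic50_a = float(10 ** rng.uniform(-3.0, math.log10(ACTIVE_IC50_BELOW) - 1e-9))
        ic50_i = float(10 ** rng.uniform(math.log10(INACTIVE_IC50_ABOVE) + 1e-9, 2.0))
        actives.append(_assemble(a_subs, f"pair{i:02d}_active", ic50_a))
        inactives.append(_assemble(i_subs, f"pair{i:02d}_inactive", ic50_i))
    return actives, inactives


# ---------------------------------------------------------------------------
# Toy receptor-ligand complexes
# ---------------------------------------------------------------------------

# Binding-site residues shared by every toy complex (Ballesteros-Weinstein
# labels as optional metadata).  Unreferenced residues are parked far from
# the ligand and contribute zero fingerprint bits.
SITE_RESIDUES: list[tuple[str, int, str]] = [
    ("GLU", 119, "2.61"),
    ("CYS", 137, "3.25"),
    ("ASN", 141, "3.29"),
    ("ARG", 144, "3.32"),
    ("THR", 145, "3.33"),
    ("PHE", 300, "6.51"),
    ("ARG", 307, "6.58"),
    ("MET", 332, "7.47"),
]

# The canonical "active" signature: salt bridge to the acidic TM2 residue,
# plus hydrogen-bond and pi interactions with the two binding-site
# arginines -- the pattern that also satisfies all three pose-filter
# constraints.  Inactive poses keep a residual Arg144 hydrogen bond and
# drift toward Thr145.
ACTIVE_POSE_PATTERN: tuple[tuple[str, str, int], ...] = (
    ("CHARGED", "GLU", 119),
    ("PI", "ARG", 144),
    ("HBOND", "ARG", 307),
    ("PI", "ARG", 307),
)
INACTIVE_POSE_PATTERN: tuple[tuple[str, str, int], ...] = (
    ("HBOND", "ARG", 144),
    ("HBOND", "THR", 145),
)
# Bits that clustering-noise flips may toggle (slot-capacity reduction in
# gen_pose_set keeps any flipped combination realizable).
POSE_BIT_UNIVERSE: tuple[tuple[str, str, int], ...] = (
    ("CHARGED", "GLU", 119),
    ("HBOND", "ARG", 144),
    ("HBOND", "THR", 145),
    ("HBOND", "ASN", 141),
    ("PI", "ARG", 144),
    ("PI", "ARG", 307),
    ("HBOND", "ARG", 307),
    ("PI", "PHE", 300),
)


def site_residue_keys(chain: str = "A") -> list[tuple[str, int]]:
    return [(chain, seq) for _, seq, _ in SITE_RESIDUES]


def default_pose_filter_rules(chain: str = "A") -> PoseFilterRules:
    """Canonical constraint set in the toy numbering (Glu119/Arg144/Arg307)."""
    return PoseFilterRules(
        charged_residue=(chain, 119),
        hbond_residues=[(chain, 144), (chain, 307)],
        pi_residues=[(chain, 144), (chain, 307)],
    )


# Local residue templates: (atom name, element, offset) in a frame whose +x
# axis points from the interacting group away from the ligand.
_RES_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "ARG": [
        ("NH1", "N", (0.0, 0.0, 0.0)),
        ("HH11", "H", (-1.0, 0.0, 0.0)),
        ("CZ", "C", (1.33, 0.0, 0.0)),
        ("NE", "N", (1.995, 1.152, 0.0)),
        ("NH2", "N", (1.995, -1.152, 0.0)),
        ("CD", "C", (3.495, 1.152, 0.0)),
        ("CG", "C", (4.995, 1.152, 0.0)),
        ("CB", "C", (6.495, 1.152, 0.0)),
        ("CA", "C", (7.995, 1.152, 0.0)),
    ],
    "GLU": [
        ("CD", "C", (0.0, 0.0, 0.0)),
        ("OE1", "O", (0.0, 1.1, 0.0)),
        ("OE2", "O", (0.0, -1.1, 0.0)),
        ("CG", "C", (1.5, 0.0, 0.0)),
        ("CB", "C", (3.0, 0.0, 0.0)),
        ("CA", "C", (4.5, 0.0, 0.0)),
    ],
    "THR": [
        ("OG1", "O", (0.0, 0.0, 0.0)),
        ("HG1", "H", (-1.0, 0.0, 0.0)),
        ("CB", "C", (1.43, 0.0, 0.0)),
        ("CG2", "C", (1.93, 1.35, 0.0)),
        ("CA", "C", (2.93, -0.8, 0.0)),
    ],
    "ASN": [
        ("ND2", "N", (0.0, 0.0, 0.0)),
        ("HD21", "H", (-1.0, 0.0, 0.0)),
        ("CG", "C", (1.33, 0.0, 0.0)),
        ("OD1", "O", (1.99, 1.05, 0.0)),
        ("CB", "C", (2.83, -0.9, 0.0)),
        ("CA", "C", (4.33, -0.9, 0.0)),
    ],
    "PHE": [
        ("CG", "C", (0.0, 1.39, 0.0)),
        ("CD1", "C", (0.0, 0.695, 1.204)),
        ("CD2", "C", (0.0, 0.695, -1.204)),
        ("CE1", "C", (0.0, -0.695, 1.204)),
        ("CE2", "C", (0.0, -0.695, -1.204)),
        ("CZ", "C", (0.0, -1.39, 0.0)),
        ("CB", "C", (1.2, 2.3, 0.0)),
        ("CA", "C", (2.4, 3.2, 0.0)),
    ],
    "CYS": [
        ("SG", "S", (0.0, 0.0, 0.0)),
        ("CB", "C", (1.8, 0.0, 0.0)),
        ("CA", "C", (3.3, 0.0, 0.0)),
    ],
    "MET": [
        ("SD", "S", (0.0, 0.0, 0.0)),
        ("CG", "C", (1.8, 0.0, 0.0)),
        ("CE", "C", (-0.9, 1.55, 0.0)),
        ("CB", "C", (3.3, 0.0, 0.0)),
        ("CA", "C", (4.8, 0.0, 0.0)),
    ],
}

# Ligand local geometry: benzene ring centered at the origin (normal +z), a
# carbonyl acceptor arm along +x, an aryl-guanidinium cation arm along -x
# and a ring methoxy whose ether oxygen serves the combined HBond+pi slot.
_LIG_RING = [
    (_RING_RADIUS * math.cos(math.radians(60 * i)),
     _RING_RADIUS * math.sin(math.radians(60 * i)), 0.0)
    for i in range(6)
]
_LIG_ATOMS: list[tuple[str, str, tuple[float, float, float]]] = (
    [(f"C{i+1}", "C", p) for i, p in enumerate(_LIG_RING)]
    + [
        ("C7", "C", (2.89, 0.0, 0.0)),
        ("O1", "O", (4.12, 0.0, 0.0)),
        ("N1", "N", (-2.89, 0.0, 0.0)),
        ("C8", "C", (-4.22, 0.0, 0.0)),
        ("N2", "N", (-4.885, 1.152, 0.0)),
        ("N3", "N", (-4.885, -1.152, 0.0)),
        ("O2", "O", (-1.395, 2.416, 0.0)),
        ("C9", "C", (-2.095, 3.628, 0.0)),
    ]
)
_LIG_O = np.array([4.12, 0.0, 0.0])
_LIG_O2 = np.array([-1.395, 2.416, 0.0])
_LIG_GUA = np.array([-4.22, 0.0, 0.0])
_LIG_RING_CENTER = np.zeros(3)

_HBOND_SLOT_ANGLES = (0.0, 40.0, -40.0)  # degrees in the xy plane around +x
_PI_SLOTS = (np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0]))
_CHARGED_SLOT_ANGLES = (0.0, 30.0)  # degrees around -x

_CHARGED_CENTROID_DIST = 3.9
_HBOND_DONOR_DIST = 2.9
_PI_CATION_DIST = 3.3  # NH1 height over the ring; keeps a < 4 A heavy contact
_PI_STACK_DIST = 3.8
# Combined HBond+pi arginine: NH1 donates to the ring-ether O2 while the
# guanidinium centroid stays inside the pi-cation cone over the ring.
_COMBINED_ARG_DIR = np.array([0.4, -0.7, 2.8]) / np.linalg.norm([0.4, -0.7, 2.8])
_COMBINED_ARG_ANCHOR = _LIG_O2 + 2.92 * _COMBINED_ARG_DIR


def _rotation_from_x(direction: np.ndarray) -> np.ndarray:
    """Proper rotation sending +x to ``direction`` (unit)."""
    x = np.array([1.0, 0.0, 0.0])
    d = _unit(direction)
    v = np.cross(x, d)
    c = float(np.dot(x, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _place_residue(
    name: str, seq: int, bw: str | None, anchor: np.ndarray, direction: np.ndarray,
    chain: str = "A",
) -> Residue:
    """Instantiate a side-chain template with its business group at ``anchor``
    and its tail running along ``direction`` (away from the ligand)."""
    rot = _rotation_from_x(direction)
    atoms = [
        SiteAtom(an, el, anchor + rot @ np.asarray(off), 0)
        for an, el, off in _RES_TEMPLATES[name]
    ]
    return Residue(name=name, seq_number=seq, chain=chain, atoms=atoms, bw_label=bw)


def gen_toy_complex(
    pattern: tuple[tuple[str, str, int], ...] | list[tuple[str, str, int]],
    seed: int = 0,
    pose_id: str = "pose",
    chain: str = "A",
) -> ComplexStructure:
    """Toy complex realizing exactly the requested interaction bits.

    ``pattern`` lists (channel, residue name, residue number) requests with
    channel in {HBOND, CHARGED, PI}; the referenced residues must belong to
    the fixed binding-site roster.  All roster residues are present in the
    output (unreferenced ones parked >20 A away), so fingerprints computed
    over the site share one index map across poses.  The realized
    fingerprint is verified against the request before returning.
    """
    site = {(rn, seq): bw for rn, seq, bw in SITE_RESIDUES}
    rng = _rng(seed)
    by_residue: dict[tuple[str, int], set[str]] = {}
    for channel, resname, seq in pattern:
        if (resname, seq) not in site:
            raise GeneratorError(f"residue {resname}{seq} not in the toy binding site")
        if channel not in CHANNELS:
            raise GeneratorError(f"unknown channel {channel}")
        by_residue.setdefault((resname, seq), set()).add(channel)

    slots = {"HBOND": list(_HBOND_SLOT_ANGLES), "CHARGED": list(_CHARGED_SLOT_ANGLES),
             "PI": list(_PI_SLOTS), "COMBINED": [0]}
    placements: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    for (resname, seq), channels in sorted(by_residue.items()):
        if channels == {"HBOND", "PI"}:
            if resname != "ARG":
                raise GeneratorError(f"combined HBOND+PI is only realizable for ARG, not {resname}")
            if not slots["COMBINED"]:
                raise GeneratorError("only one combined HBOND+PI slot exists")
            slots["COMBINED"].pop()
            placements[(resname, seq)] = (_COMBINED_ARG_ANCHOR.copy(), _COMBINED_ARG_DIR.copy())
        elif channels == {"HBOND"}:
            if not slots["HBOND"]:
                raise GeneratorError("too many HBOND requests for the slot geometry")
            ang = math.radians(slots["HBOND"].pop(0))
            d = np.array([math.cos(ang), math.sin(ang), 0.0])
            placements[(resname, seq)] = (_LIG_O + _HBOND_DONOR_DIST * d, d)
        elif channels == {"CHARGED"}:
            if not slots["CHARGED"]:
                raise GeneratorError("too many CHARGED requests for the slot geometry")
            ang = math.radians(slots["CHARGED"].pop(0))
            d = np.array([-math.cos(ang), math.sin(ang), 0.0])
            placements[(resname, seq)] = (_LIG_GUA + _CHARGED_CENTROID_DIST * d, d)
        elif channels == {"PI"}:
            if not slots["PI"]:
                raise GeneratorError("too many PI requests for the slot geometry")
            axis = slots["PI"].pop(0)
            if resname in ("ARG", "LYS"):
                anchor = _LIG_RING_CENTER + _PI_CATION_DIST * axis
            elif resname in ("PHE", "TYR", "TRP"):
                anchor = _LIG_RING_CENTER + _PI_STACK_DIST * axis
            else:
                raise GeneratorError(f"residue {resname} cannot realize a PI interaction")
            placements[(resname, seq)] = (anchor, axis)
        else:
            raise GeneratorError(
                f"channel combination {sorted(channels)} at {resname}{seq} is not realizable"
            )

    residues: list[Residue] = []
    far_i = 0
    for resname, seq, bw in SITE_RESIDUES:
        if (resname, seq) in placements:
            anchor, direction = placements[(resname, seq)]
        else:
            anchor = np.array([25.0 + 5.0 * far_i, 0.0, 12.0])
            direction = np.array([1.0, 0.0, 0.0])
            far_i += 1
        residues.append(_place_residue(resname, seq, bw, anchor, direction, chain))

    ligand = [SiteAtom(an, el, np.asarray(off), 0) for an, el, off in _LIG_ATOMS]
    cx = ComplexStructure(residues=residues, ligand_atoms=ligand, pose_id=pose_id)

    # seeded global rigid placement (detection must be frame-invariant)
    from .chemstruct import random_rigid_transform
    from .complexes import transform_complex

    R, t = random_rigid_transform(rng)
    cx = transform_complex(cx, R, t)
    cx.pose_id = pose_id

    fp = interaction_fingerprint(cx, site_residue_keys(chain))
    expected = {
        (f"{chain}:{rn}:{seq}", ch) for ch, rn, seq in pattern
    }
    realized = set(fp.on_bits())
    if realized != expected:
        raise GeneratorError(
            f"pattern not realized for {pose_id}: requested {sorted(expected)}, "
            f"got {sorted(realized)}"
        )
    return cx


def _reduce_to_slot_capacity(bits: set[tuple[str, str, int]]) -> set[tuple[str, str, int]]:
    """Deterministically drop bits until the slot geometry can realize them:
    at most one combined HBOND+PI residue, 2 PI-only, 3 HBOND-only, 2 CHARGED."""
    out = set(bits)
    by_res: dict[tuple[str, int], set[str]] = {}
    for ch, rn, seq in out:
        by_res.setdefault((rn, seq), set()).add(ch)
    combined = sorted(k for k, v in by_res.items() if v == {"HBOND", "PI"})
    for rn, seq in [k for k in combined if k[0] != "ARG"] + combined[1:]:
        out.discard(("PI", rn, seq))
        by_res[(rn, seq)].discard("PI")
    pi_only = sorted(k for k, v in by_res.items() if v == {"PI"})
    for rn, seq in pi_only[2:]:
        out.discard(("PI", rn, seq))
    hb_only = sorted(k for k, v in by_res.items() if v == {"HBOND"})
    for rn, seq in hb_only[3:]:
        out.discard(("HBOND", rn, seq))
    charged = sorted(k for k, v in by_res.items() if "CHARGED" in v)
    for rn, seq in charged[2:]:
        out.discard(("CHARGED", rn, seq))
    return out


def gen_pose_set(
    n_active: int = 20,
    n_inactive: int = 20,
    flip_prob: float = 0.05,
    seed: int = 0,
    chain: str = "A",
) -> tuple[list[ComplexStructure], dict[str, str]]:
    """Active-pattern and inactive-pattern toy poses with bit-flip noise.

    Each pose starts from the canonical active or inactive interaction
    pattern; every bit of the candidate universe is then flipped with
    probability ``flip_prob`` (adds are skipped when the slot geometry is
    exhausted).  Returns the poses and a pose-id -> class label map.
    """
    poses: list[ComplexStructure] = []
    labels: dict[str, str] = {}
    for i in range(n_active + n_inactive):
        rng = _rng(seed, 300_000 + i)
        is_active = i < n_active
        base = set(ACTIVE_POSE_PATTERN if is_active else INACTIVE_POSE_PATTERN)
        for bit in POSE_BIT_UNIVERSE:
            if rng.uniform() < flip_prob:
                base.symmetric_difference_update({bit})
        base = _reduce_to_slot_capacity(base)
        label = "active" if is_active else "inactive"
        pose_id = f"{label}_{i:03d}"
        poses.append(gen_toy_complex(tuple(sorted(base)), seed=seed * 1000 + i,
                                     pose_id=pose_id, chain=chain))
        labels[pose_id] = label
    return poses, labels
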