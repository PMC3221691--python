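"""Receptor-ligand complexes: interactions, fingerprints, clustering, filters.

A :class:`ComplexStructure` holds binding-site residues (side-chain fragments
are sufficient; no backbone model is required beyond an optional CA) and one
ligand pose sharing the same coordinate frame (Angstrom).  Interaction
detection is purely geometric, with one config block of criteria:

* H-bond      -- donor-acceptor heavy-atom distance <= 3.5 A and, when the
                 donor hydrogen is present, a D-H...A angle >= 120 deg.
* Charged     -- centroids of opposite formal-charge groups <= 5.5 A.
* pi-pi       -- ring centroids <= 5.5 A with interplanar angle <= 30 deg
                 (parallel), or 60-120 deg with centroids <= 6.0 A (T-shaped).
* pi-cation   -- cation group centroid <= 6.0 A from the ring centroid and
                 <= 30 deg off the ring normal.

Every emitted interaction additionally requires at least one protein-ligand
heavy-atom pair below the 4 A contact cutoff, so interaction bits always
imply a van der Waals contact record.

Per-pose interaction fingerprints are binary vectors over (binding-site
residue x channel) with three channels per residue: HBOND, CHARGED and a
merged PI channel (pi-pi and pi-cation pooled).  Poses are compared with the
normalized Hamming distance (fraction of differing coordinates) and grouped
by agglomerative hierarchical clustering.  Structure-based pose filters
encode the constraint set used for GPCR antagonist poses: (1) a charged
interaction with the Glu119-role residue, (2) at least one hydrogen bond
with an Arg144/Arg307-role residue, and (3) at least two pi interactions
with those arginine-role residues.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy

logger = logging.getLogger("pharmscreen")

# --- geometric criteria (one config block; Angstrom / degrees) -------------
CONTACT_CUTOFF = 4.0            # heavy-atom contact, strict <
HBOND_MAX_DIST = 3.5            # donor-acceptor heavy atoms
HBOND_MIN_ANGLE = 120.0         # D-H...A angle when H is present
CHARGED_MAX_DIST = 5.5          # opposite-charge group centroids
PIPI_PARALLEL_MAX_DIST = 5.5
PIPI_PARALLEL_MAX_ANGLE = 30.0
PIPI_TSHAPE_MAX_DIST = 6.0
PIPI_TSHAPE_ANGLE = (60.0, 120.0)
PICATION_MAX_DIST = 6.0
PICATION_MAX_OFFNORMAL = 30.0

_BOND_CUTOFF_DEFAULT = 1.75     # heavy-atom bond inference
_BOND_CUTOFF_S = 1.95
_H_BOND_CUTOFF = 1.3

CHANNELS = ("HBOND", "CHARGED", "PI")


class InteractionType(str, Enum):
    HBOND = "HBOND"
    CHARGED = "CHARGED"
    PIPI = "PIPI"
    PICATION = "PICATION"

    @property
    def channel(self) -> str:
        return "PI" if self in (InteractionType.PIPI, InteractionType.PICATION) else self.value


@dataclass
class SiteAtom:
    name: str
    element: str
    coord: np.ndarray
    charge: int = 0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class Residue:
    name: str
    seq_number: int
    chain: str = "A"
    atoms: list[SiteAtom] = field(default_factory=list)
    bw_label: str | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.seq_number)

    @property
    def id_str(self) -> str:
        return f"{self.chain}:{self.name}:{self.seq_number}"

    def atom(self, name: str) -> SiteAtom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if a.element != "H"], dtype=float)


@dataclass
class ComplexStructure:
    residues: list[Residue]
    ligand_atoms: list[SiteAtom]
    pose_id: str = "pose"
    docking_score: float | None = None

    def __post_init__(self) -> None:
        if sum(1 for a in self.ligand_atoms if a.element != "H") < 1:
            raise ValueError("ligand needs at least one heavy atom")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue (chain, seq) keys")

    def residue_by_key(self, key: tuple[str, int]) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"no residue {key} in complex {self.pose_id}")

    def ligand_heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.ligand_atoms) if a.element != "H"]

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.ligand_atoms], dtype=float)

    def ligand_graph(self) -> nx.Graph:
        """Heavy-atom bond graph, inferred from interatomic distances."""
        g = nx.Graph()
        heavy = self.ligand_heavy_indices()
        for i in heavy:
            g.add_node(i, element=self.ligand_atoms[i].element)
        for i, j in itertools.combinations(heavy, 2):
            ai, aj = self.ligand_atoms[i], self.ligand_atoms[j]
            cutoff = _BOND_CUTOFF_S if "S" in (ai.element, aj.element) else _BOND_CUTOFF_DEFAULT
            if np.linalg.norm(ai.coord - aj.coord) < cutoff:
                g.add_edge(i, j)
        return g

    def ligand_h_attachments(self) -> dict[int, list[int]]:
        """heavy atom index -> indices of attached hydrogens."""
        out: dict[int, list[int]] = {}
        heavy = self.ligand_heavy_indices()
        for i, a in enumerate(self.ligand_atoms):
            if a.element != "H":
                continue
            dists = [(float(np.linalg.norm(a.coord - self.ligand_atoms[j].coord)), j) for j in heavy]
            d, j = min(dists)
            if d < _H_BOND_CUTOFF:
                out.setdefault(j, []).append(i)
        return out


def transform_complex(cx: ComplexStructure, R: np.ndarray, t: np.ndarray) -> ComplexStructure:
    """Apply a global rigid transform to receptor and ligand alike."""
    res = [
        Residue(
            name=r.name,
            seq_number=r.seq_number,
            chain=r.chain,
            atoms=[SiteAtom(a.name, a.element, R @ a.coord + t, a.charge) for a in r.atoms],
            bw_label=r.bw_label,
        )
        for r in cx.residues
    ]
    lig = [SiteAtom(a.name, a.element, R @ a.coord + t, a.charge) for a in cx.ligand_atoms]
    return ComplexStructure(res, lig, pose_id=cx.pose_id, docking_score=cx.docking_score)


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_complex(
    pdb_path: str | Path, ligand_resname: str | None = None
) -> ComplexStructure:
    """Parse a PDB file into residues plus one HETATM ligand.

    Waters are skipped; ligand connectivity is inferred from interatomic
    distances when CONECT records are absent.  Raises when no HETATM ligand
    is present.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(pdb_path))
    arr = pdb_file.get_structure(model=1, extra_fields=["charge"])
    residues: dict[tuple[str, int], Residue] = {}
    ligand_atoms: list[SiteAtom] = []
    for i in range(arr.array_length()):
        resname = str(arr.res_name[i])
        if resname in _WATER_NAMES:
            continue
        atom = SiteAtom(
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]).capitalize(),
            coord=np.array(arr.coord[i], dtype=float),
            charge=int(arr.charge[i]),
        )
        if bool(arr.hetero[i]) and (ligand_resname is None or resname == ligand_resname):
            ligand_atoms.append(atom)
        else:
            key = (str(arr.chain_id[i]), int(arr.res_id[i]))
            if key not in residues:
                residues[key] = Residue(name=resname, seq_number=key[1], chain=key[0])
            residues[key].atoms.append(atom)
    if not ligand_atoms:
        expected = ligand_resname or "any HETATM record"
        raise ValueError(f"no ligand found in {pdb_path} (expected {expected})")
    return ComplexStructure(
        residues=list(residues.values()),
        ligand_atoms=ligand_atoms,
        pose_id=Path(pdb_path).stem,
    )


def write_complex(cx: ComplexStructure, path: str | Path, ligand_resname: str = "LIG") -> None:
    """Write the complex as a PDB file (receptor ATOM + ligand HETATM)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = sum(len(r.atoms) for r in cx.residues) + len(cx.ligand_atoms)
    arr = struc.AtomArray(n)
    arr.add_annotation("charge", int)
    i = 0
    for r in cx.residues:
        for a in r.atoms:
            arr.chain_id[i] = r.chain
            arr.res_id[i] = r.seq_number
            arr.res_name[i] = r.name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element.upper()
            arr.coord[i] = a.coord
            arr.hetero[i] = False
            arr.charge[i] = a.charge
            i += 1
    for a in cx.ligand_atoms:
        arr.chain_id[i] = "L"
        arr.res_id[i] = 1
        arr.res_name[i] = ligand_resname
        arr.atom_name[i] = a.name
        arr.element[i] = a.element.upper()
        arr.coord[i] = a.coord
        arr.hetero[i] = True
        arr.charge[i] = a.charge
        i += 1
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Protein-side chemistry templates (side-chain atom names)
# ---------------------------------------------------------------------------

_RES_DONORS = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "ASN": ("ND2",), "GLN": ("NE2",),
    "THR": ("OG1",), "SER": ("OG",), "TYR": ("OH",), "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"),
}
_RES_ACCEPTORS = {
    "GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2"), "ASN": ("OD1",), "GLN": ("OE1",),
    "THR": ("OG1",), "SER": ("OG",), "TYR": ("OH",), "HIS": ("ND1", "NE2"),
}
_RES_CHARGED = {  # residue -> (sign, group atom names)
    "GLU": (-1, ("CD", "OE1", "OE2")), "ASP": (-1, ("CG", "OD1", "OD2")),
    "ARG": (+1, ("CZ", "NE", "NH1", "NH2")), "LYS": (+1, ("NZ",)),
}
_RES_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
# Residue H naming convention used for donors written with hydrogens.
_DONOR_H_PREFIX = {"NE": "HE", "NH1": "HH1", "NH2": "HH2", "NZ": "HZ", "ND2": "HD2",
                   "NE2": "HE2", "OG1": "HG1", "OG": "HG", "OH": "HH", "NE1": "HE1",
                   "ND1": "HD1"}


@dataclass(frozen=True)
class Interaction:
    kind: InteractionType
    residue_key: tuple[str, int]
    residue_name: str
    protein_atoms: tuple[str, ...]
    ligand_atoms: tuple[int, ...]
    distance: float


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    v = vt[2]
    return v / np.linalg.norm(v)


def _ligand_rings(cx: ComplexStructure) -> list[tuple[tuple[int, ...], np.ndarray, np.ndarray]]:
    """(atom indices, centroid, normal) for planar 5/6-membered C/N rings."""
    g = cx.ligand_graph()
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if any(cx.ligand_atoms[i].element not in ("C", "N") for i in cycle):
            continue
        coords = np.array([cx.ligand_atoms[i].coord for i in cycle])
        normal = _plane_normal(coords)
        dev = np.abs((coords - coords.mean(axis=0)) @ normal)
        if dev.max() > 0.3:
            continue
        rings.append((tuple(sorted(cycle)), coords.mean(axis=0), normal))
    return rings


def _ligand_charged_groups(cx: ComplexStructure) -> list[tuple[int, tuple[int, ...], np.ndarray]]:
    """(sign, atom indices, centroid) for ligand formal-charge groups.

    Uses explicit charge annotations when present; otherwise infers a
    guanidinium (+1: C bonded to three N) or carboxylate (-1: C bonded to
    two terminal O) motif from the bond graph.
    """
    g = cx.ligand_graph()
    groups: list[tuple[int, tuple[int, ...], np.ndarray]] = []
    used: set[int] = set()
    for i in g.nodes:
        el = cx.ligand_atoms[i].element
        nbrs = list(g.neighbors(i))
        if el == "C":
            n_nbrs = [j for j in nbrs if cx.ligand_atoms[j].element == "N"]
            o_nbrs = [j for j in nbrs if cx.ligand_atoms[j].element == "O"
                      and g.degree[j] == 1]
            if len(n_nbrs) == 3:
                grp = (i, *sorted(n_nbrs))
                coords = np.array([cx.ligand_atoms[j].coord for j in grp])
                groups.append((+1, grp, coords.mean(axis=0)))
                used.update(grp)
            elif len(o_nbrs) == 2:
                grp = (i, *sorted(o_nbrs))
                coords = np.array([cx.ligand_atoms[j].coord for j in grp])
                groups.append((-1, grp, coords.mean(axis=0)))
                used.update(grp)
    for i in g.nodes:
        q = cx.ligand_atoms[i].charge
        if q != 0 and i not in used:
            groups.append((int(np.sign(q)), (i,), cx.ligand_atoms[i].coord))
    return groups


def _ligand_donors(cx: ComplexStructure) -> list[tuple[int, list[int]]]:
    h_map = cx.ligand_h_attachments()
    out = []
    for i in cx.ligand_heavy_indices():
        if cx.ligand_atoms[i].element in ("N", "O") and h_map.get(i):
            out.append((i, h_map[i]))
    return out


def _ligand_acceptors(cx: ComplexStructure) -> list[int]:
    g = cx.ligand_graph()
    h_map = cx.ligand_h_attachments()
    out = []
    for i in cx.ligand_heavy_indices():
        a = cx.ligand_atoms[i]
        if a.element == "O":
            out.append(i)
        elif a.element == "N" and a.charge <= 0 and not h_map.get(i) and g.degree[i] <= 2:
            out.append(i)
    return out


def _min_heavy_pair_distance(residue: Residue, cx: ComplexStructure) -> float:
    rc = residue.heavy_coords()
    lc = np.array([cx.ligand_atoms[i].coord for i in cx.ligand_heavy_indices()])
    if rc.size == 0 or lc.size == 0:
        return float("inf")
    d = np.linalg.norm(rc[:, None] - lc[None, :], axis=2)
    return float(d.min())


def find_contacts(
    cx: ComplexStructure, cutoff: float = CONTACT_CUTOFF
) -> list[tuple[tuple[str, int], str, int, float]]:
    """All protein-ligand heavy-atom pairs strictly closer than ``cutoff``.

    Returns (residue key, protein atom name, ligand atom index, distance),
    sorted by residue then distance.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    out = []
    heavy = cx.ligand_heavy_indices()
    for r in sorted(cx.residues, key=lambda x: x.key):
        rows = []
        for a in r.atoms:
            if a.element == "H":
                continue
            for j in heavy:
                d = float(np.linalg.norm(a.coord - cx.ligand_atoms[j].coord))
                if d < cutoff:
                    rows.append((r.key, a.name, j, d))
        rows.sort(key=lambda t: t[3])
        out.extend(rows)
    return out


def _hbond_geometry_ok(
    donor: np.ndarray, h_coords: list[np.ndarray], acceptor: np.ndarray
) -> bool:
    if float(np.linalg.norm(donor - acceptor)) > HBOND_MAX_DIST:
        return False
    if not h_coords:
        return True  # donor hydrogens absent from the structure: distance rule only
    for h in h_coords:
        v1, v2 = donor - h, acceptor - h
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-9 or n2 < 1e-9:
            continue
        ang = math.degrees(math.acos(float(np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1))))
        if ang >= HBOND_MIN_ANGLE:
            return True
    return False


def detect_interactions(cx: ComplexStructure) -> list[Interaction]:
    """Geometric H-bond, charged, pi-pi and pi-cation detection.

    Every interaction is only emitted when the residue also makes at least
    one heavy-atom contact below 4 A with the ligand, so interactions always
    imply van der Waals contact records.
    """
    interactions: list[Interaction] = []
    lig_rings = _ligand_rings(cx)
    lig_charged = _ligand_charged_groups(cx)
    lig_donors = _ligand_donors(cx)
    lig_acceptors = _ligand_acceptors(cx)

    for res in cx.residues:
        if _min_heavy_pair_distance(res, cx) >= CONTACT_CUTOFF:
            continue

        # --- hydrogen bonds (both directions) ---
        for donor_name in _RES_DONORS.get(res.name, ()):
            d_atom = res.atom(donor_name)
            if d_atom is None:
                continue
            prefix = _DONOR_H_PREFIX.get(donor_name, "H")
            h_coords = [a.coord for a in res.atoms if a.element == "H" and a.name.startswith(prefix)]
            for j in lig_acceptors:
                acc = cx.ligand_atoms[j].coord
                if _hbond_geometry_ok(d_atom.coord, h_coords, acc):
                    interactions.append(Interaction(
                        InteractionType.HBOND, res.key, res.name, (donor_name,), (j,),
                        float(np.linalg.norm(d_atom.coord - acc)),
                    ))
        for acc_name in _RES_ACCEPTORS.get(res.name, ()):
            a_atom = res.atom(acc_name)
            if a_atom is None:
                continue
            for j, h_idx in lig_donors:
                donor = cx.ligand_atoms[j].coord
                hs = [cx.ligand_atoms[h].coord for h in h_idx]
                if _hbond_geometry_ok(donor, hs, a_atom.coord):
                    interactions.append(Interaction(
                        InteractionType.HBOND, res.key, res.name, (acc_name,), (j,),
                        float(np.linalg.norm(donor - a_atom.coord)),
                    ))

        # --- charged (salt bridge) ---
        if res.name in _RES_CHARGED:
            sign, names = _RES_CHARGED[res.name]
            coords = [res.atom(n).coord for n in names if res.atom(n) is not None]
            if coords:
                centroid = np.mean(coords, axis=0)
                for lsign, grp, lcent in lig_charged:
                    if lsign * sign >= 0:
                        continue
                    d = float(np.linalg.norm(centroid - lcent))
                    if d <= CHARGED_MAX_DIST:
                        interactions.append(Interaction(
                            InteractionType.CHARGED, res.key, res.name, tuple(names), grp, d,
                        ))

        # --- pi-pi ---
        if res.name in _RES_RINGS:
            names = _RES_RINGS[res.name]
            coords = [res.atom(n).coord for n in names if res.atom(n) is not None]
            if len(coords) >= 5:
                rc = np.array(coords)
                r_cent, r_norm = rc.mean(axis=0), _plane_normal(rc)
                for ring, l_cent, l_norm in lig_rings:
                    d = float(np.linalg.norm(r_cent - l_cent))
                    ang = math.degrees(math.acos(float(np.clip(abs(np.dot(r_norm, l_norm)), 0, 1))))
                    parallel = d <= PIPI_PARALLEL_MAX_DIST and ang <= PIPI_PARALLEL_MAX_ANGLE
                    full_ang = math.degrees(math.acos(float(np.clip(np.dot(r_norm, l_norm), -1, 1))))
                    tshape = d <= PIPI_TSHAPE_MAX_DIST and (
                        PIPI_TSHAPE_ANGLE[0] <= full_ang <= PIPI_TSHAPE_ANGLE[1]
                    )
                    if parallel or tshape:
                        interactions.append(Interaction(
                            InteractionType.PIPI, res.key, res.name, tuple(names), ring, d,
                        ))
            # pi(res ring)-cation(ligand)
            if len(coords) >= 5:
                rc = np.array(coords)
                r_cent, r_norm = rc.mean(axis=0), _plane_normal(rc)
                for lsign, grp, lcent in lig_charged:
                    if lsign <= 0:
                        continue
                    d = float(np.linalg.norm(lcent - r_cent))
                    if d > PICATION_MAX_DIST or d < 1e-9:
                        continue
                    off = math.degrees(math.acos(float(np.clip(
                        abs(np.dot((lcent - r_cent) / d, r_norm)), 0, 1))))
                    if off <= PICATION_MAX_OFFNORMAL:
                        interactions.append(Interaction(
                            InteractionType.PICATION, res.key, res.name, tuple(names), grp, d,
                        ))

        # --- pi(ligand ring)-cation(residue) ---
        if res.name in _RES_CHARGED and _RES_CHARGED[res.name][0] > 0:
            _, names = _RES_CHARGED[res.name]
            coords = [res.atom(n).coord for n in names if res.atom(n) is not None]
            if coords:
                centroid = np.mean(coords, axis=0)
                for ring, l_cent, l_norm in lig_rings:
                    d = float(np.linalg.norm(centroid - l_cent))
                    if d > PICATION_MAX_DIST or d < 1e-9:
                        continue
                    off = math.degrees(math.acos(float(np.clip(
                        abs(np.dot((centroid - l_cent) / d, l_norm)), 0, 1))))
                    if off <= PICATION_MAX_OFFNORMAL:
                        interactions.append(Interaction(
                            InteractionType.PICATION, res.key, res.name, tuple(names), ring, d,
                        ))
    return interactions


# ---------------------------------------------------------------------------
# Interaction fingerprints and clustering
# ---------------------------------------------------------------------------

@dataclass
class InteractionFingerprint:
    """Binary vector over (binding-site residue x channel), 3 channels/residue."""

    bits: np.ndarray
    index_map: tuple[tuple[str, str], ...]  # ((residue id string, channel), ...)
    pose_id: str = "pose"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.index_map),):
            raise ValueError("bit vector length must equal the index map length")

    def on_bits(self) -> list[tuple[str, str]]:
        return [self.index_map[i] for i in np.flatnonzero(self.bits)]


def interaction_fingerprint(
    cx: ComplexStructure,
    site_residues: list[tuple[str, int]],
    interactions: list[Interaction] | None = None,
) -> InteractionFingerprint:
    """Fingerprint a pose over an ordered list of binding-site residue keys.

    Bit (r, HBOND) is set iff the pose makes >=1 hydrogen bond with residue
    r; (r, CHARGED) iff >=1 salt bridge; (r, PI) iff >=1 pi-pi or pi-cation
    interaction (the two pi flavours share one merged channel).
    """
    keys = {r.key for r in cx.residues}
    for k in site_residues:
        if k not in keys:
            raise KeyError(f"residue {k} not present in complex {cx.pose_id}")
    if interactions is None:
        interactions = detect_interactions(cx)
    index_map = []
    for k in site_residues:
        rid = cx.residue_by_key(k).id_str
        for ch in CHANNELS:
            index_map.append((rid, ch))
    bits = np.zeros(len(index_map), dtype=np.uint8)
    pos = {(k, ch): i for i, (k, ch) in enumerate(
        [(k, ch) for k in site_residues for ch in CHANNELS])}
    for inter in interactions:
        slot = pos.get((inter.residue_key, inter.kind.channel))
        if slot is not None:
            bits[slot] = 1
    return InteractionFingerprint(bits=bits, index_map=tuple(index_map), pose_id=cx.pose_id)


def hamming_distance(a: InteractionFingerprint, b: InteractionFingerprint) -> float:
    """Fraction of coordinates at which the two bit vectors differ."""
    if a.index_map != b.index_map:
        raise ValueError("fingerprints have different index maps")
    return float(np.mean(a.bits != b.bits))


@dataclass
class ClusterTree:
    """Agglomerative clustering result over pose fingerprints."""

    linkage_matrix: np.ndarray
    leaf_ids: list[str]

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return {leaf: int(lbl) for leaf, lbl in zip(self.leaf_ids, labels)}

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6f}"

        return rec(tree) + ";"


def hamming_matrix(fps: list[InteractionFingerprint]) -> np.ndarray:
    n = len(fps)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = hamming_distance(fps[i], fps[j])
    return out


def cluster_poses(
    fps: list[InteractionFingerprint], linkage: str = "average"
) -> ClusterTree:
    """Hierarchical clustering of interaction fingerprints (Hamming metric).

    Uses average linkage by default; pairwise distances in the tree are the
    exact normalized Hamming distances.  scipy's linkage is deterministic
    for a fixed input order, and fingerprints are processed in input order.
    """
    if len(fps) < 2:
        raise ValueError("need >= 2 fingerprints to cluster")
    d = hamming_matrix(fps)
    condensed = d[np.triu_indices(len(fps), 1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(linkage_matrix=Z, leaf_ids=[f.pose_id for f in fps])


# ---------------------------------------------------------------------------
# Structure-based pose filters
# ---------------------------------------------------------------------------

@dataclass
class PoseFilterRules:
    """Constraint set for antagonist poses, in residue-role form.

    The default role mapping follows the canonical GPCR TM-bundle constraint
    set: a charged interaction with the acidic Glu-role residue, at least
    one hydrogen bond with an Arg-role residue and at least two pi
    interactions (pi-pi or pi-cation) with the Arg-role residues.
    """

    charged_residue: tuple[str, int]
    hbond_residues: list[tuple[str, int]]
    pi_residues: list[tuple[str, int]]
    min_hbonds: int = 1
    min_pi: int = 2


class FilterConfigError(ValueError):
    pass


def apply_pose_filters(
    poses: list[ComplexStructure], rules: PoseFilterRules
) -> tuple[list[ComplexStructure], list[tuple[ComplexStructure, str]]]:
    """Partition poses into (passed, failed-with-first-violated-constraint).

    Constraint 1: charged interaction with the Glu-role residue.
    Constraint 2: >= ``min_hbonds`` hydrogen bonds with the Arg-role residues.
    Constraint 3: >= ``min_pi`` pi interactions with the Arg-role residues.
    """
    passed, failed = [], []
    for cx in poses:
        keys = {r.key for r in cx.residues}
        for k in [rules.charged_residue, *rules.hbond_residues, *rules.pi_residues]:
            if k not in keys:
                raise FilterConfigError(f"rule references residue {k} absent from pose {cx.pose_id}")
        inters = detect_interactions(cx)
        n_charged = sum(
            1 for i in inters
            if i.kind == InteractionType.CHARGED and i.residue_key == rules.charged_residue
        )
        n_hb = sum(
            1 for i in inters
            if i.kind == InteractionType.HBOND and i.residue_key in rules.hbond_residues
        )
        n_pi = sum(
            1 for i in inters
            if i.kind in (InteractionType.PIPI, InteractionType.PICATION)
            and i.residue_key in rules.pi_residues
        )
        if n_charged < 1:
            failed.append((cx, "constraint 1: no charged interaction with the Glu-role residue"))
        elif n_hb < rules.min_hbonds:
            failed.append((cx, f"constraint 2: {n_hb} hydrogen bond(s) with Arg-role residues, "
                               f"need >= {rules.min_hbonds}"))
        elif n_pi < rules.min_pi:
            failed.append((cx, f"constraint 3: {n_pi} pi interaction(s) with Arg-role residues, "
                               f"need >= {rules.min_pi}"))
        else:
            passed.append(cx)
    return passed, failed


# ---------------------------------------------------------------------------
# Docking validation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    ligand_rmsd: float
    contact_recovery: float
    residue_recovery: float


def _ligand_automorphism_maps(
    docked: ComplexStructure, reference: ComplexStructure, cap: int = 10000
) -> list[dict[int, int]]:
    """Element-preserving graph isomorphisms docked ligand -> reference ligand."""
    g_d, g_r = docked.ligand_graph(), reference.ligand_graph()
    nm = nx.algorithms.isomorphism.categorical_node_match("element", None)
    matcher = nx.algorithms.isomorphism.GraphMatcher(g_d, g_r, node_match=nm)
    maps = []
    for m in matcher.isomorphisms_iter():
        maps.append(dict(m))
        if len(maps) >= cap:
            break
    return maps


def ligand_rmsd(docked: ComplexStructure, reference: ComplexStructure) -> float:
    """Symmetry-aware heavy-atom ligand RMSD after receptor superposition.

    The docked receptor's CA atoms are superposed onto the reference's
    (Kabsch); when fewer than 3 shared CA atoms exist the transform is the
    identity (same frame assumed).  The RMSD is minimized over all element-
    preserving automorphic atom correspondences of the ligand graph.
    """
    from .chemstruct import kabsch

    ref_ca, dock_ca = [], []
    ref_res = {r.key: r for r in reference.residues}
    for r in docked.residues:
        if r.key in ref_res:
            a_d, a_r = r.atom("CA"), ref_res[r.key].atom("CA")
            if a_d is not None and a_r is not None:
                dock_ca.append(a_d.coord)
                ref_ca.append(a_r.coord)
    if len(ref_ca) >= 3:
        R, t = kabsch(np.array(dock_ca), np.array(ref_ca))
    else:
        R, t = np.eye(3), np.zeros(3)
    maps = _ligand_automorphism_maps(docked, reference)
    if not maps:
        raise ValueError("ligand atom correspondence failed (graphs not isomorphic)")
    best = float("inf")
    for mapping in maps:
        d_idx = sorted(mapping)
        r_idx = [mapping[i] for i in d_idx]
        P = np.array([docked.ligand_atoms[i].coord for i in d_idx]) @ R.T + t
        Q = np.array([reference.ligand_atoms[i].coord for i in r_idx])
        rmsd = float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
        best = min(best, rmsd)
    return best


def contact_recovery(
    docked: ComplexStructure, reference: ComplexStructure
) -> ValidationReport:
    """Fraction of reference atomic contacts / interacting residues recovered.

    Contacts are heavy-atom protein-ligand pairs below 4 A; interacting
    residues are residues with any atom below 4 A from the ligand.  Requires
    shared residue numbering and identical ligand atom ordering.
    """
    ref_contacts = {(k, an, j) for k, an, j, _ in find_contacts(reference)}
    if not ref_contacts:
        raise ValueError("reference complex has no ligand contacts; recovery undefined")
    dock_contacts = {(k, an, j) for k, an, j, _ in find_contacts(docked)}
    ref_res = {k for k, _, _ in ref_contacts}
    dock_res = {k for k, _, _ in dock_contacts}
    return ValidationReport(
        ligand_rmsd=ligand_rmsd(docked, reference),
        contact_recovery=len(ref_contacts & dock_contacts) / len(ref_contacts),
        residue_recovery=len(ref_res & dock_res) / len(ref_res),
    )
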