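"""Common-feature pharmacophore models, ligand mapping and fit-value scoring.

A pharmacophore model is a small set of typed spatial features (H-bond
acceptor, positive ionizable, aromatic ring, hydrophobic, ...) with tolerance
radii.  A ligand maps onto the model when, for some conformer and some
kind-compatible assignment of its perceived features to the model features,
a rigid superposition places every non-omitted feature inside its tolerance
sphere.  The quality of the mapping is the fit value

    fit = sum_f max(0, 1 - (d_f / r_f)^2)

over matched features, where d_f is the displacement of the ligand feature
from the model feature center after superposition and r_f the tolerance
radius.  With unit weights the fit is bounded by the feature count, so a
four-feature model has a maximal fit value of 4.

Model construction is a bounded common-feature search: k-subsets of the most
active reference ligand's features are retained when every other reference
can match the subset by feature kind with a compatible inter-feature distance
matrix.  This is a declared reimplementation of the common-feature idea, not
of any proprietary search.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemstruct import (
    ChemFeature,
    ChemFeatureKind,
    Molecule,
    apply_rigid,
    kabsch,
    perceive_features,
)

logger = logging.getLogger("pharmscreen")

# Catalyst-like defaults: tolerance sphere radius (A), minimum distance
# between feature centers (A), omitted features allowed, and the angular
# tolerance (degrees) for directional features.
DEFAULT_TOLERANCE = 1.6
DEFAULT_MIN_INTERFEATURE_DISTANCE = 1.0
DEFAULT_MAX_OMITTED = 0
DEFAULT_ANGLE_TOLERANCE = 45.0
MAX_MODELS = 10


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: ChemFeatureKind
    center: tuple[float, float, float]
    tolerance: float = DEFAULT_TOLERANCE
    direction: tuple[float, float, float] | None = None
    angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if self.direction is not None:
            n = float(np.linalg.norm(self.direction))
            if abs(n - 1.0) > 1e-6:
                object.__setattr__(
                    self, "direction", tuple((np.asarray(self.direction) / n).tolist())
                )

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]
    min_interfeature_distance: float = DEFAULT_MIN_INTERFEATURE_DISTANCE
    max_omitted: int = DEFAULT_MAX_OMITTED

    def __post_init__(self) -> None:
        if len(self.features) < 2:
            raise ValueError("a pharmacophore model needs >= 2 features")
        centers = self.centers()
        for i, j in itertools.combinations(range(len(centers)), 2):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d < self.min_interfeature_distance:
                raise ValueError(
                    f"features {i} and {j} are {d:.3f} A apart, below the "
                    f"minimum interference distance {self.min_interfeature_distance} A"
                )

    @property
    def k(self) -> int:
        return len(self.features)

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features], dtype=float)

    def kinds(self) -> list[ChemFeatureKind]:
        return [f.kind for f in self.features]

    # -- JSON schema: {"features": [{kind, center, tolerance, direction,
    #    angle_tolerance}], "min_interfeature_distance", "max_omitted"} --
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "features": [
                {
                    "kind": f.kind.value,
                    "center": list(f.center),
                    "tolerance": f.tolerance,
                    "direction": list(f.direction) if f.direction is not None else None,
                    "angle_tolerance": f.angle_tolerance,
                }
                for f in self.features
            ],
            "min_interfeature_distance": self.min_interfeature_distance,
            "max_omitted": self.max_omitted,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PharmacophoreModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        feats = [
            PharmacophoreFeature(
                kind=ChemFeatureKind(f["kind"]),
                center=tuple(f["center"]),
                tolerance=f["tolerance"],
                direction=tuple(f["direction"]) if f.get("direction") else None,
                angle_tolerance=f.get("angle_tolerance", DEFAULT_ANGLE_TOLERANCE),
            )
            for f in payload["features"]
        ]
        return cls(
            features=feats,
            min_interfeature_distance=payload.get(
                "min_interfeature_distance", DEFAULT_MIN_INTERFEATURE_DISTANCE
            ),
            max_omitted=payload.get("max_omitted", DEFAULT_MAX_OMITTED),
        )


@dataclass
class MappingResult:
    """Best mapping of a ligand onto a model."""

    assignment: dict[int, ChemFeature]  # model feature index -> ligand feature
    rotation: np.ndarray
    translation: np.ndarray
    displacements: list[float]  # per matched model feature, A
    fit_value: float
    conformer_index: int
    omitted: tuple[int, ...] = ()


def fit_value(displacements: list[tuple[float, float]]) -> float:
    """Fit value for matched features given (displacement, tolerance) pairs.

    Each feature contributes max(0, 1 - (d/r)^2); a perfectly centered
    feature contributes 1, a feature displaced beyond its tolerance radius
    contributes 0 (the mapping layer rejects such matches when no omissions
    are allowed).
    """
    total = 0.0
    for d, r in displacements:
        if not r > 0:
            raise ValueError("tolerance must be > 0")
        if d < 0:
            raise ValueError("displacement must be >= 0")
        total += max(0.0, 1.0 - (d / r) ** 2)
    return total


def _angle_ok(model_dir, ligand_dir, R: np.ndarray, tol_deg: float) -> bool:
    if model_dir is None or ligand_dir is None:
        return True
    v = R @ np.asarray(ligand_dir, dtype=float)
    cosang = float(np.clip(np.dot(v, np.asarray(model_dir, dtype=float)), -1.0, 1.0))
    # Ring normals and lone-pair vectors are axial: sign is not meaningful.
    angle = math.degrees(math.acos(abs(cosang)))
    return angle <= tol_deg + 1e-9


def map_ligand(model: PharmacophoreModel, mol: Molecule) -> MappingResult | None:
    """Best-fit mapping of a molecule onto a pharmacophore model.

    Searches over all conformers, all omission subsets up to ``max_omitted``
    and all injective kind-compatible assignments of perceived ligand
    features to model features; each candidate is scored after a Kabsch
    least-squares superposition of the assigned ligand feature centroids
    onto the model centers.  Returns None when no assignment places every
    non-omitted feature within tolerance.

    Ties are broken deterministically: higher fit, then lower conformer
    energy (index order when energies are absent), then lexicographically
    smaller assignment.
    """
    if mol.n_conformers == 0:
        return None
    best: tuple[float, float, tuple[int, ...]] | None = None
    best_result: MappingResult | None = None
    n = model.k
    for ci in range(mol.n_conformers):
        energy = (
            mol.conformer_energies[ci]
            if ci < len(mol.conformer_energies)
            else float(ci)
        )
        feats = perceive_features(mol, ci)
        by_kind: dict[ChemFeatureKind, list[tuple[int, ChemFeature]]] = {}
        for i, f in enumerate(feats):
            by_kind.setdefault(f.kind, []).append((i, f))
        for n_omit in range(model.max_omitted + 1):
            for omitted in itertools.combinations(range(n), n_omit):
                kept = [i for i in range(n) if i not in omitted]
                if len(kept) < 2:
                    continue
                candidates = [by_kind.get(model.features[i].kind, []) for i in kept]
                if any(not c for c in candidates):
                    continue
                for combo in itertools.product(*candidates):
                    idxs = [c[0] for c in combo]
                    if len(set(idxs)) != len(idxs):
                        continue
                    P = np.array([c[1].centroid for c in combo], dtype=float)
                    Q = np.array([model.features[i].center for i in kept], dtype=float)
                    R, t = kabsch(P, Q)
                    moved = apply_rigid(P, R, t)
                    ds = np.linalg.norm(moved - Q, axis=1)
                    ok = True
                    for pos, mi in enumerate(kept):
                        mf = model.features[mi]
                        if ds[pos] > mf.tolerance + 1e-9:
                            ok = False
                            break
                        if not _angle_ok(mf.direction, combo[pos][1].direction, R, mf.angle_tolerance):
                            ok = False
                            break
                    if not ok:
                        continue
                    fv = fit_value(
                        [(float(ds[pos]), model.features[mi].tolerance) for pos, mi in enumerate(kept)]
                    )
                    key = (-fv, energy, tuple(idxs))
                    if best is None or key < best:
                        best = key
                        best_result = MappingResult(
                            assignment={mi: combo[pos][1] for pos, mi in enumerate(kept)},
                            rotation=R,
                            translation=t,
                            displacements=[float(d) for d in ds],
                            fit_value=fv,
                            conformer_index=ci,
                            omitted=omitted,
                        )
    return best_result


# ---------------------------------------------------------------------------
# Common-feature model construction
# ---------------------------------------------------------------------------

def _reference_feature_sets(mol: Molecule) -> list[list[ChemFeature]]:
    return [perceive_features(mol, ci) for ci in range(mol.n_conformers)]


def _match_distance_matrix(
    subset: list[ChemFeature],
    other_feats: list[ChemFeature],
    tol: float,
) -> float | None:
    """Best mean |distance-matrix difference| for a kind-compatible injective
    assignment of ``subset`` into ``other_feats``; None when no assignment
    keeps every pairwise distance within 2*tol."""
    k = len(subset)
    ref = np.array([f.centroid for f in subset], dtype=float)
    ref_d = np.linalg.norm(ref[:, None] - ref[None, :], axis=2)
    cands = [
        [f for f in other_feats if f.kind == s.kind]
        for s in subset
    ]
    if any(not c for c in cands):
        return None
    best: float | None = None
    for combo in itertools.product(*cands):
        if len({id(c) for c in combo}) != k:
            continue
        pts = np.array([c.centroid for c in combo], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        diff = np.abs(d - ref_d)
        iu = np.triu_indices(k, 1)
        if np.any(diff[iu] > 2 * tol):
            continue
        mean_diff = float(diff[iu].mean())
        if best is None or mean_diff < best:
            best = mean_diff
    return best


# Feature types considered during common-feature search.  Donor features are
# excluded by default: donors ride along rigidly with the ionizable group on
# typical cationic scaffolds, so admitting them floods the search with
# degenerate intra-group hypotheses (the same reason feature-dictionary
# selection exists in interactive pharmacophore tools).
DEFAULT_MODEL_KINDS: tuple[ChemFeatureKind, ...] = (
    ChemFeatureKind.HBA,
    ChemFeatureKind.POS_IONIZABLE,
    ChemFeatureKind.AROMATIC,
    ChemFeatureKind.HYDROPHOBIC,
)


def build_common_feature_model(
    references: list[Molecule],
    k_range: tuple[int, int] = (4, 5),
    tolerance: float = DEFAULT_TOLERANCE,
    min_interfeature_distance: float = DEFAULT_MIN_INTERFEATURE_DISTANCE,
    kinds: tuple[ChemFeatureKind, ...] = DEFAULT_MODEL_KINDS,
    max_per_kind: int = 1,
) -> list[PharmacophoreModel]:
    """Enumerate common-feature models shared by a set of reference actives.

    The first reference is treated as the most active compound; k-subsets of
    its perceived features (largest k first, restricted to the ``kinds``
    selection with at most ``max_per_kind`` features per kind) are kept when
    every other reference exposes a kind-matched feature set whose pairwise
    distance matrix agrees within 2x tolerance.  At most 10 models are
    returned, ranked by (k descending, mean cross-reference distance
    mismatch ascending).  Raise ``max_per_kind`` to admit hypotheses with
    duplicated feature types (e.g. two hydrophobic spheres).
    """
    if len(references) < 2:
        raise ValueError("need >= 2 reference molecules")
    k_lo, k_hi = min(k_range), max(k_range)
    allowed = set(kinds)

    def restrict(feature_sets: list[list[ChemFeature]]) -> list[list[ChemFeature]]:
        return [[f for f in feats if f.kind in allowed] for feats in feature_sets]

    lead_sets = restrict(_reference_feature_sets(references[0]))
    other_sets = [restrict(_reference_feature_sets(m)) for m in references[1:]]
    scored: list[tuple[int, float, PharmacophoreModel]] = []
    seen_kind_geoms: set[tuple] = set()
    for k in range(k_hi, k_lo - 1, -1):
        for lead_feats in lead_sets:
            if len(lead_feats) < k:
                continue
            for subset in itertools.combinations(lead_feats, k):
                kind_counts: dict[ChemFeatureKind, int] = {}
                for f in subset:
                    kind_counts[f.kind] = kind_counts.get(f.kind, 0) + 1
                if any(c > max_per_kind for c in kind_counts.values()):
                    continue
                centers = np.array([f.centroid for f in subset], dtype=float)
                dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
                iu = np.triu_indices(k, 1)
                if np.any(dists[iu] < min_interfeature_distance):
                    continue
                sig = tuple(
                    sorted(
                        [f.kind.value for f in subset]
                    )
                ) + tuple(np.round(np.sort(dists[iu]), 2).tolist())
                if sig in seen_kind_geoms:
                    continue
                mismatches = []
                for ref_sets in other_sets:
                    per_ref = [
                        _match_distance_matrix(list(subset), feats, tolerance)
                        for feats in ref_sets
                    ]
                    per_ref = [x for x in per_ref if x is not None]
                    if not per_ref:
                        mismatches = None
                        break
                    mismatches.append(min(per_ref))
                if mismatches is None:
                    continue
                seen_kind_geoms.add(sig)
                # emitted models are point-feature models: the cross-reference
                # agreement check covers centers only, so attaching the lead's
                # direction vectors would impose constraints never validated
                # against the other references
                model = PharmacophoreModel(
                    features=[
                        PharmacophoreFeature(kind=f.kind, center=f.centroid, tolerance=tolerance)
                        for f in subset
                    ],
                    min_interfeature_distance=min_interfeature_distance,
                )
                scored.append((k, float(np.mean(mismatches)), model))
    if not scored:
        logger.info("no common feature subset of size >= %d found", k_lo)
        return []
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [m for _, _, m in scored[:MAX_MODELS]]
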