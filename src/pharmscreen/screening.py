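"""Property pre-filtering, decoys, virtual screening, ROC enrichment, Tanimoto.

The screening protocol mirrors standard ligand-based virtual screening
practice: candidate libraries are pre-filtered to the mean +- k*SD window of
the reference actives' molecular properties (molecular weight, logP, H-bond
donors/acceptors, rotatable bonds, formal charge, optionally requiring a
neutral-or-positive charge), mapped onto the pharmacophore model and ranked
by fit value.  Enrichment is quantified by a ROC curve of actives versus
property-matched decoys; the *full-recall cutoff* is the highest fit-value
threshold that still retrieves every known active, i.e. the minimum fit value
over the actives (ties retrieved on the >= side).

Structural similarity uses the Tanimoto coefficient on hashed path-based bit
fingerprints, SA/(SA+SB+SC): AND bits over OR bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from sklearn.metrics import roc_curve as _sk_roc_curve

from .chemstruct import Molecule, PropertyVector, compute_properties
from .pharmacophore import PharmacophoreModel, map_ligand

logger = logging.getLogger("pharmscreen")

# Decoy/library property window half-width in reference-set SDs.
DEFAULT_K_SD = 4.0
# Fingerprint parameters (hashed path-based; fixed so that similarity values
# are internally comparable).
FINGERPRINT_BITS = 2048
FINGERPRINT_MAX_PATH = 7


class UndefinedROCError(ValueError):
    """Raised when a ROC curve is requested without any scored active."""


@dataclass(frozen=True)
class ReferenceStats:
    """Per-property mean and SD over a reference active set."""

    mean: dict[str, float]
    sd: dict[str, float]
    n: int

    @classmethod
    def from_molecules(cls, mols: list[Molecule]) -> "ReferenceStats":
        if len(mols) < 2:
            raise ValueError("reference stats need >= 2 molecules")
        table = np.array([compute_properties(m).as_array() for m in mols], dtype=float)
        means = table.mean(axis=0)
        sds = table.std(axis=0, ddof=0)
        fields = PropertyVector.FIELDS
        return cls(
            mean={f: float(v) for f, v in zip(fields, means)},
            sd={f: float(v) for f, v in zip(fields, sds)},
            n=len(mols),
        )

    def window(self, prop: str, k_sd: float) -> tuple[float, float]:
        m, s = self.mean[prop], self.sd[prop]
        return m - k_sd * s, m + k_sd * s

    def contains(self, props: PropertyVector, k_sd: float) -> bool:
        for f in PropertyVector.FIELDS:
            lo, hi = self.window(f, k_sd)
            v = float(getattr(props, f))
            if v < lo - 1e-9 or v > hi + 1e-9:
                return False
        return True


def property_filter(
    mols: list[Molecule],
    stats: ReferenceStats,
    k_sd: float = DEFAULT_K_SD,
    charge_rule: bool = True,
) -> list[Molecule]:
    """Keep molecules inside the mean +- k_sd*SD window for every property.

    With ``charge_rule`` set, additionally requires a neutral or positive
    formal charge.  Order-preserving and idempotent.
    """
    if not k_sd > 0:
        raise ValueError("k_sd must be > 0")
    out = []
    for m in mols:
        p = compute_properties(m)
        if charge_rule and p.formal_charge < 0:
            continue
        if stats.contains(p, k_sd):
            out.append(m)
    return out


def build_decoy_set(
    actives: list[Molecule],
    pool: list[Molecule],
    n: int,
    seed: int,
    k_sd: float = DEFAULT_K_SD,
) -> list[Molecule]:
    """Sample ``n`` property-matched decoys from a pre-filtered pool.

    Sampling is uniform without replacement under the given seed; every
    returned decoy is asserted to sit inside the +-k_sd*SD property window of
    the actives, so enrichment cannot come from trivial property separation.
    """
    if n == 0:
        return []
    if len(pool) < n:
        raise ValueError(f"decoy pool has {len(pool)} molecules, need {n}")
    stats = ReferenceStats.from_molecules(actives)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    chosen = [pool[i] for i in sorted(idx)]
    for m in chosen:
        if not stats.contains(compute_properties(m), k_sd):
            raise ValueError(f"decoy {m.id!r} falls outside the +-{k_sd}SD window")
    return chosen


def screen(
    model: PharmacophoreModel, mols: list[Molecule]
) -> list[tuple[str, float]]:
    """Map every molecule onto the model; ranked (id, fit) hit list.

    Molecules that do not map (no valid assignment) are excluded.  Sorted by
    fit descending with a deterministic tie-break on id.
    """
    hits = []
    for m in mols:
        result = map_ligand(model, m)
        if result is not None:
            hits.append((m.id, result.fit_value))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


@dataclass
class EnrichmentResult:
    """Ranked screen with ROC points, AUC, and the full-recall cutoff."""

    ranked: list[tuple[str, float, bool]]  # (id, fit, is_active), fit desc
    roc_points: list[tuple[float, float]]  # (fpr, tpr)
    auc: float
    full_recall_cutoff: float
    fpr_at_full_recall: float = field(default=float("nan"))

    def retrieved_at_cutoff(self) -> list[str]:
        return [mid for mid, fit, _ in self.ranked if fit >= self.full_recall_cutoff]


def roc_enrichment(
    scores: list[tuple[str, float]],
    active_ids: set[str],
    all_ids: list[str] | None = None,
) -> EnrichmentResult:
    """ROC enrichment of a ranked screen against a known-active id set.

    ``scores`` holds the scored (mapped) molecules; ids listed in ``all_ids``
    but absent from ``scores`` are treated as not retrieved (score -inf).
    The full-recall cutoff is the minimum fit value over the actives, the
    highest threshold at which the true-positive rate is 1.
    """
    scored = dict(scores)
    ids = list(scored)
    if all_ids is not None:
        ids = list(all_ids)
    values = np.array([scored.get(i, -np.inf) for i in ids], dtype=float)
    labels = np.array([i in active_ids for i in ids], dtype=bool)
    if not labels.any():
        raise UndefinedROCError("no active molecule among the scored ids")
    if labels.all():
        raise UndefinedROCError("no decoy molecule among the scored ids")
    finite = values[np.isfinite(values)]
    floor = (finite.min() - 1.0) if finite.size else -1.0
    sk_scores = np.where(np.isfinite(values), values, floor)
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), sk_scores)
    auc = float(np.trapezoid(tpr, fpr))
    cutoff = float(values[labels].min())
    retrieved = values >= cutoff if np.isfinite(cutoff) else np.ones_like(labels)
    fpr_at = float(retrieved[~labels].sum() / max(1, (~labels).sum()))
    ranked_idx = sorted(range(len(ids)), key=lambda j: (-values[j], ids[j]))
    ranked = [(ids[j], float(values[j]), bool(labels[j])) for j in ranked_idx]
    return EnrichmentResult(
        ranked=ranked,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        full_recall_cutoff=cutoff,
        fpr_at_full_recall=fpr_at,
    )


# ---------------------------------------------------------------------------
# Fingerprint similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary fingerprint with its generating parameters."""

    bits: frozenset[int]
    length: int = FINGERPRINT_BITS
    params: str = f"rdkit-path:maxPath={FINGERPRINT_MAX_PATH},bits={FINGERPRINT_BITS}"

    @classmethod
    def from_molecule(cls, mol: Molecule) -> "BitFingerprint":
        fp = Chem.RDKFingerprint(
            mol.rdmol, maxPath=FINGERPRINT_MAX_PATH, fpSize=FINGERPRINT_BITS
        )
        return cls(bits=frozenset(fp.GetOnBits()))


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient SA/(SA+SB+SC).

    SA counts AND bits (present in both), SB bits only in ``a``, SC bits only
    in ``b``; the denominator is the OR bit count.  Two empty fingerprints
    are 0 by convention.
    """
    if a.length != b.length:
        raise ValueError("fingerprint length mismatch")
    sa = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return sa / union if union else 0.0


def similarity_matrix(
    mols_a: list[Molecule], mols_b: list[Molecule]
) -> np.ndarray:
    """Pairwise Tanimoto matrix, element (i, j) = T(fp(a_i), fp(b_j))."""
    fps_a = [BitFingerprint.from_molecule(m) for m in mols_a]
    fps_b = [BitFingerprint.from_molecule(m) for m in mols_b]
    out = np.zeros((len(fps_a), len(fps_b)), dtype=float)
    for i, fa in enumerate(fps_a):
        for j, fb in enumerate(fps_b):
            out[i, j] = tanimoto(fa, fb)
    return out
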