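"""End-to-end orchestration of the two analyses, with run manifests.

``run_screen_pipeline`` drives the ligand-based chain: prepare actives ->
build/accept the pharmacophore model -> generate property-matched decoys ->
screen -> ROC enrichment -> full-recall cutoff -> hit table -> similarity of
hits versus actives.  ``run_pose_pipeline`` drives the structure-based
chain: pose fingerprints -> Hamming/hierarchical clustering -> constraint
filters.  Both write their stage outputs plus a JSON manifest of config,
seeds and per-file SHA-256 digests; reruns with identical config and seed
reproduce identical digests (timestamps excluded).

A single config dictionary governs all thresholds; every default equals the
stated protocol value (IC50 cutoffs 0.05/1 uM, +-4SD property window,
1.6 A tolerance spheres, 4 A contact cutoff) and is echoed into the
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import synthdata
from .chemstruct import Molecule, write_sdf
from .complexes import (
    ComplexStructure,
    apply_pose_filters,
    cluster_poses,
    interaction_fingerprint,
)
from .pharmacophore import PharmacophoreModel
from .screening import (
    EnrichmentResult,
    ReferenceStats,
    roc_enrichment,
    screen,
    similarity_matrix,
)

logger = logging.getLogger("pharmscreen")

DEFAULT_SCREEN_CONFIG: dict[str, Any] = {
    "seed": 7,
    "n_actives": 56,
    "n_decoys": 500,
    "noise": 0.2,
    "k_sd": 4.0,
    "tolerance": 1.6,
}

DEFAULT_POSE_CONFIG: dict[str, Any] = {
    "seed": 0,
    "n_active_poses": 20,
    "n_inactive_poses": 20,
    "flip_prob": 0.05,
    "linkage": "average",
    "chain": "A",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict[str, Any]
    seed: int
    stages: dict[str, dict[str, str]]
    timestamp: float

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _record(manifest: RunManifest, stage: str, files: list[Path]) -> None:
    manifest.stages[stage] = {p.name: _sha256(p) for p in files}


def run_screen_pipeline(
    config: dict[str, Any] | None = None,
    out_dir: str | Path = "screen_run",
    model: PharmacophoreModel | None = None,
    actives: list[Molecule] | None = None,
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Ligand-based screen with enrichment; returns (enrichment, hit table).

    The hit table keeps only molecules whose fit value reaches the
    full-recall cutoff, mirroring the protocol of retaining hits scoring at
    least as well as the worst-recovered known active.
    """
    cfg = {**DEFAULT_SCREEN_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]), stages={}, timestamp=time.time())
    seed = int(cfg["seed"])

    try:
        stage = "prepare_actives"
        if model is None:
            model = synthdata.reference_pharmacophore(tolerance=float(cfg["tolerance"]))
        if actives is None:
            actives = synthdata.gen_actives(
                model, n=int(cfg["n_actives"]), noise=float(cfg["noise"]), seed=seed
            )
        if not actives:
            raise PipelineError(stage, "no reference actives configured")
        write_sdf(actives, out / "actives.sdf")
        model.to_json(out / "model.json")
        _record(manifest, stage, [out / "actives.sdf", out / "model.json"])

        stage = "decoys"
        stats = ReferenceStats.from_molecules(actives)
        decoys = synthdata.gen_decoys(
            stats, n=int(cfg["n_decoys"]), seed=seed, model=model, k_sd=float(cfg["k_sd"])
        )
        write_sdf(decoys, out / "decoys.sdf")
        _record(manifest, stage, [out / "decoys.sdf"])

        stage = "screen"
        library = actives + decoys
        hits = screen(model, library)
        pd.DataFrame(hits, columns=["id", "fit"]).to_csv(out / "fits.csv", index=False)
        _record(manifest, stage, [out / "fits.csv"])

        stage = "roc"
        active_ids = {m.id for m in actives}
        enrich = roc_enrichment(hits, active_ids, all_ids=[m.id for m in library])
        pd.DataFrame(enrich.roc_points, columns=["fpr", "tpr"]).to_csv(
            out / "roc.csv", index=False
        )
        _record(manifest, stage, [out / "roc.csv"])

        stage = "cutoff"
        hit_rows = [
            {"id": mid, "fit": fit, "is_active": act, "rank": r + 1}
            for r, (mid, fit, act) in enumerate(enrich.ranked)
            if fit >= enrich.full_recall_cutoff
        ]
        hit_table = pd.DataFrame(hit_rows, columns=["id", "fit", "is_active", "rank"])
        hit_table.to_csv(out / "hits.csv", index=False)
        _record(manifest, stage, [out / "hits.csv"])

        stage = "similarity"
        by_id = {m.id: m for m in library}
        hit_mols = [by_id[r["id"]] for r in hit_rows if not r["is_active"]]
        max_sim = 0.0
        if hit_mols:
            sim = similarity_matrix(hit_mols, actives)
            max_sim = float(sim.max())
        summary = {
            "auc": enrich.auc,
            "full_recall_cutoff": enrich.full_recall_cutoff,
            "fpr_at_full_recall": enrich.fpr_at_full_recall,
            "n_actives": len(actives),
            "n_decoys": len(decoys),
            "n_hits_at_cutoff": len(hit_rows),
            "max_hit_to_active_tanimoto": max_sim,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        _record(manifest, stage, [out / "summary.json"])
    except PipelineError:
        manifest.write(out / "manifest.json")
        raise
    except Exception as exc:  # abort with stage name and partial manifest
        manifest.write(out / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc

    manifest.write(out / "manifest.json")
    return enrich, hit_table


def run_pose_pipeline(
    config: dict[str, Any] | None = None,
    out_dir: str | Path = "pose_run",
    poses: list[ComplexStructure] | None = None,
) -> dict[str, Any]:
    """Pose fingerprints -> clustering -> structure-based filters.

    Returns a dict with the fingerprints, the cluster tree (None for a
    single pose) and the filter report.
    """
    cfg = {**DEFAULT_POSE_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]), stages={}, timestamp=time.time())
    chain = str(cfg["chain"])

    try:
        stage = "poses"
        if poses is None:
            poses, _labels = synthdata.gen_pose_set(
                n_active=int(cfg["n_active_poses"]),
                n_inactive=int(cfg["n_inactive_poses"]),
                flip_prob=float(cfg["flip_prob"]),
                seed=int(cfg["seed"]),
                chain=chain,
            )
        if not poses:
            raise PipelineError(stage, "no poses configured")

        stage = "fingerprints"
        site = synthdata.site_residue_keys(chain)
        fps = [interaction_fingerprint(cx, site) for cx in poses]
        table = pd.DataFrame(
            [fp.bits for fp in fps],
            index=[fp.pose_id for fp in fps],
            columns=[f"{rid}|{ch}" for rid, ch in fps[0].index_map],
        )
        table.to_csv(out / "fingerprints.csv")
        (out / "index_map.json").write_text(
            json.dumps(
                {"channels": "HBOND,CHARGED,PI (pi-pi and pi-cation merged)",
                 "columns": [f"{rid}|{ch}" for rid, ch in fps[0].index_map]},
                indent=2,
            )
        )
        _record(manifest, stage, [out / "fingerprints.csv", out / "index_map.json"])

        stage = "clustering"
        tree = None
        if len(fps) >= 2:
            tree = cluster_poses(fps, linkage=str(cfg["linkage"]))
            (out / "dendrogram.nwk").write_text(tree.to_newick())
            _record(manifest, stage, [out / "dendrogram.nwk"])
        else:
            logger.warning("single pose: clustering skipped")

        stage = "filters"
        rules = synthdata.default_pose_filter_rules(chain)
        passed, failed = apply_pose_filters(poses, rules)
        report = pd.DataFrame(
            [{"pose_id": cx.pose_id, "passed": True, "reason": ""} for cx in passed]
            + [{"pose_id": cx.pose_id, "passed": False, "reason": r} for cx, r in failed]
        ).sort_values("pose_id").reset_index(drop=True)
        report.to_csv(out / "filter_report.csv", index=False)
        _record(manifest, stage, [out / "filter_report.csv"])
    except PipelineError:
        manifest.write(out / "manifest.json")
        raise
    except Exception as exc:
        manifest.write(out / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc

    manifest.write(out / "manifest.json")
    return {"fingerprints": fps, "tree": tree, "filter_report": report}
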