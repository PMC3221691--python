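# pharmscreen

A Python toolkit for the computational chain used in ligand-based discovery
of small-molecule GPCR antagonist candidates — built around the prokineticin
receptor style of campaign, where a handful of potent antagonists with a
shared scaffold is leveraged into a pharmacophore screen, and docked poses
are post-processed with structural interaction fingerprints.

It is aimed at cheminformatics practitioners who want each stage of that
chain as a tested, scriptable library call rather than a GUI workflow:

* **SAR matched pairs** — split an antagonist series into actives
  (IC50 < 0.05 µM) and inactives (IC50 > 1 µM), decompose onto a labeled
  scaffold, pair compounds differing at exactly one position, and report
  which chemical feature at each position tracks with activity.
* **Common-feature pharmacophores** — build k-feature models (H-bond
  acceptor, positive ionizable, aromatic ring, hydrophobic) shared by a set
  of reference actives, and score library molecules by geometric fit.
* **Virtual screening with enrichment** — property-matched decoys
  (mean ± 4·SD window over MW, logP, HBD/HBA, rotatable bonds, formal
  charge), ROC curves, AUC, and the full-recall fit-value cutoff.
* **Pose analysis** — per-residue interaction fingerprints (H-bond /
  salt bridge / π channels), Hamming-distance hierarchical clustering, and
  structure-based pose filters over residue roles
  (Glu2.61 / Arg3.32 / Arg6.58 in Ballesteros–Weinstein notation).
* **Synthetic data generators** — seeded constructors for every input
  class (feature-bearing actives, matched decoys, SAR pairs, toy
  binding-site complexes), so the whole pipeline runs and is tested without
  any proprietary structures.

## The core scores

**Pharmacophore fit.** A model is a set of k typed features with centers
*c<sub>f</sub>* and tolerance radii *r<sub>f</sub>* (default 1.6 Å). A
ligand conformer maps when some kind-compatible assignment of its perceived
features, after least-squares rigid superposition, places every feature
within its tolerance sphere (no omitted features by default). The fit value
is

> fit = Σ<sub>f</sub> max(0, 1 − (d<sub>f</sub>/r<sub>f</sub>)²)

with d<sub>f</sub> the post-superposition displacement; a perfect 4-feature
mapping scores exactly 4. The *full-recall cutoff* of a screen is the
highest fit threshold that still retrieves every known active.

**Tanimoto similarity.** For hashed path fingerprints,
T = SA/(SA+SB+SC): AND bits over OR bits.

**Interaction fingerprints.** One bit per (binding-site residue × channel),
channels = {HBOND, CHARGED, PI} with π-π and π-cation pooled; poses are
compared by normalized Hamming distance (fraction of differing
coordinates) and clustered with average linkage.

## Worked example

```bash
pharmscreen pipeline-screen --out-dir run/ --seed 7 --n-actives 12 --n-decoys 60
# AUC 1.0000  cutoff 3.9688  hits 12

pharmscreen pipeline-poses --out-dir poses/ --seed 0
# 40 poses, 14 pass the constraint filters
```

The screen run generates 12 synthetic actives embedding the reference
4-feature pharmacophore (0.2 Å geometric noise) among 60 property-matched
decoys, maps all 72 molecules, and reports a perfect ROC (AUC 1.0): the
worst-scoring active sets the full-recall cutoff at fit 3.9688, and exactly
the 12 actives reach it — none of the decoys can map at all, because each
lacks a feature kind or violates the model geometry. Outputs (`fits.csv`,
`roc.csv`, `hits.csv`, `summary.json`, and a digest manifest) land in
`run/`.

The pose run generates 20 active-pattern and 20 inactive-pattern toy
complexes with 5% bit-flip noise, writes their fingerprints and dendrogram,
and applies the three structure-based constraints (salt bridge to the
Glu-role residue; ≥1 H-bond and ≥2 π interactions with the Arg-role
residues). The 14 passing poses are exactly the active-pattern poses whose
noisy fingerprints still satisfy all three constraints.

Mapping the generated actives back onto the model from Python:

```python
from pharmscreen import map_ligand, gen_actives, reference_pharmacophore

model = reference_pharmacophore()
for mol in gen_actives(model, n=3, noise=0.2, seed=7):
    print(mol.id, round(map_ligand(model, mol).fit_value, 3))
# active_000 3.984
# active_001 3.989
# active_002 3.983
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time, (t1) the fit value of a
zero-displacement ligand on a four-feature model and (t2) the percentage of
56 synthetic actives retrieved from a 556-molecule screen when thresholding
at the computed full-recall cutoff, and writes them as JSON.

## Layout

```
src/pharmscreen/
  chemstruct.py     molecules, I/O, protonation, properties, conformers, features
  pharmacophore.py  models, mapping, fit values, common-feature search
  screening.py      property filter, decoys, screening, ROC, Tanimoto
  sar.py            activity classes, matched pairs, position rules
  complexes.py      PDB complexes, interactions, fingerprints, clustering, filters
  synthdata.py      seeded generators for every input class
  pipeline.py       end-to-end orchestration with manifests
  cli.py            thin click front-end (`pharmscreen ...`)
```

See `docs/methods.md` for the scientific conventions, parameter defaults
and known limitations.
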