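# Methods

This note records the scientific conventions behind `pharmscreen`: the
models implemented, the parameter defaults and their rationale, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the underlying protocols are not fully specified in public
sources.

## 1. Molecular model and feature perception

Molecules are RDKit `Mol` objects wrapped with an id, optional IC50
annotation (µM, calcium-mobilization antagonism convention) and
per-conformer energies. Coordinates are Å throughout; "heavy atoms"
always excludes hydrogen.

Chemical features are perceived by a fixed, Catalyst-like rule set
(commercial perception engines are proprietary, so the rules are declared
here and used consistently on both model and library sides):

| kind | rule | centroid |
|---|---|---|
| HBD | N or O bearing ≥1 H | the atom |
| HBA | N or O with a lone pair; excludes amide N, aromatic N–H, N⁺, and neutral N conjugated into an amidinium/guanidinium cation | the atom |
| POS_IONIZABLE | group carrying +1 after protonation: guanidinium (C+3N), amidinium (C+2N), protonated amine (N) | group centroid |
| AROMATIC | each SSSR aromatic ring | ring centroid, direction = ring normal |
| HYDROPHOBIC | connected fragment of ≥3 non-aromatic carbons, none touching a heteroatom | fragment centroid |

Because feature definitions are purely atom-typed and geometric, perception
is invariant under rigid motion and independent of conformer order.

**Protonation** is rule-based at a fixed pH of 7.5 (no pKa prediction):
guanidines/amidines protonate on the sp2 nitrogen, aliphatic amines gain
+1 (anilines and amides stay neutral), carboxylic acids deprotonate. This
replaces per-ligand pKa calculation with a transparent table; it is correct
for the chemotypes this package generates and screens.

**Properties** for the ±k·SD pre-filter are MW, Crippen logP (an
atomic-contribution *estimate*, internally consistent but not any
commercial AlogP), HBD/HBA per the table above, strict rotatable-bond
count (acyclic single bonds between non-terminal heavy atoms, amides
excluded) and net formal charge. Only window membership matters for
filtering, so estimator bias cancels between actives and decoys.

**Conformers** come from ETKDG distance-geometry embedding with MMFF
(UFF fallback) minimization, sorted by energy, de-duplicated at 0.5 Å
heavy-atom RMSD and truncated to an energy window. Defaults: ≤50
conformers within 20 kcal/mol of the minimum. The seed is a required
argument; embedding is reproducible for a fixed seed. The force field and
the de-duplication radius are this package's choices — the "best quality"
conformer criterion of commercial tools is not public.

## 2. Pharmacophore models, mapping and fit

A model holds k ≥ 2 typed features with tolerance radii (default 1.6 Å, a
common tolerance-sphere default), a minimum inter-feature distance
(default 1.0 Å, enforced at construction) and a maximum number of omitted
features (default 0: every feature must be matched).

`map_ligand` searches over all conformers, all omission subsets, and all
injective kind-compatible assignments of perceived ligand features to
model features. Each candidate assignment is scored after Kabsch
least-squares superposition of the assigned ligand centroids onto the
model centers; an assignment is valid only if every non-omitted
displacement d_f ≤ r_f (and, for directional model features, the
transformed ligand direction is within the angular tolerance, default 45°,
sign-insensitive since ring normals are axial). The fit value is

    fit = Σ_f max(0, 1 − (d_f / r_f)²)

with unit weights, which makes the feature count the exact upper bound
(4 for a four-feature model, attained at zero displacement). Ties are
broken deterministically: higher fit, then lower conformer energy, then
lexicographically smaller assignment. The search is exhaustive — for
drug-sized molecules (≲12 features, ≲50 conformers) this is fast, and a
brute-force oracle in the tests confirms exact equivalence.

**Common-feature model construction** is a bounded reimplementation of the
common-feature idea: k-subsets of the *most active* reference's features
(largest k first) are retained when every other reference presents a
kind-matched feature set whose pairwise distance matrix agrees within
2× tolerance; at most 10 models are emitted, ranked by (k descending,
mean cross-reference distance mismatch ascending). Two deliberate
restrictions:

* The candidate feature types default to {HBA, POS_IONIZABLE, AROMATIC,
  HYDROPHOBIC} with at most one feature per kind. Donor features are
  excluded by default because on cationic scaffolds the N–H donors ride
  rigidly with the ionizable group, and intra-group subsets would dominate
  the mismatch ranking with chemically degenerate hypotheses. This mirrors
  the feature-dictionary selection step of interactive pharmacophore
  tools; both the kind list and the per-kind cap are arguments.
* Emitted models are point-feature models (no direction vectors): the
  cross-reference agreement check covers centers only, so inherited
  directional constraints would never have been validated.

## 3. Screening, decoys and enrichment

Libraries are pre-filtered to the mean ± k·SD window (default k = 4) of
the reference actives' property vector, optionally requiring neutral-or-
positive formal charge (the known actives are cations). The filter is
order-preserving and idempotent. Decoy sets are sampled uniformly without
replacement under a single stated seed, and every decoy is asserted to lie
inside the window, so enrichment cannot come from trivial property
separation.

`screen` maps every molecule and ranks by fit (ties broken by id).
Molecules that fail to map are "not retrieved": they enter the ROC with
score −∞. ROC points come from a descending threshold sweep
(scikit-learn), AUC by trapezoid. The **full-recall cutoff** is defined as
the minimum fit value over the actives — the highest threshold with
sensitivity 1 — and thresholding is inclusive (fit ≥ cutoff), matching the
convention of retaining hits that score at least as well as the
worst-recovered known active.

Similarity uses hashed path-based fingerprints (2048 bits, paths ≤ 7
bonds) and the Tanimoto coefficient SA/(SA+SB+SC); two empty fingerprints
score 0 by convention. The fingerprint type is fixed so thresholds are
internally comparable; absolute values are not comparable to other
fingerprint systems.

## 4. SAR matched pairs

Activity classes use strict thresholds: active iff IC50 < 0.05 µM,
inactive iff IC50 > 1 µM, excluded otherwise (boundary values are
excluded). Decomposition uses R-group decomposition against a declared
core with labeled attachment points (A1, D, L2, Q) rather than generic
MCS, because the compound series shares one fixed scaffold; "chemical
group" granularity is the whole substituent at a labeled position. A
matched pair is an (active, inactive) combination identical at every
position but one. Per-position rules flag a feature kind "required" when
it is present in every active-side substituent at that position and absent
from at least one inactive counterpart.

## 5. Complexes, interactions and pose analysis

Complexes hold binding-site residues (side-chain fragments with an
optional CA; no backbone model) and one ligand pose in a shared frame.
PDB I/O goes through biotite; ligand connectivity is inferred from
interatomic distances when CONECT records are absent (1.75 Å heavy-atom
cutoff, 1.95 Å for sulfur, 1.3 Å for H attachment).

Geometric interaction criteria (one config block; the named interaction
types of the source protocols never came with published thresholds, so
standard literature values are used):

* **H-bond**: donor–acceptor heavy atoms ≤ 3.5 Å; if the donor hydrogen is
  present, D–H…A ≥ 120°; without explicit H the distance rule alone
  applies (the common situation for X-ray protein sides).
* **Salt bridge**: opposite formal-charge group centroids ≤ 5.5 Å.
* **π-π**: ring centroids ≤ 5.5 Å with interplanar angle ≤ 30°
  (parallel), or 60–120° at ≤ 6.0 Å (T-shaped).
* **π-cation**: cation group centroid ≤ 6.0 Å from the ring centroid and
  ≤ 30° off the ring normal (both protein-cation/ligand-ring and
  ligand-cation/protein-ring directions).
* Every interaction additionally requires ≥1 protein–ligand heavy-atom
  pair strictly below the 4 Å contact cutoff, so interaction bits always
  imply van der Waals contact records. All distance cutoffs are strict
  where the protocol says "less than".

Fingerprints use three channels per residue — HBOND, CHARGED and a merged
PI channel (π-π and π-cation pooled, since the clustered categories pool
them; the merge is recorded in the output metadata). Contacts that are
van der Waals-only are reported but not fingerprinted. Pose distances are
normalized Hamming distances; clustering is agglomerative with average
linkage by default (the clustering tool's defaults are unstated upstream;
the choice is configurable), delegated to scipy on the exact Hamming
matrix.

Pose filters implement the three-constraint set in residue-role form so
they work on any numbering: (1) a salt bridge with the Glu-role residue,
(2) ≥1 H-bond with the Arg-role residues, (3) ≥2 π interactions with the
Arg-role residues; failures name the first violated constraint. Note that
constraint 3 forces at least one arginine to engage in both a hydrogen
bond or π interaction *and* a second π contact — a pose realizing only a
minimal three-interaction signature does not pass.

**Validation metrics**: ligand RMSD superposes the docked receptor's CA
atoms onto the reference (Kabsch; identity when fewer than 3 shared CAs),
then minimizes the heavy-atom RMSD over all element-preserving
automorphisms of the ligand bond graph (so a 60°-rotated benzene scores
0). Contact recovery is |docked ∩ reference| / |reference| over 4 Å
heavy-atom contact sets; residue recovery is the analogue over residues
within 4 Å of the ligand.

## 6. The synthetic world

The generators stand in for three proprietary/external inputs: a patent
antagonist series, a ZINC-derived decoy library, and docked pose sets.
All are pure functions of (parameters, seed); per-item RNG streams derive
from `[seed, item_index]`, so extending a set never reshuffles earlier
items.

* **Actives** (default n = 56, noise 0.2 Å, seed 7 — the stated campaign
  conditions) are built around an abstract guanidinium / aromatic /
  carbonyl / alkyl scaffold echoing the guanidine-triazinedione chemotype
  without reproducing any real structure: a benzene hub carries an
  aldehyde arm (HBA on the O), an aryl-guanidinium arm (+1 group centroid
  on target) and an ether-linked alkyl arm (3-carbon hydrophobic fragment
  centered on target). Feature groups land exactly on the jittered
  targets (independent uniform-in-ball jitter ≤ noise per feature, then a
  random rigid placement); realization is verified at build time.
  Decorations (0–2 methyls, 0–1 methoxy, chain length 0–2) give the
  property vector realistic spread for the ±4SD machinery. IC50s are
  log-uniform below 0.05 µM.
* **Decoys** cycle three constructions: saturated hub (no aromatic
  feature), polyether arm (no hydrophobic fragment), and full feature
  complement with all inter-feature distances scaled ×2 (unmatchable
  within 1.6 Å tolerance). All keep the guanidinium (+1) so the charge
  rule and HBD counts match the actives; decoration draws are retried
  until the molecule sits inside the actives' ±4SD window. With omissions
  disabled, none of the three constructions can map, which is what makes
  the full-recall cutoff clean.
* **Matched pairs** are assembled on a triazinone-like core (one C=O, one
  C=S — the thiocarbonyl breaks a ring automorphism that would otherwise
  make two positions indistinguishable to decomposition). The planted
  rule position carries a substituent with exactly the planted feature
  kinds on the active side; inactive counterparts cycle through variants
  so every planted kind is absent from at least one of them (necessary
  for exact rule recovery). A pair-unique alkyl tag at a non-rule
  position prevents accidental cross-pairs.
* **Toy complexes** place side-chain fragments (Glu, Arg, Thr, Asn, Phe,
  Cys, Met templates with ideal local geometry) on interaction "slots"
  around a fixed 14-heavy-atom ligand (benzene ring, carbonyl acceptor,
  aryl-guanidinium, ring methoxy): donor slots fan around the carbonyl O
  at 2.9 Å, the carboxylate slot faces the guanidinium at 3.9 Å, π slots
  sit on the ring normal (3.3 Å cation / 3.8 Å stacking), and one
  combined slot lets an arginine both donate to the ring-ether O and
  π-stack — required by filter constraint 3. Unused roster residues are
  parked > 20 Å away, so all poses share one fingerprint index map. The
  realized fingerprint is verified against the request before returning;
  a global seeded rigid transform exercises frame invariance.

What the generators do **not** emulate: force-field-plausible geometry
(linkers are placed on straight or gently bent paths; bond lengths and
angles are not relaxed — non-finite hydrogen positions occasionally
produced by RDKit's H-placement at such angles are repaired
deterministically), conformational ensembles of the synthetic actives
(one conformer each), tautomers/stereochemistry, realistic decoy chemistry
diversity (three construction families, not a ZINC-scale library), or
backbone structure in the toy complexes. A green test therefore
establishes the correctness of the *algorithms* under controlled truth,
not the campaign-level performance numbers of any real screen; published
headline values from real campaigns (enrichment against 5909 ZINC decoys,
DrugBank hit counts, similarity maxima, redocking RMSDs) depend on
proprietary software and external datasets and are documentation anchors,
not reproduction targets of this package.

## 7. Numerical conventions

* Distance cutoffs are strict (<) wherever the protocol language is
  "less than"; tolerance comparisons in mapping allow 1e-9 slack for
  float safety.
* Kabsch uses SVD with a determinant sign fix (proper rotations only).
* Degenerate inputs: molecules without conformers or without a required
  feature kind simply do not map; a screen of unmappable molecules yields
  an empty hit list; a ROC without actives (or without decoys) raises;
  clustering requires ≥2 fingerprints and the pipeline downgrades a
  single-pose run to fingerprint + filter with a warning; recovery against
  a contact-free reference raises rather than returning 0/0.
* SD = 0 reference properties (e.g. formal charge over an all-cation
  series) collapse the ±4SD window to equality, compared with 1e-9
  tolerance.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit arguments; hypothesis-based property tests are seeded/derandomized
  by the fixed example corpus.

## 8. Known limitations

* The mapping search is exhaustive over injective assignments; molecules
  with many repeated features (≫10 of one kind) would need pruning.
* Rule-based protonation covers the common ionizable groups only; exotic
  chemotypes (phosphates, tetrazoles, N-oxides) are not in the table.
* The common-feature search anchors centers on the lead reference rather
  than averaging across references, and scores geometric consistency
  only — it does not optimize feature positions.
* Interaction detection trusts residue templates by atom name; nonstandard
  residue naming requires extending the template tables.
* The ligand-automorphism RMSD enumerates graph automorphisms (capped at
  10⁴); highly symmetric ligands beyond that cap would fall back to an
  incomplete minimum.
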