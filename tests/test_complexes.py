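"""Complex parsing, interaction detection, fingerprints, clustering, filters,
and docking-validation metrics."""

import copy
import itertools

import numpy as np
import pytest

from pharmscreen.chemstruct import random_rigid_transform
from pharmscreen.complexes import (
    CONTACT_CUTOFF,
    ComplexStructure,
    FilterConfigError,
    InteractionFingerprint,
    InteractionType,
    Residue,
    SiteAtom,
    apply_pose_filters,
    cluster_poses,
    contact_recovery,
    detect_interactions,
    find_contacts,
    hamming_distance,
    hamming_matrix,
    interaction_fingerprint,
    ligand_rmsd,
    read_complex,
    transform_complex,
    write_complex,
)
from pharmscreen.synthdata import (
    ACTIVE_POSE_PATTERN,
    INACTIVE_POSE_PATTERN,
    default_pose_filter_rules,
    gen_pose_set,
    gen_toy_complex,
    site_residue_keys,
)


@pytest.fixture(scope="module")
def active_cx():
    return gen_toy_complex(ACTIVE_POSE_PATTERN, seed=1, pose_id="active")


class TestPDBIO:
    def test_roundtrip_preserves_structure(self, tmp_path, active_cx):
        path = tmp_path / "cx.pdb"
        write_complex(active_cx, path)
        back = read_complex(path)
        assert len(back.residues) == len(active_cx.residues)
        assert len(back.ligand_atoms) == len(active_cx.ligand_atoms)
        orig = np.array([a.coord for a in active_cx.ligand_atoms])
        rt = np.array([a.coord for a in back.ligand_atoms])
        assert np.abs(orig - rt).max() < 1e-3  # PDB format precision

    def test_roundtrip_preserves_interactions(self, tmp_path, active_cx):
        path = tmp_path / "cx.pdb"
        write_complex(active_cx, path)
        back = read_complex(path)
        site = site_residue_keys()
        assert sorted(interaction_fingerprint(back, site).on_bits()) == sorted(
            interaction_fingerprint(active_cx, site).on_bits()
        )

    def test_missing_ligand_raises(self, tmp_path, active_cx):
        path = tmp_path / "apo.pdb"
        write_complex(active_cx, path)
        stripped = "\n".join(
            ln for ln in path.read_text().splitlines() if not ln.startswith("HETATM")
        )
        path.write_text(stripped + "\n")
        with pytest.raises(ValueError, match="no ligand"):
            read_complex(path)


class TestContacts:
    def _two_atom_complex(self, distance):
        res = Residue(
            name="ALA", seq_number=1, chain="A",
            atoms=[SiteAtom("CB", "C", np.array([distance, 0.0, 0.0]))],
        )
        lig = [SiteAtom("L1", "C", np.zeros(3))]
        return ComplexStructure([res], lig, pose_id="t")

    def test_below_cutoff_is_contact(self):
        cx = self._two_atom_complex(3.9)
        assert len(find_contacts(cx)) == 1

    def test_exactly_cutoff_excluded(self):
        cx = self._two_atom_complex(4.0)
        assert find_contacts(cx) == []  # strictly less than 4 A

    def test_matches_brute_force_enumeration(self, active_cx):
        ours = {(k, an, j) for k, an, j, _ in find_contacts(active_cx)}
        brute = set()
        for r in active_cx.residues:
            for a in r.atoms:
                if a.element == "H":
                    continue
                for j, la in enumerate(active_cx.ligand_atoms):
                    if la.element == "H":
                        continue
                    if np.linalg.norm(a.coord - la.coord) < CONTACT_CUTOFF:
                        brute.add((r.key, a.name, j))
        assert ours == brute


class TestInteractionDetection:
    def test_active_pattern_kinds(self, active_cx):
        kinds = {
            (i.kind, i.residue_key) for i in detect_interactions(active_cx)
        }
        assert (InteractionType.CHARGED, ("A", 119)) in kinds
        assert (InteractionType.HBOND, ("A", 307)) in kinds
        assert any(
            k in (InteractionType.PIPI, InteractionType.PICATION) and key == ("A", 144)
            for k, key in kinds
        )

    def test_hbond_geometry(self):
        cx = gen_toy_complex((("HBOND", "ARG", 144),), seed=3)
        hbonds = [i for i in detect_interactions(cx) if i.kind == InteractionType.HBOND]
        assert len(hbonds) == 1
        assert hbonds[0].residue_key == ("A", 144)
        assert hbonds[0].distance <= 3.5

    def test_charged_geometry(self):
        cx = gen_toy_complex((("CHARGED", "GLU", 119),), seed=4)
        charged = [i for i in detect_interactions(cx) if i.kind == InteractionType.CHARGED]
        assert len(charged) == 1
        assert charged[0].distance <= 5.5

    def test_pication_geometry(self):
        cx = gen_toy_complex((("PI", "ARG", 307),), seed=5)
        pis = [i for i in detect_interactions(cx) if i.kind == InteractionType.PICATION]
        assert len(pis) == 1

    def test_pipi_stacking(self):
        cx = gen_toy_complex((("PI", "PHE", 300),), seed=6)
        pis = [i for i in detect_interactions(cx) if i.kind == InteractionType.PIPI]
        assert len(pis) == 1

    def test_interactions_imply_contacts(self, pose_set):
        poses, _ = pose_set
        for cx in poses[:10]:
            contact_res = {k for k, _, _, _ in find_contacts(cx)}
            for inter in detect_interactions(cx):
                assert inter.residue_key in contact_res

    def test_rigid_invariance(self, active_cx, rng):
        base = sorted(
            (i.kind.value, i.residue_key) for i in detect_interactions(active_cx)
        )
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            moved = transform_complex(active_cx, R, t)
            assert sorted(
                (i.kind.value, i.residue_key) for i in detect_interactions(moved)
            ) == base


class TestFingerprint:
    def test_far_ligand_zero_vector(self):
        cx = gen_toy_complex((), seed=7)
        fp = interaction_fingerprint(cx, site_residue_keys())
        assert fp.bits.sum() == 0

    def test_active_pattern_bits_exact(self, active_cx):
        fp = interaction_fingerprint(active_cx, site_residue_keys())
        assert sorted(fp.on_bits()) == sorted(
            [
                ("A:GLU:119", "CHARGED"),
                ("A:ARG:144", "PI"),
                ("A:ARG:307", "HBOND"),
                ("A:ARG:307", "PI"),
            ]
        )

    def test_consistent_with_detect_interactions(self, active_cx):
        site = site_residue_keys()
        fp = interaction_fingerprint(active_cx, site)
        recomputed = interaction_fingerprint(
            active_cx, site, interactions=detect_interactions(active_cx)
        )
        assert np.array_equal(fp.bits, recomputed.bits)

    def test_unknown_residue_raises(self, active_cx):
        with pytest.raises(KeyError):
            interaction_fingerprint(active_cx, [("A", 999)])

    def test_vector_length(self, active_cx, site_keys):
        fp = interaction_fingerprint(active_cx, site_keys)
        assert len(fp.bits) == 3 * len(site_keys)


class TestHamming:
    def _fp(self, bits):
        arr = np.asarray(bits, dtype=np.uint8)
        index_map = tuple((f"A:RES:{i}", "HBOND") for i in range(len(arr)))
        return InteractionFingerprint(bits=arr, index_map=index_map)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0, 1, 0], [1, 0, 1, 0], 0.0),
            ([1, 0, 1, 0], [0, 1, 0, 1], 1.0),
            ([1, 0, 1, 0], [1, 1, 1, 1], 0.5),
        ],
    )
    def test_fraction_of_differing_coordinates(self, a, b, expected):
        assert hamming_distance(self._fp(a), self._fp(b)) == pytest.approx(expected)

    def test_metric_axioms_on_random_triples(self, rng):
        n, length = 1000, 24
        vecs = rng.integers(0, 2, size=(3 * n, length))
        for i in range(n):
            a, b, c = (self._fp(vecs[3 * i + j]) for j in range(3))
            dab, dba = hamming_distance(a, b), hamming_distance(b, a)
            assert dab == dba  # symmetry
            assert hamming_distance(a, a) == 0.0  # identity
            assert dab <= hamming_distance(a, c) + hamming_distance(c, b) + 1e-12

    def test_index_map_mismatch_raises(self):
        a = self._fp([1, 0])
        b = InteractionFingerprint(
            bits=np.array([1, 0], dtype=np.uint8),
            index_map=(("A:OTHER:1", "HBOND"), ("A:OTHER:2", "HBOND")),
        )
        with pytest.raises(ValueError):
            hamming_distance(a, b)

    def test_matrix_matches_scipy(self, rng):
        from scipy.spatial.distance import pdist, squareform

        fps = [self._fp(rng.integers(0, 2, size=24)) for _ in range(12)]
        ours = hamming_matrix(fps)
        ref = squareform(pdist(np.array([f.bits for f in fps]), metric="hamming"))
        assert np.allclose(ours, ref)


class TestClustering:
    def _fp(self, bits, pose_id):
        arr = np.asarray(bits, dtype=np.uint8)
        index_map = tuple((f"A:RES:{i}", "HBOND") for i in range(len(arr)))
        return InteractionFingerprint(bits=arr, index_map=index_map, pose_id=pose_id)

    def test_two_identical_groups_split_cleanly(self):
        fps = [self._fp([1, 1, 0, 0], f"a{i}") for i in range(3)] + [
            self._fp([0, 0, 1, 1], f"b{i}") for i in range(3)
        ]
        tree = cluster_poses(fps)
        assert tree.merge_heights()[0] == pytest.approx(0.0)
        cut = tree.cut(2)
        groups = {}
        for pid, cl in cut.items():
            groups.setdefault(cl, set()).add(pid[0])
        assert sorted(groups.values(), key=len) == [{"a"}, {"b"}] or sorted(
            groups.values(), key=len
        ) == [{"b"}, {"a"}]

    def test_merge_heights_nondecreasing(self, pose_set, site_keys):
        poses, _ = pose_set
        fps = [interaction_fingerprint(cx, site_keys) for cx in poses]
        tree = cluster_poses(fps)
        heights = tree.merge_heights()
        assert np.all(np.diff(heights) >= -1e-12)
        assert sorted(tree.leaf_ids) == sorted(cx.pose_id for cx in poses)

    def test_planted_two_class_recovery(self, pose_set, site_keys):
        poses, labels = pose_set
        fps = [interaction_fingerprint(cx, site_keys) for cx in poses]
        cut = cluster_poses(fps).cut(2)
        for cl in set(cut.values()):
            members = [labels[pid] for pid, c in cut.items() if c == cl]
            purity = max(members.count("active"), members.count("inactive")) / len(members)
            assert purity >= 0.9

    def test_newick_export_contains_all_leaves(self, pose_set, site_keys):
        poses, _ = pose_set
        fps = [interaction_fingerprint(cx, site_keys) for cx in poses[:6]]
        nwk = cluster_poses(fps).to_newick()
        assert nwk.endswith(";")
        for fp in fps:
            assert fp.pose_id in nwk


class TestPoseFilters:
    def test_pose_meeting_all_constraints_passes(self, active_cx):
        passed, failed = apply_pose_filters([active_cx], default_pose_filter_rules())
        assert [cx.pose_id for cx in passed] == ["active"]
        assert failed == []

    @pytest.mark.parametrize(
        "pattern,constraint",
        [
            # no Glu salt bridge
            ((("PI", "ARG", 144), ("HBOND", "ARG", 307), ("PI", "ARG", 307)), "constraint 1"),
            # no Arg hydrogen bond
            ((("CHARGED", "GLU", 119), ("PI", "ARG", 144), ("PI", "ARG", 307)), "constraint 2"),
            # only one pi interaction
            ((("CHARGED", "GLU", 119), ("HBOND", "ARG", 307), ("PI", "ARG", 307)), "constraint 3"),
        ],
    )
    def test_first_violated_constraint_reported(self, pattern, constraint):
        cx = gen_toy_complex(pattern, seed=11)
        passed, failed = apply_pose_filters([cx], default_pose_filter_rules())
        assert passed == []
        assert failed[0][1].startswith(constraint)

    def test_rule_referencing_absent_residue(self, active_cx):
        rules = default_pose_filter_rules()
        rules.charged_residue = ("A", 999)
        with pytest.raises(FilterConfigError):
            apply_pose_filters([active_cx], rules)


class TestValidationMetrics:
    def test_identity_rmsd_zero(self, active_cx):
        assert ligand_rmsd(active_cx, active_cx) == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_rmsd(self, active_cx):
        moved = copy.deepcopy(active_cx)
        for a in moved.ligand_atoms:
            a.coord = a.coord + np.array([1.0, 0.0, 0.0])
        assert ligand_rmsd(moved, active_cx) == pytest.approx(1.0, abs=1e-9)

    def test_benzene_sixfold_symmetry(self):
        ring = [
            SiteAtom(f"C{i+1}", "C",
                     np.array([1.39 * np.cos(np.radians(60 * i)),
                               1.39 * np.sin(np.radians(60 * i)), 0.0]))
            for i in range(6)
        ]
        res = [Residue("ALA", 1, "A", [SiteAtom("CA", "C", np.array([10.0, 0, 0]))])]
        ref = ComplexStructure(res, ring, pose_id="ref")
        rot = copy.deepcopy(ref)
        th = np.radians(60.0)
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        for a in rot.ligand_atoms:
            a.coord = R @ a.coord
        # atom names now disagree with positions; automorphism matching absorbs it
        assert ligand_rmsd(rot, ref) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_invariance_of_rmsd(self, active_cx, rng):
        R, t = random_rigid_transform(rng)
        moved = transform_complex(active_cx, R, t)
        assert ligand_rmsd(moved, active_cx) == pytest.approx(0.0, abs=1e-6)

    def test_identity_recovery_is_one(self, active_cx):
        rep = contact_recovery(active_cx, active_cx)
        assert rep.contact_recovery == 1.0
        assert rep.residue_recovery == 1.0

    def test_displaced_ligand_recovers_nothing(self, active_cx):
        moved = copy.deepcopy(active_cx)
        for a in moved.ligand_atoms:
            a.coord = a.coord + np.array([50.0, 0.0, 0.0])
        rep = contact_recovery(moved, active_cx)
        assert rep.contact_recovery == 0.0
        assert rep.residue_recovery == 0.0

    def test_perturbed_pose_matches_set_oracle(self, active_cx):
        moved = copy.deepcopy(active_cx)
        for a in moved.ligand_atoms:
            a.coord = a.coord + np.array([1.5, 0.0, 0.0])
        rep = contact_recovery(moved, active_cx)
        ref = {(k, an, j) for k, an, j, _ in find_contacts(active_cx)}
        dock = {(k, an, j) for k, an, j, _ in find_contacts(moved)}
        assert rep.contact_recovery == pytest.approx(len(ref & dock) / len(ref))
        ref_res = {k for k, _, _ in ref}
        dock_res = {k for k, _, _ in dock}
        assert rep.residue_recovery == pytest.approx(
            len(ref_res & dock_res) / len(ref_res)
        )

    def test_zero_reference_contacts_raise(self):
        cx = gen_toy_complex((), seed=8)
        with pytest.raises(ValueError):
            contact_recovery(cx, cx)
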