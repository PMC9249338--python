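import math
import random

import numpy as np
import pytest

from ribovar.structcontact import (
    AtomRecord,
    StructureModel,
    classify_mutation_sites,
    contact_profile,
    find_contacts,
    find_hbonds,
    kabsch_superpose,
    read_structure,
    shrake_rupley_sasa,
    substitute_chain,
)
from oracles import all_pairs_contacts, quaternion_superpose


def _atom(chain, res, name, element, x, y, z, res_name="ALA"):
    return AtomRecord(chain, res, res_name, name, element, (x, y, z))


def _random_cloud_model(rng, n_atoms, box=30.0):
    atoms = []
    for i in range(n_atoms):
        chain = "A" if i < n_atoms // 2 else "B"
        atoms.append(
            _atom(
                chain, i + 1, "C1", "C",
                rng.uniform(0, box), rng.uniform(0, box), rng.uniform(0, box),
            )
        )
    return StructureModel("rand", atoms)


TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  P     U B   5       0.000   3.900   0.000  1.00  0.00           P
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C
ATOM      3  CB  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_toy_pdb_exact_coordinates(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        m = read_structure(p, "toy")
        assert len(m.atoms) == 3
        ca = next(a for a in m.atoms if a.atom_name == "CA")
        assert ca.xyz == (0.0, 0.0, 0.0) and ca.chain_id == "A"
        phos = next(a for a in m.atoms if a.atom_name == "P")
        assert phos.res_seq == 5 and phos.element == "P"

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        m = read_structure(p)
        ca = next(a for a in m.atoms if a.atom_name == "CA")
        assert ca.xyz[0] == 9.0  # the occ-0.60 conformer
        assert len(m.atoms) == 2

    def test_mmcif_and_pdb_renderings_agree(self, bundle_dir):
        mc = read_structure(bundle_dir / "state_A.cif", "A")
        mp = read_structure(bundle_dir / "state_A.pdb", "A")
        key = lambda a: (a.chain_id, a.res_seq, a.atom_name)
        assert sorted(map(key, mc.atoms)) == sorted(map(key, mp.atoms))
        for a, b in zip(sorted(mc.atoms, key=key), sorted(mp.atoms, key=key)):
            assert a.xyz == pytest.approx(b.xyz, abs=1e-3)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(Exception):
            read_structure(tmp_path / "nope.pdb")


class TestFindContacts:
    def test_pair_inside_cutoff(self):
        m = StructureModel("s", [_atom("A", 1, "CA", "C", 0, 0, 0), _atom("B", 1, "P", "P", 3.9, 0, 0)])
        assert len(find_contacts(m, "A", 4.0)) == 1

    def test_pair_outside_cutoff(self):
        m = StructureModel("s", [_atom("A", 1, "CA", "C", 0, 0, 0), _atom("B", 1, "P", "P", 4.1, 0, 0)])
        assert find_contacts(m, "A", 4.0) == []

    def test_hydrogens_excluded(self):
        m = StructureModel("s", [_atom("A", 1, "H1", "H", 0, 0, 0), _atom("B", 1, "P", "P", 2.0, 0, 0)])
        assert find_contacts(m, "A", 4.0) == []

    def test_same_chain_pairs_excluded(self):
        m = StructureModel("s", [_atom("A", 1, "CA", "C", 0, 0, 0), _atom("A", 2, "CA", "C", 1.0, 0, 0)])
        assert find_contacts(m, "A", 4.0) == []

    def test_missing_chain_rejected(self):
        m = StructureModel("s", [_atom("A", 1, "CA", "C", 0, 0, 0)])
        with pytest.raises(KeyError):
            find_contacts(m, "Z")

    @pytest.mark.parametrize("cutoff", [3.0, 4.0, 5.0])
    def test_matches_all_pairs_scan(self, cutoff):
        rng = random.Random(11)
        for _ in range(5):
            m = _random_cloud_model(rng, 300)
            qa = [a for a in m.chain("A")]
            oa = [a for a in m.atoms if a.chain_id != "A"]
            expected = all_pairs_contacts(
                np.array([a.xyz for a in qa]), np.array([a.xyz for a in oa]), cutoff
            )
            records = find_contacts(m, "A", cutoff)
            got = {
                (r.query_res - 1, r.partner_res - 1 - len(qa))
                for r in records
            }
            assert got == expected

    def test_count_monotone_in_cutoff(self):
        rng = random.Random(12)
        m = _random_cloud_model(rng, 200)
        counts = [len(find_contacts(m, "A", c)) for c in (2.0, 3.0, 4.0, 5.0, 8.0)]
        assert counts == sorted(counts)

    def test_distances_satisfy_triangle_inequality(self):
        rng = random.Random(13)
        m = _random_cloud_model(rng, 100)
        records = find_contacts(m, "A", 6.0)
        probe = np.array([50.0, 50.0, 50.0])
        atoms = {(a.chain_id, a.res_seq): np.array(a.xyz) for a in m.atoms}
        for r in records[:50]:
            qa = atoms[("A", r.query_res)]
            oa = atoms[(r.partner_chain, r.partner_res)]
            d_qp = np.linalg.norm(qa - probe)
            d_op = np.linalg.norm(oa - probe)
            assert r.distance <= d_qp + d_op + 1e-9


class TestContactProfile:
    def test_single_record(self):
        m = StructureModel("S1", [_atom("A", 7, "CA", "C", 0, 0, 0), _atom("B", 3, "P", "P", 3.0, 0, 0)])
        prof = contact_profile(find_contacts(m, "A"), ["S1"], query_residues=[7, 8])
        assert prof.count(7, "S1") == 1
        assert prof.never_in_contact == [8]
        assert prof.partners[(7, "S1")] == [("B", 3)]

    def test_empty_records_all_never_in_contact(self):
        prof = contact_profile([], ["S1"], query_residues=[1, 2, 3])
        assert prof.never_in_contact == [1, 2, 3]

    def test_fixture_state_table_recovery(self, bundle_dir, bundle_truth):
        for state, truth in bundle_truth["structures"].items():
            m = read_structure(bundle_dir / f"state_{state}.pdb", state)
            prof = contact_profile(
                find_contacts(m, "A"), [state], query_residues=m.residues("A")
            )
            got = {
                str(res): prof.count(res, state)
                for (res, _s) in prof.counts
            }
            assert got == truth["contact_counts"]


class TestKabsch:
    def _chain_coords(self, rng, n=20):
        return np.cumsum(rng.normal(scale=2.0, size=(n, 3)), axis=0)

    def test_self_superposition_rmsd_zero(self):
        rng = np.random.default_rng(1)
        coords = self._chain_coords(rng)
        sup = kabsch_superpose(coords, coords)
        assert sup.rmsd < 1e-9
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(2)
        coords = self._chain_coords(rng)
        theta = 0.7
        R = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = coords @ R.T + np.array([5.0, -3.0, 12.0])
        sup = kabsch_superpose(moved, coords)
        assert sup.rmsd < 1e-6
        assert np.allclose(sup.apply(moved), coords, atol=1e-6)

    def test_agrees_with_quaternion_solver_on_noisy_copies(self):
        rng = np.random.default_rng(3)
        for sigma in (0.1, 0.5, 1.0):
            coords = self._chain_coords(rng, n=40)
            noisy = coords + rng.normal(scale=sigma, size=coords.shape)
            sup = kabsch_superpose(noisy, coords)
            _, rmsd_q = quaternion_superpose(noisy, coords)
            assert sup.rmsd == pytest.approx(rmsd_q, abs=1e-8)

    def test_rmsd_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(4)
        a = self._chain_coords(rng)
        b = a + rng.normal(scale=0.3, size=a.shape)
        base = kabsch_superpose(a, b).rmsd
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [[1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
             [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
             [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]]
        )
        t = np.array([3.0, 1.0, -7.0])
        assert kabsch_superpose(a @ R.T + t, b @ R.T + t).rmsd == pytest.approx(base, abs=1e-6)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_reference_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


class TestSubstituteChain:
    def _two_chain_model(self):
        rng = np.random.default_rng(7)
        atoms = []
        for i in range(1, 16):
            x, y, z = rng.uniform(0, 20, 3)
            atoms.append(_atom("A", i, "CA", "C", x, y, z))
        for i in range(1, 11):
            x, y, z = rng.uniform(0, 20, 3)
            atoms.append(_atom("B", i, "P", "P", x, y, z))
        return StructureModel("t", atoms)

    def test_exact_copy_is_identity(self):
        m = self._two_chain_model()
        donor = list(m.chain("A"))
        new, sup, pairs = substitute_chain(m, donor, "A")
        assert sup.rmsd < 1e-9 and len(pairs) == 15
        for a, b in zip(
            sorted(m.chain("A"), key=lambda x: x.res_seq),
            sorted(new.chain("A"), key=lambda x: x.res_seq),
        ):
            assert np.allclose(a.xyz, b.xyz, atol=1e-6)

    def test_rigidly_moved_donor_restores_contacts(self):
        m = self._two_chain_model()
        base_contacts = {
            (r.query_res, r.partner_res) for r in find_contacts(m, "A", 8.0)
        }
        theta = 1.1
        R = np.array(
            [[1, 0, 0],
             [0, math.cos(theta), -math.sin(theta)],
             [0, math.sin(theta), math.cos(theta)]]
        )
        donor = [
            AtomRecord("X", a.res_seq, a.res_name, a.atom_name, a.element,
                       tuple(R @ np.array(a.xyz) + np.array([10.0, 0.0, 5.0])))
            for a in m.chain("A")
        ]
        new, sup, _ = substitute_chain(m, donor, "A")
        assert sup.rmsd < 1e-6
        new_contacts = {
            (r.query_res, r.partner_res) for r in find_contacts(new, "A", 8.0)
        }
        assert new_contacts == base_contacts

    def test_displaced_loop_changes_only_adjacent_contacts(self):
        # donor identical except residue 8, which is displaced and renamed so
        # it drops out of the fit pairing; the superposition is then exact on
        # the other residues and only residue-8 contacts may change
        m = self._two_chain_model()
        donor = [
            AtomRecord(a.chain_id, a.res_seq, a.res_name,
                       "CAX" if a.res_seq == 8 else a.atom_name, a.element,
                       (a.xyz[0] + (100.0 if a.res_seq == 8 else 0.0), a.xyz[1], a.xyz[2]))
            for a in m.chain("A")
        ]
        new, sup, pairs = substitute_chain(m, donor, "A", fit_atom_names={"CA"})
        assert sup.rmsd < 1e-9 and len(pairs) == 14
        base = {(r.query_res, r.partner_res) for r in find_contacts(m, "A", 8.0)}
        after = {(r.query_res, r.partner_res) for r in find_contacts(new, "A", 8.0)}
        changed_residues = {q for q, _ in base ^ after}
        assert changed_residues <= {8}


class TestHBonds:
    def test_n_o_pair_within_cutoff(self):
        m = StructureModel("s", [_atom("A", 1, "N", "N", 0, 0, 0), _atom("B", 2, "O2", "O", 2.9, 0, 0)])
        bonds = find_hbonds(m, "A")
        assert len(bonds) == 1 and bonds[0].angle is None

    def test_pair_beyond_cutoff_rejected(self):
        m = StructureModel("s", [_atom("A", 1, "N", "N", 0, 0, 0), _atom("B", 2, "O2", "O", 3.8, 0, 0)])
        assert find_hbonds(m, "A") == []

    def test_carbon_pairs_not_hbonds(self):
        m = StructureModel("s", [_atom("A", 1, "CA", "C", 0, 0, 0), _atom("B", 2, "C1", "C", 2.9, 0, 0)])
        assert find_hbonds(m, "A") == []

    def test_bad_angle_with_explicit_hydrogen_rejected(self):
        # D-H-A = 90 degrees: H below the D->A axis
        m = StructureModel(
            "s",
            [
                _atom("A", 1, "N", "N", 0, 0, 0),
                _atom("A", 1, "H", "H", 0, -1.0, 0),
                _atom("B", 2, "O2", "O", 1.0, -1.0, 0),
            ],
        )
        assert find_hbonds(m, "A") == []

    def test_good_angle_with_explicit_hydrogen_kept(self):
        # nearly linear N-H...O
        m = StructureModel(
            "s",
            [
                _atom("A", 1, "N", "N", 0, 0, 0),
                _atom("A", 1, "H", "H", 1.0, 0, 0),
                _atom("B", 2, "O2", "O", 2.9, 0.1, 0),
            ],
        )
        bonds = find_hbonds(m, "A")
        assert len(bonds) == 1 and bonds[0].angle > 150

    def test_fixture_hbond_counts_recovered(self, bundle_dir, bundle_truth):
        for state, truth in bundle_truth["structures"].items():
            m = read_structure(bundle_dir / f"state_{state}.pdb", state)
            counts = {}
            for b in find_hbonds(m, "A"):
                counts[str(b.donor_res)] = counts.get(str(b.donor_res), 0) + 1
            assert counts == truth["hbond_counts"]


class TestSasa:
    def test_lone_atom_closed_form(self):
        m = StructureModel("s", [_atom("A", 1, "CA", "C", 0, 0, 0)])
        sasa = shrake_rupley_sasa(m, probe=1.4, n_points=92)
        expected = 4 * math.pi * (1.7 + 1.4) ** 2
        assert sasa[("A", 1)] == pytest.approx(expected, rel=5e-3)

    def test_distant_atoms_sum_of_spheres(self):
        m = StructureModel(
            "s", [_atom("A", 1, "CA", "C", 0, 0, 0), _atom("B", 1, "O1", "O", 100, 0, 0)]
        )
        sasa = shrake_rupley_sasa(m)
        assert sasa[("A", 1)] == pytest.approx(4 * math.pi * 3.1**2, rel=5e-3)
        assert sasa[("B", 1)] == pytest.approx(4 * math.pi * 2.92**2, rel=5e-3)

    def test_overlapping_diatomic_converges(self):
        m = StructureModel(
            "s", [_atom("A", 1, "C1", "C", 0, 0, 0), _atom("A", 1, "C2", "C", 1.5, 0, 0)]
        )
        coarse = shrake_rupley_sasa(m, n_points=92)[("A", 1)]
        dense = shrake_rupley_sasa(m, n_points=10_000)[("A", 1)]
        assert coarse == pytest.approx(dense, rel=0.02)

    def test_atom_sasa_bounded_by_full_sphere(self):
        rng = random.Random(5)
        m = _random_cloud_model(rng, 50, box=10.0)
        # per-residue here equals per-atom (one atom per residue id)
        for (chain, res), area in shrake_rupley_sasa(m).items():
            assert 0.0 <= area <= 4 * math.pi * 3.1**2 + 1e-6

    def test_unknown_element_warns_and_uses_default(self):
        m = StructureModel("s", [_atom("A", 1, "Q1", "Q", 0, 0, 0)])
        with pytest.warns(UserWarning, match="unknown elements"):
            sasa = shrake_rupley_sasa(m)
        assert sasa[("A", 1)] == pytest.approx(4 * math.pi * 3.1**2, rel=5e-3)


class TestClassifySites:
    def test_always_in_contact_is_assembly_critical(self):
        m = StructureModel(
            "S1", [_atom("A", 5, "CA", "C", 0, 0, 0), _atom("B", 1, "P", "P", 3.0, 0, 0)]
        )
        prof = contact_profile(find_contacts(m, "A"), ["S1"], query_residues=[5])
        df = classify_mutation_sites(prof, {}, [5], "A", resolved_residues={5})
        assert df.iloc[0]["label"] == "ASSEMBLY_CRITICAL"

    def test_zero_contact_surface_residue_is_exposed_low_contact(self):
        prof = contact_profile([], ["S1"], query_residues=[5])
        sasa = {"S1": {("A", 5): 80.0}}
        df = classify_mutation_sites(prof, sasa, [5], "A", resolved_residues={5})
        assert df.iloc[0]["label"] == "EXPOSED_LOW_CONTACT"

    def test_unresolved_residue_reported(self):
        prof = contact_profile([], ["S1"], query_residues=[5])
        df = classify_mutation_sites(prof, {}, [99], "A", resolved_residues={5})
        assert df.iloc[0]["label"] == "UNRESOLVED"

    def test_distant_factor_chain_never_flagged(self, bundle_dir, bundle_truth):
        states = sorted(bundle_truth["structures"])
        records = []
        residues = set()
        for state in states:
            m = read_structure(bundle_dir / f"state_{state}.pdb", state)
            records.extend(find_contacts(m, "A"))
            residues.update(m.residues("A"))
        prof = contact_profile(records, states, query_residues=sorted(residues))
        roles = bundle_truth["structures"][states[0]]["chain_roles"]
        df = classify_mutation_sites(
            prof, {}, sorted(residues), "A", chain_roles=roles, resolved_residues=residues
        )
        assert not df["contacts_factor_chain"].any()
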