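"""Structure I/O, SASA/interface, bonds, contacts, distances, visibility and
secondary structure."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from idpcoev.contacts import atomic_contacts, brute_force_contacts
from idpcoev.interface import assign_interface, detect_bonds
from idpcoev.sasa import atom_sasa, residue_sasa, sphere_points
from idpcoev.scoring import EC
from idpcoev.secondary import assign_secondary_structure, CLASS_OF
from idpcoev.structure import (ComplexStructure, NumberingMap, ResidueKey,
                               classify_visibility, read_structure,
                               residue_min_distance)
from idpcoev.synthetic import (GeometryConfig, PlantedTruth, SynthConfig,
                               generate_complex)


def mini_structure(atoms, idp_chain="A", partner_chains=("B",), nmap=None):
    """Build a structure from (chain, resseq, aa, atom_name, element, xyz)."""
    residues, names, elements, coords, owner = [], [], [], [], []
    index = {}
    for chain, resseq, aa, name, element, xyz in atoms:
        key = (chain, resseq)
        if key not in index:
            index[key] = len(residues)
            residues.append(ResidueKey(chain, resseq, "", aa))
        names.append(name)
        elements.append(element)
        coords.append(xyz)
        owner.append(index[key])
    return ComplexStructure(residues, names, elements,
                           np.array(coords, dtype=float),
                           np.array(owner), idp_chain, list(partner_chains),
                           nmap)


class TestReadStructure:
    def test_roundtrip_preserves_atoms(self, synth_complex, tmp_path):
        path = tmp_path / "complex.pdb"
        synth_complex.write_pdb(path)
        s2 = read_structure(path, "A", ["B"])
        assert s2.n_atoms() == synth_complex.n_atoms()
        assert [r.aa for r in s2.residues] == \
               [r.aa for r in synth_complex.residues]
        # coordinates survive to PDB precision (1e-3 A)
        assert np.allclose(s2.coords, synth_complex.coords, atol=2e-3)

    def test_hydrogens_dropped(self, tmp_path):
        pdb = tmp_path / "h.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  H   ALA A   1       0.500   0.900   0.000  1.00  0.00           H\n"
            "ATOM      4  N   GLY B   1       5.000   0.000   0.000  1.00  0.00           N\n"
            "END\n")
        s = read_structure(pdb, "A", ["B"])
        assert s.n_atoms() == 3
        assert "H" not in s.atom_names

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      3  CA  GLY B   1       5.000   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        s = read_structure(pdb, "A", ["B"])
        ri = s.residue_index("A", 1)
        assert len(s.atom_indices(ri)) == 1
        assert np.allclose(s.residue_coords(ri)[0], [0, 0, 0])

    def test_missing_chain_lists_available(self, synth_complex, tmp_path):
        path = tmp_path / "c.pdb"
        synth_complex.write_pdb(path)
        with pytest.raises(ValueError, match="available"):
            read_structure(path, "Z", ["B"])


class TestSasaInterface:
    def test_isolated_atom_sasa_is_full_sphere(self):
        area = atom_sasa(np.zeros((1, 3)), ["C"], n_points=960)[0]
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert abs(area - expected) / expected < 1e-6

    def test_buried_atom_loses_area(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        areas = atom_sasa(coords, ["C", "C"])
        free = 4 * np.pi * 3.1 ** 2
        assert areas[0] < free
        assert areas[1] < free

    def test_separated_chains_have_no_interface(self, synth_complex):
        # translate the partner 100 A away: interface must vanish
        s = synth_complex
        shifted = np.array(s.coords, copy=True)
        shifted[s.chain_atom_mask("B")] += np.array([100.0, 0, 0])
        far = ComplexStructure(s.residues, s.atom_names, s.elements, shifted,
                               s.atom_res_index, "A", ["B"], s.numbering_map)
        iface = assign_interface(far)
        assert iface.total_area == 0.0
        assert not iface.idp_if_residues and not iface.partner_if_residues

    def test_duplicate_partner_chain_increases_area(self, synth_config,
                                                    synth_msa, synth_complex):
        # a second identical partner bound on the opposite side adds area
        s = synth_complex
        residues = list(s.residues)
        names = list(s.atom_names)
        elements = list(s.elements)
        coords = [s.coords]
        owner = [s.atom_res_index]
        b_res = s.chain_residue_indices("B")
        offset = len(residues)
        # reflect the partner through the far side of the IDP axis
        idp_centroid = s.coords[s.chain_atom_mask("A")].mean(axis=0)
        extra = 2 * idp_centroid - s.coords[s.chain_atom_mask("B")]
        for ri in b_res:
            rk = s.residues[ri]
            residues.append(ResidueKey("C", rk.resseq, "", rk.aa))
        idx_map = {ri: offset + k for k, ri in enumerate(b_res)}
        names += [s.atom_names[a] for a in np.where(s.chain_atom_mask("B"))[0]]
        elements += [s.elements[a] for a in np.where(s.chain_atom_mask("B"))[0]]
        coords.append(extra)
        owner.append(np.array([idx_map[s.atom_res_index[a]]
                               for a in np.where(s.chain_atom_mask("B"))[0]]))
        s2 = ComplexStructure(residues, names, elements, np.vstack(coords),
                              np.concatenate(owner), "A", ["B", "C"])
        base = assign_interface(s)
        both = assign_interface(s2)
        assert both.total_area > base.total_area

    def test_default_point_density_close_to_refined(self, synth_complex):
        coarse = residue_sasa(synth_complex,
                              np.ones(synth_complex.n_atoms(), bool), 960)
        fine = residue_sasa(synth_complex,
                            np.ones(synth_complex.n_atoms(), bool), 5000)
        total_coarse = sum(coarse.values())
        total_fine = sum(fine.values())
        assert abs(total_coarse - total_fine) / total_fine < 0.10

    def test_interface_residues_cover_contact_residues(self, synth_complex):
        iface = assign_interface(synth_complex)
        cmap = atomic_contacts(synth_complex)
        if_idp = {synth_complex.residues[r].resseq
                  for r in iface.idp_if_residues}
        if_partner = {synth_complex.residues[r].resseq
                      for r in iface.partner_if_residues}
        for (i, j) in cmap.entries:
            assert i in if_idp
            assert j in if_partner


class TestBonds:
    def salt_pair(self, d):
        return [
            ("A", 1, "K", "NZ", "N", (0.0, 0.0, 0.0)),
            ("B", 1, "E", "OE1", "O", (d, 0.0, 0.0)),
        ]

    def test_close_lys_glu_is_both_hbond_and_bridge(self):
        s = mini_structure(self.salt_pair(3.0))
        hb, sb = detect_bonds(s)
        assert len(hb) == 1 and len(sb) == 1

    def test_far_pair_is_neither(self):
        s = mini_structure(self.salt_pair(5.0))
        hb, sb = detect_bonds(s)
        assert hb == [] and sb == []

    def test_salt_bridge_only_window(self):
        # 3.8 A: beyond H-bond range, within salt-bridge range
        s = mini_structure(self.salt_pair(3.8))
        hb, sb = detect_bonds(s)
        assert hb == [] and len(sb) == 1

    def test_carbon_pairs_never_bond(self):
        s = mini_structure([
            ("A", 1, "L", "CD1", "C", (0.0, 0.0, 0.0)),
            ("B", 1, "V", "CG1", "C", (3.0, 0.0, 0.0)),
        ])
        hb, sb = detect_bonds(s)
        assert hb == [] and sb == []

    def test_bond_density_normalisation(self):
        from idpcoev.interface import Interface

        iface = Interface(set(), set(), total_area=2000.0,
                          hbonds=[(0, 1, 3.0), (0, 2, 3.1), (1, 1, 3.2)],
                          salt_bridges=[(0, 1, 3.5)])
        assert iface.bonds_per_1000A2 == pytest.approx(2.0)


class TestContacts:
    def test_threshold_at_vdw_sum_plus_slack(self):
        # two carbons: vdW 1.7 + 1.7 + 0.5 = 3.9 A cutoff
        for d, expected in ((3.8, 1), (4.0, 0)):
            s = mini_structure([
                ("A", 1, "L", "CB", "C", (0.0, 0.0, 0.0)),
                ("B", 1, "V", "CB", "C", (d, 0.0, 0.0)),
            ])
            assert atomic_contacts(s).total() == expected

    def test_counts_qualifying_atom_pairs(self):
        atoms = [("A", 1, "L", f"C{k}", "C", (0.0, 0.8 * k, 0.0))
                 for k in range(5)]
        atoms += [("B", 1, "V", "CB", "C", (3.0, 0.0, 0.0)),
                  ("B", 1, "V", "CG1", "C", (3.0, 1.6, 0.0))]
        s = mini_structure(atoms)
        cmap = atomic_contacts(s)
        bf = brute_force_contacts(s)
        assert cmap.entries == bf.entries
        assert cmap.entries[(1, 1)] == bf.entries[(1, 1)] > 1

    def test_grid_matches_brute_force_on_synthetic_complex(self, synth_complex):
        fast = atomic_contacts(synth_complex)
        slow = brute_force_contacts(synth_complex)
        assert fast.entries == slow.entries
        assert fast.min_distance == pytest.approx(slow.min_distance)

    def test_contact_totals_symmetric(self, synth_complex):
        cmap = atomic_contacts(synth_complex)
        assert sum(cmap.idp_totals.values()) == sum(cmap.partner_totals.values()) \
            == cmap.total()

    def test_identical_partner_chains_accumulate(self, synth_complex):
        s = synth_complex
        # stack a copy of the partner chain as chain C at the same residue
        # numbers but mirrored position; counts merge by residue number
        b_atoms = np.where(s.chain_atom_mask("B"))[0]
        residues = list(s.residues)
        offset = len(residues)
        idx_map = {}
        for ri in s.chain_residue_indices("B"):
            rk = s.residues[ri]
            idx_map[ri] = len(residues)
            residues.append(ResidueKey("C", rk.resseq, "", rk.aa))
        idp_centroid = s.coords[s.chain_atom_mask("A")].mean(axis=0)
        coords = np.vstack([s.coords, 2 * idp_centroid - s.coords[b_atoms]])
        names = list(s.atom_names) + [s.atom_names[a] for a in b_atoms]
        elements = list(s.elements) + [s.elements[a] for a in b_atoms]
        owner = np.concatenate([s.atom_res_index,
                                [idx_map[s.atom_res_index[a]] for a in b_atoms]])
        s2 = ComplexStructure(residues, names, elements, coords, owner,
                              "A", ["B", "C"])
        merged = atomic_contacts(s2)
        single = atomic_contacts(s)
        for key, count in single.entries.items():
            assert merged.entries.get(key, 0) >= count

    def test_min_distance_bounded_by_cutoff(self, synth_complex):
        cmap = atomic_contacts(synth_complex)
        for key, d in cmap.min_distance.items():
            assert d <= 1.8 + 1.8 + 0.5 + 1e-9


class TestResidueMinDistance:
    def test_residue_against_itself_is_zero(self, synth_complex):
        assert residue_min_distance(synth_complex, 0, 0) == 0.0

    def test_three_four_five(self):
        s = mini_structure([
            ("A", 1, "G", "CA", "C", (0.0, 0.0, 0.0)),
            ("B", 1, "G", "CA", "C", (3.0, 4.0, 0.0)),
        ])
        assert residue_min_distance(s, 0, 1) == pytest.approx(5.0)

    def test_matches_exhaustive_minimum(self, synth_complex, rng):
        n = len(synth_complex.residues)
        for _ in range(20):
            a, b = rng.integers(0, n, size=2)
            if not synth_complex.atom_indices(int(a)) or \
               not synth_complex.atom_indices(int(b)):
                continue
            xa = synth_complex.residue_coords(int(a))
            xb = synth_complex.residue_coords(int(b))
            expected = cdist(xa, xb).min() if a != b else 0.0
            assert residue_min_distance(synth_complex, int(a), int(b)) == \
                pytest.approx(expected)


class TestVisibility:
    def make_ec(self, i_pos, j_pos):
        return EC(i=i_pos, j=j_pos, raw=1, apc=1, scaled=2.0, probability=0.9,
                  idp_uniprot_pos=i_pos, partner_uniprot_pos=j_pos)

    @pytest.fixture(scope="class")
    def windowed_complex(self):
        cfg = SynthConfig(n_species=10, len_idp=15, len_partner=20, seed=8,
                          planted_pairs=((5, 8, 0.6),),
                          geometry=GeometryConfig(unresolved_idp=(3,),
                                                  idp_construct=(1, 12)))
        truth = PlantedTruth(pairs=((5, 8),), strengths=(0.6,))
        return generate_complex(cfg, truth)

    def test_unmapped_idp_residue_not_in_construct(self, windowed_complex):
        status, reason = classify_visibility(self.make_ec(14, 5),
                                             windowed_complex)
        assert (status, reason) == ("invisible", "not_in_construct")

    def test_mapped_but_coordinate_free_residue(self, windowed_complex):
        status, reason = classify_visibility(self.make_ec(3, 5),
                                             windowed_complex)
        assert (status, reason) == ("invisible", "no_coordinates")

    def test_both_resolved_is_visible(self, windowed_complex):
        status, reason = classify_visibility(self.make_ec(5, 8),
                                             windowed_complex)
        assert (status, reason) == ("visible", None)

    def test_partition_counts(self, windowed_complex):
        # 10 couplings, 2 touching the unresolved window / truncated tail
        ecs = [self.make_ec(i, j) for i, j in
               [(1, 1), (2, 2), (3, 4), (5, 8), (6, 9), (7, 10), (8, 11),
                (9, 12), (14, 3), (10, 13)]]
        visible = invisible = 0
        reasons = {}
        for ec in ecs:
            status, reason = classify_visibility(ec, windowed_complex)
            if status == "visible":
                visible += 1
            else:
                invisible += 1
                reasons[reason] = reasons.get(reason, 0) + 1
        assert visible == 8
        assert invisible == 2
        assert sum(reasons.values()) == invisible
        assert reasons == {"not_in_construct": 1, "no_coordinates": 1}


class TestSecondaryStructure:
    def test_ideal_helix_interior_assigned_h(self):
        cfg = SynthConfig(n_species=10, len_idp=12, len_partner=20, seed=2,
                          planted_pairs=((6, 10, 0.5),),
                          geometry=GeometryConfig(idp_conformation="helix",
                                                  contact_distance_max=6.0))
        truth = PlantedTruth(pairs=((6, 10),), strengths=(0.5,))
        s = generate_complex(cfg, truth)
        ss = assign_secondary_structure(s)
        interior = [s.residue_index("A", p) for p in range(3, 11)]
        classes = {ss.three_class(ri) for ri in interior}
        assert classes == {"helix"}

    def test_grouping_rule(self):
        assert {CLASS_OF[c] for c in "GHI"} == {"helix"}
        assert {CLASS_OF[c] for c in "EB"} == {"strand"}
        assert {CLASS_OF[c] for c in "STC"} == {"loop"}

    def test_three_residue_chain_all_loop(self):
        atoms = []
        from idpcoev.geometry import build_backbone

        bb = build_backbone(3, -57, -47)
        for r in range(3):
            for name in ("N", "CA", "C", "O"):
                atoms.append(("A", r + 1, "A", name,
                              "N" if name == "N" else
                              ("O" if name == "O" else "C"),
                              tuple(bb[name][r])))
        atoms.append(("B", 1, "G", "CA", "C", (50.0, 0, 0)))
        s = mini_structure(atoms)
        ss = assign_secondary_structure(s)
        for ri in s.chain_residue_indices("A"):
            assert ss.three_class(ri) == "loop"

    def test_missing_backbone_warns_and_assigns_c(self):
        atoms = [("A", 1, "A", "CA", "C", (0.0, 0, 0)),
                 ("B", 1, "G", "CA", "C", (50.0, 0, 0))]
        s = mini_structure(atoms)
        with pytest.warns(UserWarning, match="backbone"):
            ss = assign_secondary_structure(s)
        assert ss.codes[0] == "C"
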