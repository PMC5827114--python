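"""Structure parsing, SASA/buried-surface and geometric primitives."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from didomain.structures import (
    DEFAULT_RADII,
    Atom,
    DomainDefinition,
    StructureModel,
    buried_surface_area,
    contact_residues,
    nh_bond_vectors,
    read_structure,
    shrake_rupley_sasa,
    write_pdb,
)

MINIMAL_PDB = (
    "ATOM      1  CA  GLY A  22      11.104   6.134  -6.504  1.00  0.00           C\n"
    "END\n"
)


class TestReadWrite:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(MINIMAL_PDB)
        model = read_structure(path)
        assert len(model) == 1
        atom = model.atoms[0]
        assert atom.element == "C"
        assert atom.resnum == 22
        np.testing.assert_allclose(atom.xyz, (11.104, 6.134, -6.504))

    def test_roundtrip_preserves_coordinates(self, tmp_path, rng):
        atoms = [
            Atom("A", i + 1, "GLY", "CA", "C", tuple(np.round(rng.uniform(-50, 50, 3), 3)))
            for i in range(50)
        ]
        model = StructureModel(atoms)
        path = tmp_path / "roundtrip.pdb"
        write_pdb(model, path)
        back = read_structure(path)
        assert len(back) == 50
        np.testing.assert_allclose(back.coords, model.coords, atol=1e-3)

    def test_unparseable_file_raises(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text("this is not a structure\n")
        with pytest.raises(Exception):
            read_structure(path, fmt="mmcif")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_structure("/nonexistent/file.pdb")

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        model = read_structure(path)
        assert len(model) == 1
        assert model.atoms[0].xyz[0] == pytest.approx(5.0)


class TestDomainDefinition:
    def test_parse_selection_string(self):
        dom = DomainDefinition.from_string("N", "A:16-109,121-243")
        assert dom.contains("A", 16) and dom.contains("A", 243)
        assert not dom.contains("A", 115)
        assert not dom.contains("B", 50)

    def test_rejects_overlap_and_inversion(self):
        with pytest.raises(ValueError):
            DomainDefinition("x", "A", ((10, 5),))
        with pytest.raises(ValueError):
            DomainDefinition("x", "A", ((1, 10), (5, 20)))


class TestSasa:
    def test_isolated_carbon_matches_sphere_area(self):
        model = StructureModel([Atom("A", 1, "GLY", "C", "C", (0.0, 0.0, 0.0))])
        result = shrake_rupley_sasa(model, probe=1.4, n_points=960)
        expected = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert result.total == pytest.approx(expected, rel=0.01)

    def test_distant_spheres_fully_exposed(self):
        model = StructureModel(
            [
                Atom("A", 1, "GLY", "C", "C", (0.0, 0.0, 0.0)),
                Atom("A", 2, "GLY", "C", "C", (50.0, 0.0, 0.0)),
            ]
        )
        result = shrake_rupley_sasa(model, n_points=960)
        expected = 4.0 * math.pi * 3.1**2
        np.testing.assert_allclose(result.areas, expected, rtol=0.01)

    def test_overlapping_spheres_match_spherical_caps(self):
        """Two-sphere occlusion agrees with the closed-form cap areas to 1%."""
        d = 3.0
        r1, r2 = 1.7 + 1.4, 1.55 + 1.4
        model = StructureModel(
            [
                Atom("A", 1, "GLY", "C", "C", (0.0, 0.0, 0.0)),
                Atom("A", 1, "GLY", "N", "N", (d, 0.0, 0.0)),
            ]
        )
        result = shrake_rupley_sasa(model, n_points=4000)
        h1 = r1 - (d * d + r1 * r1 - r2 * r2) / (2 * d)
        h2 = r2 - (d * d + r2 * r2 - r1 * r1) / (2 * d)
        exact = [4 * math.pi * r1**2 - 2 * math.pi * r1 * h1, 4 * math.pi * r2**2 - 2 * math.pi * r2 * h2]
        np.testing.assert_allclose(result.areas, exact, rtol=0.01)

    def test_unknown_element_raises_and_default_radius_works(self):
        model = StructureModel([Atom("A", 1, "UNK", "X1", "XX", (0.0, 0.0, 0.0))])
        with pytest.raises(ValueError, match="XX"):
            shrake_rupley_sasa(model)
        result = shrake_rupley_sasa(model, default_radius=1.8)
        assert result.total == pytest.approx(4 * math.pi * 3.2**2, rel=0.01)

    def test_quadrature_convergence(self, toy):
        model, _, _ = toy
        coarse = shrake_rupley_sasa(model, n_points=960)
        fine = shrake_rupley_sasa(model, n_points=10000)
        assert coarse.total == pytest.approx(fine.total, rel=0.01)

    def test_matches_independent_implementation(self, toy):
        """Cross-check per-atom SASA against biotite's Shrake-Rupley."""
        struc = pytest.importorskip("biotite.structure")
        model, _, _ = toy
        heavy_atoms = [a for a in model.atoms if a.element != "H"]
        arr = struc.AtomArray(len(heavy_atoms))
        for i, at in enumerate(heavy_atoms):
            arr.coord[i] = at.xyz
            arr.chain_id[i] = at.chain
            arr.res_id[i] = at.resnum
            arr.res_name[i] = at.resname
            arr.atom_name[i] = at.name
            arr.element[i] = at.element
        radii = np.array([DEFAULT_RADII[e] for e in arr.element])
        reference = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii)
        ours = shrake_rupley_sasa(model, n_points=960)
        assert ours.total == pytest.approx(reference.sum(), rel=0.02)


class TestBuriedSurface:
    def test_no_contact_is_zero(self):
        model = StructureModel(
            [
                Atom("A", 1, "GLY", "C", "C", (0.0, 0.0, 0.0)),
                Atom("A", 2, "GLY", "C", "C", (50.0, 0.0, 0.0)),
            ]
        )
        a = DomainDefinition("a", "A", ((1, 1),))
        b = DomainDefinition("b", "A", ((2, 2),))
        assert buried_surface_area(model, a, b) == pytest.approx(0.0, abs=0.5)

    def test_symmetry(self, toy):
        model, dom_a, dom_b = toy
        assert buried_surface_area(model, dom_a, dom_b) == buried_surface_area(model, dom_b, dom_a)

    def test_contacting_vs_detached_geometry(self, toy, toy_detached):
        model, dom_a, dom_b = toy
        detached, _, _ = toy_detached
        assert buried_surface_area(model, dom_a, dom_b) > 150.0
        assert buried_surface_area(detached, dom_a, dom_b) == pytest.approx(0.0, abs=1.0)

    def test_overlapping_selections_rejected(self, toy):
        model, dom_a, _ = toy
        with pytest.raises(ValueError):
            buried_surface_area(model, dom_a, dom_a)


class TestNhVectors:
    def test_explicit_geometry(self):
        model = StructureModel(
            [
                Atom("A", 2, "GLY", "N", "N", (0.0, 0.0, 0.0)),
                Atom("A", 2, "GLY", "H", "H", (0.0, 0.0, 1.02)),
            ]
        )
        vectors, skipped = nh_bond_vectors(model)
        assert not skipped
        np.testing.assert_allclose(vectors[0][1], [0, 0, 1], atol=1e-12)

    def test_proline_skipped_with_reason(self, toy):
        model, _, _ = toy
        vectors, skipped = nh_bond_vectors(model)
        reasons = dict(skipped)
        assert ("A", 40) in reasons and "proline" in reasons[("A", 40)]
        assert all(rid != ("A", 40) for rid, _ in vectors)

    def test_ideal_h_matches_explicit_h(self, toy):
        """Rebuilt ideal amide protons agree with the generator's explicit ones."""
        model, _, _ = toy
        with_h, _ = nh_bond_vectors(model)
        stripped = model.subset(np.array([a.element != "H" for a in model.atoms]))
        rebuilt, _ = nh_bond_vectors(stripped, add_ideal_h=True)
        rebuilt_map = dict(rebuilt)
        checked = 0
        for rid, v in with_h:
            if rid not in rebuilt_map:
                continue
            angle = math.degrees(math.acos(np.clip(v @ rebuilt_map[rid], -1, 1)))
            assert angle < 15.0
            checked += 1
        assert checked > 50


class TestContacts:
    def _two_residue_model(self, distance):
        return StructureModel(
            [
                Atom("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
                Atom("A", 2, "GLY", "CA", "C", (distance, 0.0, 0.0)),
            ]
        )

    @pytest.mark.parametrize("distance,expected", [(4.9, 1), (5.1, 0)])
    def test_cutoff_boundary(self, distance, expected):
        model = self._two_residue_model(distance)
        a = DomainDefinition("a", "A", ((1, 1),))
        b = DomainDefinition("b", "A", ((2, 2),))
        assert len(contact_residues(model, a, b, cutoff=5.0)) == expected

    def test_matches_brute_force(self, toy):
        model, dom_a, dom_b = toy
        fast = contact_residues(model, dom_a, dom_b, cutoff=5.0)
        heavy = np.array([a.element != "H" for a in model.atoms])
        mask_a = model.select(dom_a) & heavy
        mask_b = model.select(dom_b) & heavy
        ids = [(a.chain, a.resnum) for a in model.atoms]
        brute = set()
        d = cdist(model.coords[mask_a], model.coords[mask_b])
        ids_a = [rid for rid, m in zip(ids, mask_a) if m]
        ids_b = [rid for rid, m in zip(ids, mask_b) if m]
        for i, j in zip(*np.where(d < 5.0)):
            brute.add((ids_a[i], ids_b[j]))
        assert fast == brute

    def test_hydrogens_ignored(self, toy):
        model, dom_a, dom_b = toy
        stripped = model.subset(np.array([a.element != "H" for a in model.atoms]))
        assert contact_residues(model, dom_a, dom_b) == contact_residues(stripped, dom_a, dom_b)
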