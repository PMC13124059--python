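"""Structure I/O, atom typing, hydrogen placement, and energy grouping."""

import math

import numpy as np
import pytest

from packfail.structio import (
    Atom,
    EnergyTable,
    LJParameterSet,
    StructureFormatError,
    TypedStructure,
    TypingScheme,
    assign_atom_types,
    baseline_parameters,
    group_energy_terms,
    place_aliphatic_hydrogens,
    read_pdb,
    refit_parameters,
    write_pdb,
)

from conftest import make_atom, pdb_line


class TestReadPdb:
    def test_gly_has_five_heavy_atoms(self, gly_pdb):
        s = read_pdb(gly_pdb)
        assert len(s) == 5
        assert [a.atom_name for a in s.atoms] == ["N", "CA", "C", "O", "OXT"]
        assert s.atoms[0].residue_name == "GLY"

    def test_altloc_b_dropped(self, tmp_path):
        lines = [
            pdb_line(1, "N", "ALA", "A", 1, 0, 0, 0, "N"),
            pdb_line(2, "CA", "ALA", "A", 1, 1.4, 0, 0, "C", altloc="A"),
            pdb_line(3, "CA", "ALA", "A", 1, 1.5, 0, 0, "C", altloc="B"),
            "END",
        ]
        p = tmp_path / "alt.pdb"
        p.write_text("\n".join(lines) + "\n")
        s = read_pdb(p)
        cas = [a for a in s.atoms if a.atom_name == "CA"]
        assert len(cas) == 1
        assert cas[0].coords[0] == pytest.approx(1.4)

    def test_non_pdb_text_raises(self, tmp_path):
        p = tmp_path / "garbage.txt"
        p.write_text("this is not a structure\nat all\n")
        with pytest.raises(StructureFormatError):
            read_pdb(p)

    def test_round_trip_preserves_atoms(self, gly_pdb, tmp_path):
        s = read_pdb(gly_pdb)
        out = tmp_path / "out.pdb"
        write_pdb(s, out)
        s2 = read_pdb(out)
        assert len(s2) == len(s)
        assert [a.atom_name for a in s2.atoms] == [a.atom_name for a in s.atoms]
        np.testing.assert_allclose(s2.coords, s.coords, atol=1.5e-3)


class TestAtomInvariants:
    def test_non_finite_coords_rejected(self):
        with pytest.raises(ValueError):
            Atom("A", 1, "ALA", "CA", "C", (0.0, float("nan"), 0.0))

    def test_empty_element_rejected(self):
        with pytest.raises(ValueError):
            Atom("A", 1, "ALA", "CA", "", (0.0, 0.0, 0.0))


class TestAtomTyping:
    @pytest.mark.parametrize(
        "resname,atom,element,expected",
        [
            ("VAL", "CG1", "C", "CH3"),
            ("LEU", "O", "O", "OCbb"),
            ("SER", "CB", "C", "C_polar_sc"),
            ("PHE", "CB", "C", "C_nonpolar_sc"),
            ("LYS", "CA", "C", "CAbb"),
            ("THR", "CG2", "C", "CH3"),
            ("THR", "OG1", "O", "OH"),
            ("MET", "CE", "C", "CH3"),
            ("LYS", "NZ", "N", "Npol"),
        ],
    )
    def test_stated_mappings(self, resname, atom, element, expected):
        s = TypedStructure([make_atom("A", 1, resname, atom, element, (0, 0, 0))])
        assert assign_atom_types(s).atom_types[0] == expected

    def test_hydrogen_on_carbon_is_apolar(self):
        atoms = [
            make_atom("A", 1, "ALA", "CB", "C", (0, 0, 0)),
            make_atom("A", 1, "ALA", "HB1", "H", (1.09, 0, 0)),
            make_atom("A", 1, "ALA", "N", "N", (0, 2, 0)),
            make_atom("A", 1, "ALA", "H", "H", (0, 3, 0)),
        ]
        types = assign_atom_types(TypedStructure(atoms)).atom_types
        assert types[1] == "Hapo"
        assert types[3] == "other"  # amide hydrogen is polar

    def test_unknown_residue_strict_vs_lenient(self):
        s = TypedStructure([make_atom("A", 1, "XYZ", "C1", "C", (0, 0, 0))])
        assert assign_atom_types(s).atom_types == ["other"]
        with pytest.raises(KeyError):
            assign_atom_types(s, TypingScheme(strict=True))

    def test_typing_is_pure_function_of_names(self):
        a = make_atom("A", 1, "VAL", "CG1", "C", (0.0, 0.0, 0.0))
        b = make_atom("B", 99, "VAL", "CG1", "C", (5.0, -3.0, 2.0))
        ta = assign_atom_types(TypedStructure([a])).atom_types[0]
        tb = assign_atom_types(TypedStructure([b])).atom_types[0]
        assert ta == tb == "CH3"

    def test_configurable_nonpolar_set(self):
        s = TypedStructure([make_atom("A", 1, "SER", "CB", "C", (0, 0, 0))])
        scheme = TypingScheme(nonpolar_residues=frozenset({"SER"}))
        assert assign_atom_types(s, scheme).atom_types[0] == "C_nonpolar_sc"


class TestHydrogenPlacement:
    def test_ala_cb_gets_three_methyl_hydrogens(self, dipeptide):
        s = place_aliphatic_hydrogens(assign_atom_types(dipeptide))
        hb = [a for a in s.atoms if a.atom_name.startswith("HB")]
        assert len(hb) == 3
        cb = next(a for a in s.atoms if a.atom_name == "CB")
        for h in hb:
            d = np.linalg.norm(np.array(h.coords) - np.array(cb.coords))
            assert d == pytest.approx(1.09, abs=1e-3)

    def test_gly_gets_two_ha(self, dipeptide):
        s = place_aliphatic_hydrogens(assign_atom_types(dipeptide))
        ha = [a for a in s.atoms if a.residue_name == "GLY" and a.atom_name.startswith("HA")]
        assert len(ha) == 2

    def test_idempotent(self, dipeptide):
        once = place_aliphatic_hydrogens(assign_atom_types(dipeptide))
        twice = place_aliphatic_hydrogens(once)
        assert len(twice) == len(once)
        np.testing.assert_allclose(twice.coords, once.coords)

    def test_existing_hydrogen_untouched(self):
        atoms = [
            make_atom("A", 1, "ALA", "N", "N", (0.0, 0.0, 0.0)),
            make_atom("A", 1, "ALA", "CA", "C", (1.458, 0.0, 0.0)),
            make_atom("A", 1, "ALA", "C", "C", (2.009, 1.42, 0.0)),
            make_atom("A", 1, "ALA", "O", "O", (1.251, 2.39, 0.0)),
            make_atom("A", 1, "ALA", "CB", "C", (2.01, -0.77, 1.21)),
            make_atom("A", 1, "ALA", "HB1", "H", (3.0, -0.5, 1.3)),
        ]
        s = place_aliphatic_hydrogens(assign_atom_types(TypedStructure(atoms)))
        hb = [a for a in s.atoms if a.atom_name == "HB1"]
        assert len(hb) == 1
        assert hb[0].coords == (3.0, -0.5, 1.3)

    def test_missing_parent_warns_and_skips(self):
        atoms = [make_atom("A", 1, "ALA", "CB", "C", (0, 0, 0))]  # no CA
        with pytest.warns(UserWarning):
            s = place_aliphatic_hydrogens(assign_atom_types(TypedStructure(atoms)))
        assert len(s) == 1

    def test_tetrahedral_angles(self, dipeptide):
        s = place_aliphatic_hydrogens(assign_atom_types(dipeptide))
        pos = {(a.residue_index, a.atom_name): np.array(a.coords) for a in s.atoms}
        cb = pos[(1, "CB")]
        hs = [pos[(1, f"HB{i}")] for i in (1, 2, 3)]
        for i in range(3):
            for j in range(i + 1, 3):
                u = (hs[i] - cb) / np.linalg.norm(hs[i] - cb)
                v = (hs[j] - cb) / np.linalg.norm(hs[j] - cb)
                angle = math.degrees(math.acos(np.clip(np.dot(u, v), -1, 1)))
                assert angle == pytest.approx(109.47, abs=0.1)


class TestLJParameterSet:
    def test_json_round_trip(self, tmp_path, params):
        p = tmp_path / "params.json"
        params.to_json(p)
        back = LJParameterSet.from_json(p)
        assert back.name == params.name
        assert back.w_rep == params.w_rep
        assert back.types == dict(params.types)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LJParameterSet("bad", {"CH3": (-1.0, 0.1)})
        with pytest.raises(ValueError):
            LJParameterSet("bad", {"CH3": (1.0, -0.1)})
        with pytest.raises(ValueError):
            LJParameterSet("bad", {"CH3": (1.0, 0.1)}, w_rep=-0.5)

    def test_combination_rules(self, params):
        assert params.radius_sum("CH3", "OCbb") == pytest.approx(
            params.radius("CH3") + params.radius("OCbb")
        )
        assert params.epsilon("CH3", "OCbb") == pytest.approx(
            math.sqrt(params.well_depth("CH3") * params.well_depth("OCbb"))
        )

    def test_shipped_tables_cover_all_labels(self, params):
        from packfail.structio import ATOM_TYPES

        refit = refit_parameters()
        for label in ATOM_TYPES:
            assert label in params.types
            assert label in refit.types


class TestEnergyGrouping:
    def test_lj_group_and_total(self):
        t = EnergyTable("s1", {"fa_atr": -10.0, "fa_rep": 2.0})
        g = group_energy_terms(t)
        assert g["LJ"] == pytest.approx(-8.0)
        assert g["total"] == pytest.approx(-8.0)

    def test_empty_table_all_zero(self):
        g = group_energy_terms(EnergyTable("s", {}))
        assert all(v == 0.0 for v in g.values())

    def test_hbond_and_solvation(self):
        g = group_energy_terms(EnergyTable("s", {"hbond_sc": -1.0, "fa_sol": 3.0}))
        assert g["H-bond"] == pytest.approx(-1.0)
        assert g["solvation"] == pytest.approx(3.0)
        assert g["total"] == pytest.approx(2.0)

    def test_unknown_term_goes_to_ungrouped_but_counts_in_total(self):
        g = group_energy_terms(EnergyTable("s", {"fa_atr": -2.0, "mystery": 5.0}))
        assert g["ungrouped"] == pytest.approx(5.0)
        assert g["LJ"] == pytest.approx(-2.0)
        assert g["total"] == pytest.approx(3.0)

    def test_groups_are_non_overlapping(self):
        from packfail.structio import DEFAULT_ENERGY_GROUPS

        seen = set()
        for terms in DEFAULT_ENERGY_GROUPS.values():
            for term in terms:
                assert term not in seen
                seen.add(term)
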