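import collections
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dqcryst import (
    AtomSite,
    CrystalStructure,
    ProtonSiteGroup,
    SymmetryOp,
    UnitCell,
    enumerate_pair_distances,
    expand_to_p1,
    parse_structure,
    write_cif,
)
from dqcryst.structures import ConfigError, FormatError, GeometryError
from dqcryst.synthetic_data import (
    brute_force_pair_distances,
    make_methyl_structure,
    make_random_structure,
)


def p1(cell, sites):
    return CrystalStructure(cell=cell, symmetry_ops=[SymmetryOp.identity()], sites=sites)


class TestUnitCell:
    def test_cubic_volume(self):
        assert UnitCell(10, 10, 10).volume == pytest.approx(1000.0)

    def test_monoclinic_volume(self):
        cell = UnitCell(5, 6, 7, 90, 100, 90)
        assert cell.volume == pytest.approx(5 * 6 * 7 * math.sin(math.radians(100)))

    @pytest.mark.parametrize("bad", [dict(a=-1), dict(alpha=0.0), dict(gamma=180.0)])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            UnitCell(**{"a": 10, "b": 10, "c": 10, **bad})

    def test_perpendicular_widths_cubic(self):
        assert np.allclose(UnitCell(4, 4, 4).perpendicular_widths(), 4.0)


class TestSymmetryOp:
    def test_identity_roundtrip(self):
        op = SymmetryOp.from_xyz("x,y,z")
        assert np.allclose(op.apply([0.1, 0.2, 0.3]), [0.1, 0.2, 0.3])

    def test_translation_and_inversion(self):
        op = SymmetryOp.from_xyz("-x, y+1/2, 1/2-z")
        assert np.allclose(op.apply([0.2, 0.2, 0.2]), [-0.2, 0.7, 0.3])

    def test_to_xyz_roundtrip(self):
        for expr in ("x,y,z", "-x,-y,-z", "-x,y+1/2,1/2-z"):
            op = SymmetryOp.from_xyz(expr)
            again = SymmetryOp.from_xyz(op.to_xyz())
            assert op.rotation == again.rotation
            assert op.translation == again.translation


class TestParseStructure:
    def test_minimal_p1(self, tmp_path):
        cif = tmp_path / "min.cif"
        cif.write_text(
            "data_x\n_cell_length_a 10\n_cell_length_b 10\n_cell_length_c 10\n"
            "_cell_angle_alpha 90\n_cell_angle_beta 90\n_cell_angle_gamma 90\n"
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "H1 H 0 0 0\n"
        )
        s = parse_structure(cif)
        assert len(s.sites) == 1
        assert len(s.symmetry_ops) == 1
        assert s.sites[0].element == "H"

    def test_inversion_gives_two_positions(self, tmp_path):
        cif = tmp_path / "inv.cif"
        cif.write_text(
            "data_x\n_cell_length_a 10\n_cell_length_b 10\n_cell_length_c 10\n"
            "loop_\n_symmetry_equiv_pos_as_xyz\n'x,y,z'\n'-x,-y,-z'\n"
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "H1 H 0.1 0.1 0.1\n"
        )
        s = expand_to_p1(parse_structure(cif))
        assert len(s.sites) == 2

    def test_roundtrip_methyl(self, tmp_path):
        s = make_methyl_structure(176, 178, 179)
        path = tmp_path / "methyl.cif"
        write_cif(s, path)
        again = parse_structure(path)
        for a, b in zip(s.sites, again.sites):
            assert np.allclose(a.frac, b.frac, atol=1e-6)

    def test_missing_cell_is_format_error(self, tmp_path):
        cif = tmp_path / "bad.cif"
        cif.write_text(
            "data_x\nloop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\nH1 H 0 0 0\n"
        )
        with pytest.raises(FormatError):
            parse_structure(cif)

    def test_unknown_element_is_format_error(self):
        with pytest.raises(FormatError):
            AtomSite("X1", "Xx", (0, 0, 0))

    def test_no_hydrogen_warns(self, tmp_path):
        cif = tmp_path / "noh.cif"
        cif.write_text(
            "data_x\n_cell_length_a 10\n_cell_length_b 10\n_cell_length_c 10\n"
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\nC1 C 0 0 0\n"
        )
        with pytest.warns(UserWarning, match="no hydrogen"):
            parse_structure(cif)

    def test_uncertainty_suffix_stripped(self, tmp_path):
        cif = tmp_path / "su.cif"
        cif.write_text(
            "data_x\n_cell_length_a 10.123(4)\n_cell_length_b 10\n_cell_length_c 10\n"
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "H1 H 0.5000(2) 0 0\n"
        )
        s = parse_structure(cif)
        assert s.cell.a == pytest.approx(10.123)
        assert s.sites[0].frac[0] == pytest.approx(0.5)


class TestExpandToP1:
    def test_idempotent_on_p1(self):
        s = p1(UnitCell(10, 10, 10), [AtomSite("H1", "H", (0.1, 0.2, 0.3))])
        assert expand_to_p1(s) is s

    def test_orbit_size_four(self):
        ops = [
            SymmetryOp.from_xyz(e)
            for e in ("x,y,z", "-x,-y,z", "x+1/2,-y,-z", "-x+1/2,y,-z")
        ]
        s = CrystalStructure(
            UnitCell(10, 10, 10), ops, [AtomSite("H1", "H", (0.13, 0.21, 0.34))]
        )
        assert len(expand_to_p1(s).sites) == 4

    def test_special_position_merged(self):
        # site on the inversion-fixed plane z=0 under (x,y,z), (x,y,-z),
        # plus two generic translations -> 2 distinct images of 4 operators
        ops = [
            SymmetryOp.from_xyz(e)
            for e in ("x,y,z", "x,y,-z", "x,y,z+1/2", "x,y,-z+1/2")
        ]
        s = CrystalStructure(UnitCell(10, 10, 10), ops, [AtomSite("H1", "H", (0.3, 0.3, 0.0))])
        assert len(expand_to_p1(s).sites) == 2

    def test_element_collision_raises(self):
        from dqcryst.structures import ConsistencyError

        ops = [SymmetryOp.from_xyz("x,y,z"), SymmetryOp.from_xyz("-x,-y,-z")]
        s = CrystalStructure(
            UnitCell(10, 10, 10),
            ops,
            [AtomSite("H1", "H", (0.1, 0, 0)), AtomSite("C1", "C", (0.9, 0, 0))],
        )
        with pytest.raises(ConsistencyError):
            expand_to_p1(s)


class TestEnumeratePairDistances:
    def test_isolated_pair(self):
        s = p1(
            UnitCell(50, 50, 50),
            [AtomSite("HA", "H", (0, 0, 0)), AtomSite("HB", "H", (0.06, 0, 0))],
        )
        groups = [ProtonSiteGroup("A", ("HA",)), ProtonSiteGroup("B", ("HB",))]
        pairs = enumerate_pair_distances(s, groups, 1000.0)
        cross = [q for q in pairs if not q.equivalent]
        assert len(cross) == 1
        assert np.allclose(cross[0].r_pm, [300.0])

    def test_cubic_self_pair_multiset(self):
        s = p1(UnitCell(4, 4, 4), [AtomSite("H1", "H", (0, 0, 0))])
        pair = enumerate_pair_distances(s, [ProtonSiteGroup("A", ("H1",))], 1000.0)[0]
        counts = collections.Counter(np.round(pair.r_pm, 1))
        assert counts[400.0] == 6
        assert counts[565.7] == 12
        assert counts[692.8] == 8
        assert counts[800.0] == 6
        assert counts[894.4] == 24

    def test_methyl_triangle_exact(self, methyl_pair):
        assert sorted(methyl_pair.r_pm) == pytest.approx([176.0, 178.0, 179.0], abs=1e-6)

    def test_unresolvable_label(self, methyl_structure):
        with pytest.raises(ConfigError):
            enumerate_pair_distances(
                methyl_structure, [ProtonSiteGroup("X", ("H9",))], 1000.0
            )

    def test_small_cutoff_rejected(self, methyl_structure, methyl_group):
        with pytest.raises(ConfigError):
            enumerate_pair_distances(methyl_structure, [methyl_group], 100.0)

    def test_too_close_contacts_raise(self):
        s = p1(
            UnitCell(50, 50, 50),
            [AtomSite("HA", "H", (0, 0, 0)), AtomSite("HB", "H", (0.0008, 0, 0))],
        )
        groups = [ProtonSiteGroup("A", ("HA",)), ProtonSiteGroup("B", ("HB",))]
        with pytest.raises(GeometryError):
            enumerate_pair_distances(s, groups, 1000.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random(self, seed):
        structure = make_random_structure(5, seed=seed)
        groups = [
            ProtonSiteGroup(f"G{i+1}", (s.label,)) for i, s in enumerate(structure.sites)
        ]
        pairs = enumerate_pair_distances(structure, groups, 1000.0)
        got = {
            tuple(sorted((q.j, q.k))): sorted(q.r_pm.tolist()) for q in pairs
        }
        expected = brute_force_pair_distances(structure, groups, 1000.0)
        assert set(got) == set(expected)
        for key in got:
            assert np.allclose(got[key], expected[key], atol=1e-6)

    def test_distance_symmetry(self, random_system):
        structure, groups, *_ = random_system
        fwd = enumerate_pair_distances(structure, groups, 800.0)
        rev = enumerate_pair_distances(structure, list(reversed(groups)), 800.0)
        fm = {tuple(sorted((q.j, q.k))): sorted(q.r_pm.tolist()) for q in fwd}
        rm = {tuple(sorted((q.j, q.k))): sorted(q.r_pm.tolist()) for q in rev}
        assert fm.keys() == rm.keys()
        for k in fm:
            assert np.allclose(fm[k], rm[k])

    def test_cutoff_monotonicity(self, random_system):
        structure, groups, *_ = random_system
        small = enumerate_pair_distances(structure, groups, 600.0)
        large = enumerate_pair_distances(structure, groups, 1000.0)
        small_m = {tuple(sorted((q.j, q.k))): sorted(q.r_pm.tolist()) for q in small}
        large_m = {tuple(sorted((q.j, q.k))): sorted(q.r_pm.tolist()) for q in large}
        for key, dists in small_m.items():
            kept = [r for r in large_m[key] if r <= 600.0 + 1e-9]
            assert np.allclose(dists, kept)

    @given(
        shift=st.tuples(
            st.floats(-0.9, 0.9), st.floats(-0.9, 0.9), st.floats(-0.9, 0.9)
        )
    )
    @settings(max_examples=20, deadline=None)
    def test_translation_invariance(self, shift):
        base = make_random_structure(4, seed=7)
        groups = [ProtonSiteGroup(f"G{i+1}", (s.label,)) for i, s in enumerate(base.sites)]
        moved = CrystalStructure(
            cell=base.cell,
            symmetry_ops=list(base.symmetry_ops),
            sites=[
                AtomSite(s.label, s.element, tuple(np.array(s.frac) + np.array(shift)))
                for s in base.sites
            ],
        )
        p_base = enumerate_pair_distances(base, groups, 900.0)
        p_moved = enumerate_pair_distances(moved, groups, 900.0)
        bm = {tuple(sorted((q.j, q.k))): sorted(q.r_pm.tolist()) for q in p_base}
        mm = {tuple(sorted((q.j, q.k))): sorted(q.r_pm.tolist()) for q in p_moved}
        assert bm.keys() == mm.keys()
        for k in bm:
            assert np.allclose(bm[k], mm[k], atol=1e-9)


class TestGroups:
    def test_fast_3site_needs_three(self):
        with pytest.raises(ConfigError):
            ProtonSiteGroup("X", ("H1",), motion="fast_3site")

    def test_load_groups(self, tmp_path):
        import json

        from dqcryst import load_groups

        path = tmp_path / "g.json"
        path.write_text(
            json.dumps(
                [
                    {"id": "CH3", "members": ["H1", "H2", "H3"], "motion": "fast_3site"},
                    {"id": "OH", "members": ["H4"], "shift": 9.2},
                ]
            )
        )
        groups = load_groups(path)
        assert groups[0].motion == "fast_3site"
        assert groups[1].shift == 9.2
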