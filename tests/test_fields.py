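"""Lattice construction, probe-energy and similarity-index fields."""

import numpy as np
import pytest

from qsar3d.chem import Atom, DataSet, Molecule
from qsar3d.fields import (COULOMB_CONSTANT, FieldConfig, FieldGenerator, GridSpec,
                           assemble_matrix, build_grid, comfa_electrostatic,
                           comfa_steric, comsia_field)


def point_mol(element="C", pos=(0.0, 0.0, 0.0), charge=0.0, radius=1.70,
              well_depth=0.107, hydrophobicity=1.0, donor=False, acceptor=False,
              mol_id="pt"):
    a = Atom(element=element, position=np.array(pos), partial_charge=charge,
             vdw_radius=radius, well_depth=well_depth,
             hydrophobicity=hydrophobicity, is_donor=donor, is_acceptor=acceptor)
    return Molecule(id=mol_id, atoms=[a])


class TestBuildGrid:
    def test_bounding_box_arithmetic(self):
        atoms = [Atom("C", p) for p in [(0, 0, 0), (10, 10, 10)]]
        data = DataSet([Molecule("m", atoms)])
        g = build_grid(data, spacing=2.0, margin=4.0)
        assert g.dims == (10, 10, 10)
        assert g.origin == (-4.0, -4.0, -4.0)

    def test_single_atom_grid(self):
        data = DataSet([point_mol()])
        g = build_grid(data, spacing=2.0, margin=4.0)
        assert g.dims == (5, 5, 5)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            build_grid(DataSet([point_mol()]), spacing=0.0)

    def test_empty_data(self):
        with pytest.raises(ValueError):
            build_grid([], spacing=2.0)

    def test_point_order_is_c_order(self):
        g = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(2, 2, 2))
        pts = g.points()
        assert np.allclose(pts[0], [0, 0, 0])
        assert np.allclose(pts[1], [0, 0, 1])  # z fastest
        assert np.allclose(pts[4], [1, 0, 0])


class TestComfaFields:
    def test_lj_minimum_at_contact_distance(self):
        cfg = FieldConfig()
        r_min = 1.70 + cfg.probe_radius
        g = GridSpec(origin=(r_min, 0.0, 0.0), spacing=40.0, dims=(2, 2, 2))
        e = comfa_steric(point_mol(), g, cfg)
        eps = np.sqrt(0.107 * cfg.probe_well_depth)
        assert e[0] == pytest.approx(-eps, abs=1e-10)

    def test_steric_clamped_at_cutoff_near_atom(self):
        g = GridSpec(origin=(0.1, 0.0, 0.0), spacing=40.0, dims=(2, 2, 2))
        e = comfa_steric(point_mol(), g)
        assert e[0] == pytest.approx(30.0)

    def test_steric_decays_to_zero(self):
        g = GridSpec(origin=(50.0, 0.0, 0.0), spacing=40.0, dims=(2, 2, 2))
        assert abs(comfa_steric(point_mol(), g)[0]) < 1e-6

    def test_electrostatic_closed_form(self):
        g = GridSpec(origin=(10.0, 0.0, 0.0), spacing=40.0, dims=(2, 2, 2))
        e = comfa_electrostatic(point_mol(charge=0.1), g)
        assert e[0] == pytest.approx(COULOMB_CONSTANT * 0.1 / 100.0, rel=1e-12)
        assert e[0] == pytest.approx(0.3322, abs=1e-4)

    def test_electrostatic_clamped(self):
        g = GridSpec(origin=(1.0, 0.0, 0.0), spacing=40.0, dims=(2, 2, 2))
        assert comfa_electrostatic(point_mol(charge=1.0), g)[0] == pytest.approx(30.0)

    def test_electrostatic_antisymmetric_for_mirrored_charges(self):
        atoms = [Atom("C", (0, 0, 1.0), partial_charge=0.5, vdw_radius=1.7, well_depth=0.107),
                 Atom("C", (0, 0, -1.0), partial_charge=-0.5, vdw_radius=1.7, well_depth=0.107)]
        mol = Molecule("dip", atoms)
        g = GridSpec(origin=(3.0, 0.0, -4.0), spacing=4.0, dims=(2, 2, 3))
        e = comfa_electrostatic(mol, g)
        pts = g.points()
        for i, p in enumerate(pts):
            mirror = p * np.array([1, 1, -1])
            j = np.argmin(np.linalg.norm(pts - mirror, axis=1))
            assert e[i] == pytest.approx(-e[j], abs=1e-10)

    def test_unparameterized_molecule_rejected(self):
        mol = Molecule("bare", [Atom("C", (0, 0, 0))])
        g = GridSpec(origin=(0, 0, 0), spacing=2.0, dims=(2, 2, 2))
        with pytest.raises(ValueError, match="parameters"):
            comfa_steric(mol, g)


class TestComsiaFields:
    def test_coincident_point_is_finite_and_closed_form(self):
        g = GridSpec(origin=(0.0, 0.0, 0.0), spacing=40.0, dims=(2, 2, 2))
        a = comsia_field(point_mol(), g, "S")
        assert a[0] == pytest.approx(-(1.70 ** 3), rel=1e-12)

    def test_gaussian_factor_at_2A(self):
        cfg = FieldConfig()
        g = GridSpec(origin=(2.0, 0.0, 0.0), spacing=40.0, dims=(2, 2, 2))
        a = comsia_field(point_mol(), g, "S", cfg)
        assert a[0] == pytest.approx(-(1.70 ** 3) * np.exp(-1.2), rel=1e-12)
        assert np.exp(-0.3 * 4.0) == pytest.approx(0.3012, abs=1e-4)

    def test_additivity_of_identical_atoms(self):
        single = point_mol()
        double = Molecule("two", [single.atoms[0], Atom("C", (0, 0, 0), vdw_radius=1.70,
                                                        well_depth=0.107, hydrophobicity=1.0)])
        g = GridSpec(origin=(1.5, 0.0, 0.0), spacing=40.0, dims=(2, 2, 2))
        assert comsia_field(double, g, "S")[0] == pytest.approx(2 * comsia_field(single, g, "S")[0])

    @pytest.mark.parametrize("prop,weight", [("E", 0.25), ("H", 1.0), ("D", 0.0), ("A", 0.0)])
    def test_property_weights(self, prop, weight):
        g = GridSpec(origin=(0.0, 0.0, 0.0), spacing=40.0, dims=(2, 2, 2))
        mol = point_mol(charge=0.25)
        assert comsia_field(mol, g, prop)[0] == pytest.approx(-weight)

    def test_unknown_property(self):
        g = GridSpec(origin=(0, 0, 0), spacing=2.0, dims=(2, 2, 2))
        with pytest.raises(ValueError, match="property"):
            comsia_field(point_mol(), g, "X")


def two_molecule_set(delta=1.0):
    m1 = point_mol(mol_id="a")
    m2 = point_mol(pos=(delta, 0, 0), charge=0.2, mol_id="b")
    return DataSet([m1, m2])


class TestAssembleMatrix:
    def test_column_count_before_masking(self):
        data = two_molecule_set()
        grid = build_grid(data, spacing=2.0, margin=4.0)
        fm = assemble_matrix(data, grid, FieldConfig(min_sigma=0.0), "CoMFA")
        assert fm.values.shape == (2, 2 * grid.n_points)

    def test_identical_molecules_filtered_to_nothing(self):
        m1 = point_mol(mol_id="a")
        m2 = point_mol(mol_id="b")
        data = DataSet([m1, m2])
        grid = build_grid(data)
        with pytest.raises(ValueError, match="filtered"):
            assemble_matrix(data, grid, FieldConfig(), "CoMFA")

    def test_assembly_is_deterministic(self):
        data = two_molecule_set()
        grid = build_grid(data)
        cfg = FieldConfig(min_sigma=0.0)
        a = assemble_matrix(data, grid, cfg, "CoMFA")
        b = assemble_matrix(data, grid, cfg, "CoMFA")
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.active_mask, b.active_mask)
        assert a.block_scales == b.block_scales

    def test_far_away_molecule_contributes_nothing(self):
        near = point_mol(mol_id="a")
        near2 = point_mol(pos=(1.0, 0, 0), mol_id="b")
        far = point_mol(pos=(200.0, 0, 0), mol_id="far")
        grid = build_grid(DataSet([near, near2]))
        fm = FieldGenerator(method="CoMSIA", fields=("S",),
                            config=FieldConfig(min_sigma=0.0), grid=grid).fit(
            DataSet([near, near2, far])).matrix_
        assert np.abs(fm.values[2]).max() < 1e-6

    def test_rigid_motion_invariance(self):
        """Moving molecules and lattice together (translation + proper
        axis-permutation rotation) leaves every field value unchanged."""
        data = two_molecule_set()
        grid = GridSpec(origin=(-3.0, -2.0, -4.0), spacing=2.0, dims=(4, 3, 5))
        cfg = FieldConfig(min_sigma=0.0)
        fm = assemble_matrix(data, grid, cfg, "CoMFA")
        # x->y, y->z, z->x (det=+1) plus a translation
        P = np.array([[0.0, 0, 1], [1, 0, 0], [0, 1, 0]])
        t = np.array([5.0, -7.0, 11.0])
        moved = data.copy()
        for m in moved:
            m.coords = m.coords @ P.T + t
        o = np.asarray(grid.origin) @ P.T + t
        grid2 = GridSpec(origin=tuple(o), spacing=grid.spacing,
                         dims=(grid.dims[2], grid.dims[0], grid.dims[1]))
        fm2 = assemble_matrix(moved, grid2, cfg, "CoMFA")
        # compare per lattice position
        lut = {tuple(np.round(p @ P.T + t, 6)): i for i, p in enumerate(grid.points())}
        perm = [lut[tuple(np.round(p, 6))] for p in grid2.points()]
        g = grid.n_points
        for block in range(2):
            v1 = fm.values[:, block * g:(block + 1) * g]
            v2 = fm2.values[:, block * g:(block + 1) * g]
            assert np.abs(v1[:, perm] - v2).max() < 1e-9

    def test_steric_never_exceeds_cutoff(self):
        data = two_molecule_set(delta=0.5)
        grid = build_grid(data, spacing=1.0)
        fm = assemble_matrix(data, grid, FieldConfig(min_sigma=0.0), "CoMFA")
        g = grid.n_points
        assert fm.values[:, :g].max() <= 30.0 + 1e-12

    def test_electrostatic_excluded_points_get_column_mean(self):
        # three molecules; at a point inside molecule c's atom the steric
        # field clamps, so c's electrostatic value there must equal the
        # mean of the others'
        a = point_mol(charge=0.3, mol_id="a")
        b = point_mol(pos=(2.0, 0, 0), charge=-0.1, mol_id="b")
        c = point_mol(pos=(4.0, 0, 0), charge=0.5, mol_id="c")
        data = DataSet([a, b, c])
        grid = build_grid(data, spacing=2.0, margin=4.0)
        cfg = FieldConfig(min_sigma=0.0)
        fm = assemble_matrix(data, grid, cfg, "CoMFA")
        g = grid.n_points
        steric = fm.values[:, :g]
        elec = fm.values[:, g:]
        excl = steric >= cfg.energy_cutoff
        pt = next(j for j in range(g) if excl[2, j] and not excl[0, j] and not excl[1, j])
        assert elec[2, pt] == pytest.approx(np.mean([elec[0, pt], elec[1, pt]]))

    def test_block_scaling_equalizes_pooled_variance(self):
        data = two_molecule_set()
        grid = build_grid(data)
        fm = assemble_matrix(data, grid, FieldConfig(min_sigma=0.0, block_scaling="block_std"), "CoMFA")
        X = fm.descriptors
        fields = fm.active_fields
        pooled = [np.sqrt(np.mean(X[:, fields == f].std(axis=0, ddof=1) ** 2)) for f in ("S", "E")]
        assert pooled[0] == pytest.approx(pooled[1], rel=1e-9)

    def test_transform_projects_new_molecules_onto_training_columns(self):
        data = two_molecule_set()
        gen = FieldGenerator(method="CoMFA", config=FieldConfig(min_sigma=0.0)).fit(data)
        new = DataSet([point_mol(pos=(0.5, 0, 0), charge=0.1, mol_id="new")])
        fm = gen.transform(new)
        assert fm.descriptors.shape == (1, gen.matrix_.descriptors.shape[1])
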