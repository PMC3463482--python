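"""Dielectric rasterization, ion accessibility and charge distribution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fdpb.core import (
    Atom,
    DielectricAveraging,
    GridSpec,
    RunParameters,
    SurfaceMode,
    build_grid,
)
from fdpb.mapping import (
    Box,
    Cone,
    Cylinder,
    Sphere,
    build_dielectric_map,
    build_ion_mask,
    distribute_charges,
    parse_object_declaration,
    _midpoint_axes,
)

SHARP = dict(dielectric_averaging=DielectricAveraging.SHARP)


def midpoint_lattice_points(grid, axis):
    x, y, z = _midpoint_axes(grid, axis)
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


class TestVdwDielectric:
    def test_single_atom_sharp_assignment_matches_distance_oracle(self):
        params = RunParameters(scale=2.0, eps_interior={0: 2.0}, eps_solvent=80.0,
                               surface=SurfaceMode.VDW, **SHARP)
        atom = Atom(position=(0.1, -0.2, 0.3), radius=2.0, charge=0.0)
        grid = build_grid([atom], [], params)
        dm = build_dielectric_map([atom], [], grid, params)
        for axis, lattice in enumerate(dm.values()):
            pts = midpoint_lattice_points(grid, axis)
            d = np.linalg.norm(pts - np.array(atom.position), axis=-1)
            expected = np.where(d <= 2.0, 2.0, 80.0)
            assert np.array_equal(lattice, expected)

    def test_two_regions_yield_exactly_three_values(self):
        params = RunParameters(
            scale=2.0, eps_interior={0: 4.0, 1: 10.0}, eps_solvent=80.0,
            surface=SurfaceMode.VDW, **SHARP,
        )
        atoms = [
            Atom(position=(-4.0, 0, 0), radius=2.0, charge=0.0, region_id=0),
            Atom(position=(4.0, 0, 0), radius=2.0, charge=0.0, region_id=1),
        ]
        grid = build_grid(atoms, [], params)
        dm = build_dielectric_map(atoms, [], grid, params)
        values = set()
        for lattice in dm.values():
            values |= set(np.unique(lattice))
        assert values == {4.0, 10.0, 80.0}

    def test_undeclared_region_rejected(self):
        params = RunParameters(scale=2.0, eps_interior={0: 4.0})
        atom = Atom(position=(0, 0, 0), radius=1.0, charge=0.0, region_id=5)
        grid = GridSpec(n=9, scale=2.0, origin=(-2, -2, -2))
        with pytest.raises(ValueError, match="region 5"):
            build_dielectric_map([atom], [], grid, params)

    def test_later_declaration_wins_overlap(self):
        params = RunParameters(
            scale=2.0, eps_interior={0: 4.0, 1: 10.0}, eps_solvent=80.0,
            surface=SurfaceMode.VDW, **SHARP,
        )
        atoms = [
            Atom(position=(0, 0, 0), radius=2.0, charge=0.0, region_id=0),
            Atom(position=(0.5, 0, 0), radius=2.0, charge=0.0, region_id=1),
        ]
        grid = build_grid(atoms, [], params)
        dm = build_dielectric_map(atoms, [], grid, params)
        # a midpoint near the shared centre lies in both spheres: region 1 wins
        pts = midpoint_lattice_points(grid, 0)
        inside_both = (
            np.linalg.norm(pts - [0, 0, 0], axis=-1) <= 2.0
        ) & (np.linalg.norm(pts - [0.5, 0, 0], axis=-1) <= 2.0)
        assert np.all(dm.eps_x[inside_both] == 10.0)

    def test_mirror_symmetric_scene_gives_mirror_symmetric_map(self):
        params = RunParameters(scale=2.0, eps_interior={0: 4.0},
                               surface=SurfaceMode.VDW)
        atoms = [
            Atom(position=(-3.0, 0, 0), radius=1.5, charge=0.0),
            Atom(position=(3.0, 0, 0), radius=1.5, charge=0.0),
        ]
        grid = build_grid(atoms, [], params)
        dm = build_dielectric_map(atoms, [], grid, params)
        # reflect through the yz-plane: x-midpoints flip across the lattice
        assert np.allclose(dm.eps_x, dm.eps_x[::-1, :, :])
        assert np.allclose(dm.eps_y, dm.eps_y[::-1, :, :])


class TestHarmonicAveraging:
    def test_values_bracketed_and_pure_away_from_surface(self):
        params = RunParameters(scale=2.0, eps_interior={0: 2.0}, eps_solvent=80.0,
                               surface=SurfaceMode.VDW)
        atom = Atom(position=(0, 0, 0), radius=2.0, charge=0.0)
        grid = build_grid([atom], [], params)
        dm = build_dielectric_map([atom], [], grid, params)
        h = grid.spacing
        for axis, lattice in enumerate(dm.values()):
            assert np.all(lattice >= 2.0 - 1e-12)
            assert np.all(lattice <= 80.0 + 1e-12)
            pts = midpoint_lattice_points(grid, axis)
            d = np.linalg.norm(pts - np.array(atom.position), axis=-1)
            assert np.all(lattice[d <= 2.0 - h] == 2.0)
            assert np.all(lattice[d >= 2.0 + h] == 80.0)

    def test_edge_fraction_matches_segment_sampling_oracle(self):
        """Harmonic values agree with dense segment sampling of the sphere."""
        params = RunParameters(scale=1.6, eps_interior={0: 3.0}, eps_solvent=80.0,
                               surface=SurfaceMode.VDW)
        atom = Atom(position=(0.17, 0.05, -0.11), radius=1.9, charge=0.0)
        grid = build_grid([atom], [], params)
        dm = build_dielectric_map([atom], [], grid, params)
        h = grid.spacing
        x, y, z = _midpoint_axes(grid, 0)
        ts = (np.arange(4000) + 0.5) / 4000 - 0.5  # samples along the edge
        rng = np.random.default_rng(5)
        pts = midpoint_lattice_points(grid, 0)
        d = np.linalg.norm(pts - np.array(atom.position), axis=-1)
        idx = np.argwhere(np.abs(d - 1.9) < h)  # near-surface edges only
        for i, j, k in idx[rng.choice(len(idx), size=20, replace=False)]:
            centre = pts[i, j, k]
            samples = centre[None, :] + np.outer(ts * h, [1.0, 0.0, 0.0])
            frac = np.mean(
                np.linalg.norm(samples - np.array(atom.position), axis=-1) <= 1.9
            )
            # compare reciprocals: 1/eps is linear in the edge fraction, so
            # the sampling-oracle error does not blow up near frac -> 0
            expected_recip = frac / 3.0 + (1.0 - frac) / 80.0
            assert 1.0 / dm.eps_x[i, j, k] == pytest.approx(expected_recip, abs=1e-3)


class TestSesDielectric:
    def test_ses_interior_contains_vdw_interior(self):
        """The probe-rolled surface fills crevices: SES volume >= vdW volume."""
        rng = np.random.default_rng(11)
        for trial in range(3):
            atoms = [
                Atom(position=tuple(p), radius=float(r), charge=0.0)
                for p, r in zip(
                    rng.uniform(-3, 3, size=(5, 3)), rng.uniform(1.2, 2.0, 5)
                )
            ]
            params_v = RunParameters(scale=2.0, eps_interior={0: 2.0},
                                     surface=SurfaceMode.VDW, **SHARP)
            params_s = params_v.with_(surface=SurfaceMode.SES)
            grid = build_grid(atoms, [], params_v)
            vdw = build_dielectric_map(atoms, [], grid, params_v)
            ses = build_dielectric_map(atoms, [], grid, params_s)
            for lv, ls in zip(vdw.values(), ses.values()):
                assert np.all(ls[lv == 2.0] == 2.0)
            assert ses.interior_midpoint_count(80.0) >= vdw.interior_midpoint_count(80.0)

    def test_single_sphere_ses_stays_near_the_sphere(self):
        """For one atom the SES equals the sphere up to lattice resolution."""
        params = RunParameters(scale=2.0, eps_interior={0: 2.0},
                               surface=SurfaceMode.SES, **SHARP)
        atom = Atom(position=(0, 0, 0), radius=2.0, charge=0.0)
        grid = build_grid([atom], [], params)
        dm = build_dielectric_map([atom], [], grid, params)
        h = grid.spacing
        for axis, lattice in enumerate(dm.values()):
            pts = midpoint_lattice_points(grid, axis)
            d = np.linalg.norm(pts, axis=-1)
            assert np.all(lattice[d <= 2.0 - h] == 2.0)
            assert np.all(lattice[d >= 2.0 + 2.0 * h] == 80.0)

    def test_zero_probe_reduces_to_vdw(self):
        params_s = RunParameters(scale=2.0, eps_interior={0: 2.0}, probe_radius=0.0,
                                 surface=SurfaceMode.SES, **SHARP)
        params_v = params_s.with_(surface=SurfaceMode.VDW)
        atoms = [
            Atom(position=(-1.0, 0, 0), radius=1.5, charge=0.0),
            Atom(position=(1.5, 0.5, 0), radius=1.2, charge=0.0),
        ]
        grid = build_grid(atoms, [], params_v)
        a = build_dielectric_map(atoms, [], grid, params_s)
        b = build_dielectric_map(atoms, [], grid, params_v)
        for la, lb in zip(a.values(), b.values()):
            assert np.array_equal(la, lb)


class TestObjects:
    def test_membership_predicates(self):
        s = Sphere((0, 0, 0), 2.0)
        assert s.contains(np.array([2.0, 0, 0]))  # surface is interior
        assert not s.contains(np.array([2.0001, 0, 0]))
        b = Box((0, 0, 0), (2.0, 4.0, 6.0))
        assert b.contains(np.array([1.0, 2.0, 3.0]))
        assert not b.contains(np.array([1.1, 0, 0]))
        c = Cylinder((0, 0, 0), (0, 0, 4.0), 1.0)
        assert c.contains(np.array([0.5, 0, 2.0]))
        assert not c.contains(np.array([0.0, 0, 4.5]))
        k = Cone((0, 0, 0), (0, 0, 4.0), 2.0)
        assert k.contains(np.array([0, 0.9, 2.0]))  # r_max = 1 at half-height
        assert not k.contains(np.array([0, 1.1, 2.0]))
        assert k.contains(np.array([0, 1.9, 4.0]))  # base disc included

    def test_rasterized_volume_converges_to_analytic(self):
        """Interior midpoint volume approaches 4/3 pi r^3 and a box volume."""
        sphere_errs, box_errs = [], []
        for scale in (1.0, 2.0, 4.0):
            params = RunParameters(
                scale=scale, perfil=50.0, eps_interior={0: 2.0, 1: 2.0},
                surface=SurfaceMode.VDW, **SHARP,
            )
            objs = [Sphere((0, 0, 0), 3.0, region_id=0)]
            grid = build_grid([], objs, params)
            dm = build_dielectric_map([], objs, grid, params)
            vol = dm.interior_midpoint_count(80.0) / 3.0 * grid.spacing**3
            sphere_errs.append(abs(vol - 4.0 / 3.0 * math.pi * 27.0))
            objs = [Box((0, 0, 0), (4.0, 3.0, 5.0), region_id=1)]
            grid = build_grid([], objs, params)
            dm = build_dielectric_map([], objs, grid, params)
            vol = dm.interior_midpoint_count(80.0) / 3.0 * grid.spacing**3
            box_errs.append(abs(vol - 60.0))
        assert sphere_errs[2] < sphere_errs[0]
        assert box_errs[2] <= box_errs[0]

    def test_declaration_round_trip(self):
        for text in (
            "sphere;0;0;0;10;0;0",
            "box;1;2;3;4;5;6;1;0.5",
            "cylinder;0;0;0;0;0;5;1.5;0",
            "cone;0;0;0;3;0;0;2;1",
        ):
            obj = parse_object_declaration(text)
            assert obj.kind == text.split(";")[0]
        with pytest.raises(ValueError, match="unknown object kind"):
            parse_object_declaration("torus;1;2;3")
        with pytest.raises(ValueError, match="malformed"):
            parse_object_declaration("sphere;1;2")


class TestIonMask:
    def test_no_atoms_all_accessible(self):
        grid = GridSpec(n=9, scale=1.0, origin=(-4, -4, -4))
        mask = build_ion_mask([], [], grid, RunParameters())
        assert mask.all()

    def test_matches_exhaustive_distance_oracle(self):
        params = RunParameters(scale=2.0, ion_exclusion_radius=2.0)
        atoms = [
            Atom(position=(0.3, -0.7, 1.1), radius=1.5, charge=0.0),
            Atom(position=(-2.0, 1.0, 0.0), radius=2.0, charge=0.0),
        ]
        grid = build_grid(atoms, [], params)
        assert grid.n <= 33
        mask = build_ion_mask(atoms, [], grid, params)
        for i in range(grid.n):
            for j in range(grid.n):
                for k in range(grid.n):
                    p = grid.node_position(i, j, k)
                    expected = all(
                        np.linalg.norm(p - a.xyz) > a.radius + 2.0 for a in atoms
                    )
                    assert mask[i, j, k] == expected

    def test_zero_exclusion_reduces_to_vdw(self):
        params0 = RunParameters(scale=2.0, ion_exclusion_radius=0.0)
        atom = Atom(position=(0, 0, 0), radius=2.0, charge=0.0)
        grid = build_grid([atom], [], params0)
        mask = build_ion_mask([atom], [], grid, params0)
        x, y, z = grid.node_positions()
        d = np.sqrt(x**2 + y**2 + z**2)
        assert np.array_equal(mask, d > 2.0)

    def test_objects_exclude_ions(self):
        params = RunParameters(scale=1.0, eps_interior={0: 2.0})
        sphere = Sphere((0, 0, 0), 3.0)
        grid = GridSpec(n=11, scale=1.0, origin=(-5, -5, -5))
        mask = build_ion_mask([], [sphere], grid, params)
        assert not mask[5, 5, 5]
        assert mask[0, 0, 0]


class TestChargeDistribution:
    def test_charge_on_node_stays_on_node(self):
        grid = GridSpec(n=9, scale=2.0, origin=(-2, -2, -2))
        atom = Atom(position=(0, 0, 0), radius=1.0, charge=2.5)
        ch = distribute_charges([atom], [], grid)
        assert ch[4, 4, 4] == 2.5
        assert np.count_nonzero(ch) == 1

    def test_cell_centre_splits_into_eight_equal_weights(self):
        grid = GridSpec(n=9, scale=2.0, origin=(-2, -2, -2))
        atom = Atom(position=(0.25, 0.25, 0.25), radius=1.0, charge=1.0)
        ch = distribute_charges([atom], [], grid)
        nz = ch[ch != 0.0]
        assert len(nz) == 8
        assert np.allclose(nz, 0.125)

    @given(
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=10)
    def test_total_charge_conserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n_atoms = 1000
        grid = GridSpec(n=21, scale=1.0, origin=(-10, -10, -10))
        pos = rng.uniform(-8.5, 8.5, size=(n_atoms, 3))
        q = rng.uniform(-1, 1, size=n_atoms)
        atoms = [
            Atom(position=tuple(p), radius=1.0, charge=float(c))
            for p, c in zip(pos, q)
        ]
        ch = distribute_charges(atoms, [], grid)
        assert ch.sum() == pytest.approx(q.sum(), rel=1e-12, abs=1e-12)

    def test_dipole_moment_error_shrinks_quadratically(self):
        pos = np.array([0.37, -0.21, 0.43])
        atom = Atom(position=tuple(pos), radius=1.0, charge=1.0)

        def dipole_error(scale):
            grid = GridSpec(n=int(8 * scale) + 1, scale=scale, origin=(-4, -4, -4))
            ch = distribute_charges([atom], [], grid)
            x, y, z = grid.node_positions()
            dip = np.array(
                [(ch * x).sum(), (ch * y).sum(), (ch * z).sum()]
            )
            return np.linalg.norm(dip - pos)

        # trilinear weights reproduce the first moment exactly
        assert dipole_error(1.0) < 1e-12
        assert dipole_error(2.0) < 1e-12

    def test_charge_outside_interior_names_atom(self):
        grid = GridSpec(n=9, scale=1.0, origin=(-4, -4, -4))
        atoms = [
            Atom(position=(0, 0, 0), radius=1.0, charge=1.0),
            Atom(position=(3.9, 0, 0), radius=1.0, charge=1.0),
        ]
        with pytest.raises(ValueError, match="atom 1"):
            distribute_charges(atoms, [], grid)

    def test_charged_object_conserves_total(self):
        grid = GridSpec(n=17, scale=1.0, origin=(-8, -8, -8))
        sphere = Sphere((0, 0, 0), 3.0, region_id=0, charge=5.0)
        ch = distribute_charges([], [sphere], grid)
        assert ch.sum() == pytest.approx(5.0, rel=1e-12)
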