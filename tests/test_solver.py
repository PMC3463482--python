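"""Red/black SOR solver: stencil correctness, convergence and symmetries."""

import math
import warnings

import numpy as np
import pytest

import fdpb._kernels as kernels
from fdpb.core import (
    Atom,
    BoundaryCondition,
    RunParameters,
    SaltSpecies,
    SurfaceMode,
    build_grid,
    coulomb_prefactor,
    debye_parameter,
)
from fdpb.fixtures import make_born_sphere
from fdpb.mapping import build_dielectric_map, build_ion_mask, distribute_charges
from fdpb.solver import (
    ConvergenceWarning,
    SolverConfig,
    boundary_potential,
    optimal_omega,
    solve_linear,
    solve_nonlinear,
    stencil_residual,
    _prepare_linear,
)
from fdpb.core import DEFAULT_CONSTANTS


def _assemble(scene):
    grid = scene.grid_override or build_grid(scene.atoms, scene.objects, scene.params)
    diel = build_dielectric_map(scene.atoms, scene.objects, grid, scene.params)
    mask = build_ion_mask(scene.atoms, scene.objects, grid, scene.params)
    charges = distribute_charges(scene.atoms, scene.objects, grid)
    bc = boundary_potential(scene.atoms, scene.objects, grid, scene.params)
    return grid, diel, mask, charges, bc


def _uniform_scene(charge=10.0, eps=80.0, scale=2.0, perfil=50.0, salts=()):
    return make_born_sphere(
        charge=charge, radius=5.0, eps_in=eps, eps_out=eps,
        scale=scale, perfil=perfil, salts=salts,
    )


class TestOptimalOmega:
    def test_approaches_two_for_large_grids(self):
        assert optimal_omega(1001) > 1.99
        assert optimal_omega(5) < optimal_omega(65) < 2.0

    def test_out_of_range_omega_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(relaxation_omega=2.0)
        with pytest.raises(ValueError):
            SolverConfig(relaxation_omega=0.0)

    def test_sor_beats_plain_gauss_seidel(self):
        scene = _uniform_scene(scale=2.0, perfil=31.5)  # N = 65
        grid, diel, mask, charges, bc = _assemble(scene)
        assert grid.n == 65
        fast = solve_linear(diel, charges, mask, grid, scene.params, boundary=bc)
        slow = solve_linear(
            diel, charges, mask, grid, scene.params,
            SolverConfig(relaxation_omega=1.0, max_iterations=20000), boundary=bc,
        )
        assert fast.converged and slow.converged
        assert fast.iterations_used < slow.iterations_used


class TestBoundaryPotential:
    def test_no_charges_all_faces_zero(self):
        scene = _uniform_scene(charge=0.0)
        grid, *_ = _assemble(scene)
        bc = boundary_potential([], [], grid, scene.params)
        assert not bc.any()

    def test_debye_huckel_equals_coulombic_without_salt(self):
        scene = _uniform_scene()
        grid, *_ = _assemble(scene)
        a = boundary_potential(scene.atoms, [], grid, scene.params,
                               mode=BoundaryCondition.COULOMBIC)
        b = boundary_potential(scene.atoms, [], grid, scene.params,
                               mode=BoundaryCondition.DEBYE_HUCKEL)
        assert np.array_equal(a, b)

    def test_face_values_match_hand_formula(self):
        scene = _uniform_scene(charge=3.0, salts=(SaltSpecies(0.1, 1),
                                                  SaltSpecies(0.1, -1)))
        params = scene.params.with_(boundary_condition=BoundaryCondition.DEBYE_HUCKEL)
        grid, *_ = _assemble(scene)
        bc = boundary_potential(scene.atoms, [], grid, params)
        cu = coulomb_prefactor()
        kappa = debye_parameter(params.salts, params.eps_solvent)
        n = grid.n
        for idx in [(0, 0, 0), (n - 1, 3, 5), (2, 0, n - 4), (4, n - 1, 1),
                    (n - 1, n - 1, n - 1)]:
            p = grid.node_position(*idx)
            d = np.linalg.norm(p)  # single source at the origin
            expected = cu * 3.0 * math.exp(-kappa * d) / (80.0 * d)
            assert bc[idx] == pytest.approx(expected, rel=1e-12)


class TestLinearSolve:
    def test_zero_charge_zero_boundary_is_identically_zero(self):
        scene = _uniform_scene(charge=0.0)
        grid, diel, mask, charges, _ = _assemble(scene)
        res = solve_linear(diel, charges, mask, grid, scene.params,
                           boundary=np.zeros((grid.n,) * 3))
        assert res.converged and res.iterations_used == 1
        assert not res.values.any()

    def test_uniform_medium_matches_coulomb_oracle(self):
        """Away from the charge the FD potential follows C_u q/(eps d).

        The 7-point lattice Green's function deviates from 1/(4 pi d) by a
        direction-dependent O((h/d)^2) term, largest on-axis: about 4% at
        3h and below 2% beyond 6h, which is what is asserted.
        """
        scene = _uniform_scene(charge=10.0, scale=2.0, perfil=30.0)
        grid, diel, mask, charges, bc = _assemble(scene)
        res = solve_linear(diel, charges, mask, grid, scene.params, boundary=bc)
        cu = coulomb_prefactor()
        c = (grid.n - 1) // 2
        h = grid.spacing
        x, y, z = grid.node_positions()
        d = np.sqrt(x * x + y * y + z * z)
        analytic = np.where(d > 0, cu * 10.0 / (80.0 * np.maximum(d, h)), 0.0)
        rel = np.abs((res.values - analytic) / np.where(d > 0, analytic, 1.0))
        assert np.max(rel[d >= 3 * h]) < 0.05
        assert np.max(rel[d >= 6 * h]) < 0.02

    def test_residual_below_tolerance_at_convergence(self):
        scene = make_born_sphere(radius=2.0, scale=2.0)
        grid, diel, mask, charges, bc = _assemble(scene)
        res = solve_linear(diel, charges, mask, grid, scene.params, boundary=bc)
        assert res.converged
        source, den = _prepare_linear(
            diel, charges, mask, grid, scene.params, DEFAULT_CONSTANTS
        )
        assert stencil_residual(res.values, diel, source, den) <= scene.params.tolerance

    def test_superposition_of_charges(self):
        """With fixed maps the linear PBE is linear in the source charges."""
        params = RunParameters(scale=2.0, eps_interior={0: 4.0},
                               surface=SurfaceMode.VDW)
        a1 = Atom(position=(-1.5, 0, 0), radius=1.5, charge=5.0)
        a2 = Atom(position=(2.0, 0.5, 0), radius=1.5, charge=-3.0)
        both = [a1, a2]
        grid = build_grid(both, [], params)
        diel = build_dielectric_map(both, [], grid, params)
        mask = build_ion_mask(both, [], grid, params)

        def solve_subset(atoms):
            charges = distribute_charges(atoms, [], grid)
            bc = boundary_potential(atoms, [], grid, params)
            cfg = SolverConfig(tolerance=1e-7, max_iterations=20000)
            return solve_linear(diel, charges, mask, grid, params, cfg, bc).values

        total = solve_subset(both)
        parts = solve_subset([a1]) + solve_subset([a2])
        assert np.max(np.abs(total - parts)) < 5e-5

    def test_mirror_symmetric_scene_gives_symmetric_potential(self):
        params = RunParameters(scale=2.0, eps_interior={0: 4.0},
                               surface=SurfaceMode.VDW, tolerance=1e-6)
        atoms = [
            Atom(position=(-3.0, 0, 0), radius=1.5, charge=4.0),
            Atom(position=(3.0, 0, 0), radius=1.5, charge=4.0),
        ]
        grid = build_grid(atoms, [], params)
        diel = build_dielectric_map(atoms, [], grid, params)
        mask = build_ion_mask(atoms, [], grid, params)
        charges = distribute_charges(atoms, [], grid)
        bc = boundary_potential(atoms, [], grid, params)
        res = solve_linear(diel, charges, mask, grid, params, boundary=bc)
        assert np.max(np.abs(res.values - res.values[::-1, :, :])) < 1e-8

    def test_iteration_cap_flags_non_convergence(self):
        scene = make_born_sphere(radius=2.0, scale=2.0)
        grid, diel, mask, charges, bc = _assemble(scene)
        cfg = SolverConfig(max_iterations=1)
        with pytest.warns(ConvergenceWarning):
            res = solve_linear(diel, charges, mask, grid, scene.params, cfg, bc)
        assert not res.converged
        assert res.iterations_used == 1

    def test_numba_kernel_matches_numpy_fallback(self, monkeypatch):
        if not kernels.HAVE_NUMBA:
            return  # fallback is already the only path
        scene = make_born_sphere(radius=2.0, scale=2.0, perfil=40.0)
        grid, diel, mask, charges, bc = _assemble(scene)
        fast = solve_linear(diel, charges, mask, grid, scene.params, boundary=bc)
        monkeypatch.setattr(kernels, "HAVE_NUMBA", False)
        slow = solve_linear(diel, charges, mask, grid, scene.params, boundary=bc)
        assert np.array_equal(fast.values, slow.values)


class TestNonlinearSolve:
    SALT = (SaltSpecies(0.1, 1), SaltSpecies(0.1, -1))

    def _solve_pair(self, charge, salts, **kw):
        scene = make_born_sphere(charge=charge, radius=2.0, scale=2.0,
                                 perfil=40.0, salts=salts, **kw)
        grid, diel, mask, charges, bc = _assemble(scene)
        lin = solve_linear(diel, charges, mask, grid, scene.params, boundary=bc)
        nl = solve_nonlinear(diel, charges, mask, grid, scene.params, boundary=bc)
        return lin, nl

    def test_zero_salt_identical_to_linear(self):
        lin, nl = self._solve_pair(5.0, ())
        assert np.max(np.abs(lin.values - nl.values)) < 1e-10

    def test_weak_potential_limit_agrees_with_linear(self):
        lin, nl = self._solve_pair(0.01, self.SALT)
        assert nl.converged
        scale = np.abs(lin.values)
        mask = scale > 1e-6 * scale.max()
        rel = np.abs(nl.values[mask] - lin.values[mask]) / np.abs(lin.values[mask])
        assert np.max(rel) < 1e-3

    def test_symmetric_salt_gives_odd_potential(self):
        _, nl_plus = self._solve_pair(10.0, self.SALT)
        _, nl_minus = self._solve_pair(-10.0, self.SALT)
        assert nl_plus.converged and nl_minus.converged
        assert np.max(np.abs(nl_plus.values + nl_minus.values)) < 1e-9

    def test_strong_charge_screens_more_than_linear(self):
        """Boltzmann ions screen a strong charge harder than the linear term."""
        lin, nl = self._solve_pair(10.0, self.SALT)
        assert nl.converged
        assert np.max(np.abs(nl.values - lin.values)) > 1.0
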