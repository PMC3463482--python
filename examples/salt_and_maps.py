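"""Salt screening, the nonlinear PBE and volumetric map export.

A +10 e sphere in 0.1 M 1:1 salt: the linear PBE screens with the Debye
factor, the full nonlinear PBE lets counterions pile up Boltzmann-style.
The potential and the total ion concentration are written as OpenDX maps.
"""

import numpy as np

from fdpb import (
    SaltSpecies,
    VolumeMap,
    build_grid,
    debye_parameter,
    ion_concentration_map,
    write_volume_map,
)
from fdpb.fixtures import make_born_sphere
from fdpb.mapping import build_dielectric_map, build_ion_mask, distribute_charges
from fdpb.solver import boundary_potential, solve_linear, solve_nonlinear

salts = (SaltSpecies(0.1, 1), SaltSpecies(0.1, -1))
print(f"Debye screening length at 0.1 M 1:1: {1/debye_parameter(salts, 80.0):.2f} Å")

scene = make_born_sphere(charge=10.0, radius=2.0, scale=2.0, perfil=25.0,
                         salts=salts)
grid = build_grid(scene.atoms, [], scene.params)
diel = build_dielectric_map(scene.atoms, [], grid, scene.params)
mask = build_ion_mask(scene.atoms, [], grid, scene.params)
charges = distribute_charges(scene.atoms, [], grid)
bc = boundary_potential(scene.atoms, [], grid, scene.params)

linear = solve_linear(diel, charges, mask, grid, scene.params, boundary=bc)
nonlin = solve_nonlinear(diel, charges, mask, grid, scene.params, boundary=bc)
print(f"grid: N={grid.n}; linear solve {linear.iterations_used} sweeps, "
      f"nonlinear {nonlin.iterations_used} total sweeps")

# probe the potential along +x from the sphere surface outwards
c = (grid.n - 1) // 2
h = grid.spacing
print("  x (Å)   phi linear (kT/e)   phi nonlinear (kT/e)")
for k in (4, 6, 8, 10):
    print(f"  {k*h:5.1f}   {linear.values[c+k, c, c]:14.3f}   "
          f"{nonlin.values[c+k, c, c]:14.3f}")

cation, anion = ion_concentration_map(nonlin, salts, mask)
print(f"anion concentration at the Stern surface: "
      f"{anion[mask].max():.2f} mol/L (bulk 0.10)")

write_volume_map(VolumeMap(grid=grid, values=nonlin.values, kind="potential"),
                 "opendx", "potential.dx")
write_volume_map(
    VolumeMap(grid=grid, values=cation + anion, kind="ion_concentration"),
    "opendx", "ions.dx")
print("wrote potential.dx and ions.dx (OpenDX scalar grids)")
print("\nThe nonlinear potential is weaker than the linear one near the "
      "solute:\nBoltzmann counterion crowding screens a strong charge more "
      "efficiently\nthan the linearized salt term.")
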