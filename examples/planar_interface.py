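"""A charged sphere crossing a planar dielectric interface.

Space is split at x=0 into eps1=2 (left) and eps2=80 (right).  A 2 Å sphere
of eps1 carrying 1 e sits at signed distance d from the plane; its solvation
energy has a closed image-charge form on both sides (undefined only while
the sphere straddles the plane).  The grid scene realises the half-space as
a cube-spanning box object and uses the exact image potential as the
boundary condition.
"""

from fdpb import PlanarInterfaceSystem, planar_interface_energy, solvation_energy
from fdpb.fixtures import make_planar_interface

print("   d (Å)   closed form (kT)   grid engine (kT)   deviation")
for d in (10.0, 6.0, 4.0, -4.0, -6.0, -10.0):
    exact = planar_interface_energy(PlanarInterfaceSystem(distance=d))
    result = solvation_energy(make_planar_interface(d, scale=2.0))
    err = 100.0 * (result.energy - exact) / exact
    print(f"  {d:+6.0f}   {exact:14.3f}    {result.energy:14.3f}    {err:+7.2f}%")

print("\nPositive d: the sphere sits in water and pays the Born transfer "
      "penalty\nplus an attractive image term; negative d: it is back in its "
      "native low-\ndielectric region and the energy decays to zero as 1/d.")
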