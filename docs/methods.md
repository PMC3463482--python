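# Methods

## Model

`fdpb` treats a solute as a set of charged spheres (atoms) and geometric
objects embedded in a dielectric continuum with mobile ions.  The
electrostatic potential φ (in kT/e) obeys the Poisson–Boltzmann equation

    ∇·[ε(r) ∇φ] − 4π C_u λ(r) Σᵢ c'ᵢ zᵢ e^(−zᵢ φ) = −4π C_u ρ_f ,

where ε(r) is the position-dependent relative permittivity, ρ_f the fixed
solute charge density (e/Å³), c'ᵢ = cᵢ N_A 10⁻²⁷ the bulk number density of
ion species i (concentration cᵢ in mol/L, valence zᵢ), and λ ∈ {0, 1} the
ion-accessibility indicator.  Linearizing the exponential gives the linear
PBE with the Debye parameter κ² = 8π C_u (N_A 10⁻²⁷) I / ε_s, I = ½Σcᵢzᵢ².
The salt term is stored as κ̄² = ε_s κ² in the stencil — conventions differ
between PB codes, so this is fixed explicitly.

### Units and constants

Lengths are in Å, charges in e, potentials in kT/e and energies in kT at the
reference temperature T = 297.33 K.  The single SI bridge is
C_u = e²/(4π ε₀ · 1 Å · kT) ≈ 562.005 kT·Å/e².  Constants are CODATA-2010
values at full precision.  This matters: rounding the Boltzmann constant to
two digits (1.38×10⁻²³ J/K) shifts C_u by 0.05%, which is clearly visible
against the analytic benchmarks this package carries — with full-precision
k the closed-form Born energies for the standard 10 e / ε 4→80 system are
−6673.81, −3336.90 and −2224.60 kT (r = 1, 2, 3 Å), and published values
for this system agree with these to about 10⁻⁵ relative, i.e. to within
rounding of the reported digits.  `PhysicalConstants` is a frozen dataclass;
any member can be overridden per run.

## Discretization

The cube is derived from two user parameters: `scale` (points/Å; the grid
spacing is h = 1/scale exactly) and `perfil` (the solute's largest
bounding-box dimension as a percentage of the cube edge; default 70).  N is
the smallest odd node count covering the edge, so one node sits at the cube
centre and symmetric scenes discretize symmetrically.

The flux form of the PBE is differenced on the standard 7-point stencil
with permittivities at the three staggered midpoint lattices.  At interior
node 0 the converged solution satisfies

    φ₀ = [Σₖ εₖ φₖ + 4π C_u q₀ scale] / [Σₖ εₖ + λ₀ ε_s (κh)²] ,

with q₀ the node charge in e.  Point charges are spread trilinearly over
their 8 enclosing nodes (exact conservation of total charge and dipole);
charged objects are sub-sampled at h/2 and each sample spread the same way.

### Dielectric boundary assignment

Two surface models define the solute interior:

* **vdW** — the union of the atom spheres and declared objects.
* **SES** — the solvent-excluded volume of the atoms under a probe of
  radius 1.4 Å (default), built by the two-pass distance construction:
  inflate every atom by the probe radius, then keep points at least one
  probe radius away from the probe-accessible region.  Depth inside any
  single inflated sphere is evaluated in closed form (which makes the SES
  of an isolated atom exactly its own sphere, and guarantees vdW ⊆ SES);
  reentrant crevice points are recovered with a Euclidean distance
  transform on the lattice, tightened by half the cell diagonal so lattice
  sampling can only carve inward, never inflate the surface.  The residual
  O(h) surface uncertainty of this lattice construction makes SES the
  right choice for molecular runs but a poor probe of fine grid
  convergence; the convergence benchmarks therefore use vdW surfaces,
  whose closed forms define the boundary exactly.

Midpoint values are assigned in one of two modes (`dielectric_averaging`):

* **harmonic** (default) — each node-to-node edge is assigned the
  fraction-weighted harmonic mean of the interior and solvent
  permittivities, with the interior fraction of the edge computed exactly
  for spheres and axis-aligned boxes (point membership for other shapes).
  This is the standard flux-matched interface treatment; it converges
  smoothly (the Born benchmark error falls 7.0% → 2.5% → 0.46% over scales
  1, 2, 4 points/Å for the hardest r = 1 Å case, and an order of magnitude
  faster for larger solutes).
* **sharp** — pure point membership of the midpoint, each entry exactly one
  of the declared permittivities.  Kept because several workflows expect
  literal region values in exported dielectric maps; its interface error
  oscillates at O(h) with the phase of the surface against the lattice,
  and it is not recommended for energy-convergence studies.

Overlapping entities are resolved by declaration order (later wins); in
harmonic mode the entity covering the largest edge fraction owns the edge.
Ties at exact surface distance count as interior.

### Ion accessibility

A node is ion-accessible when outside every atom inflated by the Stern
(ion-exclusion) radius, default 2.0 Å, and outside every object.  κ̄²
enters the stencil only at accessible nodes.

## Solver

Red/black checkerboard Gauss–Seidel with successive over-relaxation; the
relaxation factor defaults to ω = 2/(1+√(1−ρ²)) with the Jacobi estimate
ρ = cos(π/N).  Sweeps are deterministic; an optional numba kernel computes
the same per-colour arithmetic as the numpy fallback (nodes of one colour
do not neighbour each other, so within-colour order is immaterial and the
two paths agree bitwise).  Convergence is declared when the maximum
unrelaxed per-node update over a sweep is at most the tolerance (default
10⁻⁴ kT/e) *and* an explicit recomputation of the Gauss–Seidel displacement
on the final field confirms it; hitting the iteration cap returns the field
with `converged=False` and a warning rather than an exception.

Boundary values on the six faces: zero, a Coulomb sum C_u Σqᵢ/(ε_s dᵢ), or
its Debye–Hückel screened form (defaults to Coulombic).  A scene may
instead carry an exact boundary function; the planar-interface fixture uses
the classic image-charge solution this way, because a Coulomb boundary in a
two-dielectric half-space problem would be wrong by roughly ε₂/ε₁ on the
low-dielectric side.

### Nonlinear PBE

The full Boltzmann ion term is solved by damped Newton successive
linearization: each outer step linearizes the ion charge density
ρ(φ) = Σc'ᵢzᵢe^(−zᵢφ) about the current iterate, moves −ρ′(φ̄) (always
positive) into the stencil denominator and the remainder into the source,
then under-relaxes the outer update (damping 0.6).  The growing denominator
makes every inner linear solve diagonally dominant regardless of the
potential amplitude, which is what lets the 10 e benchmark solute in 0.1 M
salt (|zφ| ≈ 17 at the Stern surface) converge; a derivative-free Picard
split of the same equation diverges there through exponential feedback.  In
the weak-potential limit ρ′ → −2I′ and the scheme reduces exactly to the
linear equation; with no salt the linear solver result is returned
unchanged.  Exponents are clipped at ±60 to keep transients finite.

## Energies

* **Grid energy** ½Σ q φ over node charges.  It contains the lattice
  self-energy, which grows ∝ scale and is unphysical on its own — only
  differences between runs with identical charge lattices are physical.
* **Coulombic energy** Σ_{i<j} C_u qᵢqⱼ/(ε_int rᵢⱼ) over atom pairs.
* **Solvation (reaction-field) energy** — the difference of two grid
  energies on the identical grid and node-charge array: the scene as
  declared (heterogeneous ε, salt) minus a uniform reference at the
  solute's interior permittivity with no salt.  The self-energy cancels
  exactly.  The reference run always uses the analytic uniform-medium
  Coulomb boundary, which is the exact boundary condition for that run;
  choosing a different reference boundary would add a harmonic potential
  at the charges that does not cancel, so it is not exposed as an option.
* **Ion concentration maps** cᵢ e^(−zᵢφ) at accessible nodes, zero
  elsewhere (φ already in kT/e).

## Validation systems

Three closed-form systems are built in and double as the test oracles:

1. **Born ion** ΔG = −(Q²C_u/2r)(1/ε_in − 1/ε_out).
2. **Two charges in a spherical cavity** — the four-term solution
   (Coulomb + pairwise polarization + two self terms) with series
   coefficients Bₙ = (RᵢRⱼ/b²)ⁿ/b · (n+1)(ε_in−ε_out)/[(n+1)ε_out+nε_in]
   and Legendre polynomials from the Bonnet recurrence.  The series is
   summed until the relative tail is below 10⁻¹²; because individual terms
   can vanish by symmetry (odd Legendre polynomials at cos(θᵢ−θⱼ) = 0,
   which the canonical geometry hits exactly), three consecutive
   sub-threshold terms are required before stopping.  For the canonical
   geometry (b = 10 Å, both charges at 5√2 Å, ε 2/80) the total is
   −5083.26 kT; the numerical engine reproduces the reaction-field part
   (−7893.29 kT) to 0.1% at 2 points/Å.
3. **Sphere near a planar interface** — image-charge closed form on both
   sides of the plane, undefined while the sphere straddles it (|d| ≤ r);
   realised numerically as a cube-spanning box object with the exact image
   potential as boundary values.  The engine tracks the curve to ≤0.6% at
   2 points/Å for |d| ∈ {4, 6, 10} Å.

## Fixtures and what they do (and do not) show

All test inputs are generated: the three analytic scenes above plus a
seeded uniform random atom cloud (default 20 atoms in a 12 Å box, radii
1–2 Å, charges ±1 e) that stands in for an irregular protein-like solute in
conservation, symmetry and grid-plateau properties.  The cloud emulates the
geometric irregularity and charge heterogeneity of a small protein but not
its chemistry: no bonded structure, no force-field radii/charges, no
surface crevice statistics of real packing.  Passing the plateau property
(solvation energy stable to ≤2% between 2 and 4 points/Å) therefore
demonstrates grid convergence of the machinery, not force-field accuracy on
real molecules.

## Numerical choices and degenerate inputs

* Tolerance is an absolute max-norm on per-sweep updates in kT/e; energies
  inherit roughly tolerance × Σ|q| worth of uncertainty.
* Charges must sit at least one spacing inside the cube (distribution and
  boundary sums would otherwise collide); violations name the atom.
* Zero-radius atoms carry charge but no dielectric volume; zero-charge
  scenes solve to the boundary field; empty systems are rejected at grid
  construction.
* A memory guard caps N (default 513) and fails fast with the requested
  size.
* Reruns are bit-identical: no randomness exists outside the seeded cloud
  generator.

## Known limitations

* The solvation-energy route requires two solves per scene; focusing
  (nested-grid) runs, multigrid and conjugate-gradient back-ends are out of
  scope, as are periodic boundaries and non-cubic grids.
* The lattice SES construction carries an O(h) surface uncertainty between
  exactly-resolved sphere depth and the crevice distance transform; use
  vdW+harmonic for convergence studies.
* Mean-field PB ions are point-like: predicted surface counterion
  concentrations can exceed physical packing limits near highly charged
  solutes (hundreds of mol/L); finite-ion-size corrections are not
  implemented.
* Energies compare runs on the same grid only; comparing grid energies
  across different scales is meaningless by construction.
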