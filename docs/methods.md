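# Methods

This note documents the models implemented in `helitube`, the conventions
and numerical choices behind them, what the scaled-down test ensembles do
and do not establish, and the known limitations.

## Model

**Monomers and sheets.** A monomer is a triangle of three vertices joined by
harmonic bonds; assembled structures are oriented triangular meshes in which
every triangle carries one edge of each type *i* ∈ {1, 2, 3} and only edges
of equal type bind. Energies are in units of k<sub>B</sub>T, lengths in
units of the stress-free edge length l₀ (monomer area a₀ = (√3/4)l₀²). The
Hamiltonian is

    E = Σ_edges (k_S/2)(l_j − l0)²  +  Σ_bound (B/2)(θ_i − θ⁰_i)²  −  E_B · n_bound,

with stretching modulus k_S = 200 kT/l₀² (thin-sheet limit: bending much
softer than stretching), bending modulus *B*, binding energy E_B per bound
edge pair, and preferred dihedral angles θ⁰_i taken from the ideal geometry
of a chosen target tubule. The harmonic ½ prefactors are the package's
convention and propagate consistently: per monomer, the bending energy of a
uniformly curved geometry is Σ_i (B/4)(θ_i − θ⁰_i)² because every bound edge
is shared by two monomers.

**Tubule geometry.** A tubule (m, n) is the triangular lattice rolled so
lattice vector m·a1 + n·a2 closes on itself. Its equilateral embedding is
computed exactly from helical symmetry: vertex (i, j) sits at angle
i·α₁ + j·α₂ and height i·h₁ + j·h₂ on a cylinder of radius ρ, with the five
parameters solving the three unit-edge conditions plus the two closure
conditions (m·α₁ + n·α₂ = 2π, m·h₁ + n·h₂ = 0) to ~1e−12 residual. Dihedral
angles are measured through the material, flat = π. On the exact embedding
the hoop-direction edge type is slightly reflex (> π, chord recessed below
the cylinder) while the two cross types are convex; all approach π as the
diameter grows. The three angles, one per type, are constant along the
tubule by helical symmetry (enforced to 1e−6 rad) and define θ⁰ for that
target. Mirror geometries (handedness −1) carry permuted angle triples and
are recorded as canonical (m ≥ n) indices plus a handedness flag.

## Grand-canonical kinetic Monte Carlo

The structure exchanges monomers with an ideal bath at chemical potential μ
(default −3 kT). The standard-state concentration c_SS ≈ 10 μM corresponds
to roughly one monomer per monomer volume, which we identify with 1 l₀³;
the activity is then exp(μ) per l₀³ and the bath concentration is
c₀ = c_SS·exp(μ/kT) ≈ 500 nM at the default. This convention fixes the
absolute normalisation of all free energies.

Moves and state-dependent attempt weights:

- **vertex moves** (weight 1 per vertex; one attempted move per vertex
  defines a sweep): uniform displacement in a cube of half-width δ_v = 0.1 l₀,
  Metropolis acceptance.
- **association / dissociation** (weight p_exchange per free boundary edge):
  a monomer is grown across a uniformly chosen free edge, its apex proposed
  uniformly in a cube (half-width 0.25 l₀) around the exact
  preferred-dihedral position; only monomers with exactly one bond and an
  unshared apex may dissociate, which maintains a single connected structure
  and N ≥ 1. Dissociation is proposed only when the apex lies inside the
  reverse proposal cube, making the pair exactly reversible.
- **edge fusion / fission** (weight f_fusion per vertex): two free edges of
  equal type and opposite sublattice parity whose vertex pairs are each
  within r_c bind, merging the pairs at their midpoints; fission reverses
  this, drawing the lost separation vectors uniformly from a ball of radius
  r_c. Fission is restricted to bound edges adjacent to a boundary vertex
  (the interior of a closed tubule is locked). The one exception to exact
  reversibility is deliberate: the final bond of a fully zipped crack
  (a fusion that merges no vertices) is accepted irreversibly, since its
  reverse would be an interior fission; re-opening of healed interior bonds
  is assumed rare and transient.

Every acceptance ratio carries the full forward/reverse selection
probability (free-edge, removable-monomer, fusable-pair and fissionable-
edge counts and the state-dependent total weights), so the chain obeys
detailed balance with respect to exp(μN − E) with monomers treated as
indistinguishable. This is validated in the test suite against independent
quadrature oracles (single-triangle shape statistics; grand-canonical
monomer↔dimer occupancy, where the two-fold assembly symmetry factor
matters), equipartition on a fixed sheet, and flow audits on enumerable
micro-systems.

**Closure and classification.** Intrinsic lattice coordinates are defined
by per-triangle steps (fixed by sublattice parity); the holonomy of the
coordinate field around a closed loop is the rollup vector. A trajectory is
*closed* at the first fusion that creates nonzero holonomy. Final
structures are *defect-free* when they have exactly two boundary cycles and
a globally consistent holonomy (a unique (m, n)); *defective* when closed
with residual cracks (extra boundary cycles) or with inconsistent holonomy
(dislocations, multiple local geometries); *open* when they never closed —
the spiral ("toilet paper roll") outcome. Tubule length and diameter follow
from L = N·a₀/(πD), D = |C|/π; ΔD is the population standard deviation of D
over the defect-free ensemble.

**Kinetic calibration.** The attempt-frequency ratios are the model's
kinetic conventions. f_fusion (closure attempts per vertex move) is the
paper-facing control parameter; p_exchange = 0.02 per free edge and
r_c = 0.35 l₀ were calibrated once so that the f_fusion → outcome mapping
reproduces the expected regimes (at f_fusion = 10⁻² essentially no open
spirals; at 10⁻⁴ open-dominated; defective structures common at B = 20 kT
and rare at B = 50 kT) and were not adjusted afterwards. One geometric
consequence of isotropic (round-sheet) growth is that closure cannot occur
before the unrolled sheet width spans the circumference, which bounds the
closure length at L_close ≳ (π²/4)D₀ ≈ 2.5 D₀; reported closure lengths
therefore sit near 2.5–3 D₀ rather than ~1.5 D₀, which would require
axially elongated pre-closure sheets.

## Equilibrium theory

Discrete model: per monomer, g(m,n; L) = 2γa₀/L − (3/2)E_B +
Σ_i (B/4)(θ_i − θ⁰_i)² − T·s. With entropy taken geometry-independent the
equilibrium geometry distribution of an N-monomer structure is
P ∝ exp[−N·Σ_i (B/4)Δθ_i²]. Continuum limit: Helfrich density
(B̃/2)(2/D − 2/D₀)² with B̃ = (√3/2)B (validated against the discrete
bending energies of achiral tubules to ~1%; note the continuum density
misses the twist penalty of chiral competitors of similar diameter).
Equipartition on the quadratic expansion of the total bending energy gives
ΔD/D₀ = √(kT·D₀ / 4πB̃L).

**Thermodynamic integration.** Absolute free energies of closed tubule
lattices are computed along a linear path from an Einstein solid (every
vertex tethered to its ideal position, k_E = 100 kT/l₀² — comparable to the
Hamiltonian's local stiffness, for endpoint overlap) to the elastic
Hamiltonian, with six coordinates pinned (one vertex fully, one to a line,
one to a plane) to remove rigid-body modes in both endpoints; the binding
term is a topological constant added analytically. The λ-integral uses an
8-node Gauss–Legendre grid by default (doubling the grid shifts F by less
than the quoted error); errors come from block averaging per node. The
threshold binding affinity solves g(E_B) = μ with the bulk bond count 3/2:
E_B* = (g_el − μ)/(3/2), with g_el the per-monomer elastic+vibrational free
energy of the target lattice. Finite lattices carry rim contributions, so
small systems bias g_el slightly low.

## Kinetic growth–closure model

Pre-closure structures are idealised as disks growing one monomer at a time
at rate k_grow(N) = k⁰_grow·P(N)/l₀ with isoperimetric perimeter
P(N) = 2√(πNa₀). While at size N the disk closes into any geometry (m, n)
whose circumference its width spans (indicator 2√(Na₀/π) ≥ πD_mn), at rate
k⁰_close·exp(−ΔG) with ΔG = N·Σ_i (B/4)Δθ_i² — the discrete bending cost of
deforming the whole sheet to the closed geometry, exactly zero for the
target. (A pure Helfrich barrier was rejected because it misses the twist
penalty of chiral competitors and smears the predicted distributions.)
Closure is irreversible; the survival recursion conserves probability to
1e−12 and is validated against a Gillespie simulation of the same competing
rates. Candidate geometries default to all (m, n), both chiralities, with
diameters within ±40 % of the target.

The ΔD ∼ B^(−1/2) scaling of the predicted width fluctuation is a
continuum-regime statement: it holds (fitted exponent ≈ −0.45) over the
decade B ∈ [2, 20] kT where the predicted ΔD exceeds the spacing between
discrete geometries; at higher B the distribution collapses onto the target
exponentially, a direct consequence of the late closure sizes implied by
the disk-width indicator. The model's absolute target yields at B = 20
(peak ≈ 0.9 across the closure-rate axis with the discrete barrier; ≈ 0.09
with a Helfrich barrier) bracket, but do not reproduce, intermediate
reference values near 0.4; the closure-barrier magnitude at intermediate
deformation is the main open reconstruction uncertainty.

## Scaled-down study conditions

The test suite and `scripts/acceptance.py` run the full stack at sizes
chosen to finish in minutes while keeping every qualitative claim testable:

- *Fusion-rate trend*: target (5,0), B = 20, f_fusion ∈ {10⁻², 10⁻⁴},
  10–12 trials each, stop at L = 2|C|.
- *Stiffness trend*: target (5,0), f_fusion = 10⁻², B ∈ {20, 50},
  10–12 trials each (the f = 10⁻² ensemble doubles as the B = 20 member).
- *Width quench*: target (10,0), B = 50, f_fusion = 10⁻² (the fast-closure
  regime, so that scaled ensembles close within budget), 10 trials, stop at
  L = 1.3|C|; since the geometry is quenched at closure, equilibrium
  comparisons are evaluated at the measured L_close and at the standard
  measurement length L_end = 3|C|.
- *Thermodynamic integration*: rows = 5 lattices (72–88 monomers), 8 λ
  nodes, 1200 sampling sweeps per node.
- Kinetic-model checks are exact desk computations (N_max = 600).

Ensembles of ~10 trials resolve only large effects (binomial margins are
asserted explicitly); they do not constrain the quantitative outcome
fractions reported for 1000-trajectory campaigns, and the defect fractions
at B = 20 are sensitive to the fusion capture radius. Trends asserted on
these ensembles (open fraction vs f_fusion, defect fraction vs B,
quench-at-closure) were chosen because they are robust at this scale.

## Known limitations

- Assembly is strictly single-structure and grand-canonical: no
  inter-structure binding, no monomer depletion.
- Only boundary-adjacent bonds can fission; re-opening of closed tubules is
  excluded by construction.
- The kinetic model ignores nucleation–closure coupling (valid when the
  critical nucleus, ~5 monomers at default conditions, is far below the
  closure size).
- Round-sheet growth delays closure relative to experiments/simulations
  with elongated sheets (see the calibration note above); absolute closure
  lengths inherit this bias, while quench-at-closure comparisons use the
  measured closure length.
- The continuum model treats diameter as the only soft variable; chirality
  changes at fixed diameter are penalised only in the discrete model.
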