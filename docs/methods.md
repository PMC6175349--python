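# Methods

`chirasieve` models chiral separation by *molecular sieving* through
single-atom-thick membranes.  The working hypothesis is geometric: a chiral
"gatekeeper" molecule attached to a pore rim forms a temporary bimolecular
complex with a passing target molecule, and the spatial extent of that complex
— not its binding energy — controls whether it can swing through the pore.
The toolkit therefore provides three layers of machinery: (i) descriptors of
complex-size differences between same- and opposite-chirality pairings,
(ii) reproducible finite pore models with calibrated diameters, and
(iii) one-dimensional propagation energetics (constrained scans and
nudged-elastic-band pathways) with Boltzmann selectivity/permeance mappings.

## Molecular model

A `Structure` is a finite list of atoms (element, Cartesian position in Å,
optional partial charge in e, optional nonbonded type).  Atom order is
significant and preserved everywhere; there is no canonicalization, which
keeps round trips and oracle comparisons exact.  Enantiomers are generated by
reflection.  The chirality witness superposes a structure on its mirror image
with the Kabsch algorithm (proper rotations only, correspondence by index);
an RMSD below 1e-3 Å counts as achiral.  That threshold separates floating
point noise from genuine chirality at fixture scales, but the witness is
order-preserving: molecules that are achiral only under permutation of
topologically equivalent atoms (e.g. four identical hydrogens) are not
recognized as such.  All screening fixtures have four distinct substituents,
where the witness is exact.

## Energy model

The internal engine is a rigid-fragment Lennard-Jones 12-6 + Coulomb sum over
*inter*-fragment pairs,

E = Σᵢⱼ 4εᵢⱼ[(σᵢⱼ/rᵢⱼ)¹² − (σᵢⱼ/rᵢⱼ)⁶] + kₑ qᵢqⱼ/rᵢⱼ ,

with Lorentz–Berthelot combination by default, kₑ = 332.0636 kcal·Å/(mol·e²),
and energies in kcal/mol.  The per-element σ/ε table is UFF-style and the
fixture charges are hand-assigned group dipoles; both are deliberately simple
stand-ins — the toolkit's claims are symmetry and ordering properties that any
physically sane engine satisfies, and external backends can be plugged in
through the `EnergyEngine` contract (XYZ in, kcal/mol out, declared failure
mode).  Intramolecular terms are omitted because monomers are rigid
throughout.

Two cutoff settings are used, both documented in run metadata:

* **Scans** truncate hard at 12 Å, unshifted.  This realizes an exact zero
  reference: a profile is identically zero once the molecule is farther from
  the pore than cutoff + both molecular extents, and the "infinite
  separation" reference point is placed deterministically at three times that
  distance.
* **Complex searches** run untruncated (`cutoff=None`).  A bimolecular
  complex is smaller than any sensible cutoff, so truncation could only act
  on *candidate* poses near the cutoff radius — where a hard cutoff
  manufactures an artificial energy minimum by letting attractive cross pairs
  sit just inside and repulsive ones just outside the boundary.  Removing the
  cutoff removes the artifact without changing the physics of bound
  complexes.

Energies above 1e4 kcal/mol (hard-core overlap during scans) are capped and
flagged; this keeps spline fits finite while preserving the ordering of
barriers.

## Pore models

Graphene pores are built on an ideal honeycomb lattice (aromatic C–C
1.42 Å, C–H 1.09 Å): hexagonal rings are addressed by axial indices, a flake
consists of the rings needed to define the pore shape, cutting a pore deletes
every carbon of the removed rings, and each remaining carbon with missing
neighbors is re-passivated with an in-plane hydrogen along the vacant bond
direction.  The models are intentionally unrelaxed — geometric idealization is
what makes atom counts, C₃ symmetries and diameters bit-reproducible.  Any
relaxation belongs to an external engine and is never implicit.

The graphdiyne unit is a single triangular pore: three benzene rings at the
corners of an equilateral triangle joined by diacetylene links
(C(ar)–C 1.40 Å, C≡C 1.22 Å, central C–C 1.34 Å, ring C–C 1.43 Å), H-capped
elsewhere, threefold symmetric by construction.

**Rim detection** walks the face of the planar heavy-atom bond graph that
contains the pore center (clockwise-next half-edge traversal), then keeps the
cycle atoms and their hydrogens that lie within 1.5 Å of the closest approach
to the center.  The window makes "the atoms that border the opening" precise
for both graphene (inward C–H units) and graphdiyne (sp carbons).

**Diameter conventions.**  `geometric` is twice the radius of the largest
in-plane circle inscribed among rim nuclei (maximized over circle centers
from a fixed grid of Nelder–Mead starts, hence deterministic); `vdw`
additionally subtracts the van der Waals radii of the limiting rim atoms.
The calibrated default is `geometric`: with the standard bond lengths above,
the three shipped presets measure 6.04 / 5.50 / 5.61 Å against the reference
openings 6.0 / 5.6 / 5.6 Å, all within 0.1 Å.  The `vdw` convention misses
those values by over 2 Å and is therefore not the convention behind the
printed diameters; it remains available for kinetic-diameter style analyses.

**Preset layouts.**  Many removed-ring topologies are compatible with a given
ring count, so the presets are the package's own choice, shipped as named
ring sets and overridable:

* `graphene4` — a central ring plus three alternating edge-neighbours
  (triphenylene-shaped, C₃-symmetric hole).  A compact rhombus of four fused
  rings was rejected because its inscribed opening (5.76 Å) cannot reproduce
  the 6.0 Å reference under either convention; the C₃ layout gives 6.04 Å and
  a nearly circular opening.
* `graphene3` — the compact triangle of three fused rings (5.50 Å).
* `graphene5` — the `graphene4` hole plus one ring filling a notch; host for
  the gatekeeper and for nitrogen substitution.
* `graphene5-gatekeeper` — `graphene5` with a rigid 1-aminoethanol bonded at
  a rim carbon (replacing its hydrogen, tilted out of plane).

Nitrogen substitution replaces a rim C–H unit by N (one atom fewer per site),
"opposite" or "adjacent" to the gatekeeper site; removing the inward-pointing
hydrogens measurably enlarges the geometric opening, which is the intended
pore-tuning effect.

## Complex-size screening

For monomers A (both enantiomers) and B, the descriptors are
ΔE = E(RS) − E(SS) and ΔR = R(RS) − R(SS), where E is the interaction energy
of the best rigid complex found and R is the distance between the two most
distant atoms of the complex.  The search optimizes the six pose degrees of
freedom of B (rotation about its centroid + translation):

* **Starts.**  Approach directions come from a prefix-stable Halton sequence
  on the sphere crossed with eight fixed orientations plus a small seeded
  orientation jitter.  Prefix stability means raising `n_starts` only adds
  poses, so the best energy found is monotonically non-increasing in
  `n_starts` — a testable convergence property.  Along each approach ray a
  0.25 Å radial pre-scan is taken and *every* local minimum of that radial
  profile (up to the two lowest) seeds a local search; this matters because
  tight, electrostatically locked basins can hide behind a repulsive wall at
  shorter range than the outer dispersion minimum.
* **Local optimizer.**  Derivative-free coordinate pattern search (poll ±step
  on each of the 6 DOF, halve steps on failure), run with a coarse step
  tolerance for all starts and re-converged at 1e-4 for the best ten distinct
  poses.  Candidates within 0.25 Å RMSD after alignment are merged; ties in
  energy (1e-9) break toward the smaller complex, then the earlier start.
* **Defaults.**  `n_starts=64`, `seed=7`.  Identical configuration gives
  bit-identical tables.

The full five-template screening matrix (organic acid, aldehyde, alcohol,
olefinic alcohol, methyl ether — all built as real small molecules around a
stereocenter with idealized internal coordinates) yields the 15 unordered
combinations including self-pairings.  Because the internal engine is exactly
mirror-invariant, pairing with an achiral partner gives ΔE = ΔR = 0 up to
search tolerance — a built-in null control.  The CHFClBr probe, whose charges
create one dominant H···F docking contact, shows a stable size split of
|ΔR| ≈ 0.24 Å between RS and SS pairings and serves as the positive control.

## Propagation machinery

**Constrained scans** translate the rigid molecule's center of mass along the
membrane normal through the pore center in 0.25 Å steps over [−8, +8] Å by
default, with a fixed orientation and no rotation, so the reaction
coordinate is a pure Cartesian translation and profiles from different
engines are comparable point by point.  Cubic splines with not-a-knot boundaries interpolate the
samples (natural boundaries would pin the end curvature to zero and could not
reproduce even a locally cubic profile); interior
extrema are roots of the spline derivative classified by curvature, cleaned
to an alternating sequence, and mapped in z-order onto the five-slot pathway
schema *left minimum, 1st transition state, intermediate, 2nd transition
state, right minimum*.  The rate-determining step is the highest transition
state.  Both barrier conventions — from the global zero of separated species
and from the preceding minimum — are computed and labelled.

**NEB.**  The band optimizer implements improved-tangent NEB with
finite-difference gradients and a damped velocity-projection integrator;
climbing image is optional (off by default, and the saddle is then estimated
from a spline through the image energies).  It operates on any coordinate
vector with an energy callback: the shipped 2-DOF double well
E(x, y) = (x²−1)² + 2(y−x/2)² (minima at (±1, ±½), saddle 1 at the origin)
validates it against a union-find minimax-barrier oracle, and the molecular
wrapper runs the same optimizer over the rigid molecule's 6-DOF pose with the
pore frozen.  Rigid-pose NEB is a documented simplification: the engine
contract leaves room for flexible-molecule backends.

**Selectivity and permeance.**  Barrier differences map to a ratio
exp(−ΔΔE‡/kT) and absolute barriers to an indicator exp(−max(0, E‡)/kT), with
k_B = 0.0019872 kcal/(mol·K) and T = 298.15 K by default.  These are
single-pathway Boltzmann estimates on the electronic surface — no
zero-point, entropic or dynamical corrections — and are meant for ranking
pore variants, not for absolute flux prediction.

## What the synthetic fixtures do and do not show

All probes (CO₂-like, CH₄-like, ethane-like, CHFClBr, 1-aminoethanol, the
five templates) are generated from idealized internal coordinates with
synthetic charges; no external data is read.  Passing tests therefore
demonstrate the *machinery*: exact mirror symmetry of the energy model,
correct bookkeeping of the ΔE/ΔR contract, calibrated pore geometry, spline
and band correctness against brute-force oracles, and the monotone
size-vs-barrier link.  They do not validate force-field accuracy for real
molecules — quantitative screening and pathway energetics call for DFT,
semiempirical tight-binding or fitted force fields, which sit behind the
engine contract and are out of scope here.

Two property families are deliberately restricted to the steric-sieving
regime (positive, repulsion-dominated barriers): pore dilation
(graphene3 × CH₄, radial scale 1.0–1.1) and the perpendicular dumbbell family
(H–H extent 1.5–3.5 Å).  Once the opening comfortably exceeds the probe, the
profile maximum is set by dispersion wells near zero energy and may drift
non-monotonically with size — physically expected, and outside the regime the
sieving argument addresses.

## Numerical choices

* Scan overlap cap 1e4 kcal/mol (flagged per sample).
* Inscribed-circle maximization: 7×7 grid of Nelder–Mead starts within
  ±1 Å of the pore center, xatol 1e-8.
* Pattern-search tolerances: coarse 2e-2, fine 1e-4 (steps, not energies);
  dedup RMSD 0.25 Å.
* NEB: spring constant 1.0 kcal/(mol·Å²), force tolerance 1e-3, step 0.05,
  max step 0.2 per image per iteration; finite-difference step 1e-5.
* Bond perception: covalent-radius sum × 1.25.
* Seeds are mandatory for every stochastic operation; derived per-pairing
  seeds stay below 2³¹.

## Known limitations

* Monomers and pores are rigid everywhere; no intramolecular relaxation,
  no gatekeeper flexibility in the shipped engine.
* The chirality witness does not permute equivalent atoms.
* The internal engine's parameters are illustrative; quantitative barrier
  heights for real systems require an external backend.
* Pathway thermochemistry (ZPE, entropy, Gibbs corrections) and dynamical
  transport (MD, stochastic flux models) are out of scope.
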