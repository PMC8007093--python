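# Methods

This note documents the models, conventions, numerical choices and known
limitations of `voapipe`.  Empirical statements here are limited to what the
test suite and `scripts/acceptance.py` themselves compute.

## Collective variables

**Dihedrals.**  Signed dihedral of four points, IUPAC sign convention
(clockwise positive looking from atom 2 to atom 3), reported on (−180°, 180°].
Degenerate inputs — a zero-length bond or three collinear points — raise an
explicit error rather than returning a number.  In per-frame CV tables a
degenerate cell becomes NaN and the row is kept; only topology errors
(out-of-range atom indices) abort, naming the offending CV.

**Two-torsion pseudorotation.**  For a five-ring, ν_j (j = 0…4) is the
dihedral about the bond between ring atoms j+1 and j+2 (1-based, cyclic).
Under the torsional pseudorotation model ν_j = A_r·cos(P_θ + 144°·j), the
pair (ν₁, ν₃) inverts to

    Z_x = (sin144°·ν₃ − sin72°·ν₁)/sin72°,
    Z_y = (cos144°·ν₃ − cos72°·ν₁)/sin72°,

with P_θ = atan2(Z_y, Z_x) and A_r = |Z|.  Consequences of the model worth
knowing: a planar ring gives A_r = 0 (phase undefined, flagged below a 0.1°
amplitude tolerance); negating all torsions (the enantiomer) shifts P_θ by
exactly 180° and leaves A_r unchanged; cyclically relabelling the ring start
shifts P_θ by 144° per step.  On a *geometric* ring the torsions carry small
higher harmonics, so amplitude invariance under relabelling is only
approximate (a few percent); the phase convention is therefore fixed once by
the ring definition and used everywhere.  A_r inherits the degree units of
the torsions.

**Cremer–Pople coordinates.**  Standard construction for six-rings: centre
at the geometric mean, mean-plane normal from the sine/cosine weighted
position sums, out-of-plane displacements z_j decomposed into the m = 2
amplitude/phase (q₂, φ) and the signed chair amplitude q₃, with
Q² = q₂² + q₃² (+ higher terms absent for N = 6).  The normal is oriented so
that a ring numbered counterclockwise in its own plane has the normal on its
+z side; with that choice, displacements planted as z_j = c·cos(4πj/6 + φ₀)
are recovered as φ = φ₀.  φ is undefined (flagged) below q₂ = 10⁻⁴ Å.
Applied both to covalent six-rings and to the intermolecular six-atom
pseudo-ring closed by the two O–H···O=C hydrogen bonds of a lactone dimer,
whose phase discriminates boat-like (φ ≈ −64°) from skew-like (φ ≈ 90°)
dimer arrangements.

Angles are degrees in every public interface; user-facing atom indices are
1-based (chemical numbering), converted to 0-based storage in exactly one
function.  No periodic-boundary unwrapping is attempted: inputs must be
whole molecules (a validator rejects five-ring bonds over 3 Å, and shell
extraction warns on implausibly large bounding boxes).

## Hydrogen bonds and association

Criteria: donor–acceptor distance ≤ 3.0 Å and angular deviation ≤ 30°, both
inclusive and configurable.  The angular criterion is the
deviation-from-linearity convention used by common trajectory-analysis
tools — the angle between the D→H and D→A vectors — because a literal
D–H–A angle below 30° is geometrically impossible at a 3 Å contact.  The
literal convention remains available (`convention="dha"`, cutoff then
D–H–A ≥ 150°).

Monomer/dimer assignment takes the minimum over all declared intermolecular
donor–acceptor pairs (configurable to a subset) and labels a frame dimeric
iff that distance ≤ 4.0 Å, inclusive.  Shell extraction keeps the solute
plus every solvent molecule with *any* atom within the radius (inclusive),
whole molecules only — the any-atom rule is what captures H-bonded partners
at small radii.  Shells are monotone in the radius by construction.

## k-medoids on periodic CVs

Distance: Euclidean norm of per-CV differences, each periodic difference
wrapped to [0°, 180°], with optional positive per-CV weights.  This is a
metric (the wrapped 1-D distance is, and the weighted L2 combination
preserves the triangle inequality); the suite spot-checks 10⁴ random
triples.

Optimisation, in order:

1. **BUILD seeding** — first medoid minimises the total distance to all
   points; each next medoid maximises the total cost decrease.
2. **Alternating refinement** — reassign points to the nearest medoid, then
   recompute each cluster's medoid; repeats until stable.
3. **SWAP phase** — best-improvement medoid/non-medoid exchanges, each
   candidate evaluated in O(n) from the nearest and second-nearest medoid
   distances (the FastPAM observation); accepted only if the total cost
   strictly decreases.

Candidate sets for seeding, medoid updates and swaps are capped at
`max_candidates` (default 1024) points drawn deterministically from a
seed-derived generator, always retaining the incumbent medoid, so each step
stays near-linear in n and the cost never increases (the recorded
`cost_history` is non-increasing, which the suite asserts).  Because BUILD
can seed a basin that neither refinement nor any single swap escapes, the
fit is repeated `n_restarts` times (default 3) with different candidate
subsamples and the lowest-cost model returned.  Everything is deterministic
given (data, k, seed); ties break to the lowest frame index.  k is a user
choice — a histogram of the CV distributions is the intended guide — and no
automatic selection is attempted.

Cluster tables report populations as percentages to one decimal and circular
means (atan2 of mean sine/cosine; undefined below a 10⁻⁹ resultant length),
sorted by descending population.  Medoid frames are exported in that order,
optionally shell-extracted, with cluster id and population in the XYZ
comment line.

## Spectral assembly

**Broadening.**  Each mode contributes a unit-area Lorentzian of full width
at half maximum `bandwidth` (default 6 cm⁻¹ — "bandwidth" is interpreted as
FWHM, recorded in the output provenance since HWHM is the other plausible
reading) centred at `scale × wavenumber` and multiplied by the stick
intensity.  Scaling factors act on wavenumbers only, never intensities;
region-dependent factors (e.g. 0.96 for the OH/CH stretching region, 0.985
for the mid-IR) are applied by broadening each region with its own factor.
The isolated-stick peak height is 2/(π·FWHM); integral conservation to 0.5%
requires a window of several hundred bandwidths because Lorentzian tails are
heavy.  Grids are uniform (default 1 cm⁻¹) and must match exactly for
averaging — no silent resampling.

**Weighting.**  Boltzmann populations use w_i ∝ exp(−(E_i − min E)/RT) with
energies in kcal/mol and T = 300 K by default (the usual simulation
temperature); shifting by the minimum keeps 50 kcal/mol gaps from
overflowing.  Averaging is a pointwise convex combination; weights off unity
by more than 10⁻⁹ are renormalised with a warning.

**Monomer–dimer equilibrium.**  With K = [D]/[M]² and mass balance
c = [M] + 2[D], the monomer concentration is [M] = (−1 + √(1+8Kc))/(4K),
evaluated in the rationalised form 2c/(1 + √(1+8Kc)) which has no
small-Kc cancellation and contains the K → 0 limit.  Mixing weights are
[M]/c for the monomer and, for the dimer, 2[D]/c when the dimer spectrum is
normalised per molecule or [D]/c when normalised per dimer species — the
convention must be declared explicitly because silently guessing it would
change intensities by a factor of two.  K has no default: it is a measured
property of the system that the package cannot infer.

**Displacement scan.**  Geometries are displaced along unit-normalised
normal-mode vectors by user-chosen dimensionless steps (the 3 modes × 4
steps layout is the documented example); symmetric step sets average back to
the input geometry exactly.  Averaging the spectra of such displaced
structures reproduces the characteristic flexibility effect: bisignate VCD
couplets with displacement-dependent sign/position largely cancel while the
integrated IR intensity is conserved.  Per-structure energies can feed the
Boltzmann weighting of the displaced set.

Stick intensities are taken as already in plottable units; conversions from
dipole strength (D = 9.184×10⁻³⁹ ∫(ε/ν̃)dν̃ esu²cm²) and rotational strength
(R = 2.296×10⁻³⁹ ∫(Δε/ν̃)dν̃) are provided as separate, never-implicit
utilities.

## Synthetic fixtures: what they emulate and what they do not

The generators stand in for MD trajectories and quantum-chemistry outputs:

* `make_ring_geometry` plants (P_θ, A_r) by an out-of-plane cosine ansatz
  z_j ∝ cos(4πj/5 + φ_z) on a regular pentagon, rescaled in-plane to restore
  the RMS bond length, iterated until the *measured* phase and amplitude
  match the request to 10⁻⁴; amplitudes up to 55° are realisable.  Hydroxyl
  (O, H) and carbonyl (O) probe atoms are placed by internal-coordinate
  construction so the planted OH torsion is exact.
* `make_dimer_frame` places the six pseudo-ring atoms on an inscribed
  hexagon whose intramolecular edges use bonded-geometry distances and whose
  two H-bond edges equal the requested donor–acceptor distance exactly,
  with out-of-plane displacements iterated to the planted Cremer–Pople
  phase; the five-rings are attached rigidly (rigid motion preserves their
  planted P_θ).
* `make_cv_samples`/`make_trajectory` draw CV values from a von Mises
  mixture (the canonical circular noise model, one concentration parameter
  κ per CV); `make_trajectory` additionally builds a geometry per frame.
  For the reference six-state mixture (weights 0.474/0.221/0.100/0.099/
  0.080/0.026), κ = 200 per CV (circular sd ≈ 4°) is the default study
  condition: the two closest planted centres are only ~28° apart, and this
  concentration keeps them ~7 sd separated so that the planted partition is
  itself the cost-optimal clustering — the premise without which "recovery
  of planted truth" is not a well-posed test.  At κ = 50 that premise fails:
  splitting the 47% state is then objectively cheaper than separating the
  2.6% state, and no correct k-medoids would return the planted structure.
* `make_solvated_frames` plants an H-bond contact probability on the
  carbonyl acceptor and fills a shell (11 waters inside 4 Å by default,
  matching the observed occupancy of a first hydration shell) plus an outer
  diffuse layer, with rejection sampling keeping each water's intended
  distance band exact.
* `make_stick_spectrum` provides seeded random mode sets and the bisignate
  carbonyl VCD couplet (± equal rotational strengths at center ±
  splitting/2) characteristic of coupled C=O oscillators in a dimer.

These fixtures are geometrically and statistically controlled but not
physical: no force field, no realistic solvent structure, no coupling
between ring pucker and torsional strain.  Passing tests therefore
demonstrate that the *analysis* is correct (phases measured as planted,
populations recovered, weights applied exactly), not that any particular
molecule behaves this way; conclusions about a real system still require
real MD and QM inputs.

## Problem sizes and tolerances

The suite and the acceptance script use: 24 phases × 3 amplitudes for
puckering round trips (tolerances 1° / 10⁻³, achieved ~10⁻⁴); a 15-point φ
grid for Cremer–Pople (0.5°, achieved ~10⁻¹³); 100 random frames against
the exhaustive H-bond oracle; n = 10 000 frames for six-state population
recovery (±0.02, means within 5°); 600 frames for occupancy recovery
(binomial 3σ); ±600-bandwidth windows for integral conservation (0.5%);
10⁻¹² for mass balance and averaging linearity; 10⁻¹⁰ for the closed-form
vs numeric equilibrium root.  These sizes were chosen so every check runs
comfortably on a single CPU while keeping sampling error well inside the
asserted tolerances.

## Known limitations

* The two-torsion pseudorotation is a two-parameter reduction; it does not
  implement the five-torsion least-squares phase, and its amplitude is only
  approximately invariant under ring relabelling on real geometries.
* No periodic-boundary handling anywhere: inputs must be pre-wrapped whole
  clusters.
* k-medoids with subsampled candidates is a heuristic: restarts make basin
  capture rare on well-separated data but optimality is not guaranteed.
* Degenerate couplets, overlapping bands and anharmonic effects are outside
  the spectral model: sticks in, Lorentzians out.
* The dimer builder aims for geometric plausibility, not chemical accuracy;
  its structures are for exercising the analysis, not for QM input.
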