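# Methods

## Pulling directions

Given one model of a protein–peptide complex, the package defines two unit
pulling vectors.

**COM vector.**  `normalize(COM_ligand − COM_receptor)` with mass-weighted
centres using standard atomic masses — the unbinding sense, pointing from
the receptor toward the peptide.

**RDM vector.**  The interface is the set of receptor residues with at
least one heavy atom within a cutoff (default 0.45 nm) of any peptide heavy
atom.  Hydrogens are excluded from the contact criterion because deposited
X-ray structures usually lack them.  The resultant dipole moment is then

    μ = Σᵢ qᵢ (rᵢ − r₀)          [e·nm; 1 e·nm = 48.032 D]

over the backbone atoms N, H, CA, C, O of those residues, with r₀ the
centre of geometry of the selection.  Charges are the GROMOS 43A1
united-atom backbone values shipped in
`src/rdmpull/data/gromos43a1_backbone_charges.json` (amide group N −0.28,
H +0.28; CA 0; carbonyl C +0.38, O −0.38; proline has a tertiary amide:
N 0, no H).  Every charge group is neutral, so μ is origin-independent; if
a selection nonetheless carries net charge (clipped groups), the result is
flagged `origin_dependent` instead of being silently reported.  Side
chains are excluded: their dipoles largely cancel or are screened, while
the peptide-bond dipoles of an interface stretch add coherently — which is
exactly the signal the RDM direction is meant to capture.  The atom set is
configurable.

Missing amide hydrogens are rebuilt at 0.1 nm from N along the bisector of
the C(prev)→N and CA→N directions (in the peptide plane, anti to the
preceding carbonyl); at a chain start, where no preceding carbonyl exists,
the N→CA direction is used.  Chain-terminal residues receive interior
backbone charges with a logged warning — the bundled table carries no
termini variants, and interface selections rarely include termini.

The physical dipole convention (negative→positive) leaves the pulling
sense ambiguous; `orient = raw | flip | toward-ligand` controls it, with
`toward-ligand` (sign chosen so the dipole direction has positive dot
product with the COM vector) as the workflow default, since pulling must
extract the peptide.  Dipoles are computed on the deposited model-1
coordinates by default; any coordinate file can be substituted for
sensitivity analysis.

## Pulling protocol emission

The emitted configuration is constant-velocity umbrella pulling along an
explicit vector in the GROMACS pull-code dialect: spring constant
k = 1000 kJ·mol⁻¹·nm⁻² (≈1660.5 pN/nm ≈ the upper stiffness of an AFM
cantilever; conversion factor 10²⁴/N_A), pulling speed v = 1e-5 nm/ps
(= 10⁷ nm/s), T = 310 K, peptide as pulled group, receptor as reference.
One mdp per trajectory with `gen-seed = base_seed + index` makes a
50-trajectory protocol scriptable and exactly reproducible.  Fields the
pull code cannot carry (trajectory count, base seed) are stored in
machine-readable meta comments so `parse_pull_mdp` is a full inverse of
`emit_pull_mdp`.  The package never shells out to an MD engine; it emits
configurations and analyses force outputs.

Where sources disagree on the speed notation (0.01 nm/ps vs 0.01 nm/ns for
the same protocol), the internally consistent 10⁷ nm/s = 1e-5 nm/ps is
taken as canonical.

## The Brownian toy simulator

A single bead in an analytic landscape is pulled by the same spring
protocol, with the logged force exactly `F = k(vt − x)` (x = bead
displacement along the pulling direction).  Integration is overdamped
Euler–Maruyama, `dr = F/γ dt + sqrt(2 kB T dt/γ) η`, with kB in kJ/mol/K
(0.0083145) so forces match engine units; the stability bound
`dt·(k + max|U″|)/γ < 0.1` is enforced, and runs use half that bound.
A compiled (numba) kernel integrates batches trajectory-by-trajectory;
the pure-Python recording integrator is the same dynamical system and the
two are cross-checked at T = 0 in the tests.

Landscape terms (all with analytic gradients, self-checked against finite
differences to 1e-4 relative):

* **Binding well**, two shapes.  *Gaussian*: `U = −D exp(−s²/2w²)` — a
  soft ("ductile") well whose force-tilted barrier distance stretches and
  shrinks with load.  *Ramp*: a flat-bottomed well climbing linearly to
  zero over width w with softplus-smoothed corners (scale w/20) — a
  "brittle" well whose escape barrier sits at the outer corner regardless
  of load, so its barrier distance is w for any force well below the
  critical slope D/w.
* **Point-charge electrostatics** with GROMACS's Coulomb constant
  (138.935 kJ·mol⁻¹·nm·e⁻²), a dielectric scale factor, and an optional
  soft core `d → sqrt(d² + σ²)` that keeps the toy bounded near charges.
  The bead may carry a net charge and a rigidly attached point dipole.
* **Interface-field slab**: the double-layer field of a quasi-planar
  binding interface — field along a normal n̂, Gaussian-localised over a
  thin thickness t along n̂ and a long lateral width L.  A ligand dipole
  aligned with n̂ is stabilised inside the slab; unbinding across the slab
  climbs the full coupling over t (large force), unbinding sideways leaves
  it over L (small force).  Point-charge constructions were rejected for
  this role: a bead pulled in 3-D can slide around any localized charge,
  and a monopole behind the well actually makes the *orthogonal* exit
  harder because that path stays closer to the source.

**Rupture detection.**  The spring force is smoothed with an exponential
moving average (time constant 20 bead-relaxation times by default) and
rupture is declared when the smoothed force stays below
max(10% of the running peak, a noise floor estimated as 3 standard errors
of the smoothed thermal force) for one smoothing time — but only after the
bead has left the well region (displacement > 4 well widths along the
pulling direction; a bead still inside the well cannot have ruptured,
and without this arming condition slow ramps false-trigger on early
noise).  `F_max` is the maximum of the smoothed force, which keeps the
extreme-value bias of long slow-speed runs from distorting loading-rate
analyses.  All thresholds are configurable (`PullSettings`).

**Static oracle.**  `static_rupture_oracle` scans `∇U·d` on a dense 1-D
grid along the pulling ray from the well minimum, doubling the grid until
converged to 0.1% — an independent brute-force reference for the
zero-temperature rupture force.  It accepts any object with a `gradient`
and a well position, so harmonic and Morse profiles cross-check it in the
tests.

## The two canonical experiments

**Bell sweep** (`bell_benchmark`).  A ramp well with D = 50 kJ/mol
(≈19 kB·T at 310 K) and w = 0.3 nm is pulled at v ∈ {1e-5, 1e-4, 1e-3}
nm/ps, 30 trajectories per speed (seeds `base + index`, continuing across
speeds), with a soft spring k = 20 kJ·mol⁻¹·nm⁻² and γ = 200
kJ·mol⁻¹·ps·nm⁻².  These choices place all three speeds in the thermally
activated force-ramp regime: rupture forces (≈26–67 kJ/mol/nm) stay far
below the critical force D/w ≈ 167, the soft spring makes the load
force-like rather than position-clamped, and the brittle well keeps the
barrier distance force-independent — the regime in which the Bell relation
`F_max = (kB·T/x_β) ln v + const` holds with x_β equal to the programmed
width.  A least-squares line of mean F_max against ln v then gives
R² ≈ 0.999 and x_β = kB·T/slope within a few percent of 0.3 nm.  The high
friction doubles as a numerical economy: the stability bound scales with
γ, so slow pulls stay affordable.  On a Gaussian well the same sweep
recovers 2–3× the width — not an artifact but the ductile well's larger
effective barrier distance at low force — which is why the brittle shape
is the calibration standard.

**Direction dependence** (`direction_dependence_benchmark`).  A Gaussian
well (D = 40, w = 0.2 nm) plus the interface-field slab (coupling
μ·E₀ = 0.5 e·nm × 40 kJ·mol⁻¹·nm⁻¹·e⁻¹ = 20 kJ/mol, t = 0.15 nm,
L = 1.0 nm), pulled at v = 1e-3 nm/ps, k = 100, T = 310 K, three
independent 20-seed batches per direction.  Field-aligned pulling yields
mean F_max ≈ 108 kJ/mol/nm vs ≈ 79 orthogonal (pooled effect size ≈ 4.5),
with the sign stable across batches — the desk-scale analogue of stronger
unbinding resistance along the interface-dipole direction than along an
arbitrary one.

## The synthetic complex generator

`generate_toy_complex` builds two parallel extended backbones (N, H, CA,
C, O per residue, ideal local geometry, per-residue jitter from the seed)
with the peptide against the middle of the receptor at an exact closest
heavy-atom gap (default 0.3 nm).  The complex is then measured with the
package's own interface and dipole code and rigidly rotated so the
interface backbone dipole lands exactly on the requested direction; by
rotation equivariance the planted direction is recovered up to numerical
precision (the 5° contract in the tests is generous).  What it emulates:
chain structure, backbone atoms and charges, a contact interface with a
known dipole, NMR-style multi-model files (via repeated writes).  What it
does not: side chains, secondary structure, realistic packing, solvent,
charged termini.  Tests passing on it therefore validate the geometry,
bookkeeping and invariances of the pipeline — not force-field accuracy on
real complexes, for which the deposited reference structures (fetchable
with `scripts/fetch_pdb.py`) are the check.

## Statistics

Rupture statistics follow force-spectroscopy convention: per-trajectory
F_max; mean with sample (n−1) SD; histogram (Freedman–Diaconis by default
— the most probable rupture force is reported as the mode bin centre, ties
to the lower bin, requiring n ≥ 5); direction comparisons report mean and
mode differences, pooled-SD effect size, and a fixed-seed percentile
bootstrap (10⁴ resamples) interval for the mean difference.  `peak_force`
is the global maximum of the (optionally moving-average smoothed) curve;
window 1 is exactly the sample maximum.

## Numerical choices and degenerate inputs

* Lengths are nm internally (PDB Å divided by exactly 10); dipoles e·nm,
  Debye only in reports; forces kJ/mol/nm.
* Alternate locations resolve to highest occupancy (ties: first
  encountered); HETATM records are excluded by default; insertion codes
  are appended to the residue key.
* Model 1 of an NMR ensemble is the reproducible default frame.
* Contact search uses a KD-tree; its output contract (tested) is identical
  to the all-pairs scan.
* Zero dipole raises an explicit `ZeroDipoleError`; coincident centres of
  mass, empty selections, overlapping groups, non-unit directions, ragged
  or empty force files, and unstable time steps all raise named errors
  rather than propagating NaNs.
* PDB writing rejects residue numbers outside the fixed-width field rather
  than renumbering silently.

## Known limitations

* The bundled charge table covers backbone atoms only and has no termini
  variants; full-residue dipoles are out of scope by design.
* The published pulling-vector components for the reference complexes
  depend on an unstated coordinate frame (deposited model vs equilibrated
  snapshot); the dipole check against them is reported as an angle, not a
  hard bound.
* The contact criterion behind the published interface lists is likewise
  unstated; 0.45 nm heavy-atom cutoff is a calibrated convention, and the
  lists are treated as approximate references (Jaccard overlap), not exact
  oracles.
* The toy simulator reproduces mechanisms and statistics, not the absolute
  rupture forces of explicit-solvent all-atom systems; its direction
  dependence tests the sign of the effect, not its magnitude.
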