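# Methods

This note documents the models and numerical choices behind each analysis,
what the synthetic systems emulate (and do not), and the defaults a user is
most likely to need to change.  Every number quoted here is computed by the
test suite or the `analysis/` scripts; nothing is asserted that the code
does not reproduce.

## Coordinate conventions and superposition

All axis-referenced analyses run on an `OrientedFrameSet`: every frame is
rigidly superposed (least-squares Kabsch fit, via
`scipy.spatial.transform.Rotation.align_vectors`) onto a reference frame,
the principal axis of the alignment selection in the reference frame is
mapped to +z, and the selection centroid is placed at the origin.  The
package-wide sign convention is intracellular at low z, extracellular at
high z; every module inherits it.  The RMSD series is computed on the
already-superposed frames against the reference (so it is zero there by
construction), with the atom selection exposed as a parameter — commonly
all Cα atoms.

Frames read from disk get a re-wrapping pass that shifts each residue's
atoms by whole box lengths to sit within half a box of the residue's first
atom, because every downstream quantity is distance based.  Only
orthorhombic boxes are supported.

## Contact map

Entry (a,b) is the trajectory mean of the minimum inter-atomic distance
between residues a and b, in nm, with each frame's distance truncated at
1.5 nm *before* averaging (so entries are bounded by the truncation; the
alternative — truncate after averaging — gives different values for pairs
that cross the cutoff and is not what bounded-distance contact tools
produce).  Default sampling is 370 equidistant frames.

## Binding sites and occupancy

A site is realized as the z-slab between the mean heights of its lower and
upper carbonyl-oxygen planes, intersected with a cylinder of
`radial_cutoff` (default 3 Å) around the pore axis.  The outermost site has
only one plane below it; its ceiling is a configurable offset (default
3.1 Å).  Ties at a shared slab boundary go to the lower site,
deterministically.  Occupancy is the raw indicator sum divided by the frame
count: two ions co-occupying a site count twice, faithfully to the defining
formula, and the value may exceed 1.  Water presence is judged by the water
oxygen only.  The lateral extent of a site volume and the
cavity/extracellular boundaries used for event counting are not uniquely
defined by the site geometry; both are exposed (`radial_cutoff`,
`cavity_radius`, default 5 Å).

Permeation events: an outward event is a label sequence cavity → (any
filter sites) → extracellular with no cavity visit in between; inward is
the mirror.  Bulk excursions neither arm nor cancel a traversal in
progress.  Ion z-traces can be unwrapped across periodic images
(`unwrap_z`: a jump larger than half the box is a boundary crossing).  The
inferred current is I = n·q·e/t, reported in pA.

## Carbonyl orientation

Descriptors are the (C, Cα, N, O) torsion (IUPAC sign convention, 0° = cis,
computed in double precision — the test suite holds it to 1e-9° against an
independent vector-algebra formulation) and the radial distance of the
carbonyl O to the pore axis.  DBSCAN runs on standardized features (each
column divided by its standard deviation) because degrees and Å are
incommensurate; the dihedral is made circular by clustering together with
±360°-shifted copies and folding labels back through a union–find, so
clusters spanning the ±180° seam are not split.  Defaults eps = 0.5,
min_samples = 10 (in standardized space) suit well-populated two-state
clouds; a single compact cluster standardized to unit variance is sparse
and needs a larger eps.  Clusters are named pore-facing or helix-facing by
the nearer of two reference anchors (circular in the dihedral); real
studies would take the anchors from conductive-state channel structures,
and the packaged defaults are synthetic, matched to the scaffold
generator's two oxygen positions.  Clustering is per (residue, subunit)
pair by default, with pooling available.  An exact anchor tie raises an
error rather than guessing.

## Electrostatics

Units are Gaussian-style reduced units: charge in e, length in Å, so
∇²Φ = −4πρ yields Φ in e/Å, converted on output via
1 e/Å = 14 399.645 mV.  Charges are deposited cloud-in-cell (trilinear) on
a periodic grid (default 1.5 Å) and attenuated in reciprocal space by a
Gaussian.  A nominal width of 0.15 Å is not representable on a 1.5 Å grid,
so the effective width is clamped to ≥ spacing/2 and recorded in the field
metadata.  The Poisson solve is spectral with the exact continuous k²; the
k = 0 mode is dropped, which is the uniform-neutralizing-background,
mean-zero-gauge choice.  Accuracy: a unit Gaussian charge matches the
closed-form erf potential (plus the periodic quadratic background term)
within 1 % beyond 3σ; superposition is exact to rounding; shifting charges
by one grid spacing shifts the solution by exactly one voxel.

The electrical-distance profile δ(z) is the cylinder-averaged (default
radius 5 Å) difference between the potentials with and without applied
voltage, anchored to 0 at an intracellular bulk z-interval and normalized
by the measured bulk-to-bulk difference — not by the nominal applied
voltage — so δ = 1 at the extracellular anchor by construction and the
profile stays well defined on any fixture.  Default anchors are 8–25 % and
75–92 % of the box height, clear of both the membrane slab and the
periodic boundary.  Per-charge δ values are linear interpolations at the
charge's z (the cylinder average is itself the axial reduction), and the
gating charge Q = Σ q_i Δδ_i telescopes exactly along any path.

**The plate fixture.**  The voltage-imposing system is a parallel-plate
capacitor: lattices of point charges at z1 and z2 with surface densities ±s
chosen so the analytic drop 4πs(z2−z1) equals the target (default
+500 mV).  In a periodic box the loop integral of the field must vanish, so
a bare plate pair would force a compensating ramp through the bulk; the
charged system therefore also carries an electrode-like return double layer
straddling the periodic z boundary, which absorbs the return drop and
leaves both bulk regions field-free — the role the conducting electrolyte
plays in a real membrane simulation.  On this fixture the measured drop is
500.0 mV and δ deviates from the ideal (z−z1)/(z2−z1) ramp by < 3e-4
inside the slab.

## Lipid interface

The occupancy map re-implements VolMap-style binary marking: a voxel
(default 1 Å) counts as occupied in a frame iff any lipid atom center lies
within `atom_radius` (default 1 Å) of its center; occupancy is the marked
fraction over frames sampled every 1 ns.  Whether the original volumetric
tools used atom radii or point atoms varies; the radius is a parameter.
Per-residue contacts count unique lipid atoms within `cutoff` of any atom
of the residue, per frame, reporting mean and max.  The 1 Å default cutoff
is deliberately tight — it selects near-overlap contacts only — and is
surfaced prominently in the interface; contacts include hydrogens when
present.

## Blocker affinities

K_i = exp(ΔG/RT), R = 8.3145 J/(K·mol), T = 298.15 K, ΔG in kJ/mol and
negative for favorable binding; the inverse conversion round-trips to
1e-12 relative.  Experimental Ki values are treated as dimensionless
(dilute solution, activity coefficient 1).  The packaged `kcv_blockers`
table holds the five classical Kcv blockers.  The predicted-vs-experimental
correlation defaults to Pearson on log10 Ki — equivalent to correlating
free energies — because the association between the two Ki columns is an
order-of-magnitude relationship: on this table the log-scale R is 0.87
while the linear-scale R is 0.43.  Both scales are available.

## Synthetic systems: what they emulate and what they do not

The generators are pure functions of (spec, seed) — identical inputs give
bitwise-identical outputs — and every planted quantity (hop schedules,
cluster labels, voltage drops, binder contact fractions) is exported as
ground truth for the tests.

- The filter scaffold places one residue per carbonyl plane and subunit
  (6 planes × 4 subunits), with plane spacing 3.1 Å and cage radius 1.4 Å
  mimicking canonical K⁺-filter geometry.  These are test-fixture values,
  not claims about any real channel.  Each carbonyl stores a pore-facing
  and a helix-facing oxygen position (rotated 120° about the Cα–N axis)
  so orientation flips can be scripted.
- Scripted trajectories hop particles instantaneously between site centers
  with isotropic Gaussian jitter; real thermal motion is correlated and
  continuous.  The analyses are required to be robust to step-like traces.
  With jitter off, site assignment must reproduce the schedule exactly;
  with 0.3 Å jitter the misassignment rate stays below 1 %.
- The conduction-cycle schedule plants the canonical single-file knock-on
  sequence ({W,S2,W,S4,S5} → … → {W,W,S3,0,S5}); the traversal schedule
  plants complete cavity→extracellular passages on a 344 ns time base, so
  two events imply 0.93 pA.
- The toy bilayer is three-atom pseudo-lipids jittering in a slab, one of
  them pinned within 1 Å of a chosen residue in 96 % of frames.  It
  exercises the contact and occupancy machinery; it has no membrane
  physics.

Because the fixtures are geometric, passing tests demonstrate the
*correctness of the analysis operators* — counting, clustering, solving,
normalizing — under known ground truth.  They do not demonstrate anything
about real trajectories: quantities that depend on real MD sampling (RMSD
plateaus, the specific per-site gating-charge steps of a real filter,
event counts of a particular simulation, which residues bind lipid) are
outside what the synthetic systems can establish, and the corresponding
tests check structural properties (telescoping, conservation, oracle
agreement) instead.

## Problem sizes

Default grids are a few tens of voxels per axis (24×24×60 Å at 1.5 Å);
scripted trajectories are 80–200 frames with ≤ 10 tracked particles; the
toy bilayer is ~100 frames × ~44 atoms.  These sizes keep every analysis
and the full test suite in the seconds range on one CPU while leaving all
code paths identical to production use on real trajectories.

## Known limitations

- Orthorhombic boxes only; no Poisson–Boltzmann dielectrics or Ewald
  forces — the solver maps voltage, it does not compute energies.
- The permeation counter assumes labels from oriented frames; it does not
  itself periodic-unwrap (use `unwrap_z` first for wrapped traces).
- DBSCAN defaults are tuned for the two-state carbonyl problem, not for
  arbitrary descriptor clouds.
- The config runner executes stages sequentially; no workflow-engine or
  cluster integration.
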