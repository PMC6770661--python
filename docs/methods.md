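# Methods

## Coordinate and numbering conventions

All coordinates are in ångström; GRO nanometres are converted on read.
Residue numbering is always the author numbering of the input file (for
CYPs, the 1-based UniProt-aligned numbering); nothing renumbers. Only
orthorhombic boxes are supported — the slab geometries this package targets
are orthorhombic, and triclinic input is rejected explicitly rather than
silently mishandled. "Backbone particles" are particles whose atom name is
in a configurable set (default `{CA, BB}`), so coarse-grained bead models
and atomistic models go through identical code paths.

The membrane normal is the +z axis. The z axis is oriented so that the
globular-domain CoM lies above the bilayer CoM; frames violating the
convention are mirrored in z and the flip is logged in the series
attributes and the run manifest. This makes the unfolded α/β angles
comparable across inputs (class-B orientations have β well above 90°,
which a folded convention would destroy).

## Orientation observables

α and β are the unfolded angles in [0°, 180°] between the membrane normal
and the v1 (I-helix) and v2 (C-helix→F-helix) vectors, each vector taken
between the centres of mass of terminal four-residue groups of backbone
particles. γ (TM tilt) and the heme tilt are folded to [0°, 90°]: a helix
axis and a plane carry no head/tail distinction.

The heme tilt is defined from the four pyrrole nitrogens coordinating the
iron. Their best-fit plane is computed by least squares (smallest singular
vector of the centred coordinates) rather than from a cross product of two
diagonals: for a near-planar heme the difference is negligible, and least
squares remains well defined for thermally distorted input. The reported
angle is the plane–line angle |90° − fold(∠(n̂, ẑ))|; a heme lying flat in
the membrane plane scores 90°, an upright heme 0°. This convention
reproduces the ranges reported for membrane-bound CYPs (≈30–45° for the
class-A regime, ≈55–75° for class B and for database-predicted
orientations, see `membpos.refdata.heme_tilt_comparison()`).

Centre-of-mass weighting is uniform by default (appropriate for CG beads,
and the convention used for the reference observables); element-mass
weighting is available and inferred from atom names for atomistic input.
No minimal-image correction is applied inside the protein: frames are
assumed molecule-whole, as produced by standard trajectory
post-processing. The bilayer z-CoM uses raw z coordinates.

## Classification, summaries, convergence, representative frames

Orientation classes partition β: A below 125°, A/B in the closed interval
[125°, 130°], B above 130°. The boundaries are inclusive into A/B because
the class-A definition is strict ("below 125°"), so ties belong to the
intermediate class. Thresholds are configurable for reuse with other
proteins.

Summaries report sample mean and SD per field over a strided window; the
default window is the last 90 % of the series, mirroring the practice of
summarising long production runs over their converged tail, and the class
is assigned from the mean β.

Convergence ("no further significant change in the orientation") has no
universal quantitative test, so this package defines one and keeps every
part configurable: the series is tiled into non-overlapping windows
aligned with the final window (default size: 10 % of the series), and the
converged region extends backwards for as long as every window mean of
every monitored field (default {β, d_globular}) lies within tolerance of
the final window's mean (defaults: 2° for angles, 1 Å for distances —
the scale of converged-run standard deviations). A partial leading window
is included, so a fully stationary series converges from frame 0; at
least two windows must agree, so a monotone drift spanning the whole
series is "not converged". Aligning windows with the end of the series
(rather than scanning every start frame) quantises the reported start to
window boundaries but prevents windows straddling the tail of a smooth
drift from triggering early; on a drift-then-hold protocol the reported
start is never earlier than the end of the drift.

The representative frame — the frame a multiscale protocol would hand to
back-mapping — must have every monitored value (default
{α, β, γ, d_globular, d_fg}) within 1 % relative deviation of its
converged-window mean; among qualifying frames the one minimising the
maximum relative deviation is returned, and when none qualifies the
minimiser is returned with a warning flag (also recorded in the run
manifest). Heme tilt is excluded from the default convergence and
representative sets because coarse-grained models typically carry no heme.

## Contact occupancy

A residue counts as contacting the head (tail) region in a frame iff any
of its particles lies within the cutoff (default 5 Å) of any lipid head
(tail) particle. Head defaults to the phosphate group
(`{P, O11, O12, O13, O14, PO4}`); tail names are configured per force
field; choline and glycerol atoms belong to neither set by default since
the head-contact definition here is the phosphate. Hydrogens are excluded
by default for atomistic input (the cutoff is calibrated on heavy atoms);
this is switchable because conventions differ. The minimal-image
convention is applied in x and y only: the membrane is periodic in-plane
while the protein never wraps in z in slab systems. The occupancy
denominator is the number of analysed frames after windowing and striding.
The implementation is a vectorised all-pairs distance computation; tests
pin it to exact equality with a scalar brute-force oracle, so any future
acceleration structure must not change results.

## Structural stability

Superposition uses the optimal least-squares rigid fit (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`); the returned RMSD is
minimal over all rigid transforms and never exceeds the unfitted RMSD.
B-factors are computed per selected atom from fluctuations about the mean
structure of a pre-superposed trajectory, B = (8π²/3)·⟨|r − ⟨r⟩|²⟩, and
averaged per residue. For isotropic Gaussian jitter of width σ this
converges to 8π²σ², which the tests verify to 5 %.

## Sequence comparison

Equal-length isoform pairs (the CYP 2C9/2C19 pair is 490 + 490 residues)
are compared positionally, gap-free; that mode reproduces the reported
91.2 % identity for the pair. Unequal-length pairs use a BLOSUM62 global
alignment with affine gaps (open 10, extend 0.5), and the identity
denominator is the full alignment length including gapped columns — the
conservative convention, stated explicitly because reported identity
figures rarely state theirs. The comparison mode is recorded in CLI output
metadata. Difference reports list mismatches as `X<pos>Y` substitution
strings and can be restricted to positions or ranges (e.g. the
membrane-interface set {46, 72, 73, 99, 220, 221}).

Because the real UniProt entries cannot be bundled, the package generates
a deterministic *synthetic* isoform pair
(`membpos.synthetic.synthetic_isoform_pair`): two 490-residue sequences
differing at exactly 43 positions (91.2 % positional identity) with the
six membrane-interface substitutions (G46D, K72E, P73R, I99H, S220P,
P221T) and the two active-site ones (L208V, L362I) pinned at their
canonical positions and the remaining 35 differences placed by a fixed
seeded draw. It exercises the comparison machinery end to end; it is not
the real sequences, and real FASTA input flows through the same API.

## The synthetic generator

The generator emulates the geometry — not the physics — of a
CYP–bilayer system: a rigid body with an I-helix (residues 110–125 of the
compact layout), C/F-helix stubs (60–67, 80–87), an F′–G′ cluster
(95–102), globular filler on a deterministic spiral (so the domain has
bulk), a TM helix (3–21), a linker (22–49), and a planar four-nitrogen
pseudo-heme; and a two-leaflet pseudo-bilayer on a square grid (head PO4
beads at z = ±19 Å — the POPC half-thickness — and two tail beads per
site at 6 and 12 Å below each head plane, mirror-symmetric so the bilayer
z-CoM is exactly 0).

Poses are solved in closed form. The body frame fixes v1 = +z and v2 at a
constant angle δ to it (default 80°). Given targets (α, β), the lab
directions are a₁ = (sin α, 0, cos α) and a₂ solved from a₂·ẑ = cos β,
a₁·a₂ = cos δ; the target is feasible iff the spherical triangle
inequality |α − δ| ≤ β ≤ min(α + δ, 360° − α − δ) holds, and infeasible
requests raise an error quoting the feasible β interval. δ = 80° was
chosen once so the entire recovery grid α ∈ [70°, 110°] × β ∈ [100°, 150°]
is feasible; it is a generator parameter, not a claim about CYP anatomy.
The TM direction and heme-plane normal are then placed in the body frame
as R⁻¹ of lab directions with the target γ and tilt, so all four angles
are met simultaneously by one rigid pose.

Ground truth is computed by closed-form transformation of the stored body
vectors — a code path independent of the analysis kernels — so recovery
tests are not self-fulfilling. Drift between two orientations uses
spherical interpolation (every intermediate frame is a rigid pose) up to
the switch frame, then holds; positional noise is isotropic Gaussian
jitter applied to every particle; all randomness flows from a single
seeded generator recorded in the output, and identical specs emit
bit-identical trajectories.

What the generator does **not** emulate — and hence what passing recovery
tests do and do not show: there are no lipid dynamics, no elastic
deformation of the protein, no membrane insertion thermodynamics, no
force field. Recovery tests certify that the geometric constructions are
exact and noise-robust on rigid poses; they say nothing about whether a
particular force field or sampling protocol produces correct orientations
for real proteins.

## Problem sizes and numerical choices

Test and acceptance runs use compact systems chosen for fast, fully
deterministic verification: a 4×4 to 8×8 lipid grid, ~160 protein beads,
5–1000 frames. At 0.5 Å per-particle jitter the terminal four-residue CoM
noise is ≈0.25 Å on vectors ≥18 Å long, so per-frame angular noise is
below ~1.5° and 1000-frame means recover β to well under 1°; the
acceptance script reports the measured maximum over three seeds.
Degenerate inputs fail loudly: empty particle sets, zero orientation
vectors, collinear heme nitrogens, fewer than 2×4 residues in an axis
range, overlapping head/tail name sets, and heme selections not matching
exactly four particles all raise typed errors. Angle arccos arguments are
clipped to [−1, 1] to absorb rounding.

## Known limitations

- Trajectories are held in memory; multi-microsecond atomistic
  trajectories should be strided or windowed on read (binary formats
  arrive via adapters, which can stream).
- The convergence test compares windowed means only; a field whose mean is
  stable but whose variance grows would still count as converged.
- Contact occupancy is binary per residue and frame; it does not resolve
  per-lipid residence times or hydrogen-bond geometry.
- The pipeline analyses one replica at a time; pooling across replicas is
  the caller's concern (means/SDs can be pooled from the summary TSVs).
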