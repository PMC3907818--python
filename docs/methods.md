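# Methods

This note records the definitions, conventions and numerical choices the
package commits to, and what its validation on synthetic data does and
does not establish about real trajectories.

## Units, numbering and data model

Lengths are nm, times ps, angles degrees. PDB files (Å) are converted on
read/write; PDB stores three decimals in Å, so a file round-trip quantizes
coordinates to 1e-4 nm. Residue numbers are taken verbatim from the input
and never renumbered — antibody constant-domain work uses Eu numbering, and
the default loop ranges (AB 358–362, CD 383–391, EF 413–422) assume it.
Segment classes (protein / glycan / solvent / ion) are inferred from
configurable residue-name lists (HOH/SOL/WAT → solvent, NAG/MAN/FUC/BMA/…
→ glycan, NA/CL/… → ion); glycan residues are additionally numbered per
chain in order of appearance, mirroring attachment order. Bonds are read
from CONECT records; torsion terms always come from a supplied TSV table,
never derived from chemistry. A frame without box information simply
disables the periodicity analysis for that frame instead of failing, so
vacuum toy systems analyse cleanly.

## Superposition statistics

The roto-translational fit is the Kabsch SVD algorithm with reflection
correction (the returned rotation always has det = +1), with optional
per-point weights. Collinearity is detected from the second singular value
of the cross-covariance. RMSD series fit every frame to frame 0 on the fit
selection and evaluate on the calculation selection; frame 0 is exactly 0.
RMSF uses the mean position of the *fitted* trajectory as the reference
(the standard definition), not frame 0. The radius of gyration is
mass-weighted by default, matching the convention of the common MD
analysis suites, with a unit-weight option.

A caution the test suite encodes: when the fit selection itself carries the
noise being measured, the superposition absorbs part of it (a factor
√(1 − 6/3N) on average, unevenly distributed toward peripheral atoms), so
the analytic RMSF limit σ√3 is only reached when fitting on atoms that do
not fluctuate. The generator provides such anchors.

## Hydrogen bonds

Criteria: H···A distance ≤ 0.25 nm and D–H–A angle ≥ 135°, both inclusive,
with the hydrogen at the angle vertex so 180° is a linear bond — the only
reading under which "minimum angle" admits near-linear geometry. Each
(D, H, A) triplet is unique; two hydrogens on one donor give two distinct
triplets. Candidate donors are N/O atoms with a bonded hydrogen (donors
without one — united-atom inputs — are skipped with a warning), acceptors
are N/O. Prevalence is the percentage of frames satisfying the criteria;
triplets never observed are omitted. Aggregation over groups sums
prevalences of records whose donor side lies in one group and acceptor in
the other, counted once per record in either orientation, so group totals
exceed 100% by design.

## Dihedral transitions

Torsional maxima of V(φ) = K[1 + cos(mφ − δ)] are φ = (δ + 360°k)/m; K ≤ 0
is rejected. Between consecutive snapshots the angle is assumed to move
along the shortest arc (a step of exactly 180° resolves in the positive
direction); every maximum strictly inside the arc counts once, and
multiple terms on one quadruple contribute the union of their maxima. A
sample landing exactly on a maximum opens a *pending* crossing that is
realized only when the angle departs to the side opposite its approach —
this prevents double counting when a boundary value is sampled repeatedly,
and makes the count invariant under 10× dense resampling of a continuous
path (a property the tests enforce).

## Orientation descriptors

A domain is summarized by its center of geometry and the unit eigenvector
of the largest eigenvalue of the positional covariance matrix of its
backbone selection. A (near-)degenerate leading eigenvalue is an error
reporting the eigengap, since the axis is then meaningless. Eigenvector
sign is fixed by continuity with the previous frame; on the first frame the
largest-magnitude component is made positive. Descriptor time series are
therefore comparable across runs only up to a global sign per axis — an
intrinsic ambiguity of covariance eigenvectors, not an implementation
choice.

The pseudo-dihedral of a domain pair is the torsion of the two axes about
the center-to-center line, realized as the dihedral of the four points
(c₁+a₁, c₁, c₂, c₂+a₂). This is the unique well-defined construction
using exactly the two named vectors and two centers; an axis parallel to
the center line (within 1e-6) is an error. The standard descriptor set
A–H pairs the four domains of a two-chain construct: A–D are axis angles
(CH2A–CH3A, CH2B–CH3B, CH2A–CH2B, CH3A–CH3B), E–H the corresponding
torsions.

## Periodicity check

For rectangular boxes, the minimum over all solute atom pairs (including
self-pairs) of the distance to the nearest *nonzero* periodic image, over
the 26 neighbor images — sufficient whenever the cutoff is below half the
smallest box edge, which is checked and warned otherwise. The contact flag
is `min_image_distance < cutoff` (default 1.4 nm, the long-range
interaction cutoff): a solute closer than the cutoff to its own image can
interact with itself across the boundary.

## SASA

Shrake–Rupley with a deterministic golden-spiral lattice (default 960
points, probe 0.14 nm), so repeated runs are bitwise identical. Radii are
the Bondi element-wise set, supplied as an overridable table; hydrogens
default to zero radius (united-atom convention) and zero-radius atoms
neither contribute nor occlude. A lattice point is buried when strictly
inside another selected atom's probe-inflated sphere; points exactly on a
neighbor's surface are buried only for the later atom of the pair, so
exactly coincident atoms contribute the area of one sphere rather than two
or zero. Interface areas are per-monomer differences, SASA(alone) −
SASA(in complex), floored at zero per atom against sampling noise. No
analytic (Lee–Richards) variant is provided; an independent dense
latitude–longitude quadrature serves as the cross-check in the tests.

## Synthetic generator

The generator emulates the *kinematics* of a glycosylated two-chain
Fc-like construct — no force field, solvent or energetics; ground truth is
exact by construction:

- **Domains.** Each chain has a CH2 and CH3 domain of 13 beads placed on a
  rigid template symmetric about the domain center with three distinct
  covariance eigenvalues, so the leading principal axis is exactly the
  template's long axis. Three extra beads per CH3 sit at loop residues
  360/387/417. Real domains have ~110 residues; with only 13 beads the
  principal axis is ~3× more sensitive to coordinate noise than it would
  be on real data, which is why the noisy-recovery tolerance (3° at
  σ = 0.02 nm) is looser than the noise-free one (exact).
- **Angle schedule.** The CH3A/CH3B axes realize a prescribed inter-axis
  angle D(t) and twist T(t) in closed form: with the center line along x,
  axis i = (cos ψᵢ, sin ψᵢ cos φᵢ, sin ψᵢ sin φᵢ), the twist is φ₁ − φ₂
  and the angle follows from the dot product; choosing the azimuths ±T/2
  and the polar angles symmetrically about 90° (or equal, for D < |T|)
  covers every (D, T) combination. Defaults sweep 30°→60° and 0°→90°
  linearly. CH2 axes are constant; all eight descriptors are recorded in
  the ground truth from the constructed axes via independent closed-form
  expressions (dot products and a projection/atan2 torsion), not via the
  analysis code.
- **Hydrogen bonds.** Three cross-chain N–H···O sites (defaults 47%, 80%,
  100%) in geometrically isolated pockets, placed at (0.20 nm, 170°) when
  on and (0.40 nm, 170°) when off. On-frames are a deterministic Bresenham
  spread of round(p·n/100) frames, so the realized prevalence is exact
  whenever p·n/100 is integral (the default n = 200 makes 47% exact).
- **Dihedrals.** Two glycan-like linkages: a monotone sweep in 2.4° steps
  starting at −150° (samples stay ≥ 1.2° from every multiple of 120°, so
  counts survive PDB round-off) against an m = 3 term, and a 171–191°
  triangle wave crossing the 180° maximum of an m = 2 term. Intended
  counts come from enumerating level crossings of the designed continuous
  path.
- **Noise.** Gaussian σ per coordinate on domain and loop beads only;
  planned hydrogen-bond and dihedral atoms are exempt so their ground
  truth stays exact rather than statistical. Default σ = 0: the standard
  dataset is the noise-free configuration in which every analysis must
  recover ground truth exactly. A single `numpy.random.default_rng(seed)`
  drives all randomness; no global state.
- **Box.** Default (12 nm)³, comfortably larger than the solute, so the
  standard dataset has no periodic contact and the CH3 domains are in the
  "separated" burial regime (interface exactly zero on domain residues).
  Smaller boxes and closer domains are exercised by dedicated tests.

What passing on this generator shows: the geometric definitions,
conventions and bookkeeping of every analysis are correct, to exactness
where the input is exact. What it does not show: behaviour on dense
all-atom packing, on non-rigid domains, under force-field physics, or the
statistical properties of real thermal motion beyond isotropic Gaussian
noise.

## Pipeline and problem sizes

The pipeline subsamples to 2 ps (the generator writes frames 2 ps apart,
so subsampling is the identity on its output), validates configuration
before computing (e.g. dihedral analysis without torsion terms fails up
front), and writes fixed-format TSV so identical inputs give byte-identical
outputs; partial outputs are removed on error. Reports carry a manifest
with the config hash and input checksums.

Default validation sizes were chosen to keep the full suite fast while
leaving no statistical test marginal: 200-frame end-to-end datasets,
2000 frames for the RMSF noise limit, 100 random 50-atom frames for the
hydrogen-bond brute-force comparison, 50 random paths of 41 samples for
transition counting, 960 lattice points (vs. a 320 000-point quadrature
oracle) for SASA.

## Known limitations

- Rectangular boxes only; no triclinic cells or Ewald-style image sums.
- Multi-model PDB is the only trajectory format wired in; PDB carries no
  time stamps, so frame times are reconstructed from a user-supplied
  spacing.
- Prevalence aggregation reports both triplets when a donor has two
  hydrogens to the same acceptor; whether that should collapse to one
  "pair of distinct atoms" is convention-dependent, and summation over
  triplets was chosen as the stricter bookkeeping.
- Per-residue RMSF averages the backbone atoms of each residue; with
  one-bead-per-residue toys this is the identity.
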