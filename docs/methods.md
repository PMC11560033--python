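# Methods

## Scope and model

The package reimplements, at desk scale, the analysis layer of a
steered-MD study of GPCR mechanosensitivity: helix-orientation
quaternions, conformational-state classification, lateral-pressure-profile
processing, membrane property measures, protein cross-section profiles,
the work-against-lateral-pressure integral, and lipid–receptor contact
detection. It does **not** run molecular dynamics: coordinates come either
from multi-model PDB files standing in for trajectory snapshots or from
the synthetic generators, and pressure tensors come from a documented TSV
emulating an MD engine's per-slab pressure-profile output.

Coordinate conventions throughout: z is the membrane normal, the bilayer
center is z = 0 and the intracellular side is positive z. Working units
are Å, bar, ns, degrees, kcal/mol and dyn/cm; the two conversion constants
(1 bar·Å = 0.01 dyn/cm, 1 bar·Å³ = 1.4393 × 10⁻⁵ kcal/mol) are
centralized in `gpcrmech.units`.

## Helix axes and quaternions

The helix axis is computed from bond-bisector geometry: for consecutive
Cα positions the second differences h_i = (P_{i+2} − P_{i+1}) − (P_{i+1} −
P_i) point radially toward the axis, so each cross product h_i × h_{i+1}
lies along it; their sum is exact for an ideal helix and averages out
noise for a distorted one. A principal-component fit was considered and
rejected: on a 17-residue ideal helix (≈ 4.7 turns) the unbalanced helical
phase tilts the PCA axis by ~0.03 rad-equivalents, an order of magnitude
above the 10⁻³ agreement the bisector construction achieves. The sign is
fixed N-terminus → C-terminus. At least 5 Cα positions are required
(fewer leave no cross term).

The reorientation between two axes a, b is the quaternion with axis
(a × b)/‖a × b‖ and angle atan2(‖a × b‖, a·b); the scalar part is kept
non-negative so θ ∈ [0°, 180°]. Parallel axes give the identity;
antiparallel axes give a 180° turn about a deterministic perpendicular
(the canonical basis vector of smallest index, orthogonalized), chosen for
reproducibility. Orientation interpolation is spherical (linear in angle
about the fixed axis), which is what a moving steering target needs.

The default moving segment for TM6 is BW 6.32–6.48 and the default marker
residues are 3.50/6.34/7.55 (helix distances) and 7.56 (internal-lipid
reference); all are configurable through the BW anchor table
(N46/D74/R126/W153/P207/P255/P299 for the AT1 model, H8 numbered by offset
from 7.50).

## Toy steering simulator

The restraint is harmonic in the relative rotation angle,
U = ½·k·θ_dev², the simplest form consistent with the printed
rad²→deg² force-constant conversion (whether the original engine restrains
θ_dev or 1 − |q·q_target| is not documented; the choice is recorded here).
Dynamics are single-angle overdamped Langevin along the geodesic toward
the moving target:

    dθ = −(k/γ)(θ − θ_target(t)) dt + √(2D dt) ξ

with stiffness k (kcal/(mol·deg²)), friction γ (kcal·ns/(mol·deg²)) and
angular diffusivity D (deg²/ns). The deterministic limit has a closed-form
tracking lag γ·v/k for a ramp of rate v, which the tests pin to 1%.
Defaults (k = 1.523, γ = 2.6, D = 2.0, dt = 0.01 ns) are chosen so the
20 ns, 35° ramp is well resolved and the realized end-of-pull angle sits a
few degrees under the target (≈ 32°), the qualitative behaviour of the
full simulations. Explicit integration requires k·dt/γ ≤ 0.5; larger
steps are rejected. The companion restraint holding TM3 at (1,0,0,0) is
represented by the fixed laboratory frame and not simulated.

## Conformational states

Classification uses the TM3–TM7 Cα distance averaged over the analysis
window (default: the last 30 ns of a 90 ns run), not a per-frame majority.
Intervals are half-open and closed on the lower edge: [0,16) pre-active,
[16,19) non-canonical, [19,∞) atypical; heatmap bins split the atypical
range at 21 Å into green (inactive-like) and yellow (outward TM7). The
equality convention at 19 Å follows the "equal to or larger than the
inactive distance" reading of the atypical criterion. Heatmap bins are
serialized as integers 0–3 with a legend header so plotting stays
decoupled.

## Lateral pressure profiles

π(z,t) = (pxx + pyy)/2 − pzz per slab, in bar. Input is a TSV
(time, slab_index, pxx, pyy, pzz) with a sidecar (time, Lz, z_P) rather
than any engine-native log; the cell height Lz is bookkeeping for the
surface-tension relation γ = Lz(Pz − PT), not a normalization of π.
Drift correction shifts each instantaneous profile so the phosphorus
barycenter z_P(t) maps to z = 0, resampling by linear interpolation onto
the fixed grid (nearest-slab shifting is available behind a flag); time
averaging starts at t_min = 20 ns by default (box stabilization), and the
final curve is smoothed with a 3-point running mean whose endpoints
average the two available points.

Bilayer thickness is the peak-to-peak distance of the pooled phosphorus z
histogram, 0.5 Å bins by default, with parabolic refinement of the top
bin per leaflet; unimodal distributions are rejected. Area per lipid in
the presence of the protein is (cell area − protein cross-section)/n per
leaflet. The order parameter S_CH consumes explicit C–H unit vectors, so
synthetic chains are orientation distributions rather than atomistic
tails.

## Cross-section areas and the work integral

A(z) is computed per 0.2 Å slab as the area of the union of disks cut
from atomic van der Waals spheres (H 1.2, C 1.7, N 1.55, O 1.52, S 1.8,
P 1.8 Å; configurable) at the slab-center plane, evaluated on a 2-D
occupancy grid (0.1 Å default). The disk radius is the sphere's
cross-section at the slab center, appropriate for slabs thin relative to
atomic radii. The grid estimator is validated against analytic disk areas
and a Monte-Carlo union oracle to 1–2%; any constant offset relative to
other area definitions cancels in the difference δA(z).

W = ∫ δA(z)·π(z) dz is a trapezoidal integral over a common grid
(pressure linearly resampled), converted bar·Å³ → kcal/mol. The reference
conformational change — a 50 Ų mean area increase over the intracellular
0–20 Å band, i.e. a 1000 Å³ volume — against profiles with
few-hundred-bar peaks yields work in the low-kcal/mol range, matching the
scale on which membrane composition and applied tension act.

## Contacts

H-bonds use donor–acceptor heavy-atom distance ≤ 3.5 Å and an H–D–A angle
≤ 30° (the convention of the analysis tool the cutoffs come from), with a
10⁻⁹ tolerance so exact-boundary geometries count as bonded. Counting is
per donor-atom/acceptor-atom pair (a residue making two simultaneous
bonds counts twice); positions with missing side-chain donors are skipped
with a warning. Donor atoms are the side-chain N–H groups of Lys/Arg;
acceptors are phosphate and glycerol/ester oxygens of PC/PG heads
(configurable name lists).

A lipid of the intracellular leaflet is *internal* when its phosphorus P
satisfies, strictly: d(P, Cα3.50) < 15 Å, d(P, Cα7.56) < 12 Å, and both
distances < d(Cα3.50, Cα7.56) (the last pair excludes external lipids
near the TM5–TM6 cleft). Equality at any cutoff → not internal. The
per-trajectory summary is the fraction of frames with ≥ 1 internal lipid.

## Synthetic data

The generators encode geometric/statistical structure only — no
force-field energetics, no acyl-chain conformers. Defaults are the study
conditions: a 35° TM6 opening scheduled linearly over 20 ns then held
through 70 ns of relaxation, sampled as 12 equidistant snapshots
(Δt = 7.5 ns); initial d₃₆ = 8 Å and d₃₇ = 20 Å (the inactive value);
leaflet separation 38.8 Å; a 9:1 PC:PG head-group mix; 100 pressure slabs
over a 100 Å box with ±500/−400 bar Gaussian head/interface peaks, 50 bar
white noise. Reduced scale (30 lipids per leaflet rather than 60, and
12–100 frames) keeps every test in seconds while preserving the slab
count and window structure of the real analysis.

The toy receptor places seven ideal helices (rise 1.5 Å, twist 100°,
radius 2.3 Å) on a circle, aligns the marker Cαs on one z plane and
translates helices 6 and 7 rigidly so the marker distances equal the
requested d₃₆/d₃₇ exactly. TM6 opening is a rigid rotation of the
6.32–6.48 segment about a hinge at 6.48, about an in-plane axis
perpendicular to the radial direction, so measuring the segment axis
recovers the programmed θ(t) exactly; TM7 scenarios translate helix 7 so
d₃₇(t) ramps linearly to its target over 60 ns and holds. The
internal-lipid program reserves one intracellular-leaflet PG lipid and
places its head at the cavity midpoint (internal) or far outside
(external) in a programmed fraction of frames.

What passing tests show — and what they do not: round-trip recovery
demonstrates that the measurement operators invert the generators within
stated tolerances under controlled noise; it does not validate force
fields, sampling convergence, or any biological conclusion from μs-scale
simulation campaigns, whose state populations and H-bond statistics are
not reproducible at this scale.

## Statistics

"Student's t-test" is implemented as Welch's unequal-variance variant
(equal-variance pooling available behind a flag) since replica groups are
small with unequal spread. The Wilcoxon rank-sum test enumerates all
labelings exactly for pooled n ≤ 12 and otherwise uses the normal
approximation with tie correction. Two grouping granularities are
supported (per replica, or per starting snapshot). No multiple-testing
correction is applied; p-values are reported raw, and output files record
the seed.

## Numerical choices and limitations

* PDB coordinates round-trip at the format's 0.001 Å precision; 4-letter
  lipid residue names are stored in files under 3-letter codes (PPC/DPC/
  PPG/DPG) to stay within the strict PDB field width and restored on read.
* Range masks on z grids carry a 10⁻⁹ edge tolerance so accumulated
  floating-point error in `arange` grids cannot drop an endpoint slab.
* The multi-model reader validates per-model atom counts up front and
  names the offending model; parse errors surface the underlying reader's
  message.
* Degenerate inputs (collinear Cα sets, unimodal phosphorus
  distributions, empty analysis windows, unstable integrator steps,
  non-positive distances) raise with specific messages rather than
  propagating NaNs.
* The acceptance script and the analysis drivers use reduced problem
  sizes (12–40 frames, 200–500 pressure time points, 10–30 lipids per
  leaflet) chosen to keep each stage in seconds; all are config-exposed.
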