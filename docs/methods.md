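# Methods

This note documents the models, estimators and numerical choices behind each
analysis stage, what the synthetic-data generators do and do not emulate, and
the design decisions taken where more than one reasonable definition exists.

## Coordinate frame and channel alignment

All analyses run in the channel frame: barrel centroid at the origin, barrel
axis along z, the N-/C-terminus side on positive z. Coordinates are carried in
Å and energies in kcal/mol throughout; conversions to nm appear only in
reported tables (axis means, integrated ΔG).

The barrel axis is estimated from the positional covariance of the selected
barrel Cα atoms. A cylindrical Cα shell has two nearly equal in-plane
eigenvalues (≈ R²/2) and one distinct axial eigenvalue (≈ H²/12), so the axis
is taken as the eigenvector whose eigenvalue is most separated from the other
two — the smallest for a flat ring, the largest for a barrel taller than its
radius. Two refinements matter in practice:

* **Reference axis from the trajectory mean.** Per-frame eigenvalue gaps can
  momentarily invert during a large breathing excursion (the in-plane split
  exceeding the axial gap), which would swap the axis onto an in-plane
  eigenvector for isolated frames. The axis label is therefore fixed once from
  the trajectory-averaged covariance, and each frame uses its eigenvector most
  parallel to that reference.
* **Minimal (geodesic) rotation, no in-plane spin.** The rotation taking the
  axis onto the nearer pole is the smallest rotation doing so. Using in-plane
  covariance eigenvectors to fix the x/y orientation is unstable — they flip
  by 90° whenever breathing swaps the long and short diameters — and any
  per-frame in-plane spin scrambles displacement correlation maps. If the
  terminus marker ends up on −z, a fixed 180° rotation about x (not a
  wobble-dependent geodesic) flips it up, keeping frame-to-frame orientation
  deterministic. Alignment is idempotent to ~1e−13 Å and exactly rigid.

A collinear barrel selection (no in-plane extent) raises an alignment error.

## Lumen radius profile

For each 0.5 Å slab normal to z, every atom whose probe-inflated sphere
(van der Waals radius + 1.4 Å probe) intersects the slab contributes a 2D disk
of its full inflated radius. The accessible cross-section is the connected
free region around the pore axis on a 2D grid (0.1 Å default spacing,
flood-filled from the axis with `scipy.ndimage.label`), and the effective
radius is √(area/π). Slices whose free region reaches the grid boundary — no
enclosing wall — are reported at the configurable cap (20 Å default) and
flagged unbounded rather than given a misleading number. Van der Waals radii
are the Bondi values with a 1.7 Å fallback for unlisted elements.

The estimator agrees with an independent flood-fill oracle to the grid
resolution and reproduces closed forms on analytic fixtures (circular ring:
R − r_vdW − r_probe; reduced ellipse: √(a′b′)). Note the accessible area of a
crevicked wall can legitimately exceed the inscribed-disk area, so the
"radius never exceeds the nearest-wall distance" sanity bound applies to
sealed, convex-ish lumens only.

## Breathing axes and correlation maps

Cross-barrel axis lengths are per-frame Cα–Cα distances for configured residue
pairs (defaults: the diameters along and perpendicular to the N-terminal
direction, at z ≈ −8, 0, +8 Å — the exact residues behind the published axis
choices are not specified, so these pairs are configuration, not constants).
Axis distributions are pooled over replicas and normalised to unit integral;
means are reported in Å and nm.

The correlation map is the standard normalised covariance of Cα displacement
vectors about their time means, computed per replica and averaged. Zero-
variance residues give NaN entries (flagged undefined) rather than a value.
Anti-correlation axes are identified exactly as in the breathing analysis: the
barrel residue most positively correlated with the start (anchored end) of the
N-terminal fragment, paired with its minimum-correlation partner on the
opposite wall (longitudinal); the same construction seeded from the central
N-terminal residues gives the transversal axis. Ties break to the lower
residue index. On synthetic barrels with planted anti-phase diameters the
recovered pairs lie on the planted diameters to within one strand spacing.

## Secondary structure and hydrogen bonds

The classifier is a minimal DSSP-style pattern matcher. A helical turn of span
n exists at residue i when the carbonyl O of i accepts the amide H of i+n
under the H-bond criterion; two consecutive i→i+4 turns label residues
i+1…i+4 α-helical, two consecutive i→i+3 turns label i+1…i+3 3₁₀, and α takes
precedence where both patterns hold. Everything else is unordered. The
three per-state fractions sum to one exactly per residue per replica.

The H-bond criterion is donor–acceptor heavy-atom distance ≤ 3.5 Å and a
D–H···A deviation from linearity ≤ 30°. These are package defaults (exposed in
configuration), chosen as conventional values; occurrence tables report the
percentage of frames a bond is present, per replica, then mean ± sample (n−1)
standard deviation across replicas — the replica convention used everywhere.
The table filter keeps bonds whose replica-mean occurrence exceeds the
threshold (20% default); the alternative of pooling frames before
thresholding would keep marginally different bond sets near the cutoff.
Amide hydrogens absent from the input are built at 1.01 Å from N along the
bisector of the N→C(prev) and N→Cα directions.

Ideal-helix fixtures are built by natural-extension-reference-frame chaining
from canonical dihedrals (α: φ=−57°, ψ=−47°; 3₁₀: φ=−49°, ψ=−26°; extended:
φ=ψ=180°) with ideal bond geometry; the α fixture shows the textbook 1.5 Å
rise per residue and both helical fixtures satisfy the default H-bond
criterion comfortably (3₁₀: d(N···O) ≈ 2.8 Å, deviation ≈ 7°).

## Ion statistics

The lumen is −18 ≤ z ≤ +18 Å (the bounds are dimensionless in the source
convention; they are treated as Å, consistent with a ~4 nm channel), with a
20 Å radial gate to exclude same-height ions outside the barrel. Selectivity
is the ratio of time-averaged Cl⁻ and K⁺ counts within each replica
(ratio-of-means; the mean-of-ratios alternative is a flag), reported
mean ± sd over replicas.

Translocation events use a crossing state machine: an ion that entered the
lumen through one boundary and next leaves through the opposite boundary
scores one event; re-exit through the entry boundary resets the state. The
entry frame is the first frame inside, the exit frame the last frame inside,
and the passage time (exit − entry) × timestep. A single step jumping across
the whole lumen scores an event of zero passage time; missing-position (NaN)
stretches reset the state. The implementation agrees exactly with an
independently formulated oracle on randomized walks.

The free-energy profile is the Boltzmann inversion ΔG(z) = −k_B T ln(ρ(z)/ρ_bulk)
with k_B = 0.0019872 kcal/(mol·K) and T = 300 K. ρ(z) is the per-frame number
density from time- and replica-pooled positions in 0.5 Å bins; ρ_bulk is the
mean density over the bins outside the pore region. Empty bins are masked
(never ±∞), and the lumen integral is trapezoidal over bin centers with the
half-bin margins closed by edge-value rectangles — exact for linear profiles
and yielding the full 3.6 nm width for constant ones. Per-bin cross-section
areas can be supplied when pore and reservoir geometry differ; with uniform
cross-sections they cancel in the density ratio.

## Ion-position clustering and lining residues

Clustering follows the greedy neighbour-count construction: count neighbours
within the 6.0 Å cutoff for every recorded position (the "RMSD" between two
single-ion positions reduces to their Euclidean distance), seed the first
cluster at the position with the most neighbours, remove it and its
neighbours, and repeat until the candidate cluster's occurrence
(population / total analysed frames) falls below the 10% minimum. Ties on the
neighbour count break to the lowest point index. Neighbour counts are
re-evaluated on the surviving pool each iteration with a fresh KD-tree
(`return_length` counting), which keeps memory flat for ~10⁵ pooled positions
while matching a brute-force O(n²) oracle exactly. Display filtering
(occurrence ≥ 20%) is a separate, independently configurable threshold with
the same frame-count denominator.

A charged residue lines a cluster when its charged-group centroid is within
5 Å (configurable; no published value exists) of any member position.
Per-cluster P/N counts are averaged per species and union-totalled with
de-duplication; residues lining clusters of both species go to the "both"
categories, so P_total = P_only + P_both holds as a set identity.

## Charge annotation and distribution maps

Lys → +1 at NZ, Arg → +1 at the guanidinium carbon CZ, Asp/Glu → −1 at the
carboxylate carbon, histidine and everything else neutral, termini uncharged.
Missing side chains fall back to Cβ (then Cα) with an explicit flag. A residue
is lumen-facing when its charged-group radial distance is below 85% of the
local barrel Cα radius at its z (configurable operationalisation of an
otherwise qualitative notion). ΔP_z is the signed histogram density along z
(Σ ΔP_z·Δz = N₊ − N₋ exactly when unsmoothed; optional Gaussian smoothing is
display-only), and ΔP_xy the signed 2D histogram whose cell sum equals the
signed mapped-residue count.

Hydropathy uses the Kyte–Doolittle scale with a 3-residue window weighted
(0.3, 1.0, 0.3)/1.6; termini drop the missing neighbour and renormalise the
weight sum. Profiles are min-max normalised to [0, 1] per profiled fragment,
with flat profiles flagged constant instead of divided by zero.

## Synthetic-data generators

The generators produce data with *planted, known* statistical structure at the
study conditions the analyses target; they are first-class, tested code.

**Pseudo-barrel with breathing.** 19 vertical strands of Cα pseudo-atoms on a
cylinder (radius 12.5 Å, height 36 Å — a ~2.5 nm-bore, ~4 nm-tall channel)
plus an interior 12-residue helical segment running along +x→−x near z = 0,
offset towards the −y wall like the wall-adhering N-terminal helix. Two
orthogonal diameters (longitudinal = x, along the helix; transversal = y) are
modulated by a stationary bivariate AR(1) process with configurable marginal
amplitudes (1 Å default), cross-correlation (−0.8 default, the anti-correlated
breathing of the strongly breathing isoforms) and lag-1 coefficient 0.5 — the
stored-frame spacing is comparable to the breathing correlation time, which
makes a 10⁴-frame sample recover a planted correlation to ±0.05 by standard
sampling theory. Atom positions scale as x → x(1 + u_L/2R), so the x-diameter
length is exactly 2R + u_L. The helix start rides the longitudinal mode and
the helix centre the transversal mode, emulating the anchored-start /
central-crossing geometry that the axis-identification procedure exploits.
A small isotropic jitter (0.05 Å) keeps every residue's variance positive.
About 20% of residues are given charged identities (Lys/Arg/Asp/Glu) so the
charge-annotation and lining stages operate on realistic inputs.

**Langevin ion tracks.** Overdamped dynamics
z ← z − (D/k_B T) U′(z) dt + √(2 D dt) ξ with D = 100 Å²/ns by default
(free-solution-like small-ion mobility), reflecting axial walls beyond the
reservoirs, radial harmonic confinement inside the pore and free diffusion in
a reflecting cylinder outside. The confinement stiffness defaults to
k_r = 2 k_B T/R², which makes the pore's effective cross-section
(2π k_B T/k_r) equal the reservoir area (πR²): the stationary axial marginal
is then exactly ∝ exp(−U/k_B T) with no geometric offset, so Boltzmann
inversion recovers the planted potential directly. Initial z positions are
drawn from the stationary Boltzmann density by inverse-CDF sampling, removing
the axial equilibration transient. The step-size precondition √(2 D dt) < 1 Å
is enforced. Axial potentials are piecewise (constant / harmonic / Gaussian
well / linear) with continuity checked at junctions to 1e−6 kcal/mol.

What the generators do **not** emulate: explicit water and lipids, ion–ion
electrostatics and ion pairing, transmembrane voltage, sequence-specific
side-chain packing, or the slow conformational drift of a real protein.
Passing recovery tests therefore demonstrates the correctness of the
estimators — not that a given force field or sampling protocol is adequate
for the real channel.

## Problem sizes and statistical tolerances

Recovery runs use 10⁶ recorded samples per condition, taken with a stride of
~24 steps from 100 independent ions over 480 ns of dynamics, with 28 Å
reservoirs and the bulk average taken over the whole region outside the pore
(|z| > 22 Å). The limiting error is the bulk-density estimate: for a
3 kcal/mol well nearly all ions sit in the well, the bulk holds only a few
ions at a time, and well↔bulk exchange is slow, so the recorded-sample budget
is spread over as much dynamics time and bulk volume as the conditions allow.
Under these settings the worst per-seed profile RMSD over the pore region is
≈ 0.08 kcal/mol at the hardest condition (3 kcal/mol well) across ten seeds
(bound asserted: 0.15).
Goodness-of-fit tests on Langevin output (χ² uniformity, KS against
exp(−U/k_B T)) thin samples to ≥ 20 ns spacing — the box-traversal diffusion
time — because their p-values assume independent draws.

Flat-potential translocation statistics use 100 ions × 300 ns per species:
~2,000 events per species, enough that the Cl/K ratio concentrates at
1.0 ± 0.1 and directional symmetry holds within 3√N.

## Known limitations

* PDB parsing targets conventional fixed-column ATOM/HETATM records; exotic
  dialects (hybrid-36 serials, multi-character chain IDs) are out of scope.
* The radius profile is a 2D slice construction, not a 3D spherical-probe
  pathfinder; tilted or baroque pore shapes read slightly differently.
* The secondary-structure classifier distinguishes only α / 3₁₀ / unordered;
  no π-helix, strand or turn states.
* Binary trajectory formats (DCD/XTC) are intentionally unsupported; convert
  to multi-model PDB or XYZ first.
* With a single replica, replica standard deviations are reported as 0 rather
  than NaN, and pooled and per-replica statistics coincide.
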